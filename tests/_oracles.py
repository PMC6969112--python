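"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive expected results through a different route than
the package: recursive symbolic expansion of the full probability tree for
inheritance cubes, direct combinatorics for Mendelian segregation, and
exhaustive enumeration of label assignments for the randomization tests.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

STATES = ("W", "T", "R", "B")


# ---------------------------------------------------------------------------
# Symbolic cube expansion
# ---------------------------------------------------------------------------

def _roles(arch):
    return list(arch.loci)


def _machinery(haps, arch) -> bool:
    cas9 = grna = False
    for h in haps:
        for i, role in enumerate(arch.loci):
            if h[i] == "T":
                if role in ("cas9_site", "fused_site"):
                    cas9 = True
                if role in ("grna_site", "fused_site"):
                    grna = True
    return cas9 and grna


def _germline_outcomes(haps, sex, arch, q, c, rho):
    """Recursively expand germline resolution; yields (haps, prob)."""
    results = {}

    def recurse(cur, prob, pending):
        if not pending:
            key = tuple(tuple(h) for h in cur)
            results[key] = results.get(key, 0.0) + prob
            return
        (hi, locus), rest = pending[0], pending[1:]
        qq = q[locus][0 if sex == "F" else 1]
        cc = c[locus][0 if sex == "F" else 1]
        for state, p in (
            ("W", 1 - qq),
            ("T", qq * cc),
            ("R", qq * (1 - cc) * rho),
            ("B", qq * (1 - cc) * (1 - rho)),
        ):
            if p == 0:
                continue
            nxt = [list(h) for h in cur]
            nxt[hi][locus] = state
            recurse(nxt, prob * p, rest)

    pending = []
    if len(haps) == 2 and _machinery(haps, arch):
        for hi in (0, 1):
            for locus in range(len(arch.loci)):
                if haps[hi][locus] == "W" and haps[1 - hi][locus] == "T":
                    pending.append((hi, locus))
    recurse([list(h) for h in haps], 1.0, pending)
    return results


def _gametes(haps, arch, hemizygous):
    if hemizygous:
        return {tuple(haps[0]): 0.5, "Y": 0.5}
    h1, h2 = haps
    if len(arch.loci) == 1:
        out = {}
        for h in (h1, h2):
            out[tuple(h)] = out.get(tuple(h), 0.0) + 0.5
        return out
    r = arch.recomb_fraction
    out = {}
    for h, p in (
        (tuple(h1), (1 - r) / 2),
        (tuple(h2), (1 - r) / 2),
        ((h1[0], h2[1]), r / 2),
        ((h2[0], h1[1]), r / 2),
    ):
        if p:
            out[h] = out.get(h, 0.0) + p
    return out


def _deposition_outcomes(haps, active, arch, d, rho):
    results = {}

    def recurse(cur, prob, pending):
        if not pending:
            key = tuple(tuple(h) for h in cur)
            results[key] = results.get(key, 0.0) + prob
            return
        (hi, locus), rest = pending[0], pending[1:]
        dd = d[locus]
        for state, p in (
            ("W", 1 - dd),
            ("R", dd * rho),
            ("B", dd * (1 - rho)),
        ):
            if p == 0:
                continue
            nxt = [list(h) for h in cur]
            nxt[hi][locus] = state
            recurse(nxt, prob * p, rest)

    pending = []
    if active:
        for hi, h in enumerate(haps):
            for locus in range(len(arch.loci)):
                if h[locus] == "W":
                    pending.append((hi, locus))
    recurse([list(h) for h in haps], 1.0, pending)
    return results


def oracle_offspring(mother_haps, father_haps, arch, q, c, d, rho):
    """Full symbolic expansion of one cross.

    Parameters are plain nested lists: ``q[locus] = (qF, qM)``, same for
    ``c``; ``d[locus]`` scalar.  ``father_haps`` has one haplotype for
    hemizygous X-linked males.  Returns ``{(sorted haps, sex): prob}`` with
    hemizygous sons keyed by a single haplotype.
    """
    x = arch.chromosome_type == "X"
    mg = {}
    for haps, p in _germline_outcomes(mother_haps, "F", arch, q, c, rho).items():
        for g, pg in _gametes(haps, arch, False).items():
            mg[g] = mg.get(g, 0.0) + p * pg
    father_hemi = x and len(father_haps) == 1
    fg = {}
    for haps, p in _germline_outcomes(father_haps, "M", arch, q, c, rho).items():
        for g, pg in _gametes(haps, arch, father_hemi).items():
            fg[g] = fg.get(g, 0.0) + p * pg
    active = _machinery(mother_haps, arch)
    out = {}
    for gm, pm in mg.items():
        for gf, pf in fg.items():
            base = pm * pf
            if gf == "Y":
                zygotes = [((gm,), "M", base)]
            elif x:
                zygotes = [((gm, gf), "F", base)]
            else:
                zygotes = [((gm, gf), "F", base / 2), ((gm, gf), "M", base / 2)]
            for haps, sex, p in zygotes:
                for final, pd in _deposition_outcomes(haps, active, arch, d, rho).items():
                    key = (tuple(sorted(final)), sex)
                    out[key] = out.get(key, 0.0) + p * pd
    return out


# ---------------------------------------------------------------------------
# Mendelian cube by direct combinatorics (no drive machinery at all)
# ---------------------------------------------------------------------------

def mendelian_offspring(mother_haps, father_haps, arch):
    return oracle_offspring(
        mother_haps,
        father_haps,
        arch,
        q=[(0.0, 0.0)] * len(arch.loci),
        c=[(0.0, 0.0)] * len(arch.loci),
        d=[0.0] * len(arch.loci),
        rho=1.0,
    )


# ---------------------------------------------------------------------------
# Exhaustive randomization enumeration
# ---------------------------------------------------------------------------

def exact_perm_mean_pvalue(a, b):
    """Exact two-sided permutation p for a difference in means.

    Enumerates all C(n, n_a) assignments of the pooled values to group A;
    returns the exact fraction of assignments at least as extreme as the
    observed difference (tie tolerance 1e-12).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n, n_a = len(pooled), len(a)
    obs = abs(sum(a) / n_a - sum(b) / len(b))
    total = extreme = 0
    for ix in itertools.combinations(range(n), n_a):
        ga = [pooled[i] for i in ix]
        gb = [pooled[i] for i in range(n) if i not in ix]
        d = abs(sum(ga) / len(ga) - sum(gb) / len(gb))
        total += 1
        if d >= obs - 1e-12:
            extreme += 1
    return extreme / total


def exact_perm_prop_pvalue(sa, ta, sb, tb):
    """Exact permutation p for a difference in proportions (hypergeometric)."""
    s = sa + sb
    n = ta + tb
    obs = abs(sa / ta - sb / tb)
    total = comb(n, ta)
    extreme = 0
    for k in range(max(0, s - tb), min(ta, s) + 1):
        d = abs(k / ta - (s - k) / tb)
        if d >= obs - 1e-12:
            extreme += comb(s, k) * comb(n - s, ta - k)
    return extreme / total
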