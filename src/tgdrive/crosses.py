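"""F0 -> F1 -> F2 cross simulation and analysis for homing-drive experiments.

The experimental design mirrored here: an F0 cross combines the Cas9 and
gRNA transgenes (from separate parents, or coupled on one chromosome of a
double-homozygous parent) into F1 trans-heterozygotes; single F1 flies are
outcrossed to wild type and their F2 progeny are scored per vial for the
fluorescent markers (DsRed tags the Cas9 construct, GFP the gRNA construct)
and for the body-color / eye-color phenotypes of the two target genes.

The generative model separates two cleavage phases in the F1:

* a **zygotic** phase, active only when the F0 mother deposited both Cas9 and
  gRNA into the egg: each target wild-type allele is cleaved with probability
  ``z`` and repaired by end joining, fixing a *single* indel clonally across
  the entire germline (hence ~50% marker inheritance and one resistant allele
  per vial when ``z`` is high);
* a **germline** phase: each of ``k`` primordial germline precursor cells
  (pole cells, ~3 in the fly embryo) independently resolves every remaining
  drive-competent wild-type allele — conversion with probability
  ``q_late * c_late``, otherwise an end-joining indel.  The clonal pole-cell
  structure bounds the number of distinct resistant alleles per vial by ``k``
  per locus.

Indel identities are categorical: a small set of recurrent labels plus an
"infinite tail" of always-novel singleton labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .genetics import (
    STATES,
    CubeParams,
    DriveArchitecture,
    architecture as _architecture,
)

__all__ = [
    "SCORING_COLUMNS",
    "CrossScheme",
    "IndelSpectrum",
    "GermlineTimingParams",
    "InheritanceSummary",
    "FitResult",
    "simulate_cross",
    "inheritance_summary",
    "fit_conversion",
    "distinct_indel_tally",
]

#: Canonical column order of a scoring table (one row per distinct
#: (vial, sex, phenotype, indel) combination; `count` is the number of flies).
SCORING_COLUMNS = [
    "experiment",
    "vial",
    "sex",
    "dsred",
    "gfp",
    "body",
    "eye",
    "count",
    "indel",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class IndelSpectrum:
    """Categorical indel identities at one cut site.

    ``labels``/``probs`` are the recurrent indels; ``tail_prob`` is the mass
    on always-novel singleton identities (each tail draw creates a fresh
    label).  ``locus_tag`` namespaces labels, e.g. tag ``"w"`` yields
    recurrent labels like ``"wA"`` and singleton labels ``"wx<n>"``.
    """

    labels: tuple[str, ...] = ("A", "B", "C")
    probs: tuple[float, ...] = (0.40, 0.30, 0.23)
    tail_prob: float = 0.07
    locus_tag: str = "w"

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("indel labels must be unique")
        if len(self.labels) != len(self.probs):
            raise ValueError("labels and probs must have equal length")
        total = sum(self.probs) + self.tail_prob
        if abs(total - 1.0) > 1e-9:
            raise ValueError("probs + tail_prob must sum to 1")
        if any(p < 0 for p in self.probs) or self.tail_prob < 0:
            raise ValueError("probabilities must be non-negative")

    @property
    def full_labels(self) -> tuple[str, ...]:
        return tuple(self.locus_tag + lab for lab in self.labels)

    def draw(self, rng: np.random.Generator, counter: itertools.count) -> str:
        u = rng.random()
        acc = 0.0
        for lab, p in zip(self.labels, self.probs):
            acc += p
            if u < acc:
                return self.locus_tag + lab
        return f"{self.locus_tag}x{next(counter)}"


@dataclass
class GermlineTimingParams:
    """Timing structure of cleavage in the F1 (zygote vs germline phase).

    z : per-allele zygotic deposition-cleavage probability (forced to 0 when
        the F0 mother does not carry both drive components).
    k : number of primordial germline precursor cells (default 3).
    q_late, c_late : per-precursor-cell cleavage and conversion probabilities
        during germline development (scalar or per-locus).
    rho : in-frame fraction of end-joining repairs.
    spectra : one IndelSpectrum per locus (a single spectrum is broadcast).
    """

    z: float = 0.0
    k: int = 3
    q_late: object = 1.0
    c_late: object = 1.0
    rho: float = 1.0
    spectra: Sequence[IndelSpectrum] | IndelSpectrum = field(
        default_factory=IndelSpectrum
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.z <= 1.0:
            raise ValueError("z must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def per_locus(self, n_loci: int) -> tuple[np.ndarray, np.ndarray, list[IndelSpectrum]]:
        def broadcast(v, name):
            arr = np.asarray(v, dtype=float)
            if arr.ndim == 0:
                arr = np.full(n_loci, float(arr))
            if arr.shape != (n_loci,):
                raise ValueError(f"{name}: expected scalar or {n_loci} values")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            return arr

        if isinstance(self.spectra, IndelSpectrum):
            spectra = [self.spectra] * n_loci
        else:
            spectra = list(self.spectra)
            if len(spectra) != n_loci:
                raise ValueError(f"need {n_loci} indel spectra")
        return broadcast(self.q_late, "q_late"), broadcast(self.c_late, "c_late"), spectra


@dataclass
class CrossScheme:
    """Which F0 parent contributes each drive element, and which F1 sex is scored."""

    f0_cas9_parent: str = "father"  # "father" | "mother"
    f0_grna_parent: str = "mother"
    coupled: bool = False
    f1_sex_scored: str = "female"  # "female" | "male"
    architecture: DriveArchitecture | str = "tGDX_linked"

    def __post_init__(self) -> None:
        for attr in ("f0_cas9_parent", "f0_grna_parent"):
            if getattr(self, attr) not in ("father", "mother"):
                raise ValueError(f"{attr} must be 'father' or 'mother'")
        if self.f1_sex_scored not in ("female", "male"):
            raise ValueError("f1_sex_scored must be 'female' or 'male'")
        if isinstance(self.architecture, str):
            self.architecture = _architecture(self.architecture)
        same = self.f0_cas9_parent == self.f0_grna_parent
        if self.coupled and not same:
            raise ValueError("coupled elements must come from a single F0 parent")
        if same and not self.coupled:
            # both elements from one F0 parent are modeled only via the
            # coupled double-homozygous line
            raise ValueError(
                "both elements from one F0 parent require coupled=True"
            )
        if self.f1_sex_scored == "male" and self.architecture.x_linked:
            raise ValueError(
                "male F1 germline scoring is only valid for autosomal loci "
                "(hemizygous males cannot undergo allelic conversion)"
            )

    @property
    def mother_carries_both(self) -> bool:
        return self.f0_cas9_parent == "mother" and self.f0_grna_parent == "mother"


# ---------------------------------------------------------------------------
# Labeled-allele machinery (internal)
# ---------------------------------------------------------------------------

# a labeled haplotype is a tuple of (state, label-or-None) per locus
_Y = "Y"


def _f1_zygote(scheme: CrossScheme) -> tuple[tuple, tuple]:
    """(maternal haplotype, paternal haplotype) of the scored F1, unlabeled."""
    arch = scheme.architecture
    n = arch.n_loci
    wt = tuple(("W", None) for _ in range(n))
    if n == 1:
        carrier = (("T", None),)
        maternal = carrier if scheme.f0_cas9_parent == "mother" else wt
        paternal = carrier if scheme.f0_cas9_parent == "father" else wt
        return maternal, paternal
    if scheme.coupled:
        carrier = tuple(("T", None) for _ in range(n))
        if scheme.f0_cas9_parent == "mother":
            return carrier, wt
        return wt, carrier
    cas9_hap = (("T", None), ("W", None))
    grna_hap = (("W", None), ("T", None))
    maternal = cas9_hap if scheme.f0_cas9_parent == "mother" else grna_hap
    paternal = cas9_hap if scheme.f0_cas9_parent == "father" else grna_hap
    return maternal, paternal


def _has_machinery_labeled(haps: Sequence[tuple], arch: DriveArchitecture) -> bool:
    has_cas9 = any(h[i][0] == "T" for h in haps for i in arch.cas9_loci)
    has_grna = any(h[i][0] == "T" for h in haps for i in arch.grna_loci)
    return has_cas9 and has_grna


def _resolve_cell(
    haps: list[list[tuple]],
    arch: DriveArchitecture,
    q_late: np.ndarray,
    c_late: np.ndarray,
    rho: float,
    spectra: list[IndelSpectrum],
    rng: np.random.Generator,
    counters: list[itertools.count],
) -> list[list[tuple]]:
    """One precursor cell resolves each competent W allele once."""
    cell = [list(h) for h in haps]
    if not _has_machinery_labeled(cell, arch):
        return cell
    for hi in range(len(cell)):
        other = cell[1 - hi] if len(cell) == 2 else None
        for locus in range(arch.n_loci):
            if cell[hi][locus][0] != "W":
                continue
            if other is None or other[locus][0] != "T":
                continue  # no HDR template on the homolog
            if rng.random() >= q_late[locus]:
                continue
            if rng.random() < c_late[locus]:
                cell[hi][locus] = ("T", None)
            else:
                lab = spectra[locus].draw(rng, counters[locus])
                state = "R" if rng.random() < rho else "B"
                cell[hi][locus] = (state, lab)
    return cell


def _gametes_of_cell(
    cell: list[list[tuple]], arch: DriveArchitecture, hemizygous: bool
) -> list[tuple[object, float]]:
    """Gamete distribution of a resolved precursor cell (labels retained)."""
    if hemizygous:
        return [(tuple(cell[0]), 0.5), (_Y, 0.5)]
    h1, h2 = tuple(cell[0]), tuple(cell[1])
    if arch.n_loci == 1:
        return [(h1, 0.5), (h2, 0.5)]
    r = arch.recomb_fraction
    out = [
        (h1, (1 - r) / 2),
        (h2, (1 - r) / 2),
        ((h1[0], h2[1]), r / 2),
        ((h2[0], h1[1]), r / 2),
    ]
    agg: dict = {}
    for g, p in out:
        if p > 0:
            agg[g] = agg.get(g, 0.0) + p
    return list(agg.items())


def _phenotype_row(
    gamete,
    sex: str,
    arch: DriveArchitecture,
) -> tuple[str, str, str, str, str]:
    """(dsred, gfp, body, eye, indel) for an F2 fly.

    The scored-parent gamete is combined with a wild-type gamete (or Y for
    X-linked sons).  Markers track transgene presence; body/eye phenotypes
    depend on functional-allele content (W or R functional; T and B not) at
    loci 0 and 1 respectively.  Indel labels are reported for males only,
    mimicking sequencing of F2 males.
    """
    n = arch.n_loci
    if gamete == _Y:
        states = [None] * n
        labels = []
    else:
        states = [a[0] for a in gamete]
        labels = [a[1] for a in gamete if a[1] is not None]
    # partner gamete: wild type (or absent for X-linked sons)
    x_linked_son = arch.x_linked and sex == "M"
    if gamete == _Y:
        # X-linked F1 male transmitting Y: daughter impossible; son gets
        # mother's wild-type X only
        states = ["W"] * n

    def functional(locus: int) -> bool:
        own = states[locus] in ("W", "R")
        partner = not x_linked_son  # wild-type homolog unless hemizygous son
        return own or partner

    has = lambda st, loci: any(states[i] == st for i in loci)
    dsred = "+" if has("T", arch.cas9_loci) else "-"
    gfp = "+" if has("T", arch.grna_loci) else "-"
    body = "wt" if functional(0) else "mutant"
    eye = ("wt" if functional(1) else "mutant") if n == 2 else "na"
    indel = ";".join(sorted(labels)) if (sex == "M" and labels) else ""
    return dsred, gfp, body, eye, indel


# ---------------------------------------------------------------------------
# Cross simulation
# ---------------------------------------------------------------------------

def simulate_cross(
    scheme: CrossScheme,
    cube_params: CubeParams | None = None,
    timing: GermlineTimingParams | None = None,
    n_vials: int = 11,
    n_offspring_per_vial: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    experiment: str = "sim",
) -> pd.DataFrame:
    """Simulate per-vial F2 scoring data for a cross scheme.

    Each vial is one scored F1 individual: its zygote is formed from the F0
    gametes of the scheme, maternal deposition acts with probability ``z``
    per wild-type allele (only when the F0 mother carried both components,
    fixing one clonal indel per cleaved locus), then each of ``k`` precursor
    cells independently resolves the remaining competent wild-type alleles
    with ``q_late``/``c_late``.  Each F2 offspring samples a precursor cell
    uniformly, then a gamete, then a sex.  Fully determined by ``seed``.

    ``cube_params`` is accepted for interface symmetry; the timing parameters
    govern the F1's cleavage behavior.
    """
    if n_vials < 1 or n_offspring_per_vial < 1:
        raise ValueError("n_vials and n_offspring_per_vial must be >= 1")
    if timing is None:
        timing = GermlineTimingParams()
    arch = scheme.architecture
    q_late, c_late, spectra = timing.per_locus(arch.n_loci)
    if rng is None:
        rng = np.random.default_rng(seed)
    z = timing.z if scheme.mother_carries_both else 0.0

    f1_is_female = scheme.f1_sex_scored == "female"
    hemizygous = arch.x_linked and not f1_is_female  # guarded by scheme checks

    counters = [itertools.count(1) for _ in range(arch.n_loci)]
    rows: dict[tuple, int] = {}
    for vial in range(1, n_vials + 1):
        maternal, paternal = _f1_zygote(scheme)
        haps = [list(maternal)] + ([] if hemizygous else [list(paternal)])
        # zygotic deposition phase: clonal, one indel label per cleaved allele
        if z > 0.0:
            for hi in range(len(haps)):
                for locus in range(arch.n_loci):
                    if haps[hi][locus][0] == "W" and rng.random() < z:
                        lab = spectra[locus].draw(rng, counters[locus])
                        state = "R" if rng.random() < timing.rho else "B"
                        haps[hi][locus] = (state, lab)
        # germline phase: k precursor cells, each resolved once
        cells = [
            _resolve_cell(haps, arch, q_late, c_late, timing.rho, spectra, rng, counters)
            for _ in range(timing.k)
        ]
        gametes = [_gametes_of_cell(c, arch, hemizygous) for c in cells]
        per_cell = rng.multinomial(
            n_offspring_per_vial, np.full(timing.k, 1.0 / timing.k)
        )
        for ci, n_c in enumerate(per_cell):
            if n_c == 0:
                continue
            gams = gametes[ci]
            probs = np.array([p for _, p in gams])
            counts = rng.multinomial(n_c, probs)
            for (gam, _), m in zip(gams, counts):
                if m == 0:
                    continue
                if arch.x_linked and f1_is_female:
                    # sex set by the wild-type father's gamete (X or Y)
                    n_sons = rng.binomial(m, 0.5)
                    splits = [("F", m - n_sons), ("M", n_sons)]
                elif gam == _Y:
                    splits = [("M", m)]  # Y-bearing sperm -> sons
                elif hemizygous:
                    splits = [("F", m)]  # X-bearing sperm -> daughters
                else:
                    n_sons = rng.binomial(m, 0.5)
                    splits = [("F", m - n_sons), ("M", n_sons)]
                for sex, cnt in splits:
                    if cnt == 0:
                        continue
                    ph = _phenotype_row(gam, sex, arch)
                    key = (experiment, vial, sex) + ph
                    rows[key] = rows.get(key, 0) + int(cnt)

    records = [
        {
            "experiment": k[0],
            "vial": k[1],
            "sex": k[2],
            "dsred": k[3],
            "gfp": k[4],
            "body": k[5],
            "eye": k[6],
            "count": v,
            "indel": k[7] if k[7] else pd.NA,
        }
        for k, v in sorted(rows.items(), key=lambda kv: (kv[0][1], kv[0][2:]))
    ]
    return pd.DataFrame.from_records(records, columns=SCORING_COLUMNS)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class InheritanceSummary:
    """Per-vial marker-inheritance summary (vials averaged, not flies)."""

    marker: str
    per_vial: pd.Series  # vial -> fraction marker-positive
    mean: float
    sd: float
    n_vials: int
    total_flies: int


def inheritance_summary(table: pd.DataFrame, marker: str = "gfp") -> InheritanceSummary:
    """Per-vial marker fractions with their unweighted mean and SD.

    The mean averages vials, not flies, matching how single-germline
    inheritance outputs are reported.  Empty vials are excluded with a
    warning; an empty table is an error.
    """
    if marker not in ("dsred", "gfp"):
        raise ValueError("marker must be 'dsred' or 'gfp'")
    if table.empty:
        raise ValueError("scoring table is empty")
    totals = table.groupby("vial")["count"].sum()
    empty = totals[totals == 0]
    if len(empty):
        warnings.warn(f"excluding {len(empty)} empty vial(s): {list(empty.index)}")
        totals = totals[totals > 0]
    if totals.empty:
        raise ValueError("no vial contains any fly")
    pos = (
        table[table[marker] == "+"].groupby("vial")["count"].sum()
        .reindex(totals.index, fill_value=0)
    )
    frac = pos / totals
    mean = float(frac.mean())
    sd = float(frac.std(ddof=1)) if len(frac) > 1 else 0.0
    return InheritanceSummary(
        marker=marker,
        per_vial=frac,
        mean=mean,
        sd=sd,
        n_vials=int(len(frac)),
        total_flies=int(totals.sum()),
    )


def _vial_counts(table: pd.DataFrame, marker: str) -> tuple[np.ndarray, np.ndarray]:
    totals = table.groupby("vial")["count"].sum()
    totals = totals[totals > 0]
    pos = (
        table[table[marker] == "+"].groupby("vial")["count"].sum()
        .reindex(totals.index, fill_value=0)
    )
    return pos.to_numpy(dtype=float), totals.to_numpy(dtype=float)


@dataclass
class FitResult:
    model: str
    estimate: dict
    ci: dict
    boundary: bool
    n_boot: int


def _germline_only_mle(pos: np.ndarray, tot: np.ndarray) -> float:
    # binomial likelihood with common p across vials -> pooled fraction
    p_hat = pos.sum() / tot.sum()
    return 2.0 * p_hat - 1.0


def _mixture_nll(params: np.ndarray, pos: np.ndarray, tot: np.ndarray) -> float:
    z, u = params
    p1 = 0.5 + 0.5 * u
    la = np.log(max(z, 1e-300)) + sps.binom.logpmf(pos, tot, 0.5)
    lb = np.log(max(1.0 - z, 1e-300)) + sps.binom.logpmf(pos, tot, min(p1, 1.0))
    return -float(np.sum(special.logsumexp(np.stack([la, lb]), axis=0)))


def _mixture_mle(pos: np.ndarray, tot: np.ndarray) -> tuple[float, float]:
    best = None
    for z0 in (0.1, 0.5, 0.9):
        for u0 in (0.3, 0.7, 0.95):
            res = optimize.minimize(
                _mixture_nll,
                x0=np.array([z0, u0]),
                args=(pos, tot),
                method="L-BFGS-B",
                bounds=[(0.0, 1.0), (0.0, 1.0)],
            )
            if best is None or res.fun < best.fun:
                best = res
    return float(best.x[0]), float(best.x[1])


def fit_conversion(
    table: pd.DataFrame,
    scheme: CrossScheme | None = None,
    model: str = "germline_only",
    marker: str = "gfp",
    n_boot: int = 2000,
    seed: int | None = None,
) -> FitResult:
    """Maximum-likelihood conversion estimates from per-vial marker counts.

    ``germline_only`` fits the expected marker probability p = 1/2 + (q c)/2
    under a binomial per-vial likelihood; the MLE of ``q*c`` is reported with
    a percentile bootstrap CI over vials.  ``zygotic_mixture`` fits the
    two-component vial mixture implied by the timing model: a fraction ``z``
    of germlines were fixed at Mendelian transmission by zygotic cleavage,
    the rest transmit at 1/2 + (q_late c_late)/2.

    Estimates on the parameter boundary are flagged (``boundary=True``); the
    reported estimate is clamped to [0, 1] but the raw value is kept in
    ``estimate['raw']``.
    """
    pos, tot = _vial_counts(table, marker)
    if len(tot) == 0:
        raise ValueError("no non-empty vials")
    rng = np.random.default_rng(seed)
    n = len(tot)

    if model == "germline_only":
        raw = _germline_only_mle(pos, tot)
        est = min(max(raw, 0.0), 1.0)
        boundary = raw <= 0.0 or raw >= 1.0
        if n_boot > 0:
            boots = np.empty(n_boot)
            for b in range(n_boot):
                ix = rng.integers(0, n, size=n)
                boots[b] = np.clip(_germline_only_mle(pos[ix], tot[ix]), 0.0, 1.0)
            ci = {
                "qc": (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
            }
        else:
            ci = {}
        return FitResult(model, {"qc": est, "raw": raw}, ci, boundary, n_boot)

    if model == "zygotic_mixture":
        z_hat, u_hat = _mixture_mle(pos, tot)
        boundary = min(z_hat, u_hat) <= 0.0 or max(z_hat, u_hat) >= 1.0
        if n_boot > 0:
            bz = np.empty(n_boot)
            bu = np.empty(n_boot)
            for b in range(n_boot):
                ix = rng.integers(0, n, size=n)
                bz[b], bu[b] = _mixture_mle(pos[ix], tot[ix])
            ci = {
                "z": (float(np.percentile(bz, 2.5)), float(np.percentile(bz, 97.5))),
                "qc_late": (
                    float(np.percentile(bu, 2.5)), float(np.percentile(bu, 97.5))
                ),
            }
        else:
            ci = {}
        return FitResult(
            model, {"z": z_hat, "qc_late": u_hat}, ci, boundary, n_boot
        )

    raise ValueError("model must be 'germline_only' or 'zygotic_mixture'")


def distinct_indel_tally(table: pd.DataFrame, locus_tag: str) -> pd.DataFrame:
    """Per-vial count of distinct indel labels at one locus.

    ``locus_tag`` is the label-namespace prefix of the locus of interest
    (e.g. ``"w"`` when labels are ``wA``, ``wB``, ``wx7``, ...).  Returns a
    DataFrame indexed by vial with columns ``n_distinct`` and ``n_sampled``
    (number of labeled male flies bearing an indel at that locus); vials with
    no labeled flies report zeros.
    """
    out = {}
    for vial, sub in table.groupby("vial"):
        labels: set[str] = set()
        sampled = 0
        males = sub[(sub["sex"] == "M") & sub["indel"].notna()]
        for _, row in males.iterrows():
            here = [
                lab for lab in str(row["indel"]).split(";")
                if lab.startswith(locus_tag)
            ]
            if here:
                labels.update(here)
                sampled += int(row["count"])
        out[vial] = (len(labels), sampled)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["n_distinct", "n_sampled"])
    df.index.name = "vial"
    return df
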