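"""Genotype enumeration and inheritance cubes for CRISPR homing gene drives.

A homing drive biases its own transmission above the Mendelian 50% by cutting
the homologous wild-type allele in the germline and copying itself across via
homology-directed repair (HDR).  Two families of architecture are supported:

* **full drives** — Cas9 and gRNAs inserted together as a single element at the
  target locus (``full_GD`` autosomal, ``full_GDX`` X-linked);
* **trans-complementing (split) drives** — a Cas9 transgene and a tandem-gRNA
  transgene at two separate loci, each copying itself only when both are present
  in the same individual (``tGD_linked``/``tGDc`` autosomal, ``tGDX_linked``/
  ``tGDXc`` X-linked; the ``c`` variants are freely recombining).

Each allele at a drive locus is in one of four states: ``W`` wild type, ``T``
transgene, ``R`` in-frame (functional) resistant, ``B`` out-of-frame (broken)
resistant.  The central object is the :class:`InheritanceCube`: for every
(mother genotype, father genotype) pair, the exact distribution over offspring
genotype and sex, obtained by composing three exact probabilistic transforms:

1. :func:`germline_transform` — cleavage (``q``) and conversion (``c``) of each
   drive-competent wild-type allele in the parental germline;
2. :func:`gamete_distribution` — Mendelian segregation with recombination;
3. :func:`deposition_transform` — maternal Cas9/gRNA deposition cleaving
   zygotic wild-type alleles (probability ``d``), repaired by end joining only.

All distributions are built by exact expansion of the branching probabilities
in double precision; rows of the cube sum to 1 by construction (no
renormalization is ever applied).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STATES",
    "Genotype",
    "DriveArchitecture",
    "CubeParams",
    "InheritanceCube",
    "architecture",
    "ARCHITECTURE_NAMES",
    "enumerate_genotypes",
    "germline_transform",
    "gamete_distribution",
    "deposition_transform",
    "build_cube",
    "mendelian_cube",
    "transmission_rate",
    "genotype_to_str",
    "genotype_from_str",
    "haplotype_to_str",
    "haplotype_from_str",
]

#: Allele states in canonical sort order (wild type < transgene < in-frame
#: resistant < out-of-frame resistant).
STATES: tuple[str, ...] = ("W", "T", "R", "B")
_STATE_ORDER = {s: i for i, s in enumerate(STATES)}

#: Locus letters used in genotype string codes ("TA-WB/WA-TB|F").
_LOCUS_LETTERS = "AB"

#: Sentinel haplotype for the Y chromosome of hemizygous males.
Y = "Y"

_SEXES = ("F", "M")


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriveArchitecture:
    """Drive layout: loci, their roles, linkage and chromosome type.

    ``loci`` holds one role per drive locus: ``"fused_site"`` for a full-drive
    element (Cas9+gRNA in one cassette at the target), or ``"cas9_site"`` /
    ``"grna_site"`` for the two elements of a split drive.  ``recomb_fraction``
    is the recombination probability between the two loci of a split drive
    (0 = complete linkage, 0.5 = independent assortment).
    """

    name: str
    loci: tuple[str, ...]
    chromosome_type: str  # "autosome" | "X"
    recomb_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.chromosome_type not in ("autosome", "X"):
            raise ValueError(f"unknown chromosome_type {self.chromosome_type!r}")
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recomb_fraction must lie in [0, 0.5]")
        roles = tuple(self.loci)
        if roles == ("fused_site",):
            pass
        elif sorted(roles) == ["cas9_site", "grna_site"]:
            pass
        else:
            raise ValueError(f"unsupported locus layout {roles}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def x_linked(self) -> bool:
        return self.chromosome_type == "X"

    @property
    def cas9_loci(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.loci) if r in ("cas9_site", "fused_site"))

    @property
    def grna_loci(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.loci) if r in ("grna_site", "fused_site"))


_ARCHITECTURES: dict[str, DriveArchitecture] = {
    "full_GD": DriveArchitecture("full_GD", ("fused_site",), "autosome", 0.0),
    "full_GDX": DriveArchitecture("full_GDX", ("fused_site",), "X", 0.0),
    "tGD_linked": DriveArchitecture("tGD_linked", ("cas9_site", "grna_site"), "autosome", 0.0),
    "tGDc": DriveArchitecture("tGDc", ("cas9_site", "grna_site"), "autosome", 0.5),
    "tGDX_linked": DriveArchitecture("tGDX_linked", ("cas9_site", "grna_site"), "X", 0.0),
    "tGDXc": DriveArchitecture("tGDXc", ("cas9_site", "grna_site"), "X", 0.5),
}

ARCHITECTURE_NAMES = tuple(_ARCHITECTURES)


def architecture(name: str, recomb_fraction: float | None = None) -> DriveArchitecture:
    """Look up a named architecture, optionally overriding linkage.

    ``tGDc`` and ``tGDXc`` are unlinked by definition; their recombination
    fraction cannot be overridden.
    """
    try:
        arch = _ARCHITECTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown architecture {name!r}; expected one of {ARCHITECTURE_NAMES}"
        ) from None
    if recomb_fraction is not None:
        if name in ("tGDc", "tGDXc") and recomb_fraction != 0.5:
            raise ValueError(f"{name} is unlinked by definition (recomb_fraction = 0.5)")
        arch = DriveArchitecture(arch.name, arch.loci, arch.chromosome_type, recomb_fraction)
    return arch


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

Haplotype = tuple  # tuple of state chars, one per locus


def _hap_key(hap: Haplotype) -> tuple[int, ...]:
    return tuple(_STATE_ORDER[s] for s in hap)


@dataclass(frozen=True, order=False)
class Genotype:
    """A sexed genotype: one haplotype per chromosome copy.

    ``hap2`` is ``None`` exactly for hemizygous males of X-linked
    architectures (their second sex chromosome is the drive-free Y).
    Diploid genotypes are canonicalized so ``hap1 <= hap2`` in the
    ``W < T < R < B`` per-locus order.
    """

    sex: str
    hap1: Haplotype
    hap2: Haplotype | None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")

    @property
    def hemizygous(self) -> bool:
        return self.hap2 is None

    @property
    def haplotypes(self) -> tuple[Haplotype, ...]:
        return (self.hap1,) if self.hap2 is None else (self.hap1, self.hap2)

    def count_state(self, state: str, locus: int | None = None) -> int:
        n = 0
        for hap in self.haplotypes:
            for i, s in enumerate(hap):
                if s == state and (locus is None or i == locus):
                    n += 1
        return n

    def __str__(self) -> str:  # pragma: no cover - convenience
        return genotype_to_str(self)


def make_genotype(sex: str, hap1: Haplotype, hap2: Haplotype | None) -> Genotype:
    """Construct a canonical genotype (unordered haplotype pair)."""
    if hap2 is not None and _hap_key(hap2) < _hap_key(hap1):
        hap1, hap2 = hap2, hap1
    return Genotype(sex, tuple(hap1), None if hap2 is None else tuple(hap2))


def _all_haplotypes(n_loci: int) -> list[Haplotype]:
    return sorted(itertools.product(STATES, repeat=n_loci), key=_hap_key)


def enumerate_genotypes(arch: DriveArchitecture) -> tuple[list[Genotype], list[Genotype]]:
    """All distinct genotypes for an architecture, as ``(females, males)``.

    Ordering is stable: haplotypes are sorted lexicographically by per-locus
    state code (W < T < R < B) and unordered pairs are listed in
    combinations-with-replacement order of that ranking.  Males of X-linked
    architectures are hemizygous (single haplotype + Y).
    """
    haps = _all_haplotypes(arch.n_loci)
    pairs = [
        make_genotype("F", h1, h2)
        for h1, h2 in itertools.combinations_with_replacement(haps, 2)
    ]
    females = pairs
    if arch.x_linked:
        males = [Genotype("M", h, None) for h in haps]
    else:
        males = [Genotype("M", g.hap1, g.hap2) for g in pairs]
    return females, males


# ---------------------------------------------------------------------------
# String codes
# ---------------------------------------------------------------------------

def haplotype_to_str(hap: Haplotype | str) -> str:
    """Canonical haplotype code: ``"T"`` (one locus) or ``"TA-WB"`` (two)."""
    if hap == Y:
        return Y
    if len(hap) == 1:
        return hap[0]
    return "-".join(s + _LOCUS_LETTERS[i] for i, s in enumerate(hap))


def haplotype_from_str(code: str, n_loci: int) -> Haplotype | str:
    if code == Y:
        return Y
    if n_loci == 1:
        if code not in STATES:
            raise ValueError(f"bad haplotype code {code!r}")
        return (code,)
    parts = code.split("-")
    if len(parts) != n_loci:
        raise ValueError(f"bad haplotype code {code!r}")
    hap = []
    for i, p in enumerate(parts):
        if len(p) != 2 or p[0] not in STATES or p[1] != _LOCUS_LETTERS[i]:
            raise ValueError(f"bad haplotype code {code!r}")
        hap.append(p[0])
    return tuple(hap)


def genotype_to_str(g: Genotype) -> str:
    """Canonical genotype code, e.g. ``"TA-WB/WA-TB|F"`` or ``"T/Y|M"``."""
    h2 = Y if g.hap2 is None else haplotype_to_str(g.hap2)
    return f"{haplotype_to_str(g.hap1)}/{h2}|{g.sex}"


def genotype_from_str(code: str, arch: DriveArchitecture) -> Genotype:
    try:
        haps, sex = code.rsplit("|", 1)
        h1, h2 = haps.split("/")
    except ValueError:
        raise ValueError(f"bad genotype code {code!r}") from None
    hap1 = haplotype_from_str(h1, arch.n_loci)
    hap2 = haplotype_from_str(h2, arch.n_loci)
    if hap1 == Y:
        raise ValueError(f"bad genotype code {code!r}: Y cannot be first")
    if hap2 == Y:
        if sex != "M" or not arch.x_linked:
            raise ValueError(f"bad genotype code {code!r}: hemizygosity is X-linked male only")
        return make_genotype(sex, hap1, None)
    return make_genotype(sex, hap1, hap2)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _per_locus_sex(value, n_loci: int, name: str) -> np.ndarray:
    """Broadcast a probability spec to shape (n_loci, 2) [locus, sex F/M]."""
    if isinstance(value, Mapping):
        arr = np.zeros((n_loci, 2))
        for (locus, sex), v in value.items():
            arr[locus, _SEXES.index(sex)] = v
    else:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full((n_loci, 2), float(arr))
        elif arr.ndim == 1:
            if arr.shape[0] != n_loci:
                raise ValueError(f"{name}: expected {n_loci} per-locus values")
            arr = np.repeat(arr[:, None], 2, axis=1)
        elif arr.shape != (n_loci, 2):
            raise ValueError(f"{name}: expected shape ({n_loci}, 2)")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def _per_locus(value, n_loci: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_loci, float(arr))
    elif arr.shape != (n_loci,):
        raise ValueError(f"{name}: expected scalar or {n_loci} per-locus values")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


@dataclass
class CubeParams:
    """Drive parameters: cleavage, conversion, deposition, repair and fitness.

    q : cleavage probability per competent wild-type allele, per locus and
        parental sex (scalar, per-locus vector, (locus, sex) array, or mapping
        ``{(locus, 'F'|'M'): p}``); default 1 (cleavage frequency of 100%).
    c : conversion (HDR) probability given cleavage, same shapes; default 1.
    d : maternal-deposition cleavage probability per locus; default 0.
    rho : probability an end-joining repair is in-frame (R) rather than
        out-of-frame (B); default 1 (all resistant alleles in-frame/cost-free).
    omega : relative fitness multiplier per genotype, used as a mating weight
        for males and a fecundity multiplier for females; default 1 everywhere.
    fertility_rule : optional predicate returning True for *sterile* female
        genotypes (population-suppression mode).
    """

    q: object = 1.0
    c: object = 1.0
    d: object = 0.0
    rho: float = 1.0
    omega: Callable[[Genotype], float] | None = None
    fertility_rule: Callable[[Genotype], bool] | None = None

    def resolved(self, arch: DriveArchitecture) -> "ResolvedParams":
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        return ResolvedParams(
            q=_per_locus_sex(self.q, arch.n_loci, "q"),
            c=_per_locus_sex(self.c, arch.n_loci, "c"),
            d=_per_locus(self.d, arch.n_loci, "d"),
            rho=float(self.rho),
            omega=self.omega,
            fertility_rule=self.fertility_rule,
        )

    def fitness(self, g: Genotype) -> float:
        w = 1.0 if self.omega is None else float(self.omega(g))
        if w < 0:
            raise ValueError("omega must be >= 0")
        return w

    def fertile(self, g: Genotype) -> bool:
        if self.fertility_rule is None:
            return True
        return not self.fertility_rule(g)


@dataclass
class ResolvedParams:
    q: np.ndarray
    c: np.ndarray
    d: np.ndarray
    rho: float
    omega: Callable[[Genotype], float] | None
    fertility_rule: Callable[[Genotype], bool] | None


def _resolve(params: CubeParams | ResolvedParams, arch: DriveArchitecture) -> ResolvedParams:
    if isinstance(params, ResolvedParams):
        return params
    return params.resolved(arch)


# ---------------------------------------------------------------------------
# Drive competence and exact transforms
# ---------------------------------------------------------------------------

def _has_machinery(g: Genotype, arch: DriveArchitecture) -> bool:
    """True iff the genotype carries >=1 Cas9 source and >=1 gRNA source."""
    has_cas9 = any(hap[i] == "T" for hap in g.haplotypes for i in arch.cas9_loci)
    has_grna = any(hap[i] == "T" for hap in g.haplotypes for i in arch.grna_loci)
    return has_cas9 and has_grna


def _competent_positions(g: Genotype, arch: DriveArchitecture) -> list[tuple[int, int]]:
    """(haplotype index, locus) of each germline-convertible W allele.

    A W allele is drive-competent when the genotype carries complete drive
    machinery and the homologous chromosome carries the transgene at that
    locus (the HDR template).  Hemizygous males have no homolog, hence no
    competent positions.
    """
    if g.hemizygous or not _has_machinery(g, arch):
        return []
    out = []
    haps = g.haplotypes
    for hi in (0, 1):
        for locus in range(arch.n_loci):
            if haps[hi][locus] == "W" and haps[1 - hi][locus] == "T":
                out.append((hi, locus))
    return out


def _expand(
    g: Genotype,
    positions: list[tuple[int, int]],
    outcomes: Callable[[int, int], list[tuple[str, float]]],
) -> dict[Genotype, float]:
    """Exact expansion of independent per-allele branchings at `positions`."""
    if not positions:
        return {g: 1.0}
    dist: dict[Genotype, float] = {}
    per_pos = [outcomes(hi, locus) for hi, locus in positions]
    for combo in itertools.product(*per_pos):
        p = 1.0
        haps = [list(h) for h in g.haplotypes]
        for (hi, locus), (state, pr) in zip(positions, combo):
            p *= pr
            haps[hi][locus] = state
        if p == 0.0:
            continue
        new = make_genotype(g.sex, tuple(haps[0]), tuple(haps[1]) if len(haps) > 1 else None)
        dist[new] = dist.get(new, 0.0) + p
    return dist


def germline_transform(
    g: Genotype, params: CubeParams | ResolvedParams, arch: DriveArchitecture
) -> dict[Genotype, float]:
    """Exact post-conversion genotype distribution for a parental germline.

    Each drive-competent W allele independently: cleaved with probability
    ``q[locus, sex]``; given cleavage, converted to the transgene with
    probability ``c[locus, sex]``; otherwise repaired by end joining to R
    (probability ``rho``) or B.  Conversion events at different loci are
    independent given competence.
    """
    rp = _resolve(params, arch)
    sex_ix = _SEXES.index(g.sex)

    def outcomes(hi: int, locus: int) -> list[tuple[str, float]]:
        q = rp.q[locus, sex_ix]
        c = rp.c[locus, sex_ix]
        return [
            ("W", 1.0 - q),
            ("T", q * c),
            ("R", q * (1.0 - c) * rp.rho),
            ("B", q * (1.0 - c) * (1.0 - rp.rho)),
        ]

    return _expand(g, _competent_positions(g, arch), outcomes)


def gamete_distribution(
    g: Genotype, arch: DriveArchitecture
) -> dict[Haplotype | str, float]:
    """Gamete (haplotype) distribution from a post-conversion genotype.

    Standard Mendelian segregation; for two-locus diploids, recombinant
    haplotypes form with probability ``recomb_fraction``.  Hemizygous males
    transmit their X haplotype or the drive-free ``Y`` with probability 1/2
    each.
    """
    if g.hemizygous:
        return {g.hap1: 0.5, Y: 0.5}
    dist: dict[Haplotype | str, float] = {}

    def add(h: Haplotype, p: float) -> None:
        if p > 0.0:
            dist[h] = dist.get(h, 0.0) + p

    h1, h2 = g.hap1, g.hap2
    if arch.n_loci == 1:
        add(h1, 0.5)
        add(h2, 0.5)
    else:
        r = arch.recomb_fraction
        add(h1, (1.0 - r) / 2.0)
        add(h2, (1.0 - r) / 2.0)
        add((h1[0], h2[1]), r / 2.0)
        add((h2[0], h1[1]), r / 2.0)
    return dist


def deposition_transform(
    zygote: Genotype,
    mother: Genotype,
    params: CubeParams | ResolvedParams,
    arch: DriveArchitecture,
) -> dict[Genotype, float]:
    """Maternal-deposition transform of a zygote's genotype.

    Active iff the mother's own genotype carries both a Cas9 and a gRNA
    source.  When active, every W allele in the zygote at a drive locus is
    independently cleaved with probability ``d[locus]`` and repaired by end
    joining only (R with probability ``rho``, else B) — deposited
    ribonucleoprotein never performs HDR, so deposition creates resistant
    alleles rather than conversions.
    """
    rp = _resolve(params, arch)
    if not _has_machinery(mother, arch):
        return {zygote: 1.0}
    positions = [
        (hi, locus)
        for hi, hap in enumerate(zygote.haplotypes)
        for locus in range(arch.n_loci)
        if hap[locus] == "W"
    ]

    def outcomes(hi: int, locus: int) -> list[tuple[str, float]]:
        d = rp.d[locus]
        return [
            ("W", 1.0 - d),
            ("R", d * rp.rho),
            ("B", d * (1.0 - rp.rho)),
        ]

    return _expand(zygote, positions, outcomes)


# ---------------------------------------------------------------------------
# Inheritance cube
# ---------------------------------------------------------------------------

@dataclass
class InheritanceCube:
    """Offspring-genotype distributions for every parental pair.

    ``table[i, j, k]`` is the probability that a mother of genotype
    ``female_genotypes[i]`` crossed to a father of genotype
    ``male_genotypes[j]`` produces the offspring indexed by ``k``, where the
    offspring axis lists all daughter genotypes followed by all son genotypes
    (``offspring_index``).  Rows sum to 1 exactly up to double-precision
    accumulation (no renormalization).
    """

    architecture: DriveArchitecture
    female_genotypes: list[Genotype]
    male_genotypes: list[Genotype]
    table: np.ndarray  # (n_f, n_m, n_f + n_m)

    # index lookups -------------------------------------------------------
    @property
    def n_f(self) -> int:
        return len(self.female_genotypes)

    @property
    def n_m(self) -> int:
        return len(self.male_genotypes)

    @property
    def offspring_index(self) -> list[Genotype]:
        return self.female_genotypes + self.male_genotypes

    def _findex(self) -> dict[Genotype, int]:
        return {g: i for i, g in enumerate(self.female_genotypes)}

    def _mindex(self) -> dict[Genotype, int]:
        return {g: i for i, g in enumerate(self.male_genotypes)}

    def female_index(self, g: Genotype | str) -> int:
        if isinstance(g, str):
            g = genotype_from_str(g, self.architecture)
        return self._findex()[g]

    def male_index(self, g: Genotype | str) -> int:
        if isinstance(g, str):
            g = genotype_from_str(g, self.architecture)
        return self._mindex()[g]

    def offspring_distribution(self, mother: Genotype | str, father: Genotype | str) -> np.ndarray:
        return self.table[self.female_index(mother), self.male_index(father)]


def _wild_type_haplotype(arch: DriveArchitecture) -> Haplotype:
    return tuple("W" for _ in range(arch.n_loci))


def wild_type_genotypes(arch: DriveArchitecture) -> tuple[Genotype, Genotype]:
    """(female, male) all-wild-type genotypes for an architecture."""
    w = _wild_type_haplotype(arch)
    female = make_genotype("F", w, w)
    male = Genotype("M", w, None) if arch.x_linked else make_genotype("M", w, w)
    return female, male


def drive_homozygotes(arch: DriveArchitecture) -> tuple[Genotype, Genotype]:
    """(female, male) genotypes fully loaded with the drive transgene(s)."""
    t = tuple("T" for _ in range(arch.n_loci))
    female = make_genotype("F", t, t)
    male = Genotype("M", t, None) if arch.x_linked else make_genotype("M", t, t)
    return female, male


def build_cube(
    arch: DriveArchitecture | str, params: CubeParams | None = None
) -> InheritanceCube:
    """Construct the exact inheritance cube for an architecture.

    For each parental pair the offspring distribution is the deposition
    transform (conditioned on the mother's genotype) applied to the zygote
    distribution formed from independent draws of each parent's
    post-conversion gamete distribution.  Deterministic given parameters.
    """
    if isinstance(arch, str):
        arch = architecture(arch)
    if params is None:
        params = CubeParams()
    rp = _resolve(params, arch)

    females, males = enumerate_genotypes(arch)
    n_f, n_m = len(females), len(males)
    f_ix = {g: i for i, g in enumerate(females)}
    m_ix = {g: i for i, g in enumerate(males)}

    def parent_gametes(g: Genotype) -> dict[Haplotype | str, float]:
        out: dict[Haplotype | str, float] = {}
        for g_post, p_post in germline_transform(g, rp, arch).items():
            for hap, p_h in gamete_distribution(g_post, arch).items():
                out[hap] = out.get(hap, 0.0) + p_post * p_h
        return out

    mother_gametes = [parent_gametes(g) for g in females]
    father_gametes = [parent_gametes(g) for g in males]

    # Deposition is a linear map on zygote genotypes that depends on the
    # mother only through whether she carries complete machinery, so the two
    # possible zygote -> offspring matrices are precomputed.
    n_off = n_f + n_m

    def deposition_matrix(active: bool) -> np.ndarray:
        mat = np.zeros((n_off, n_off))
        dummy_active = None
        for k, z in enumerate(females + males):
            if not active:
                mat[k, k] = 1.0
                continue
            if dummy_active is None:
                # any genotype with machinery serves as the "active mother" tag
                t = tuple("T" for _ in range(arch.n_loci))
                dummy_active = make_genotype("F", t, t)
            for z2, p in deposition_transform(z, dummy_active, rp, arch).items():
                k2 = f_ix[z2] if z2.sex == "F" else n_f + m_ix[z2]
                mat[k, k2] += p
        return mat

    dep_active = deposition_matrix(True)
    dep_inactive = deposition_matrix(False)

    table = np.zeros((n_f, n_m, n_off))
    for i, mother in enumerate(females):
        mg = mother_gametes[i]
        active = _has_machinery(mother, arch)
        dep = dep_active if active else dep_inactive
        for j in range(n_m):
            fg = father_gametes[j]
            zyg = np.zeros(n_off)
            for mh, pm in mg.items():
                for fh, pf in fg.items():
                    p = pm * pf
                    if fh == Y:
                        son = make_genotype("M", mh, None)
                        zyg[n_f + m_ix[son]] += p
                    elif arch.x_linked:
                        daughter = make_genotype("F", mh, fh)
                        zyg[f_ix[daughter]] += p
                    else:
                        zyg[f_ix[make_genotype("F", mh, fh)]] += 0.5 * p
                        zyg[n_f + m_ix[make_genotype("M", mh, fh)]] += 0.5 * p
            table[i, j] = zyg @ dep
    return InheritanceCube(arch, females, males, table)


def mendelian_cube(arch: DriveArchitecture | str) -> InheritanceCube:
    """The no-drive (q = 0, d = 0) cube: pure Mendelian segregation."""
    return build_cube(arch, CubeParams(q=0.0, c=0.0, d=0.0))


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _parse_allele_query(query: str, arch: DriveArchitecture) -> tuple[str, int | None]:
    """Parse queries like "T" (any locus) or "T@A"/"T@1" (specific locus)."""
    if "@" in query:
        state, locus_s = query.split("@", 1)
        if locus_s in _LOCUS_LETTERS:
            locus = _LOCUS_LETTERS.index(locus_s)
        else:
            locus = int(locus_s)
        if not 0 <= locus < arch.n_loci:
            raise ValueError(f"locus {locus_s!r} not present in {arch.name}")
    else:
        state, locus = query, None
    if state not in STATES:
        raise ValueError(f"unknown allele class {state!r}")
    return state, locus


def carries(g: Genotype, state: str, locus: int | None = None) -> bool:
    """True iff genotype carries >=1 allele of the given class."""
    return g.count_state(state, locus) > 0


def transmission_rate(
    cube: InheritanceCube,
    mother: Genotype | str,
    father: Genotype | str,
    allele_query: str = "T",
    restrict_sex: str | None = None,
) -> float:
    """Expected fraction of offspring carrying >=1 copy of an allele class.

    ``allele_query`` is a state letter optionally tagged with a locus
    (``"T"``, ``"T@A"``).  ``restrict_sex`` conditions on daughters (``"F"``)
    or sons (``"M"``).
    """
    state, locus = _parse_allele_query(allele_query, cube.architecture)
    dist = cube.offspring_distribution(mother, father)
    mask = np.array(
        [carries(g, state, locus) for g in cube.offspring_index], dtype=float
    )
    if restrict_sex is not None:
        sex_mask = np.array(
            [g.sex == restrict_sex for g in cube.offspring_index], dtype=float
        )
        denom = float(dist @ sex_mask)
        if denom == 0.0:
            raise ValueError(f"no offspring of sex {restrict_sex!r} from this cross")
        return float(dist @ (mask * sex_mask)) / denom
    return float(dist @ mask)
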