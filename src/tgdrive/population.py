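"""Stochastic stage-structured mosquito population model with drive genetics.

Single-patch, daily-time-step, genotype-resolved life-history model of
*Aedes aegypti* in the style of the MGDrivE framework family: egg, larval and
pupal cohorts tracked by age-in-stage and genotype, adult males mating
throughout life, adult females mating once upon emergence and retaining their
mate's genotype, overlapping generations.  Offspring genotypes come from an
:class:`~tgdrive.genetics.InheritanceCube`, so the same genetic engine used
for fly crosses drives the population dynamics.

Daily step order: (1) oviposition, (2) survival, (3) stage advancement and
adult emergence, (4) mating of newly emerged females, (5) releases.

Density-independent juvenile mortality ``mu_J`` is identical across juvenile
stages and calibrated so the density-free linearized dynamics grow at the
daily rate ``r``; additional density-dependent larval mortality uses the
Deredec-style survival multiplier ``(alpha / (alpha + L_total))**(1/T_L)``
applied daily to all larvae, with ``alpha`` calibrated so the deterministic
equilibrium holds ``N`` adults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .genetics import (
    CubeParams,
    DriveArchitecture,
    InheritanceCube,
    architecture as _architecture,
    build_cube,
    drive_homozygotes,
    genotype_from_str,
    wild_type_genotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LifeHistoryParams",
    "DerivedRates",
    "PopulationState",
    "ReleaseSchedule",
    "Scenario",
    "Trajectory",
    "calibrate_life_history",
    "equilibrium_state",
    "step_day",
    "run_scenario",
    "weekly_male_releases",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class LifeHistoryParams:
    """Mosquito life-history parameters (days / per-day rates).

    beta : eggs per female per day (20)
    T_E, T_L, T_P : egg / larval / pupal stage durations in days (5, 6, 4)
    r : daily population growth rate in the absence of density dependence
        (1.175)
    mu_M : adult daily mortality (0.090)
    N : equilibrium adult population size (10,000)
    """

    beta: float = 20.0
    T_E: int = 5
    T_L: int = 6
    T_P: int = 4
    r: float = 1.175
    mu_M: float = 0.090
    N: float = 10_000.0

    def __post_init__(self) -> None:
        if min(self.T_E, self.T_L, self.T_P) < 1:
            raise ValueError("stage durations must be positive integers")
        if not 0.0 < self.mu_M < 1.0:
            raise ValueError("mu_M must lie in (0, 1)")
        if self.r <= 1.0:
            raise ValueError("daily growth rate r must exceed 1")
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def tau(self) -> int:
        """Days from egg laying to adult emergence."""
        return self.T_E + self.T_L + self.T_P


@dataclass
class DerivedRates:
    """Calibrated rates and deterministic equilibrium cohort sizes."""

    mu_J: float
    alpha: float
    f_star: float  # daily larval density survival multiplier at equilibrium
    eq_eggs: np.ndarray  # (T_E,) totals by age-in-stage
    eq_larvae: np.ndarray  # (T_L,)
    eq_pupae: np.ndarray  # (T_P,)
    eq_adult_f: float
    eq_adult_m: float


def calibrate_life_history(params: LifeHistoryParams) -> DerivedRates:
    """Solve for ``mu_J`` and ``alpha`` consistent with ``r`` and ``N``.

    ``mu_J`` solves the daily Euler–Lotka identity of the density-free
    linearized model,

        1 = (beta/2) (1-mu_J)^tau r^-tau / (r - (1-mu_M)),

    by bracketed root finding to 1e-10.  The equilibrium daily larval
    density factor then follows from the adult balance
    ``f*^T_L = 2 mu_M / (beta (1-mu_J)^tau)``, the equilibrium larval total
    from the cohort recursion, and ``alpha = L* f*^T_L / (1 - f*^T_L)``.
    """
    tau = params.tau

    def residual(mu_j: float) -> float:
        return (
            (params.beta / 2.0)
            * (1.0 - mu_j) ** tau
            * params.r ** (-tau)
            / (params.r - (1.0 - params.mu_M))
            - 1.0
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    if residual(lo) <= 0.0:
        raise ValueError(
            "no juvenile mortality in (0, 1) is consistent with the requested "
            "growth rate: r too large for beta/mu_M"
        )
    mu_J = float(optimize.brentq(residual, lo, hi, xtol=1e-10, rtol=1e-12))

    s_total = 2.0 * params.mu_M / (params.beta * (1.0 - mu_J) ** tau)
    if not 0.0 < s_total < 1.0:
        raise ValueError("infeasible equilibrium: density survival outside (0, 1)")
    f_star = s_total ** (1.0 / params.T_L)

    e_new = params.beta * params.N / 2.0  # eggs laid per day at equilibrium
    sj = 1.0 - mu_J
    eq_eggs = e_new * sj ** np.arange(params.T_E)
    entry_l = e_new * sj ** params.T_E
    eq_larvae = entry_l * (sj * f_star) ** np.arange(params.T_L)
    entry_p = entry_l * (sj * f_star) ** params.T_L
    eq_pupae = entry_p * sj ** np.arange(params.T_P)
    L_star = float(eq_larvae.sum())
    alpha = L_star * s_total / (1.0 - s_total)
    return DerivedRates(
        mu_J=mu_J,
        alpha=alpha,
        f_star=f_star,
        eq_eggs=eq_eggs,
        eq_larvae=eq_larvae,
        eq_pupae=eq_pupae,
        eq_adult_f=params.N / 2.0,
        eq_adult_m=params.N / 2.0,
    )


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Age-by-genotype cohort state of one patch.

    Juvenile arrays have shape ``(stage_duration, n_offspring_slots)`` where
    the genotype axis lists all female genotypes followed by all male
    genotypes (matching the cube's offspring axis).  Adult females are
    tracked by (own genotype, stored mate genotype); ``adult_f_unmated``
    holds females that emerged when no males were present.
    """

    day: int
    eggs: np.ndarray  # (T_E, G)
    larvae: np.ndarray  # (T_L, G)
    pupae: np.ndarray  # (T_P, G)
    adult_m: np.ndarray  # (n_m,)
    adult_f: np.ndarray  # (n_f, n_m)
    adult_f_unmated: np.ndarray  # (n_f,)

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.day,
            self.eggs.copy(),
            self.larvae.copy(),
            self.pupae.copy(),
            self.adult_m.copy(),
            self.adult_f.copy(),
            self.adult_f_unmated.copy(),
        )

    @property
    def total_adult_f(self) -> float:
        return float(self.adult_f.sum() + self.adult_f_unmated.sum())

    @property
    def total_adult_m(self) -> float:
        return float(self.adult_m.sum())

    @property
    def total_adults(self) -> float:
        return self.total_adult_f + self.total_adult_m

    def female_counts(self) -> np.ndarray:
        """Adult females by own genotype (mated + unmated)."""
        return self.adult_f.sum(axis=1) + self.adult_f_unmated


def _largest_remainder(vec: np.ndarray, total: int) -> np.ndarray:
    """Round a non-negative vector to integers preserving the given total."""
    floor = np.floor(vec).astype(np.int64)
    short = total - int(floor.sum())
    if short > 0:
        order = np.argsort(-(vec - floor))
        floor[order[:short]] += 1
    return floor


def equilibrium_state(
    params: LifeHistoryParams,
    derived: DerivedRates,
    cube: InheritanceCube,
    mode: str = "stochastic",
) -> PopulationState:
    """All-wild-type deterministic-equilibrium state, mated to wild type.

    Stochastic mode rounds every cohort with the largest-remainder method
    (which preserves each cohort's total within 1).
    """
    arch = cube.architecture
    n_f, n_m = cube.n_f, cube.n_m
    G = n_f + n_m
    gf, gm = wild_type_genotypes(arch)
    i_f = cube.female_index(gf)
    i_m = cube.male_index(gm)

    def stage(eq: np.ndarray, duration: int) -> np.ndarray:
        # the cube's offspring axis is half daughters / half sons, so each
        # wild-type cohort splits equally between the two wild-type slots
        arr = np.zeros((duration, G))
        arr[:, i_f] = eq / 2.0
        arr[:, n_f + i_m] = eq / 2.0
        return arr

    # eq arrays are ordered youngest (age 0) first; state rows likewise
    eggs = stage(derived.eq_eggs, params.T_E)
    larvae = stage(derived.eq_larvae, params.T_L)
    pupae = stage(derived.eq_pupae, params.T_P)
    adult_m = np.zeros(n_m)
    adult_m[i_m] = derived.eq_adult_m
    adult_f = np.zeros((n_f, n_m))
    adult_f[i_f, i_m] = derived.eq_adult_f

    if mode == "stochastic":
        for arr in (eggs, larvae, pupae):
            for a in range(arr.shape[0]):
                arr[a] = _largest_remainder(arr[a], int(round(arr[a].sum())))
        adult_m = _largest_remainder(adult_m, int(round(adult_m.sum())))
        adult_f = _largest_remainder(
            adult_f.ravel(), int(round(adult_f.sum()))
        ).reshape(n_f, n_m)
        eggs = eggs.astype(np.int64)
        larvae = larvae.astype(np.int64)
        pupae = pupae.astype(np.int64)
        unmated = np.zeros(n_f, dtype=np.int64)
    elif mode == "deterministic":
        unmated = np.zeros(n_f)
    else:
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    return PopulationState(0, eggs, larvae, pupae, adult_m, adult_f, unmated)


# ---------------------------------------------------------------------------
# Releases
# ---------------------------------------------------------------------------

@dataclass
class ReleaseSchedule:
    """Release events: list of ``(day, sex, genotype_code, count)``."""

    events: list = field(default_factory=list)

    def on_day(self, day: int) -> list:
        return [e for e in self.events if e[0] == day]

    @property
    def first_day(self) -> int | None:
        return min((e[0] for e in self.events), default=None)


def weekly_male_releases(
    arch: DriveArchitecture | str,
    first_day: int = 50,
    n_events: int = 5,
    interval: int = 7,
    count: int = 100,
) -> ReleaseSchedule:
    """5 weekly releases of 100 adult males homozygous for the drive (defaults)."""
    if isinstance(arch, str):
        arch = _architecture(arch)
    from .genetics import genotype_to_str

    _, male = drive_homozygotes(arch)
    code = genotype_to_str(male)
    return ReleaseSchedule(
        [(first_day + i * interval, "M", code, count) for i in range(n_events)]
    )


# ---------------------------------------------------------------------------
# Daily step
# ---------------------------------------------------------------------------

class _SimContext:
    """Precomputed vectors shared across days for one (cube, params) pair."""

    def __init__(self, cube: InheritanceCube, params: CubeParams, lh: LifeHistoryParams):
        self.cube = cube
        self.lh = lh
        self.n_f, self.n_m = cube.n_f, cube.n_m
        # per-female-genotype fecundity multiplier (omega x fertility)
        self.fecundity = np.array(
            [
                params.fitness(g) * (1.0 if params.fertile(g) else 0.0)
                for g in cube.female_genotypes
            ]
        )
        # per-male-genotype mating weight
        self.male_weight = np.array([params.fitness(g) for g in cube.male_genotypes])


def step_day(
    state: PopulationState,
    cube: InheritanceCube,
    params: CubeParams,
    derived: DerivedRates,
    lh: LifeHistoryParams,
    releases: Sequence | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "stochastic",
    _ctx: _SimContext | None = None,
) -> PopulationState:
    """Advance the population by exactly one day (in place on a copy).

    Stochastic mode draws Poisson egg counts, multinomial offspring
    genotypes, binomial survival and multinomial mate choice; deterministic
    mode propagates the corresponding expectations.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    stoch = mode == "stochastic"
    if stoch and rng is None:
        raise ValueError("stochastic mode requires an rng")
    ctx = _ctx or _SimContext(cube, params, lh)
    n_f, n_m = ctx.n_f, ctx.n_m
    G = n_f + n_m
    s = state.copy()

    # (1) oviposition ------------------------------------------------------
    table = cube.table
    if stoch:
        eggs_new = np.zeros(G, dtype=np.int64)
        fi, mi = np.nonzero(s.adult_f)
        for i, j in zip(fi, mi):
            mean = lh.beta * ctx.fecundity[i] * s.adult_f[i, j]
            if mean <= 0.0:
                continue
            n_eggs = rng.poisson(mean)
            if n_eggs:
                eggs_new += rng.multinomial(n_eggs, table[i, j])
    else:
        weights = lh.beta * ctx.fecundity[:, None] * s.adult_f
        eggs_new = np.einsum("fm,fmk->k", weights, table)

    # (2) survival ---------------------------------------------------------
    sj = 1.0 - derived.mu_J
    l_total = float(s.larvae.sum())
    dens = (derived.alpha / (derived.alpha + l_total)) ** (1.0 / lh.T_L)
    p_l = sj * dens
    sa = 1.0 - lh.mu_M
    if stoch:
        s.eggs = rng.binomial(s.eggs, sj)
        s.larvae = rng.binomial(s.larvae, p_l)
        s.pupae = rng.binomial(s.pupae, sj)
        s.adult_m = rng.binomial(s.adult_m, sa)
        s.adult_f = rng.binomial(s.adult_f, sa)
        s.adult_f_unmated = rng.binomial(s.adult_f_unmated, sa)
    else:
        s.eggs = s.eggs * sj
        s.larvae = s.larvae * p_l
        s.pupae = s.pupae * sj
        s.adult_m = s.adult_m * sa
        s.adult_f = s.adult_f * sa
        s.adult_f_unmated = s.adult_f_unmated * sa

    # (3) advancement ------------------------------------------------------
    emerging = s.pupae[-1].copy()
    s.pupae = np.vstack([s.larvae[-1][None, :], s.pupae[:-1]])
    s.larvae = np.vstack([s.eggs[-1][None, :], s.larvae[:-1]])
    s.eggs = np.vstack([eggs_new[None, :], s.eggs[:-1]])
    new_f = emerging[:n_f]
    new_m = emerging[n_f:]
    s.adult_m = s.adult_m + new_m

    # (4) mating of newly emerged females ---------------------------------
    def mate(new_females: np.ndarray) -> None:
        w = s.adult_m * ctx.male_weight
        total_w = float(w.sum())
        if total_w <= 0.0:
            if new_females.sum() > 0:
                logger.info(
                    "day %d: %s females emerged with no adult males; they "
                    "remain unmated",
                    s.day + 1,
                    new_females.sum(),
                )
            s.adult_f_unmated = s.adult_f_unmated + new_females
            return
        probs = w / total_w
        for i in np.nonzero(new_females)[0]:
            cnt = new_females[i]
            if stoch:
                s.adult_f[i] += rng.multinomial(int(cnt), probs)
            else:
                s.adult_f[i] = s.adult_f[i] + cnt * probs

    mate(new_f)

    # (5) releases ---------------------------------------------------------
    for day, sex, code, count in releases or ():
        g = genotype_from_str(code, cube.architecture) if isinstance(code, str) else code
        if count <= 0:
            raise ValueError("release counts must be positive")
        if sex == "M":
            s.adult_m[cube.male_index(g)] += count
        else:
            rel = np.zeros(n_f)
            rel[cube.female_index(g)] = count
            mate(rel if not stoch else rel.astype(np.int64))

    s.day = state.day + 1
    return s


# ---------------------------------------------------------------------------
# Scenarios and trajectories
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A complete simulation experiment: genetics + ecology + releases."""

    architecture: DriveArchitecture | str = "full_GD"
    cube_params: CubeParams = field(default_factory=CubeParams)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    releases: ReleaseSchedule | None = None
    mode: str = "replacement"  # "replacement" | "suppression"
    sim_mode: str = "stochastic"  # "stochastic" | "deterministic"
    replicates: int = 1
    seed: int = 0
    horizon: int = 365
    burn_in: int = 50

    def __post_init__(self) -> None:
        if isinstance(self.architecture, str):
            self.architecture = _architecture(self.architecture)
        if self.mode not in ("replacement", "suppression"):
            raise ValueError("mode must be 'replacement' or 'suppression'")
        if self.mode == "suppression" and self.cube_params.fertility_rule is None:
            raise ValueError("suppression mode requires a fertility_rule")
        if self.releases is None:
            self.releases = weekly_male_releases(self.architecture, first_day=self.burn_in)


@dataclass
class Trajectory:
    """Per-day adult counts by genotype plus juvenile stage totals."""

    cube: InheritanceCube
    days: np.ndarray  # (T,)
    adult_f: np.ndarray  # (T, n_f) by own genotype
    adult_m: np.ndarray  # (T, n_m)
    juveniles: np.ndarray  # (T, 3) egg/larva/pupa totals
    release_days: list
    seed: int | None = None

    @property
    def total_adults(self) -> np.ndarray:
        return self.adult_f.sum(axis=1) + self.adult_m.sum(axis=1)

    @property
    def total_adult_f(self) -> np.ndarray:
        return self.adult_f.sum(axis=1)

    def to_dataframe(self, replicate: int = 0):
        """Tidy (replicate, day, stage, sex, genotype, count) table."""
        import pandas as pd
        from .genetics import genotype_to_str

        recs = []
        for t, day in enumerate(self.days):
            for j, g in enumerate(self.cube.female_genotypes):
                if self.adult_f[t, j]:
                    recs.append(
                        (replicate, int(day), "adult", "F", genotype_to_str(g), self.adult_f[t, j])
                    )
            for j, g in enumerate(self.cube.male_genotypes):
                if self.adult_m[t, j]:
                    recs.append(
                        (replicate, int(day), "adult", "M", genotype_to_str(g), self.adult_m[t, j])
                    )
            for k, stage in enumerate(("egg", "larva", "pupa")):
                recs.append((replicate, int(day), stage, "both", "all", self.juveniles[t, k]))
        return pd.DataFrame(
            recs, columns=["replicate", "day", "stage", "sex", "genotype", "count"]
        )


def _simulate_one(
    scenario: Scenario,
    cube: InheritanceCube,
    derived: DerivedRates,
    seed: np.random.SeedSequence | None,
) -> Trajectory:
    lh = scenario.life_history
    stoch = scenario.sim_mode == "stochastic"
    rng = np.random.default_rng(seed) if stoch else None
    state = equilibrium_state(lh, derived, cube, mode=scenario.sim_mode)
    ctx = _SimContext(cube, scenario.cube_params, lh)
    n_days = scenario.burn_in + scenario.horizon
    days = np.arange(1, n_days + 1)
    adult_f = np.zeros((n_days, cube.n_f))
    adult_m = np.zeros((n_days, cube.n_m))
    juv = np.zeros((n_days, 3))
    for t in range(n_days):
        rel = scenario.releases.on_day(state.day + 1)
        state = step_day(
            state,
            cube,
            scenario.cube_params,
            derived,
            lh,
            releases=rel,
            rng=rng,
            mode=scenario.sim_mode,
            _ctx=ctx,
        )
        adult_f[t] = state.female_counts()
        adult_m[t] = state.adult_m
        juv[t] = (state.eggs.sum(), state.larvae.sum(), state.pupae.sum())
    return Trajectory(
        cube=cube,
        days=days,
        adult_f=adult_f,
        adult_m=adult_m,
        juveniles=juv,
        release_days=sorted({e[0] for e in scenario.releases.events}),
    )


def run_scenario(
    scenario: Scenario, cube: InheritanceCube | None = None
) -> list[Trajectory]:
    """Run all replicates of a scenario; reproducible given the master seed.

    Replicate RNG streams are spawned from ``SeedSequence(scenario.seed)``;
    deterministic mode runs a single trajectory regardless of ``replicates``.
    """
    if cube is None:
        cube = build_cube(scenario.architecture, scenario.cube_params)
    derived = calibrate_life_history(scenario.life_history)
    if scenario.sim_mode == "deterministic":
        return [_simulate_one(scenario, cube, derived, None)]
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.replicates)
    out = []
    for i, ss in enumerate(seeds):
        traj = _simulate_one(scenario, cube, derived, ss)
        traj.seed = scenario.seed
        out.append(traj)
    return out
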