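"""Release-experiment composition and summary metrics.

Builds replacement and suppression experiments from the six drive systems
(full_GD, full_GDX, tGD_linked, tGDc, tGDX_linked, tGDXc) over a grid of
allelic conversion efficiencies, runs the population model, and computes the
reported summary metrics: transgene carrier fraction, per-class allele
counts, time to steady state, and crash/rebound classification.

All metrics are pure functions of trajectories: recomputation is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genetics import (
    CubeParams,
    DriveArchitecture,
    Genotype,
    InheritanceCube,
    STATES,
    architecture as _architecture,
    build_cube,
)
from .population import (
    LifeHistoryParams,
    ReleaseSchedule,
    Scenario,
    Trajectory,
    run_scenario,
    weekly_male_releases,
)

__all__ = [
    "Scenario",
    "carrier_fraction",
    "allele_counts",
    "time_to_steady_state",
    "crash_and_rebound",
    "suppression_fertility_rule",
    "replacement_experiment",
    "suppression_experiment",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def carrier_fraction(traj: Trajectory) -> np.ndarray:
    """Per-day fraction of adults carrying >=1 transgene (T) allele.

    Days with zero adults report 0 (flagged implicitly by the zero total).
    """
    cube = traj.cube
    f_mask = np.array([g.count_state("T") > 0 for g in cube.female_genotypes], float)
    m_mask = np.array([g.count_state("T") > 0 for g in cube.male_genotypes], float)
    carriers = traj.adult_f @ f_mask + traj.adult_m @ m_mask
    total = traj.total_adults
    out = np.zeros_like(total)
    nz = total > 0
    out[nz] = carriers[nz] / total[nz]
    return out


def allele_counts(traj: Trajectory) -> pd.DataFrame:
    """Per-day adult allele-copy counts for each (locus, state) class.

    Autosomal loci contribute two copies per adult; X-linked loci contribute
    two per female and one per (hemizygous) male.  Columns are e.g.
    ``"T@A"``; rows are days.  Class counts always sum to the total number of
    allele copies present.
    """
    cube = traj.cube
    arch = cube.architecture
    letters = "AB"[: arch.n_loci]
    cols = {}
    for locus, letter in enumerate(letters):
        for state in STATES:
            fvec = np.array(
                [g.count_state(state, locus) for g in cube.female_genotypes], float
            )
            mvec = np.array(
                [g.count_state(state, locus) for g in cube.male_genotypes], float
            )
            cols[f"{state}@{letter}"] = traj.adult_f @ fvec + traj.adult_m @ mvec
    return pd.DataFrame(cols, index=pd.Index(traj.days, name="day"))


def time_to_steady_state(
    series: np.ndarray, epsilon: float = 0.001, window: int = 30
) -> int | None:
    """First day index t where the series' range over [t, t+window] < epsilon.

    Returns None when no such window exists (the series must be longer than
    the window).
    """
    x = np.asarray(series, dtype=float)
    if x.size <= window:
        raise ValueError("series must be longer than the window")
    for t in range(x.size - window):
        seg = x[t : t + window + 1]
        if seg.max() - seg.min() < epsilon:
            return t
    return None


def _settled_from(series: np.ndarray, epsilon: float, window: int) -> int | None:
    """First day from which *every* later window of the series has range < eps.

    Unlike :func:`time_to_steady_state` (first quiet window anywhere), this
    ignores transiently flat stretches before the drive spreads: it returns
    the day after the last windowed violation, or None when the final window
    still violates.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= window:
        raise ValueError("series must be longer than the window")
    violations = [
        t
        for t in range(x.size - window)
        if x[t : t + window + 1].max() - x[t : t + window + 1].min() >= epsilon
    ]
    if not violations:
        return 0
    last = violations[-1]
    if last == x.size - window - 1:
        return None
    return last + 1


def crash_and_rebound(
    traj: Trajectory,
    N: float,
    rebound_threshold: float = 0.5,
    dip_threshold: float = 0.95,
) -> tuple[int | None, bool, int | None]:
    """Classify a suppression trajectory as crashed and/or rebounded.

    A *crash* is adult-female extinction (females == 0), reported in days
    relative to the first release.  A *rebound* (evaluated only without a
    crash) is a post-release local minimum of total adults followed by
    recovery to at least ``rebound_threshold * N``.  To count as a genuine
    suppression transient rather than demographic noise (which is of order
    sqrt(N)), the minimum must fall below ``dip_threshold * N``; a constant
    or never-suppressed population therefore reports no rebound.  Returns
    ``(crash_day, rebound, rebound_day)``.
    """
    if not traj.release_days:
        raise ValueError("trajectory has no release annotations")
    t0 = traj.release_days[0]
    females = traj.total_adult_f
    adults = traj.total_adults
    after = traj.days >= t0
    crash_ix = np.nonzero(after & (females == 0))[0]
    if crash_ix.size:
        return int(traj.days[crash_ix[0]] - t0), False, None
    post_ix = np.nonzero(after)[0]
    dip = post_ix[np.argmin(adults[post_ix])]
    if adults[dip] >= dip_threshold * N:
        return None, False, None  # never genuinely suppressed
    thresh = rebound_threshold * N
    rec = np.nonzero((np.arange(adults.size) > dip) & (adults >= thresh))[0]
    if rec.size == 0:
        return None, False, None
    return None, True, int(traj.days[rec[0]] - t0)


# ---------------------------------------------------------------------------
# Suppression fertility rule
# ---------------------------------------------------------------------------

def suppression_fertility_rule(arch: DriveArchitecture | str):
    """Sterility predicate: the drive disrupts a female-fertility gene.

    The gRNA locus (the fused locus for full drives) sits in a gene required
    in at least one copy for female fertility; W and R alleles are
    functional, T and B are not.  A female with zero functional copies there
    is sterile.  Hemizygosity is impossible for females, so the rule only
    inspects diploid genotypes.
    """
    if isinstance(arch, str):
        arch = _architecture(arch)
    locus = arch.grna_loci[0]

    def sterile(g: Genotype) -> bool:
        if g.sex != "F":
            return False
        functional = g.count_state("W", locus) + g.count_state("R", locus)
        return functional == 0

    return sterile


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def _scenario_for(
    system: str,
    conversion: float,
    mode: str,
    life_history: LifeHistoryParams,
    replicates: int,
    seed: int,
    horizon: int,
    burn_in: int,
    sim_mode: str,
    rho: float = 1.0,
) -> Scenario:
    arch = _architecture(system)
    fert = suppression_fertility_rule(arch) if mode == "suppression" else None
    params = CubeParams(q=1.0, c=conversion, d=0.0, rho=rho, fertility_rule=fert)
    return Scenario(
        architecture=arch,
        cube_params=params,
        life_history=life_history,
        releases=weekly_male_releases(arch, first_day=burn_in),
        mode=mode,
        sim_mode=sim_mode,
        replicates=replicates,
        seed=seed,
        horizon=horizon,
        burn_in=burn_in,
    )


def replacement_experiment(
    conversions: Sequence[float] = (1.0, 0.9, 0.5),
    systems: Sequence[str] = (
        "full_GD",
        "tGD_linked",
        "tGDc",
        "full_GDX",
        "tGDX_linked",
        "tGDXc",
    ),
    replicates: int = 1,
    life_history: LifeHistoryParams | None = None,
    seed: int = 0,
    horizon: int = 730,
    burn_in: int = 50,
    sim_mode: str = "deterministic",
    steady_epsilon: float = 0.001,
    steady_window: int = 30,
) -> pd.DataFrame:
    """Replacement-mode grid: per (system, conversion, replicate) metrics.

    Returns a summary table with the carrier fraction at the end of the
    horizon (the equilibrium carrier fraction when steady state is reached)
    and the time to steady state of the carrier-fraction series.
    """
    if life_history is None:
        life_history = LifeHistoryParams()
    recs = []
    for system in systems:
        for conv in conversions:
            sc = _scenario_for(
                system, conv, "replacement", life_history, replicates, seed,
                horizon, burn_in, sim_mode,
            )
            for rep, traj in enumerate(run_scenario(sc)):
                cf = carrier_fraction(traj)
                post = cf[traj.days >= burn_in]
                tss = _settled_from(post, steady_epsilon, steady_window)
                recs.append(
                    {
                        "system": system,
                        "conversion": conv,
                        "replicate": rep,
                        "carrier_final": float(cf[-1]),
                        "time_to_steady": tss,
                    }
                )
    return pd.DataFrame.from_records(recs)


def suppression_experiment(
    conversions: Sequence[float] = (1.0, 0.99),
    systems: Sequence[str] = ("full_GD", "tGD_linked"),
    replicates: int = 10,
    life_history: LifeHistoryParams | None = None,
    seed: int = 0,
    horizon: int = 1095,
    burn_in: int = 50,
    rho: float = 1.0,
) -> pd.DataFrame:
    """Suppression-mode grid: per-replicate crash days and rebound flags.

    The drive disrupts a gene required in >=1 copy for female fertility;
    stochastic replicates are classified by :func:`crash_and_rebound`.
    """
    if life_history is None:
        life_history = LifeHistoryParams()
    recs = []
    for system in systems:
        for conv in conversions:
            sc = _scenario_for(
                system, conv, "suppression", life_history, replicates, seed,
                horizon, burn_in, "stochastic", rho=rho,
            )
            for rep, traj in enumerate(run_scenario(sc)):
                crash, rebound, reb_day = crash_and_rebound(traj, life_history.N)
                recs.append(
                    {
                        "system": system,
                        "conversion": conv,
                        "replicate": rep,
                        "crash_day": crash,
                        "rebound": rebound,
                        "rebound_day": reb_day,
                    }
                )
    return pd.DataFrame.from_records(recs)
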