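"""Deterministic synthetic fixtures with the structure the analyses assume.

Generates per-vial scoring tables (the layout of the deposited scoring
workbooks, as diff-able CSV), indel-labeled sequencing-style male records,
and miniature calibrated population scenarios for fast tests.  Every fixture
embeds its generating parameters in a sibling JSON manifest, so pipeline
estimates can be checked against ground truth; regeneration with the same
seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .crosses import (
    CrossScheme,
    GermlineTimingParams,
    IndelSpectrum,
    simulate_cross,
)
from .io import write_scoring_csv
from .population import LifeHistoryParams, Scenario, calibrate_life_history
from .genetics import CubeParams

__all__ = [
    "FixtureSpec",
    "make_scoring_fixture",
    "make_sequencing_fixture",
    "make_small_population_fixture",
    "default_spectra",
]


def default_spectra() -> list[IndelSpectrum]:
    """Two-locus indel spectra emulating the observed allele classes.

    Locus A (*yellow*-style): three recurrent indels plus a 19% singleton
    tail; locus B (*white*-style): three recurrent indels plus a 7% tail.
    """
    return [
        IndelSpectrum(("A", "B", "C"), (0.35, 0.26, 0.20), 0.19, "y"),
        IndelSpectrum(("A", "B", "C"), (0.40, 0.30, 0.23), 0.07, "w"),
    ]


@dataclass
class FixtureSpec:
    """Everything needed to regenerate a scoring fixture byte-identically."""

    scheme: CrossScheme = field(
        default_factory=lambda: CrossScheme(
            f0_cas9_parent="father", f0_grna_parent="mother",
            architecture="tGDX_linked",
        )
    )
    timing: GermlineTimingParams = field(
        default_factory=lambda: GermlineTimingParams(
            z=0.0, k=3, q_late=1.0, c_late=0.9, rho=1.0, spectra=default_spectra()
        )
    )
    n_vials: int = 11
    n_offspring_per_vial: int = 50
    seed: int = 0
    experiment: str = "fixture"

    def manifest(self) -> dict:
        t = self.timing
        return {
            "experiment": self.experiment,
            "scheme": {
                "f0_cas9_parent": self.scheme.f0_cas9_parent,
                "f0_grna_parent": self.scheme.f0_grna_parent,
                "coupled": self.scheme.coupled,
                "f1_sex_scored": self.scheme.f1_sex_scored,
                "architecture": self.scheme.architecture.name,
            },
            "timing": {
                "z": t.z,
                "k": t.k,
                "q_late": t.q_late,
                "c_late": t.c_late,
                "rho": t.rho,
            },
            "n_vials": self.n_vials,
            "n_offspring_per_vial": self.n_offspring_per_vial,
            "seed": self.seed,
        }


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def make_scoring_fixture(spec: FixtureSpec, path: str | Path | None = None) -> pd.DataFrame:
    """Per-vial scoring CSV in the supplementary-workbook layout.

    Writes ``<path>`` and a ``<path>.manifest.json`` recording the generating
    parameters when ``path`` is given; always returns the table.
    """
    table = simulate_cross(
        spec.scheme,
        timing=spec.timing,
        n_vials=spec.n_vials,
        n_offspring_per_vial=spec.n_offspring_per_vial,
        seed=spec.seed,
        experiment=spec.experiment,
    )
    if path is not None:
        path = Path(path)
        write_scoring_csv(table, path)
        _write_manifest(path.with_suffix(path.suffix + ".manifest.json"), spec.manifest())
    return table


def make_sequencing_fixture(
    spec: FixtureSpec,
    n_vials: int | None = None,
    males_per_vial: int = 4,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Indel-labeled male records emulating F2 sequencing samples.

    Simulates the cross and keeps only male rows bearing an indel label,
    down-sampling to at most ``males_per_vial`` labeled males per vial
    (deterministically, by row order) to mimic per-vial sequencing effort.
    """
    spec2 = FixtureSpec(
        scheme=spec.scheme,
        timing=spec.timing,
        n_vials=n_vials or spec.n_vials,
        n_offspring_per_vial=spec.n_offspring_per_vial,
        seed=spec.seed,
        experiment=spec.experiment,
    )
    table = make_scoring_fixture(spec2)
    males = table[(table["sex"] == "M") & table["indel"].notna()].copy()
    out = []
    for vial, sub in males.groupby("vial"):
        kept = 0
        for _, row in sub.iterrows():
            take = min(int(row["count"]), males_per_vial - kept)
            if take <= 0:
                break
            row = row.copy()
            row["count"] = take
            out.append(row)
            kept += take
    seq = pd.DataFrame(out, columns=table.columns).reset_index(drop=True)
    if path is not None:
        path = Path(path)
        write_scoring_csv(seq, path)
        _write_manifest(
            path.with_suffix(path.suffix + ".manifest.json"),
            {**spec2.manifest(), "males_per_vial": males_per_vial},
        )
    return seq


def make_small_population_fixture(
    N: float = 500.0,
    horizon: int = 200,
    seed: int = 0,
    architecture: str = "full_GD",
    **scenario_kwargs,
) -> Scenario:
    """A calibrated miniature scenario for fast population tests.

    The returned scenario's deterministic equilibrium equals the requested
    ``N`` within 1% (calibration is checked here; an infeasible ``N``
    raises).
    """
    lh = LifeHistoryParams(N=N)
    calibrate_life_history(lh)  # raises if infeasible
    return Scenario(
        architecture=architecture,
        cube_params=scenario_kwargs.pop("cube_params", CubeParams()),
        life_history=lh,
        seed=seed,
        horizon=horizon,
        **scenario_kwargs,
    )
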