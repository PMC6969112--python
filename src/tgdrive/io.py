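"""File formats: scoring-table CSV, cube CSV export/import, config schema.

The scoring CSV schema has header
``experiment,vial,sex,dsred,gfp,body,eye,count,indel`` with one row per
distinct phenotype combination per vial and non-negative integer counts.  An
import shim also accepts single-sheet spreadsheet exports of per-vial scoring
workbooks after a documented column mapping.

Cube CSVs are long format: ``mother,father,offspring,sex,probability`` using
the canonical genotype string codes (``"TA-WB/WA-TB|F"``); import reverses
the export bit-exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .crosses import SCORING_COLUMNS
from .genetics import (
    InheritanceCube,
    architecture as _architecture,
    enumerate_genotypes,
    genotype_from_str,
    genotype_to_str,
)

__all__ = [
    "read_scoring_csv",
    "write_scoring_csv",
    "read_supplementary_xlsx",
    "export_cube_csv",
    "import_cube_csv",
    "load_config",
]


class ValidationError(ValueError):
    """Raised for malformed input files or configs (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# Scoring tables
# ---------------------------------------------------------------------------

def write_scoring_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a scoring table in the canonical column order."""
    missing = [c for c in SCORING_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"scoring table missing columns: {missing}")
    table[SCORING_COLUMNS].to_csv(path, index=False)


def read_scoring_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a scoring CSV; malformed rows are reported by line.

    Unknown extra columns are ignored with a warning; missing required
    columns, negative or non-integer counts raise :class:`ValidationError`
    naming the offending line numbers (header = line 1).
    """
    df = pd.read_csv(path, dtype={"indel": "string"})
    extra = [c for c in df.columns if c not in SCORING_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")
        df = df.drop(columns=extra)
    missing = [c for c in SCORING_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != counts.round())]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 0-based index
        raise ValidationError(
            f"{path}: invalid count on line(s) {lines} "
            "(counts must be non-negative integers)"
        )
    df["count"] = counts.astype(np.int64)
    return df[SCORING_COLUMNS]


#: Default mapping from per-vial spreadsheet exports to the scoring schema.
#: Keys are canonical column names; values are candidate source headers
#: (matched case-insensitively after stripping).
SUPPLEMENTARY_COLUMN_MAP = {
    "experiment": ("experiment", "cross", "condition"),
    "vial": ("vial", "vial id", "female", "f1 female"),
    "sex": ("sex",),
    "dsred": ("dsred", "dsred+", "red", "cas9 marker"),
    "gfp": ("gfp", "gfp+", "green", "grna marker"),
    "body": ("body", "body color", "body phenotype"),
    "eye": ("eye", "eye color", "eye phenotype"),
    "count": ("count", "n", "number", "flies"),
    "indel": ("indel", "allele", "indel label"),
}


def read_supplementary_xlsx(
    path: str | Path,
    sheet: int | str = 0,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Import a single-sheet spreadsheet export of per-vial scoring data.

    Columns are matched to the scoring schema via ``SUPPLEMENTARY_COLUMN_MAP``
    (case-insensitive); absent optional columns (``experiment``, ``body``,
    ``eye``, ``indel``) are filled with defaults.  Marker columns accept
    ``+/-`` flags or positive-count columns alongside a total count.
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    cmap = column_map or SUPPLEMENTARY_COLUMN_MAP
    lower = {str(c).strip().lower(): c for c in raw.columns}
    out = {}
    for canon, candidates in cmap.items():
        for cand in candidates:
            if cand in lower:
                out[canon] = raw[lower[cand]]
                break
    df = pd.DataFrame(out)
    for col, default in (
        ("experiment", Path(path).stem),
        ("sex", "both"),
        ("dsred", "-"),
        ("gfp", "-"),
        ("body", "na"),
        ("eye", "na"),
        ("indel", pd.NA),
    ):
        if col not in df.columns:
            df[col] = default
    if "vial" not in df.columns or "count" not in df.columns:
        raise ValidationError(
            f"{path}: could not locate vial/count columns; "
            "supply an explicit column_map"
        )
    df["count"] = pd.to_numeric(df["count"], errors="coerce").fillna(0).astype(np.int64)
    return df[SCORING_COLUMNS]


# ---------------------------------------------------------------------------
# Cube CSV
# ---------------------------------------------------------------------------

def export_cube_csv(cube: InheritanceCube, path: str | Path, threshold: float = 0.0) -> None:
    """Long-format cube export: mother,father,offspring,sex,probability.

    Probabilities are written with ``repr`` round-trip precision so import
    reproduces the cube bit-exactly; zero entries are omitted.
    """
    off = cube.offspring_index
    with open(path, "w") as fh:
        fh.write(f"# architecture={cube.architecture.name}\n")
        fh.write("mother,father,offspring,sex,probability\n")
        for i, mg in enumerate(cube.female_genotypes):
            for j, fg in enumerate(cube.male_genotypes):
                row = cube.table[i, j]
                for k in np.nonzero(row > threshold)[0]:
                    g = off[k]
                    fh.write(
                        f"{genotype_to_str(mg)},{genotype_to_str(fg)},"
                        f"{genotype_to_str(g)},{g.sex},{float(row[k])!r}\n"
                    )


def import_cube_csv(path: str | Path) -> InheritanceCube:
    """Rebuild an :class:`InheritanceCube` from its CSV export."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# architecture="):
            raise ValidationError(f"{path}: missing architecture header comment")
        arch = _architecture(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    females, males = enumerate_genotypes(arch)
    f_ix = {g: i for i, g in enumerate(females)}
    m_ix = {g: i for i, g in enumerate(males)}
    n_f = len(females)
    table = np.zeros((n_f, len(males), n_f + len(males)))
    for _, row in df.iterrows():
        mg = genotype_from_str(row["mother"], arch)
        fg = genotype_from_str(row["father"], arch)
        og = genotype_from_str(row["offspring"], arch)
        k = f_ix[og] if og.sex == "F" else n_f + m_ix[og]
        table[f_ix[mg], m_ix[fg], k] = float(row["probability"])
    return InheritanceCube(arch, females, males, table)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "architecture",
    "cube_params",
    "timing",
    "life_history",
    "releases",
    "mode",
    "sim_mode",
    "replicates",
    "seed",
    "horizon",
    "burn_in",
    "output",
    "experiment",
}


def load_config(path: str | Path) -> dict:
    """Load and schema-check a JSON run config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a JSON object")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg
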