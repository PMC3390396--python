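"""Reading, writing and validating the tab-delimited table dialect.

Two tables circulate between the simulator and the analyses:

* cells:  cell_id, genotype, bivalent_id, sc_length, shape_class,
          n_class1, n_class2
* foci:   cell_id, bivalent_id, channel, position_frac
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["CELLS_COLUMNS", "FOCI_COLUMNS", "SchemaReport", "read_cells", "read_foci", "validate_tables"]

CELLS_COLUMNS = ("cell_id", "genotype", "bivalent_id", "sc_length", "shape_class", "n_class1", "n_class2")
FOCI_COLUMNS = ("cell_id", "bivalent_id", "channel", "position_frac")
SHAPE_LABELS = {"univalent_pair", "rod", "ring"}


@dataclass
class SchemaReport:
    """Outcome of validating one or more tables."""

    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, msg: str) -> None:
        self.errors.append(msg)

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.errors)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CELLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cells table {path} is missing columns: {missing}")
    return df


def read_foci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FOCI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"foci table {path} is missing columns: {missing}")
    return df


def _validate_cells(df: pd.DataFrame, name: str, report: SchemaReport) -> None:
    for col in CELLS_COLUMNS:
        if col not in df.columns:
            report.add(f"{name}: missing column '{col}'")
    if not report.ok:
        return
    bad_shape = ~df["shape_class"].isin(SHAPE_LABELS)
    for row in df.index[bad_shape]:
        report.add(f"{name}: row {row}: unknown shape_class {df.at[row, 'shape_class']!r}")
    bad_len = df["sc_length"] <= 0
    for row in df.index[bad_len]:
        report.add(f"{name}: row {row}: non-positive sc_length {df.at[row, 'sc_length']!r}")
    for col in ("n_class1", "n_class2"):
        bad = df[col] < 0
        for row in df.index[bad]:
            report.add(f"{name}: row {row}: negative {col}")
    dup = df.duplicated(subset=["cell_id", "bivalent_id"])
    for row in df.index[dup]:
        report.add(f"{name}: row {row}: duplicate (cell_id, bivalent_id) key")


def _validate_foci(df: pd.DataFrame, name: str, report: SchemaReport) -> None:
    for col in FOCI_COLUMNS:
        if col not in df.columns:
            report.add(f"{name}: missing column '{col}'")
    if not report.ok:
        return
    bad = (df["position_frac"] < 0) | (df["position_frac"] > 1)
    for row in df.index[bad]:
        report.add(f"{name}: row {row}: position_frac {df.at[row, 'position_frac']} outside [0, 1]")
    empty = df["channel"].astype(str).str.len() == 0
    for row in df.index[empty]:
        report.add(f"{name}: row {row}: empty channel label")


def validate_tables(cells_path=None, foci_path=None) -> SchemaReport:
    """Check column names, value domains and duplicate keys of the tables."""
    report = SchemaReport()
    if cells_path is not None:
        path = Path(cells_path)
        if not path.exists():
            report.add(f"{path}: file not found")
        else:
            _validate_cells(pd.read_csv(path, sep="\t"), path.name, report)
    if foci_path is not None:
        path = Path(foci_path)
        if not path.exists():
            report.add(f"{path}: file not found")
        else:
            _validate_foci(pd.read_csv(path, sep="\t"), path.name, report)
    return report
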