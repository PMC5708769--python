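"""Concentration-panel container and delimited-table IO.

A panel is a subjects x analytes matrix of cytokine concentrations in pg/ml,
tagged with the body compartment (seminal_fluid | serum) and species it was
drawn from. Undetectable analytes are stored as exact 0, not as missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CytokinePanel", "read_panel", "write_panel"]


@dataclass
class CytokinePanel:
    """Subjects x analytes concentration matrix (pg/ml) with sample metadata."""

    values: pd.DataFrame
    compartment: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate analyte names: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if np.isfinite(arr).all() and (arr < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values.index)

    def drop_analytes(self, names: Iterable[str]) -> "CytokinePanel":
        names = list(names)
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise ValueError(f"analytes not in panel: {missing}")
        return replace(self, values=self.values.drop(columns=names))

    def select_subjects(self, index: Sequence[int]) -> "CytokinePanel":
        """Row-resample (e.g. bootstrap) by positional index."""
        return replace(self, values=self.values.iloc[list(index)])


def read_panel(path: str | Path, compartment: str = "", species: str = "") -> CytokinePanel:
    """Read a delimited panel: first column subject ID, remaining columns analytes."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index.name = None
    return CytokinePanel(df, compartment=compartment, species=species)


def write_panel(panel: CytokinePanel, path: str | Path, sep: str = ",") -> None:
    panel.values.to_csv(path, sep=sep, index_label="subject")
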