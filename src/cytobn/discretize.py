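"""Ternary discretisation: z-score normalisation + equal-frequency binning.

Concentrations are standardised per analyte and allocated to three ordered
relative-concentration bins (low, intermediate, high) holding (approximately)
equal numbers of subjects. Tied raw values always share a bin — deterministic
and label-independent — at the cost of count imbalance for zero-inflated
columns. Equal-frequency binning is invariant under strictly increasing
transforms, so the z-score step cannot change bin membership; it is retained
to keep the pipeline's order of operations explicit and is pinned by a
regression test rather than removed.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import CytokinePanel

__all__ = [
    "DiscretePanel",
    "zscore",
    "equal_frequency_bins",
    "apply_bins",
    "discretize_panel",
    "write_discrete_panel",
    "read_discrete_panel",
]

log = logging.getLogger(__name__)


@dataclass
class DiscretePanel:
    """Subjects x analytes matrix over states {0: low, 1: intermediate, 2: high},
    with per-analyte cut points on the z-scale and a note of any constant
    columns excluded from learning."""

    states: pd.DataFrame
    cutpoints: dict[str, tuple[float, float]]
    excluded: tuple[str, ...] = ()
    compartment: str = ""
    species: str = ""

    @property
    def analytes(self) -> list[str]:
        return list(self.states.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.states.index)

    def to_array(self) -> np.ndarray:
        return self.states.to_numpy(dtype=np.int64)


def zscore(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardise each column to mean 0, sample SD 1 (ddof=1).

    Columns with fewer than two distinct values cannot be standardised; they
    are returned unchanged and listed as constant for the caller to exclude.
    """
    out = values.copy().astype(float)
    constant: list[str] = []
    for col in values.columns:
        x = out[col].to_numpy()
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            constant.append(col)
            log.warning("column %r is constant; flagged and excluded from learning", col)
            continue
        out[col] = (x - x.mean()) / sd
    return out, constant


def equal_frequency_bins(
    values: Sequence[float], k: int = 3
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Allocate values to k ordered equal-frequency bins; return states and cuts.

    Distinct values are consumed in ascending order; each bin's capacity is
    re-targeted as ceil(remaining / bins_left) so tied values always land in
    one bin and counts stay within +/-1 of equal when values are distinct.
    Cut points are the largest value in each bin but the last; re-applying
    them with ``apply_bins`` reproduces the same states.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    uniq, counts = np.unique(x, return_counts=True)
    states = np.zeros(n, dtype=np.int64)
    cuts: list[float] = []
    bin_idx, filled, remaining = 0, 0, n
    target = math.ceil(remaining / k)
    for v, c in zip(uniq, counts):
        if bin_idx < k - 1 and filled >= target:
            cuts.append(float(prev))
            remaining -= filled
            bin_idx += 1
            filled = 0
            target = math.ceil(remaining / (k - bin_idx))
        states[x == v] = bin_idx
        filled += c
        prev = v
    while len(cuts) < k - 1:  # fewer distinct values than bins
        cuts.append(float(uniq[-1]))
    observed = np.bincount(states, minlength=k)
    if observed.max() - observed[observed > 0].min() > 1:
        log.info("tied values produced imbalanced bin counts %s", observed.tolist())
    return states, tuple(cuts)


def apply_bins(values: Sequence[float], cuts: Sequence[float]) -> np.ndarray:
    """State of each value under existing cut points: v <= cuts[i] -> bin i."""
    x = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(cuts, dtype=float), x, side="left").astype(np.int64)


def discretize_panel(panel: CytokinePanel, k: int = 3) -> DiscretePanel:
    """z-score then equal-frequency bin every non-constant analyte column."""
    z, constant = zscore(panel.values)
    keep = [c for c in panel.analytes if c not in constant]
    states = {}
    cutpoints: dict[str, tuple[float, float]] = {}
    for col in keep:
        s, cuts = equal_frequency_bins(z[col].to_numpy(), k=k)
        states[col] = s
        cutpoints[col] = tuple(cuts)
    return DiscretePanel(
        states=pd.DataFrame(states, index=panel.values.index, columns=keep),
        cutpoints=cutpoints,
        excluded=tuple(constant),
        compartment=panel.compartment,
        species=panel.species,
    )


def write_discrete_panel(dpanel: DiscretePanel, prefix: str | Path) -> None:
    """CSV of 0/1/2 states plus a sidecar JSON of per-analyte cut points."""
    prefix = Path(prefix)
    dpanel.states.to_csv(prefix.with_suffix(".csv"), index_label="subject")
    meta = {
        "cutpoints": {a: list(c) for a, c in sorted(dpanel.cutpoints.items())},
        "excluded": list(dpanel.excluded),
        "compartment": dpanel.compartment,
        "species": dpanel.species,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_discrete_panel(prefix: str | Path) -> DiscretePanel:
    prefix = Path(prefix)
    states = pd.read_csv(prefix.with_suffix(".csv"), index_col=0)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return DiscretePanel(
        states=states,
        cutpoints={a: tuple(c) for a, c in meta["cutpoints"].items()},
        excluded=tuple(meta["excluded"]),
        compartment=meta["compartment"],
        species=meta["species"],
    )
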