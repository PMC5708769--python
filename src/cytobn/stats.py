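"""Univariate panel comparisons: dilution correction, normality-routed tests,
Holm's sequential correction, and significance-annotated comparison tables.

Normality of each comparison is assessed by Shapiro-Wilk (on the paired
difference vector, or on each group separately for unpaired designs) and the
comparison routed to a parametric t-test or its rank-based counterpart.
Zero-inflated columns keep their zeros as true values; zero-difference pairs
in the Wilcoxon signed-rank test are handled by the Pratt rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .panel import CytokinePanel

__all__ = [
    "DilutionRecord",
    "correct_dilution",
    "correct_panel_dilution",
    "route_test",
    "holm_adjust",
    "compare_panels",
    "SIGNIFICANCE_TIERS",
]

SIGNIFICANCE_TIERS = ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"))


@dataclass(frozen=True)
class DilutionRecord:
    """Sample mass and diluent volume for one specimen.

    Sample volume is derived from mass at unit density (1 g = 1 ml), so the
    correction factor is (sample + diluent volume) / sample volume >= 1.
    """

    sample_mass_g: float
    diluent_volume_ul: float = 200.0

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.diluent_volume_ul < 0:
            raise ValueError("diluent volume must be non-negative")

    @property
    def sample_volume_ul(self) -> float:
        return self.sample_mass_g * 1000.0

    @property
    def factor(self) -> float:
        v = self.sample_volume_ul
        return (v + self.diluent_volume_ul) / v


def correct_dilution(measured: float | np.ndarray, record: DilutionRecord) -> float | np.ndarray:
    """Scale a measured concentration back to the undiluted specimen."""
    measured = np.asarray(measured, dtype=float)
    if (measured < 0).any():
        raise ValueError("measured concentrations must be non-negative")
    out = measured * record.factor
    return float(out) if out.ndim == 0 else out


def correct_panel_dilution(
    panel: CytokinePanel,
    sample_mass_g: Sequence[float] | pd.Series,
    diluent_volume_ul: float = 200.0,
) -> CytokinePanel:
    """Apply per-subject dilution correction to a whole panel."""
    mass = pd.Series(sample_mass_g, index=panel.values.index, dtype=float)
    factors = np.array(
        [DilutionRecord(m, diluent_volume_ul).factor for m in mass], dtype=float
    )
    return CytokinePanel(
        panel.values.mul(factors, axis=0),
        compartment=panel.compartment,
        species=panel.species,
    )


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > alpha


def route_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = True,
    alpha: float = 0.05,
) -> str:
    """Choose the comparison test from Shapiro-Wilk normality at level alpha.

    Paired designs test the difference vector: normal -> "paired-t", else
    "wilcoxon-signed-rank" ("degenerate" when all differences are 0).
    Unpaired designs require both groups normal for "unpaired-t", else
    "mann-whitney".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        if len(x) < 3:
            raise ValueError("need n >= 3")
        d = x - y
        if np.ptp(d) == 0:
            return "degenerate"
        return "paired-t" if _shapiro_normal(d, alpha) else "wilcoxon-signed-rank"
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 in both groups")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return "degenerate"
    if _shapiro_normal(x, alpha) and _shapiro_normal(y, alpha):
        return "unpaired-t"
    return "mann-whitney"


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _run_test(x: np.ndarray, y: np.ndarray, test: str) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "degenerate":
            return 1.0
        if test == "paired-t":
            p = sps.ttest_rel(x, y).pvalue
        elif test == "wilcoxon-signed-rank":
            try:
                p = sps.wilcoxon(x, y, zero_method="pratt").pvalue
            except ValueError:  # all differences zero
                return 1.0
        elif test == "unpaired-t":
            equal_var = sps.levene(x, y).pvalue > 0.05
            p = sps.ttest_ind(x, y, equal_var=equal_var).pvalue
        elif test == "mann-whitney":
            p = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    return 1.0 if np.isnan(p) else float(min(p, 1.0))


def _tier(p: float) -> str:
    for cut, label in SIGNIFICANCE_TIERS:
        if p < cut:
            return label
    return "ns"


def compare_panels(
    a: CytokinePanel,
    b: CytokinePanel,
    paired: bool = True,
    shapiro_alpha: float = 0.05,
    significance_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-analyte comparison table with Holm correction across the family.

    Returns one row per analyte: group means +/- SEM, the routed test, raw and
    Holm-adjusted p, which group is higher (only when adjusted p < alpha), and
    a significance tier (ns, <0.05, <0.01, <0.001).
    """
    cols_a, cols_b = set(a.analytes), set(b.analytes)
    if cols_a != cols_b:
        raise ValueError(
            "analyte sets differ; only in a: "
            f"{sorted(cols_a - cols_b)}; only in b: {sorted(cols_b - cols_a)}"
        )
    analytes = a.analytes
    if paired and a.n_subjects != b.n_subjects:
        raise ValueError("paired comparison requires equal subject counts")

    rows = []
    for name in analytes:
        x = a.values[name].to_numpy(dtype=float)
        y = b.values[name].to_numpy(dtype=float)
        test = route_test(x, y, paired=paired, alpha=shapiro_alpha)
        p_raw = _run_test(x, y, test)
        rows.append(
            {
                "analyte": name,
                "mean_a": x.mean(),
                "sem_a": sps.sem(x) if len(x) > 1 else 0.0,
                "mean_b": y.mean(),
                "sem_b": sps.sem(y) if len(y) > 1 else 0.0,
                "test": test,
                "p_raw": p_raw,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    significant = table["p_holm"] < significance_alpha
    higher = np.where(table["mean_a"] >= table["mean_b"], "a", "b")
    table["higher_in"] = np.where(significant, higher, "")
    table["tier"] = [_tier(p) for p in table["p_holm"]]
    return table
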