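"""Synthetic concentration panels with known generative structure.

The generator draws discrete analyte states by ancestral sampling along a
ground-truth DAG, then emits positive, right-skewed concentrations (pg/ml)
from per-(analyte, state) lognormal components, optionally zero-inflated to
mimic undetectable assay readings. Because the true graph is known, every
downstream stage — discretisation, scoring, structure search, bootstrap —
can be tested for recovery without access to raw assay data.

Calibration to published mean/SEM pairs works by moment-matching a single
lognormal per analyte and splitting it into three tercile components on the
log scale, so that equal-frequency state marginals reproduce the target mean
exactly (closed form) and the target SD approximately.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import CytokinePanel

__all__ = [
    "STATES",
    "GroundTruthModel",
    "PanelSpec",
    "uniform_cpt",
    "diagonal_cpt",
    "sample_states",
    "states_to_concentrations",
    "generate_panel",
    "calibrate_to_moments",
    "ground_truth_demo",
    "skeleton_f1",
    "write_edge_list",
]

STATES = ("low", "intermediate", "high")
N_STATES = 3

# Standard-normal tercile geometry used to split a lognormal into three
# equal-mass components: conditional means +/- 3*phi(z_{1/3}) and 0, and the
# common within-tercile SD.
_Z13 = sps.norm.ppf(1.0 / 3.0)
_TERCILE_MEAN = 3.0 * sps.norm.pdf(_Z13)          # ~1.0911
_TERCILE_SD = math.sqrt(1.0 - 2.0 / 3.0 * _TERCILE_MEAN**2)  # ~0.4535
_TERCILE_MEANS = np.array([-_TERCILE_MEAN, 0.0, _TERCILE_MEAN])


def uniform_cpt(n_parents: int) -> np.ndarray:
    """CPT with every row uniform over the 3 states; shape (3**k, 3)."""
    q = N_STATES**n_parents
    return np.full((q, N_STATES), 1.0 / N_STATES)


def diagonal_cpt(n_parents: int, strength: float = 0.8) -> np.ndarray:
    """CPT concentrating mass on the (rounded) mean parent state.

    For one parent this is the doubly-stochastic "noisy copy" matrix, which
    preserves uniform marginals under ancestral sampling.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if n_parents == 0:
        return uniform_cpt(0)
    q = N_STATES**n_parents
    cpt = np.full((q, N_STATES), (1.0 - strength) / (N_STATES - 1))
    for j in range(q):
        digits, rem = [], j
        for _ in range(n_parents):
            digits.append(rem % N_STATES)
            rem //= N_STATES
        target = int(math.floor(sum(digits) / n_parents + 0.5))
        cpt[j, target] = strength
    return cpt


def _parent_config_codes(states: np.ndarray) -> np.ndarray:
    """Encode rows of parent states (n, k) as base-3 integers, first parent
    most significant. Shape (n,)."""
    n, k = states.shape
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = code * N_STATES + states[:, j]
    return code


@dataclass
class GroundTruthModel:
    """Generative model: DAG + CPTs + lognormal emission + zero inflation.

    ``parents`` maps each node to its (name-sorted) parent tuple; ``cpts``
    holds a (3**k, 3) row-stochastic table per node, rows indexed by the
    base-3 code of parent states (first parent most significant); ``emission``
    holds per node a (3, 2) array of (location, scale) lognormal parameters on
    the log-pg/ml scale, one row per state; ``zero_rate`` is the per-analyte
    probability that an observation is recorded as 0 (undetectable).
    """

    nodes: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    emission: dict[str, np.ndarray]
    zero_rate: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        for v in self.nodes:
            self.parents[v] = tuple(sorted(self.parents.get(v, ())))
            self.cpts[v] = np.asarray(self.cpts[v], dtype=float)
            self.emission[v] = np.asarray(self.emission[v], dtype=float)
            self.zero_rate.setdefault(v, 0.0)
        self.validate()

    def validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth graph must be acyclic")
        for v in self.nodes:
            for p in self.parents[v]:
                if p not in self.nodes:
                    raise ValueError(f"unknown parent {p!r} of {v!r}")
            cpt = self.cpts[v]
            q = N_STATES ** len(self.parents[v])
            if cpt.shape != (q, N_STATES):
                raise ValueError(f"CPT for {v!r} must have shape ({q}, 3)")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {v!r} must sum to 1")
            if (cpt < 0).any():
                raise ValueError(f"CPT for {v!r} has negative entries")
            em = self.emission[v]
            if em.shape != (N_STATES, 2):
                raise ValueError(f"emission for {v!r} must have shape (3, 2)")
            if (em[:, 1] < 0).any():
                raise ValueError(f"emission scales for {v!r} must be >= 0")
            locs = em[:, 0]
            if np.any(np.diff(locs) < 0):
                raise ValueError(f"emission locations for {v!r} must be non-decreasing")
            if np.any(em[:, 1] > 0) and np.any(np.diff(locs) <= 0):
                raise ValueError(
                    f"emission locations for {v!r} must be strictly increasing "
                    "in state order when emission noise is present"
                )
            zr = self.zero_rate[v]
            if not 0.0 <= zr <= 1.0:
                raise ValueError(f"zero_rate for {v!r} must lie in [0, 1]")

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v in self.nodes:
            g.add_edges_from((p, v) for p in self.parents[v])
        return g

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, v) for v in self.nodes for p in self.parents[v])

    def topological_order(self) -> list[str]:
        # ties broken by analyte name for determinism
        return list(nx.lexicographical_topological_sort(self.dag()))


@dataclass
class PanelSpec:
    """What a synthetic panel should look like (size, labels, target moments)."""

    analytes: tuple[str, ...]
    n_subjects: int = 20
    compartment: str = "seminal_fluid"
    species: str = "rat"
    target_moments: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.analytes = tuple(self.analytes)
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 (three non-empty bins)")
        if len(set(self.analytes)) != len(self.analytes):
            raise ValueError("analyte names must be unique")


def sample_states(
    model: GroundTruthModel, n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ancestral sampling of discrete states; subjects x analytes, values 0/1/2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    out = pd.DataFrame(
        np.zeros((n, len(model.nodes)), dtype=np.int64),
        index=[f"S{i + 1}" for i in range(n)],
        columns=list(model.nodes),
    )
    for v in model.topological_order():
        pa = model.parents[v]
        if pa:
            codes = _parent_config_codes(out[list(pa)].to_numpy())
            probs = model.cpts[v][codes]
        else:
            probs = np.broadcast_to(model.cpts[v][0], (n, N_STATES))
        u = rng.random(n)
        out[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, N_STATES - 1)
    return out


def states_to_concentrations(
    states: pd.DataFrame,
    model: GroundTruthModel,
    rng: np.random.Generator | None = None,
) -> CytokinePanel:
    """Emit pg/ml concentrations from the per-(analyte, state) lognormal pairs,
    then zero out observations with per-analyte probability ``zero_rate``."""
    if rng is None:
        rng = np.random.default_rng(model.seed + 1)
    arr = states.to_numpy()
    if not np.isin(arr, [0, 1, 2]).all():
        raise ValueError("states must be coded 0 (low), 1 (intermediate), 2 (high)")
    n = len(states)
    values = {}
    for v in states.columns:
        if v not in model.emission:
            raise ValueError(f"no emission model for analyte {v!r}")
        em = model.emission[v]
        s = states[v].to_numpy()
        draw = np.exp(em[s, 0] + em[s, 1] * rng.standard_normal(n))
        zr = model.zero_rate.get(v, 0.0)
        if zr > 0:
            draw = np.where(rng.random(n) < zr, 0.0, draw)
        values[v] = draw
    df = pd.DataFrame(values, index=states.index, columns=list(states.columns))
    return CytokinePanel(df)


def generate_panel(
    model: GroundTruthModel,
    n: int,
    seed: int | None = None,
    compartment: str = "",
    species: str = "",
) -> CytokinePanel:
    """Sample states and concentrations with a single RNG stream.

    Fixed (model, n, seed) gives bit-identical panels across runs.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    states = sample_states(model, n, rng)
    panel = states_to_concentrations(states, model, rng)
    panel.compartment = compartment
    panel.species = species
    return panel


def _emission_from_moments(mean: float, sd: float) -> np.ndarray:
    """Three-component lognormal emission whose equal-weight mixture has the
    requested mean exactly and approximately the requested SD.

    The target lognormal (mu, sigma) is split at its terciles on the log scale;
    each state keeps the within-tercile normal moments, then all locations are
    shifted by a closed-form factor so the mixture mean equals ``mean``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive for a lognormal emission")
    if sd == 0:
        loc = math.log(mean)
        return np.array([[loc, 0.0]] * N_STATES)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(mean) - sigma2 / 2.0
    locs = mu + sigma * _TERCILE_MEANS
    scale = sigma * _TERCILE_SD
    mixture_mean = np.mean(np.exp(locs + scale**2 / 2.0))
    locs = locs + math.log(mean / mixture_mean)
    return np.column_stack([locs, np.full(N_STATES, scale)])


def calibrate_to_moments(spec: PanelSpec, seed: int = 0) -> GroundTruthModel:
    """Moment-match an independent-analyte model to per-analyte (mean, SEM).

    The target SD is SEM * sqrt(n_subjects). State marginals are uniform
    (empty DAG, uniform CPTs), so the marginal mean matches the target in
    closed form. A mean of 0 with SEM 0 is encoded as an always-undetectable
    analyte (zero_rate = 1); a non-positive mean with nonzero SEM is invalid.
    """
    if spec.target_moments is None:
        raise ValueError("PanelSpec.target_moments is required for calibration")
    parents = {a: () for a in spec.analytes}
    cpts = {a: uniform_cpt(0) for a in spec.analytes}
    emission: dict[str, np.ndarray] = {}
    zero_rate: dict[str, float] = {}
    for a in spec.analytes:
        mean, sem = spec.target_moments[a]
        if mean <= 0:
            if sem != 0 or mean < 0:
                raise ValueError(
                    f"analyte {a!r}: non-positive mean with nonzero SEM is invalid"
                )
            # below detection limit throughout: every draw recorded as 0
            emission[a] = np.array([[0.0, 0.0]] * N_STATES)
            zero_rate[a] = 1.0
            continue
        sd = sem * math.sqrt(spec.n_subjects)
        emission[a] = _emission_from_moments(mean, sd)
        zero_rate[a] = 0.0
    return GroundTruthModel(
        nodes=spec.analytes,
        parents=parents,
        cpts=cpts,
        emission=emission,
        zero_rate=zero_rate,
        seed=seed,
    )


_DEMO_EDGES: tuple[tuple[str, str], ...] = (
    ("IL-12 (p70)", "IL-10"),
    ("IL-10", "IL-6"),
    ("IL-10", "IFN-gamma"),
    ("IFN-gamma", "TNF-alpha"),
    ("MCP-1", "RANTES"),
    ("MCP-1", "KC"),
    ("RANTES", "KC"),
    ("KC", "TNF-alpha"),
)


def ground_truth_demo(seed: int = 0, strength: float = 0.8) -> GroundTruthModel:
    """Fixed 8-node / 8-edge benchmark model for structure-recovery checks.

    Two roots (IL-12 (p70), MCP-1) drive interleukin and chemokine branches
    that converge on TNF-alpha, echoing the root / hub / terminal vocabulary
    the reporting layer annotates; maximum in-degree is 2 so every family is
    well informed at moderate sample sizes. CPTs are "noisy copy" tables of
    the given strength; emissions are well-separated unit-scale lognormal
    components.
    """
    nodes = tuple(sorted({u for e in _DEMO_EDGES for u in e}))
    parents: dict[str, tuple[str, ...]] = {v: () for v in nodes}
    for p, c in _DEMO_EDGES:
        parents[c] = tuple(sorted((*parents[c], p)))
    cpts = {v: diagonal_cpt(len(parents[v]), strength) for v in nodes}
    emission = {
        v: np.column_stack([np.log([10.0, 30.0, 90.0]), np.full(3, 0.25)])
        for v in nodes
    }
    return GroundTruthModel(
        nodes=nodes,
        parents=parents,
        cpts=cpts,
        emission=emission,
        zero_rate={v: 0.0 for v in nodes},
        seed=seed,
    )


def skeleton_f1(
    true_edges: Iterable[tuple[str, str]], learned_edges: Iterable[tuple[str, str]]
) -> float:
    """F1 of the undirected skeleton of a learned edge set vs the truth."""
    truth = {frozenset(e) for e in true_edges}
    learned = {frozenset(e) for e in learned_edges}
    tp = len(truth & learned)
    if tp == 0:
        return 0.0
    precision = tp / len(learned)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write a ground-truth DAG as a tab-separated parent<TAB>child file."""
    with open(path, "w") as fh:
        for p, c in sorted(edges):
            fh.write(f"{p}\t{c}\n")
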