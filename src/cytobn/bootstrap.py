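"""Non-parametric bootstrap confidence for learned network features.

Subjects (rows) are resampled with replacement B times (default 100); the
structure learner is re-run on each replicate and, for every directed edge,
the confidence is the fraction of replicates containing it. The undirected
skeleton confidence (either orientation) is reported alongside, since edge
direction within a Markov equivalence class is weakly identified at small n.
The point-estimate DAG learned on the full data is annotated edge-by-edge and
dichotomised at the confidence threshold (default 0.80): "grey" at or above,
"red" below.

By default replicates reuse the full-data bin cut points, so resampling the
discrete states is exact; optional per-replicate re-discretisation from the
raw panel is available.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .discretize import DiscretePanel, discretize_panel
from .panel import CytokinePanel
from .priors import PriorNetwork
from .scoring import DagModel
from .search import tabu_search

__all__ = ["ConsensusNetwork", "bootstrap_confidence"]


@dataclass
class ConsensusNetwork:
    """Point-estimate DAG with per-edge bootstrap confidences.

    ``edges`` has one row per point-estimate edge: parent, child, confidence
    (directed replicate fraction), skeleton_confidence, and tier (grey | red).
    Full replicate fractions for all observed edges are kept in
    ``directed_confidence`` / ``skeleton_confidence``.
    """

    point: DagModel
    edges: pd.DataFrame
    directed_confidence: dict[tuple[str, str], float]
    skeleton_confidence: dict[frozenset, float]
    threshold: float = 0.80
    n_replicates: int = 100

    def __post_init__(self) -> None:
        for conf in self.directed_confidence.values():
            if not 0.0 <= conf <= 1.0:
                raise ValueError("confidences must lie in [0, 1]")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.point.nodes

    def high_confidence_edges(self) -> list[tuple[str, str]]:
        return [
            (r.parent, r.child)
            for r in self.edges.itertuples()
            if r.tier == "grey"
        ]


def bootstrap_confidence(
    dpanel: DiscretePanel,
    *,
    B: int = 100,
    threshold: float = 0.80,
    seed: int = 0,
    prior: PriorNetwork | None = None,
    ess: float = 1.0,
    kappa: float = 0.0,
    max_parents: int = 3,
    tabu_len: int = 10,
    max_iter: int = 1000,
    stall_window: int = 50,
    n_restarts: int = 16,
    raw_panel: CytokinePanel | None = None,
    rediscretise_per_replicate: bool = False,
    n_bins: int = 3,
) -> ConsensusNetwork:
    """Learn the full-data DAG and bootstrap per-edge confidences.

    ``rediscretise_per_replicate`` recomputes equal-frequency cut points on
    each resampled raw panel (requires ``raw_panel``); the default keeps the
    full-data cut points, which is equivalent to resampling discrete rows.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if rediscretise_per_replicate and raw_panel is None:
        raise ValueError("rediscretise_per_replicate requires raw_panel")

    learn_kw = dict(
        prior=prior,
        ess=ess,
        kappa=kappa,
        max_parents=max_parents,
        tabu_len=tabu_len,
        max_iter=max_iter,
        stall_window=stall_window,
        n_restarts=n_restarts,
    )
    point = tabu_search(dpanel, **learn_kw)
    n = dpanel.n_subjects
    rng = np.random.default_rng(seed)
    directed: dict[tuple[str, str], int] = {}
    skeleton: dict[frozenset, int] = {}
    states = dpanel.states
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if rediscretise_per_replicate:
            replicate = discretize_panel(raw_panel.select_subjects(idx), k=n_bins)
        else:
            replicate = states.iloc[idx]
        model = tabu_search(replicate, **learn_kw)
        for e in model.edges():
            directed[e] = directed.get(e, 0) + 1
            sk = frozenset(e)
            skeleton[sk] = skeleton.get(sk, 0) + 1

    directed_conf = {e: c / B for e, c in directed.items()}
    skeleton_conf = {e: c / B for e, c in skeleton.items()}
    rows = []
    for p, c in point.edges():
        conf = directed_conf.get((p, c), 0.0)
        sconf = skeleton_conf.get(frozenset((p, c)), 0.0)
        rows.append(
            {
                "parent": p,
                "child": c,
                "confidence": conf,
                "skeleton_confidence": sconf,
                "tier": "grey" if conf >= threshold else "red",
            }
        )
    edges = pd.DataFrame(
        rows, columns=["parent", "child", "confidence", "skeleton_confidence", "tier"]
    )
    return ConsensusNetwork(
        point=point,
        edges=edges,
        directed_confidence=directed_conf,
        skeleton_confidence=skeleton_conf,
        threshold=threshold,
        n_replicates=B,
    )
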