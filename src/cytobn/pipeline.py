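"""End-to-end analysis: discretise -> learn -> bootstrap -> annotate -> export.

One call takes a concentration panel (plus an optional knowledge prior) to a
bootstrap-annotated consensus network with fitted CPTs, topology roles and
colour states, and writes deterministic text outputs (edge table, node table,
SIF/GraphML, run-metadata JSON). Identical seed + config give byte-identical
outputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import ConsensusNetwork, bootstrap_confidence
from .discretize import DiscretePanel, discretize_panel
from .panel import CytokinePanel
from .priors import PriorNetwork
from .report import classify_topology, colour_nodes, export_network
from .scoring import fit_cpts

__all__ = ["LearnConfig", "PipelineResult", "run_pipeline", "write_result"]


@dataclass(frozen=True)
class LearnConfig:
    """Learner settings: scoring, search, bootstrap and discretisation knobs.

    Defaults: ESS 1.0 (a weak BDeu prior), kappa 1.0 (soft knowledge-prior
    penalty per non-prior edge; irrelevant without a prior), max 3 parents
    (27 parent configurations — about the most 20 subjects can inform),
    tabu list 10 / stall window 50 / 1000 moves, 100 bootstrap replicates
    dichotomised at 0.80 confidence, 3 concentration bins.
    """

    ess: float = 1.0
    kappa: float = 1.0
    max_parents: int = 3
    tabu_len: int = 10
    max_iter: int = 1000
    stall_window: int = 50
    n_restarts: int = 16
    n_bootstrap: int = 100
    threshold: float = 0.80
    seed: int = 0
    rediscretise_per_replicate: bool = False
    n_bins: int = 3
    hub_min_degree: int = 3

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LearnConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run produces."""

    panel: CytokinePanel
    dpanel: DiscretePanel
    consensus: ConsensusNetwork
    cpts: dict[str, np.ndarray]
    topology: pd.DataFrame
    colours: pd.DataFrame
    config: LearnConfig
    prior_edges: int = 0

    @property
    def dag(self):
        return self.consensus.point

    def metadata(self) -> dict:
        return {
            "package_version": __version__,
            "config": json.loads(self.config.to_json()),
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "species": self.panel.species,
            "compartment": self.panel.compartment,
            "n_subjects": self.panel.n_subjects,
            "analytes": list(self.panel.analytes),
            "constant_columns_excluded": list(self.dpanel.excluded),
            "prior_edges": self.prior_edges,
            "n_edges": int(len(self.consensus.edges)),
            "bde_score": float(self.dag.score),
            "score_model": "BDeu (uniform equivalent-sample-size Dirichlet prior)",
        }


def run_pipeline(
    panel: CytokinePanel,
    prior: PriorNetwork | None = None,
    config: LearnConfig | None = None,
) -> PipelineResult:
    """Full analysis of one panel; see module docstring."""
    config = config or LearnConfig()
    if prior is not None:
        prior = prior.restrict_to(panel.analytes)
    dpanel = discretize_panel(panel, k=config.n_bins)
    consensus = bootstrap_confidence(
        dpanel,
        B=config.n_bootstrap,
        threshold=config.threshold,
        seed=config.seed,
        prior=prior,
        ess=config.ess,
        kappa=config.kappa if prior is not None else 0.0,
        max_parents=config.max_parents,
        tabu_len=config.tabu_len,
        max_iter=config.max_iter,
        stall_window=config.stall_window,
        n_restarts=config.n_restarts,
        raw_panel=panel,
        rediscretise_per_replicate=config.rediscretise_per_replicate,
        n_bins=config.n_bins,
    )
    cpts = fit_cpts(consensus.point, dpanel, ess=config.ess)
    topology = classify_topology(consensus, hub_min_degree=config.hub_min_degree)
    colours = colour_nodes(cpts, consensus)
    return PipelineResult(
        panel=panel,
        dpanel=dpanel,
        consensus=consensus,
        cpts=cpts,
        topology=topology,
        colours=colours,
        config=config,
        prior_edges=0 if prior is None else len(prior),
    )


def write_result(
    result: PipelineResult, prefix: str | Path, format: str = "sif"
) -> list[Path]:
    """Write the edge table, network export and run metadata; returns paths.

    All outputs are plain text with fixed float formatting, so identical
    seed + config reproduce them byte for byte.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_path = Path(f"{prefix}.network.tsv")
    result.consensus.edges.to_csv(edge_path, sep="\t", index=False, float_format="%.6f")
    files = [edge_path]
    files += export_network(result.consensus, result.topology, result.colours, prefix, format)
    cpt_path = Path(f"{prefix}.cpts.json")
    cpt_path.write_text(
        json.dumps(
            {v: np.round(c, 10).tolist() for v, c in sorted(result.cpts.items())},
            indent=2,
            sort_keys=True,
        )
    )
    meta_path = Path(f"{prefix}.meta.json")
    meta_path.write_text(json.dumps(result.metadata(), indent=2, sort_keys=True))
    return files + [cpt_path, meta_path]
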