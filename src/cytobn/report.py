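"""Topology annotation, CPT-based node colouring, cross-species abridgement,
and Cytoscape-compatible export of learned networks.

Node vocabulary: an orphan has no edges at all; a parent (root) node has no
incoming edges and at least one outgoing; a terminal node has no outgoing
edges and at least one incoming; a hub is a highly connected non-terminal
node (total degree >= hub_min_degree, or in-degree >= 2 with out-degree >= 1
— a configurable stand-in, with raw degrees always reported so users can
apply their own criterion); everything else is internal. Node colour encodes
the modal conditional concentration state — high (green), low (red),
intermediate (white) — with intensity scaled by how far the modal probability
exceeds the uniform 1/3.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .bootstrap import ConsensusNetwork, bootstrap_confidence
from .panel import CytokinePanel
from .priors import PriorNetwork
from .scoring import DagModel

__all__ = [
    "classify_topology",
    "colour_nodes",
    "abridge_and_relearn",
    "export_network",
    "read_network",
]

_COLOUR_BY_STATE = {0: "red", 1: "white", 2: "green"}


def _as_dag(net: ConsensusNetwork | DagModel) -> DagModel:
    return net.point if isinstance(net, ConsensusNetwork) else net


def classify_topology(
    net: ConsensusNetwork | DagModel, hub_min_degree: int = 3
) -> pd.DataFrame:
    """Assign each node exactly one role; returns (node, role, in_degree,
    out_degree) sorted by node name."""
    dag = _as_dag(net)
    g = dag.to_digraph()
    rows = []
    for v in sorted(dag.nodes):
        din, dout = g.in_degree(v), g.out_degree(v)
        if din == 0 and dout == 0:
            role = "orphan"
        elif dout == 0:
            role = "terminal"
        elif din == 0:
            role = "parent"
        elif din + dout >= hub_min_degree or (din >= 2 and dout >= 1):
            role = "hub"
        else:
            role = "internal"
        rows.append({"node": v, "role": role, "in_degree": din, "out_degree": dout})
    return pd.DataFrame(rows)


def colour_nodes(
    cpts: Mapping[str, np.ndarray], net: ConsensusNetwork | DagModel
) -> pd.DataFrame:
    """Colour each node from its CPT with parents fixed at their modal states.

    Modal states are resolved in topological order from the roots; the modal
    probability p* of the node's conditional row sets colour (state) and
    intensity (p* - 1/3) / (2/3). A (near-)uniform row, or a modal
    intermediate state, is white with intensity 0. Ties prefer the
    intermediate state, then the lower state, deterministically.
    """
    dag = _as_dag(net)
    missing = [v for v in dag.nodes if v not in cpts]
    if missing:
        raise ValueError(f"missing CPTs for nodes: {missing}")
    order = list(nx.lexicographical_topological_sort(dag.to_digraph()))
    modal: dict[str, int] = {}
    rows = {}
    n_states = 3
    for v in order:
        pa = dag.parents[v]
        cpt = np.asarray(cpts[v], dtype=float)
        code = 0
        for p in pa:
            code = code * n_states + modal[p]
        row = cpt[code]
        pmax = float(row.max())
        candidates = [k for k in range(n_states) if row[k] >= pmax - 1e-12]
        state = 1 if 1 in candidates else min(candidates)
        modal[v] = state
        if pmax <= 1.0 / 3.0 + 1e-12 or state == 1:
            colour, intensity = "white", 0.0
        else:
            colour = _COLOUR_BY_STATE[state]
            intensity = (pmax - 1.0 / 3.0) / (2.0 / 3.0)
        rows[v] = {
            "node": v,
            "modal_state": state,
            "colour": colour,
            "intensity": float(np.clip(intensity, 0.0, 1.0)),
        }
    return pd.DataFrame([rows[v] for v in sorted(rows)])


def abridge_and_relearn(
    panel: CytokinePanel,
    exclusions,
    config=None,
    prior: PriorNetwork | None = None,
):
    """Drop the excluded analytes and re-run the whole pipeline from scratch.

    The full network is never edited in place: discretisation, learning and
    bootstrap all restart on the reduced panel, so abridged and full runs with
    the same seed differ only through column removal.
    """
    from .pipeline import run_pipeline  # local import: pipeline builds on report

    exclusions = list(exclusions)
    unknown = [a for a in exclusions if a not in panel.analytes]
    if unknown:
        raise ValueError(f"exclusions not in panel: {unknown}")
    if len(exclusions) >= len(panel.analytes):
        raise ValueError("cannot exclude every analyte")
    reduced = panel.drop_analytes(exclusions) if exclusions else panel
    return run_pipeline(reduced, prior=prior, config=config)


def _edge_frame(net: ConsensusNetwork) -> pd.DataFrame:
    return net.edges.sort_values(["parent", "child"]).reset_index(drop=True)


def export_network(
    net: ConsensusNetwork,
    annotations: pd.DataFrame,
    colours: pd.DataFrame,
    prefix: str | Path,
    format: str = "sif",
) -> list[Path]:
    """Write a SIF + node/edge attribute tables, or a single GraphML.

    SIF lines are ``source<TAB>regulates<TAB>target`` in sorted order; the
    node table carries role, degrees, colour and intensity, the edge table
    confidence, skeleton confidence and grey/red tier. Exports round-trip
    losslessly through :func:`read_network`.
    """
    prefix = Path(prefix)
    nodes = annotations.merge(colours, on="node").sort_values("node").reset_index(drop=True)
    edges = _edge_frame(net)
    if format == "sif":
        sif = prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for r in edges.itertuples():
                fh.write(f"{r.parent}\tregulates\t{r.child}\n")
        nodes_path = Path(f"{prefix}.nodes.tsv")
        edges_path = Path(f"{prefix}.edges.tsv")
        nodes.to_csv(nodes_path, sep="\t", index=False, float_format="%.6f")
        edges.to_csv(edges_path, sep="\t", index=False, float_format="%.6f")
        return [sif, nodes_path, edges_path]
    if format == "graphml":
        g = nx.DiGraph()
        for r in nodes.itertuples():
            g.add_node(
                r.node,
                role=r.role,
                in_degree=int(r.in_degree),
                out_degree=int(r.out_degree),
                colour=r.colour,
                intensity=float(r.intensity),
                modal_state=int(r.modal_state),
            )
        for r in edges.itertuples():
            g.add_edge(
                r.parent,
                r.child,
                confidence=float(r.confidence),
                skeleton_confidence=float(r.skeleton_confidence),
                tier=r.tier,
            )
        path = prefix.with_suffix(".graphml")
        nx.write_graphml(g, path)
        return [path]
    raise ValueError(f"unknown format {format!r}; use 'sif' or 'graphml'")


def read_network(prefix: str | Path, format: str = "sif") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back an export as (edge table, node table) for round-trip checks."""
    prefix = Path(prefix)
    if format == "sif":
        nodes = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t")
        edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")
        sif_edges = []
        for line in prefix.with_suffix(".sif").read_text().splitlines():
            u, _, v = line.split("\t")
            sif_edges.append((u, v))
        if sif_edges != [(r.parent, r.child) for r in edges.itertuples()]:
            raise ValueError("SIF and edge-attribute table disagree")
        return edges, nodes
    if format == "graphml":
        g = nx.read_graphml(prefix.with_suffix(".graphml"))
        nodes = pd.DataFrame(
            [{"node": n, **attrs} for n, attrs in sorted(g.nodes(data=True))]
        )
        edges = pd.DataFrame(
            [
                {"parent": u, "child": v, **attrs}
                for u, v, attrs in sorted(g.edges(data=True))
            ],
            columns=["parent", "child", "confidence", "skeleton_confidence", "tier"],
        )
        return edges, nodes
    raise ValueError(f"unknown format {format!r}; use 'sif' or 'graphml'")
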