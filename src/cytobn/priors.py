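"""Knowledge-prior handling: species-network intersection, feedback-loop
removal, and conversion of an adirectional prior into a structure-search bias.

Curated knowledge networks (and text-mining edge lists) enter as files; the
prior used for seeding is the undirected intersection of both species'
networks — direction information is discarded before intersecting, and any
structural feedback loops in directed inputs are broken by a deterministic
greedy feedback-arc heuristic. The prior biases structure search two ways:
as the initial structure of the Tabu search (a name-order acyclic orientation
of prior edges) and as a soft log-prior penalty of -kappa on every modelled
edge absent from the prior skeleton; kappa = 0 recovers a uniform structure
prior, so data can always overrule the seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx

__all__ = [
    "PriorNetwork",
    "intersect_networks",
    "remove_feedback_loops",
    "prior_bias",
    "read_edge_list",
    "write_edge_list",
]

log = logging.getLogger(__name__)

Edge = tuple[str, str]


def _skeleton(edges: Iterable[Edge]) -> set[frozenset]:
    out = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-edge {u!r}-{v!r} not allowed")
        out.add(frozenset((u, v)))
    return out


@dataclass
class PriorNetwork:
    """Undirected analyte-pair edge set with per-edge prior weight in (0, 1]."""

    edges: frozenset = frozenset()
    weights: dict = field(default_factory=dict)
    source: str = "knowledge-base"

    def __post_init__(self) -> None:
        self.edges = frozenset(frozenset(e) for e in self.edges)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("prior edges must join two distinct analytes")
            w = self.weights.setdefault(e, 1.0)
            if not 0 < w <= 1:
                raise ValueError(f"edge weight must lie in (0, 1], got {w}")
        self.weights = {frozenset(e): w for e, w in self.weights.items() if frozenset(e) in self.edges}

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def restrict_to(self, analytes: Iterable[str]) -> "PriorNetwork":
        """Drop edges with endpoints outside the analysed analyte set."""
        keep = set(analytes)
        dropped = {e for e in self.edges if not e <= keep}
        if dropped:
            log.warning(
                "dropping %d prior edges with endpoints outside the analyte set",
                len(dropped),
            )
        kept = self.edges - dropped
        return PriorNetwork(
            edges=kept,
            weights={e: self.weights[e] for e in kept},
            source=self.source,
        )

    def sorted_pairs(self) -> list[Edge]:
        return sorted(tuple(sorted(e)) for e in self.edges)


def intersect_networks(
    a: Iterable[Edge] | PriorNetwork,
    b: Iterable[Edge] | PriorNetwork,
    source: str = "knowledge-base",
) -> PriorNetwork:
    """Undirected intersection of two edge sets (direction discarded first).

    An empty intersection is a valid empty prior: isolated nodes simply have
    no ascribed edges and structure is learned from data alone.
    """
    sa = a.edges if isinstance(a, PriorNetwork) else _skeleton(a)
    sb = b.edges if isinstance(b, PriorNetwork) else _skeleton(b)
    wa = a.weights if isinstance(a, PriorNetwork) else {}
    wb = b.weights if isinstance(b, PriorNetwork) else {}
    common = frozenset(sa) & frozenset(sb)
    if not common:
        log.warning("prior intersection is empty; structure search proceeds unseeded")
    weights = {e: min(wa.get(e, 1.0), wb.get(e, 1.0)) for e in common}
    return PriorNetwork(edges=common, weights=weights, source=source)


def remove_feedback_loops(
    edges: Iterable[Edge],
    weights: Mapping[Edge, float] | None = None,
) -> tuple[list[Edge], list[Edge]]:
    """Break every directed cycle by greedy minimum-weight edge removal.

    On each detected cycle the lowest-weight edge is removed (ties broken by
    (parent, child) name order), until the graph is acyclic. Returns the kept
    and removed edge lists, both name-sorted. Deterministic; exact minimum
    feedback arc set is out of scope.
    """
    weights = dict(weights or {})
    g = nx.DiGraph()
    edge_list = sorted(set(edges))
    g.add_edges_from(edge_list)
    removed: list[Edge] = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        victim = min(
            ((u, v) for u, v, *_ in cycle),
            key=lambda e: (weights.get(e, 1.0), e),
        )
        g.remove_edge(*victim)
        removed.append(victim)
        log.info("removed feedback edge %s -> %s", *victim)
    kept = sorted(g.edges())
    return kept, sorted(removed)


def prior_bias(prior: PriorNetwork | None, kappa: float) -> Callable[[str, str], float]:
    """Per-edge structure log-prior: 0 for edges in the prior skeleton,
    -kappa for edges absent from it. kappa = 0 is the uniform prior."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    skeleton = prior.edges if prior is not None else frozenset()

    def bias(parent: str, child: str) -> float:
        if kappa == 0 or frozenset((parent, child)) in skeleton:
            return 0.0
        return -kappa

    return bias


def read_edge_list(path: str | Path, directed: bool = False):
    """Tab-separated edge list; optional third column is the weight (default 1).

    Returns (edges, weights) with edges as (u, v) tuples in file order.
    """
    edges: list[Edge] = []
    weights: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed edge line: {line!r}")
        u, v = parts[0], parts[1]
        w = float(parts[2]) if len(parts) > 2 else 1.0
        edges.append((u, v))
        key = (u, v) if directed else frozenset((u, v))
        weights[key] = w
    return edges, weights


def write_edge_list(
    edges: Iterable[Edge],
    path: str | Path,
    weights: Mapping | None = None,
) -> None:
    weights = weights or {}
    with open(path, "w") as fh:
        for u, v in sorted(set(edges)):
            w = weights.get((u, v), weights.get(frozenset((u, v))))
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w}\n")
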