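"""Structure optimisation: Tabu search over single-edge moves, plus an
exhaustive enumeration oracle for small node counts.

Moves are add / delete / reverse of one directed edge. The best admissible
non-tabu move is taken even when it worsens the score (the tabu list of
recently undone moves prevents immediate backtracking; an aspiration rule
admits a tabu move that beats the best structure seen). Each run returns its
best-so-far DAG after a stall window without improvement or max_iter moves.

Deterministic tabu trajectories can enter limit cycles that never visit
score basins reachable only through several jointly worsening moves (e.g. a
multi-parent collider whose single edges each look harmful), so the search
is diversified with seeded random restarts: restart 0 starts from the
prior-seeded (or supplied) structure, later restarts from random DAGs drawn
from a generator derived from ``seed``. Move enumeration is ordered
lexicographically by node name with ties broken by the smallest move tuple,
so results are bit-reproducible for a fixed data set, configuration and seed.
"""
from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator, Sequence

import numpy as np

from .priors import PriorNetwork
from .scoring import DagModel, FamilyScorer, as_state_matrix

__all__ = [
    "tabu_search",
    "exhaustive_search",
    "enumerate_dags",
    "seed_structure",
]

_EPS = 1e-12


def _is_acyclic(parents: dict[str, set[str]]) -> bool:
    # Kahn's algorithm on the parents map
    indeg = {v: len(ps) for v, ps in parents.items()}
    children: dict[str, list[str]] = {v: [] for v in parents}
    for v, ps in parents.items():
        for p in ps:
            children[p].append(v)
    queue = [v for v, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for c in children[u]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(parents)


def seed_structure(
    prior: PriorNetwork | None,
    nodes: Sequence[str],
    max_parents: int,
) -> dict[str, set[str]]:
    """Initial structure for the search: prior edges oriented by name order
    (lower name -> higher name), trimmed to the parent limit.

    Orientation along a fixed total order of names is automatically acyclic.
    """
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    if prior is None:
        return parents
    node_set = set(nodes)
    for u, v in prior.sorted_pairs():
        if u in node_set and v in node_set and len(parents[v]) < max_parents:
            parents[v].add(u)
    return parents


def _random_structure(
    nodes: Sequence[str], max_parents: int, rng: np.random.Generator, p_edge: float = 0.5
) -> dict[str, set[str]]:
    """Random DAG: random topological order, each admissible edge kept with
    probability p_edge subject to the parent limit."""
    order = list(nodes)
    rng.shuffle(order)
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for j, v in enumerate(order):
        for u in order[:j]:
            if len(parents[v]) < max_parents and rng.random() < p_edge:
                parents[v].add(u)
    return parents


def _descendants(children: dict[str, set[str]], root: str) -> set[str]:
    out: set[str] = set()
    stack = [root]
    while stack:
        u = stack.pop()
        for c in children[u]:
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def _has_other_path(children: dict[str, set[str]], src: str, dst: str) -> bool:
    """True if src reaches dst by some path other than the direct edge."""
    stack = [c for c in children[src] if c != dst]
    seen = set(stack)
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for c in children[u]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def _admissible(move, delta, current, best_score, tabu) -> bool:
    if move not in tabu:
        return True
    return current + delta > best_score + _EPS  # aspiration


def _tabu_run(
    scorer: FamilyScorer,
    names: tuple[str, ...],
    init: dict[str, set[str]],
    max_parents: int,
    tabu_len: int,
    max_iter: int,
    stall_window: int,
) -> tuple[dict[str, frozenset], float]:
    parents = {v: set(init.get(v, ())) for v in names}
    children: dict[str, set[str]] = {v: set() for v in names}
    for v, ps in parents.items():
        for p in ps:
            children[p].add(v)

    local = {v: scorer.local(v, parents[v]) for v in names}
    current = sum(local.values())
    best_parents = {v: frozenset(ps) for v, ps in parents.items()}
    best_score = current
    tabu: deque = deque(maxlen=max(tabu_len, 1))
    stall = 0

    for _ in range(max_iter):
        # descendant sets give O(1) cycle checks for add moves
        desc = {v: _descendants(children, v) for v in names}
        best_move = None
        best_delta = None
        for y in names:
            p_y = parents[y]
            base_y = local[y]
            for x in names:
                if x == y:
                    continue
                if x in p_y:
                    delta_del = scorer.local(y, p_y - {x}) - base_y
                    candidates = [(("del", x, y), delta_del)]
                    if len(parents[x]) < max_parents and not _has_other_path(children, x, y):
                        delta_rev = delta_del + scorer.local(x, parents[x] | {y}) - local[x]
                        candidates.append((("rev", x, y), delta_rev))
                else:
                    if len(p_y) >= max_parents or x in desc[y]:
                        continue
                    candidates = [(("add", x, y), scorer.local(y, p_y | {x}) - base_y)]
                for move, delta in candidates:
                    if not _admissible(move, delta, current, best_score, tabu):
                        continue
                    if (
                        best_delta is None
                        or delta > best_delta + _EPS
                        or (abs(delta - best_delta) <= _EPS and move < best_move)
                    ):
                        best_move, best_delta = move, delta
        if best_move is None:
            break
        kind, x, y = best_move
        if kind == "add":
            parents[y].add(x)
            children[x].add(y)
            tabu.append(("del", x, y))
        elif kind == "del":
            parents[y].discard(x)
            children[x].discard(y)
            tabu.append(("add", x, y))
        else:  # reverse x->y into y->x
            parents[y].discard(x)
            children[x].discard(y)
            parents[x].add(y)
            children[y].add(x)
            tabu.append(("rev", y, x))
        for v in (x, y):
            local[v] = scorer.local(v, parents[v])
        current = sum(local.values())
        if current > best_score + _EPS:
            best_score = current
            best_parents = {v: frozenset(ps) for v, ps in parents.items()}
            stall = 0
        else:
            stall += 1
            if stall >= stall_window:
                break
    return best_parents, best_score


def tabu_search(
    data,
    nodes: Sequence[str] | None = None,
    *,
    prior: PriorNetwork | None = None,
    ess: float = 1.0,
    kappa: float = 0.0,
    seed: int = 0,
    max_parents: int = 3,
    tabu_len: int = 10,
    max_iter: int = 1000,
    stall_window: int = 50,
    n_restarts: int = 16,
    n_states: int = 3,
    init_parents: dict[str, Iterable[str]] | None = None,
    scorer: FamilyScorer | None = None,
) -> DagModel:
    """Optimise the BDeu (+ knowledge-prior) score by restarted Tabu search.

    Returns the best DagModel over ``n_restarts`` runs (the first from the
    prior-seeded or supplied initial structure, the rest from seeded random
    DAGs) with its total score. Bit-reproducible for fixed inputs and seed.
    """
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    arr, names = as_state_matrix(data, nodes)
    if len(names) < 2:
        raise ValueError("need at least 2 analytes to learn structure")
    if scorer is None:
        scorer = FamilyScorer(arr, names, ess=ess, n_states=n_states, prior=prior, kappa=kappa)
    names = scorer.nodes

    if init_parents is not None:
        first = {v: set(init_parents.get(v, ())) for v in names}
        if not _is_acyclic(first):
            raise ValueError("initial structure must be acyclic")
    else:
        first = seed_structure(prior, names, max_parents)

    rng = np.random.default_rng(seed)
    best_parents = None
    best_score = -np.inf
    for run in range(n_restarts):
        init = first if run == 0 else _random_structure(names, max_parents, rng)
        parents, score = _tabu_run(
            scorer, names, init, max_parents, tabu_len, max_iter, stall_window
        )
        if score > best_score + _EPS:
            best_parents, best_score = parents, score
    return DagModel(
        nodes=names,
        parents={v: tuple(sorted(ps)) for v, ps in best_parents.items()},
        score=best_score,
    )


def enumerate_dags(
    nodes: Sequence[str], max_parents: int | None = None
) -> Iterator[dict[str, tuple[str, ...]]]:
    """Yield the parents map of every DAG over ``nodes`` (25 DAGs for 3 nodes,
    543 for 4). Intended as a brute-force oracle; refuses > 4 nodes."""
    nodes = tuple(nodes)
    p = len(nodes)
    if p > 4:
        raise ValueError("exhaustive enumeration is limited to 4 nodes")
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    m = len(pairs)
    for mask in range(1 << m):
        parents: dict[str, set[str]] = {v: set() for v in nodes}
        for bit in range(m):
            if mask >> bit & 1:
                u, v = pairs[bit]
                parents[v].add(u)
        if max_parents is not None and any(len(ps) > max_parents for ps in parents.values()):
            continue
        if not _is_acyclic(parents):
            continue
        yield {v: tuple(sorted(ps)) for v, ps in parents.items()}


def exhaustive_search(
    data,
    nodes: Sequence[str] | None = None,
    *,
    prior: PriorNetwork | None = None,
    ess: float = 1.0,
    kappa: float = 0.0,
    max_parents: int | None = None,
    n_states: int = 3,
) -> DagModel:
    """Globally optimal DAG by scoring every structure (<= 4 nodes).

    Ties are broken toward the structure whose sorted edge list is smallest,
    so the result is deterministic.
    """
    arr, names = as_state_matrix(data, nodes)
    scorer = FamilyScorer(arr, names, ess=ess, n_states=n_states, prior=prior, kappa=kappa)
    best = None
    best_score = -np.inf
    best_edges = None
    for parents in enumerate_dags(names, max_parents=max_parents):
        score = scorer.total(parents)
        edges = sorted((p, v) for v, ps in parents.items() for p in ps)
        if score > best_score + _EPS or (
            abs(score - best_score) <= _EPS and (best_edges is None or edges < best_edges)
        ):
            best, best_score, best_edges = parents, score, edges
    return DagModel(nodes=names, parents=best, score=best_score)
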