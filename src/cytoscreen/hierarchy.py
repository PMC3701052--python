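"""AUC-weighted gating hierarchies.

For each selected terminal phenotype with *m* specified markers, the space
of gating orders is the lattice of subsets of its constraints: a path from
the root (no constraints) to the terminal adds one marker at a time.  The
best path maximises the cumulative predictive power — the sum of AUC over
the phenotypes visited (root excluded, terminal included) — and is found
exactly by dynamic programming over the 2^m subset lattice rather than
enumerating all m! orders.  Paths for all terminals are merged into one
annotated DAG whose node attribute is the phenotype AUC and whose edge
weight is the AUC gained by adding that marker.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx

from .lattice import NEUTRAL, Phenotype, ROOT_CODE

CUMULATIVE = "cumulative"
TERMINAL_ONLY = "terminal-only"
MIN_EDGE = "min-edge"
SCORE_MODES = (CUMULATIVE, TERMINAL_ONLY, MIN_EDGE)


@dataclass(frozen=True)
class GatingPath:
    """A root -> terminal marker-addition path with its score."""

    phenotypes: tuple[Phenotype, ...]  # root first, terminal last
    score: float

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(p.code for p in self.phenotypes)


def _sub_phenotype(terminal: Phenotype, subset: tuple[int, ...]) -> Phenotype:
    """Phenotype keeping only the constraints at the given marker indices."""
    states = [NEUTRAL] * len(terminal.panel)
    for idx in subset:
        states[idx] = terminal.states[idx]
    return Phenotype(terminal.panel, tuple(states))


def best_paths(
    terminal: Phenotype,
    auc: Mapping[str, float],
    n_paths: int = 1,
    score_mode: str = CUMULATIVE,
) -> list[GatingPath]:
    """Top-scoring root->terminal paths through the sub-phenotype lattice.

    ``auc`` maps phenotype code -> AUC and must cover every sub-phenotype of
    the terminal (all 2^m subsets of its constraints).  The returned list is
    ranked by score, best first; ties broken deterministically by path
    codes.  The optimum is exact (dynamic programming); ``n_paths`` > 1
    returns the best distinct orderings.
    """
    if score_mode not in SCORE_MODES:
        raise ValueError(f"unknown score mode {score_mode!r}")
    spec_idx = [i for i, s in enumerate(terminal.states) if s != NEUTRAL]
    m = len(spec_idx)
    if m == 0:
        raise ValueError("terminal phenotype is the root; nothing to gate")

    # resolve AUC for every subset up front, failing loudly on gaps
    sub_auc: dict[frozenset[int], float] = {}
    sub_code: dict[frozenset[int], str] = {}
    for r in range(m + 1):
        for combo in combinations(spec_idx, r):
            ph = _sub_phenotype(terminal, combo)
            if ph.code not in auc:
                raise KeyError(
                    f"AUC missing for sub-phenotype {ph.code!r} of "
                    f"{terminal.code!r}"
                )
            key = frozenset(combo)
            sub_auc[key] = float(auc[ph.code])
            sub_code[key] = ph.code

    def step_value(subset: frozenset[int]) -> float:
        # contribution of *arriving* at `subset`
        if score_mode == CUMULATIVE:
            return sub_auc[subset]
        if score_mode == TERMINAL_ONLY:
            return sub_auc[subset] if len(subset) == m else 0.0
        return sub_auc[subset]  # MIN_EDGE handled in combine()

    def combine(prev_score: float, subset: frozenset[int]) -> float:
        if score_mode == MIN_EDGE:
            return min(prev_score, step_value(subset))
        return prev_score + step_value(subset)

    init = float("inf") if score_mode == MIN_EDGE else 0.0

    # DP over subsets by size; each entry keeps the top n_paths partial paths
    # as (score, path-of-subsets) with deterministic tie-breaking.
    frontier: dict[frozenset[int], list[tuple[float, tuple[frozenset[int], ...]]]]
    frontier = {frozenset(): [(init, (frozenset(),))]}
    for size in range(1, m + 1):
        nxt: dict[frozenset[int], list] = {}
        for combo in combinations(spec_idx, size):
            subset = frozenset(combo)
            candidates = []
            for idx in combo:
                prev = subset - {idx}
                for score, path in frontier.get(prev, []):
                    candidates.append((combine(score, subset), path + (subset,)))
            candidates.sort(
                key=lambda sc: (-sc[0], tuple(sub_code[s] for s in sc[1]))
            )
            nxt[subset] = candidates[:n_paths]
        # keep smaller frontiers reachable for the next size
        frontier.update(nxt)

    full = frozenset(spec_idx)
    out = []
    for score, path in frontier[full]:
        phenos = tuple(
            _sub_phenotype(terminal, tuple(sorted(s))) for s in path
        )
        out.append(GatingPath(phenotypes=phenos, score=float(score)))
    return out


def merge_paths(
    paths: Sequence[GatingPath], auc: Mapping[str, float]
) -> nx.DiGraph:
    """Union of gating paths as one annotated DAG.

    Nodes are phenotype codes with an ``auc`` attribute and a ``terminal``
    flag (set for each path's last node); edges carry ``delta_auc`` =
    auc(child) - auc(parent) and the added marker constraint, so weights
    telescope to auc(terminal) - auc(root) along every path.
    """
    g = nx.DiGraph()
    for path in paths:
        prev: Phenotype | None = None
        for i, ph in enumerate(path.phenotypes):
            code = ph.code
            node_auc = float(auc[code])
            if code in g.nodes and not _close(g.nodes[code]["auc"], node_auc):
                raise ValueError(
                    f"conflicting AUC values for phenotype {code!r}"
                )
            if code not in g.nodes:
                g.add_node(code, auc=node_auc, terminal=False)
            if i == len(path.phenotypes) - 1:
                g.nodes[code]["terminal"] = True
            if prev is not None:
                added = set(ph.specified()) - set(prev.specified())
                (marker,) = added
                sign = "+" if ph.specified()[marker] == 2 else "-"
                g.add_edge(
                    prev.code, code,
                    delta_auc=node_auc - float(auc[prev.code]),
                    added=f"{marker}{sign}",
                )
            prev = ph
    return g


def _close(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol


_COLOR_BUCKETS = (
    (0.6, "#fee5d9"),
    (0.7, "#fcae91"),
    (0.8, "#fb6a4a"),
    (0.9, "#de2d26"),
    (1.0 + 1e-9, "#a50f15"),
)


def _node_color(auc: float) -> str:
    for upper, color in _COLOR_BUCKETS:
        if auc <= upper:
            return color
    return _COLOR_BUCKETS[-1][1]


def to_dot(graph: nx.DiGraph, pen_scale: float = 20.0) -> str:
    """Render the hierarchy as deterministic Graphviz DOT text.

    Edge pen-width is proportional to the positive part of the AUC gain
    (negative-gain edges are drawn at hairline width so every emitted path
    stays intact); node fill colour is bucketed by AUC.
    """
    lines = ["digraph hierarchy {", '  rankdir="TB";',
             '  node [style="filled", shape="box"];']
    for code in sorted(graph.nodes):
        attrs = graph.nodes[code]
        auc = float(attrs.get("auc", 0.5))
        shape = "ellipse" if attrs.get("terminal") else "box"
        label = code.replace('"', "'")
        lines.append(
            f'  "{label}" [label="{label}\\nAUC={auc:.3f}", '
            f'fillcolor="{_node_color(auc)}", shape="{shape}"];'
        )
    for u, v in sorted(graph.edges):
        delta = float(graph.edges[u, v].get("delta_auc", 0.0))
        width = max(delta, 0.0) * pen_scale + 0.2
        added = graph.edges[u, v].get("added", "")
        lines.append(
            f'  "{u}" -> "{v}" [penwidth={width:.2f}, '
            f'label="{added} ({delta:+.3f})"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def graph_to_json(graph: nx.DiGraph) -> dict:
    """JSON-serialisable dump (sorted, deterministic)."""
    return {
        "nodes": [
            {"code": c, **{k: graph.nodes[c][k] for k in sorted(graph.nodes[c])}}
            for c in sorted(graph.nodes)
        ],
        "edges": [
            {"parent": u, "child": v,
             **{k: graph.edges[u, v][k] for k in sorted(graph.edges[u, v])}}
            for u, v in sorted(graph.edges)
        ],
    }


def build_hierarchy(
    terminals: Sequence[Phenotype],
    auc: Mapping[str, float],
    n_paths: int = 1,
    score_mode: str = CUMULATIVE,
) -> tuple[nx.DiGraph, dict[str, list[GatingPath]]]:
    """Best paths for every terminal, merged into one DAG."""
    all_paths: dict[str, list[GatingPath]] = {}
    flat: list[GatingPath] = []
    for term in terminals:
        paths = best_paths(term, auc, n_paths=n_paths, score_mode=score_mode)
        all_paths[term.code] = paths
        flat.extend(paths)
    return merge_paths(flat, auc), all_paths
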