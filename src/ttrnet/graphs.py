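"""Dense sub-network detection and degree statistics on an interaction graph.

Vertex weighting follows the molecular-complex-detection (MCODE) scheme:
the weight of v is k x density of the highest k-core of v's closed
neighbourhood. Complexes grow greedily from the heaviest unused vertex,
admitting neighbours whose weight reaches seed_weight x (1 -
node_score_cutoff); in addition a candidate joining a complex that already
has two or more members must connect to it by at least two edges (a bridge
guard — the haircut criterion applied at admission time, which keeps two
dense regions joined by a single edge from merging). A final haircut
iteratively removes members left with fewer than two in-complex edges.
Complex score = density x size.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .data import ParseError, ValidationError

log = logging.getLogger(__name__)


def load_interactions(path, min_score: float = 0.4) -> nx.Graph:
    """Read a tab-separated edge list (node_a, node_b[, score]).

    Edges with a score are kept only when score > min_score (strict, the
    "medium confidence > 0.4" convention); unscored edges are kept.
    Self-loops and duplicate edges are dropped with logged counts. A header
    row is tolerated when its score field is not numeric.
    """
    g = nx.Graph()
    dropped_score = dropped_dup = dropped_loop = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns, got {len(row)}")
            a, b = row[0].strip(), row[1].strip()
            score = None
            if len(row) == 3:
                try:
                    score = float(row[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise ParseError(f"line {lineno}: score {row[2]!r} is not numeric")
            if not a or not b:
                raise ParseError(f"line {lineno}: empty node id")
            if a == b:
                dropped_loop += 1
                continue
            if score is not None and not score > min_score:
                dropped_score += 1
                continue
            if g.has_edge(a, b):
                dropped_dup += 1
                continue
            if score is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, score=score)
    if dropped_score or dropped_dup or dropped_loop:
        log.info(
            "filtered edges: %d below score, %d duplicates, %d self-loops",
            dropped_score,
            dropped_dup,
            dropped_loop,
        )
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """k x core-density weight of each vertex's closed neighbourhood."""
    if any(graph.has_edge(v, v) for v in graph):
        raise ValidationError("graph must be simple (no self-loops)")
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbhd = graph.subgraph(set(graph[v]) | {v})
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        cores = nx.core_number(nbhd)
        kmax = max(cores.values())
        core_nodes = [n for n, c in cores.items() if c >= kmax]
        weights[v] = kmax * _density(nbhd.subgraph(core_nodes))
    return weights


def _haircut(graph: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively remove members with fewer than 2 in-complex edges."""
    members = set(members)
    changed = True
    while changed and members:
        changed = False
        for v in sorted(members):
            deg = sum(1 for u in graph[v] if u in members)
            if deg < 2:
                members.remove(v)
                changed = True
    return members


@dataclass(frozen=True)
class ComplexResult:
    members: tuple[str, ...]
    seed: str
    density: float
    mcode_score: float  # density x member count

    @property
    def size(self) -> int:
        return len(self.members)


def mcode_complexes(
    graph: nx.Graph,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    min_size: int = 3,
) -> list[ComplexResult]:
    """Greedy seed-and-grow dense complexes, each node in at most one.

    Seeds are visited in (weight desc, id asc) order; growth admits
    unvisited neighbours with weight >= seed_weight x (1 -
    node_score_cutoff) that keep at least two links into the complex once
    it has two members. Complexes are returned sorted by score descending.
    """
    if not 0 <= node_score_cutoff < 1:
        raise ValidationError("node_score_cutoff must lie in [0, 1)")
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    weights = mcode_vertex_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    used: set[str] = set()
    results: list[ComplexResult] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop(0)
            for u in sorted(graph[v], key=str):
                if u in used or u in members:
                    continue
                if weights[u] < threshold:
                    continue
                links = sum(1 for x in graph[u] if x in members)
                if len(members) >= 2 and links < 2:
                    continue
                members.add(u)
                frontier.append(u)
        if haircut:
            members = _haircut(graph, members)
        if len(members) < min_size:
            continue
        sub = graph.subgraph(members)
        density = _density(sub)
        results.append(
            ComplexResult(tuple(sorted(members)), seed, density, density * len(members))
        )
        used |= members
    results.sort(key=lambda c: (-c.mcode_score, -c.size, c.seed))
    return results


def complexes_table(results: list[ComplexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i + 1, c.seed, c.size, c.density, c.mcode_score, ",".join(map(str, c.members)))
            for i, c in enumerate(results)
        ],
        columns=["complex_id", "seed", "size", "density", "score", "members"],
    )


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    """Node degrees, sorted (degree desc, id asc)."""
    rows = sorted(graph.degree, key=lambda kv: (-kv[1], str(kv[0])))
    return pd.DataFrame(rows, columns=["node", "degree"])


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a tab-separated edge list with optional scores."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b, attrs in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            row = [a, b]
            if "score" in attrs:
                row.append(f"{attrs['score']:.6g}")
            writer.writerow(row)
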