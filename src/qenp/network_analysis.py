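"""Bipartite compound-target and scored PPI network topology.

Networks are undirected and self-loop free. Scores, when present, live on
[0, 1] (STRING-style 0-999 combined scores are normalized on load) and
drive edge filtering only: centralities always treat the graph as
unweighted. Hubs are selected by strict comparison against the mean degree,
computed once on the network being filtered (degrees are not recomputed
mid-pass).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from qenp.errors import FormatError, ValidationError
from qenp.target_sets import TargetSet

DEFAULT_MIN_SCORE = 0.400


@dataclass(frozen=True)
class CompoundTargetMap:
    """Bipartite compound -> target edge list; duplicate edges collapse."""

    edges: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        cleaned: list[tuple[str, str]] = []
        for cid, target in self.edges:
            cid = cid.strip()
            target = target.strip().upper()
            if not cid or not target:
                raise ValidationError("compound-target edge endpoints must be non-empty")
            key = (cid, target)
            if key not in seen:
                seen.add(key)
                cleaned.append(key)
        object.__setattr__(self, "edges", tuple(cleaned))

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}


def read_compound_target_map(path: str | Path) -> CompoundTargetMap:
    """Read a TSV edge list with header ``compound_id, target_symbol``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        names = [n.strip() for n in (reader.fieldnames or [])]
        for col in ("compound_id", "target_symbol"):
            if col not in names:
                raise FormatError(f"{path}: missing required column {col!r}")
        edges = [
            (row["compound_id"], row["target_symbol"])
            for row in reader
            if (row["compound_id"] or "").strip()
        ]
    return CompoundTargetMap(edges=tuple(edges))


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected network with optional per-edge scores in [0, 1].

    ``edges`` hold canonically ordered endpoint pairs; ``bipartite_flag``
    marks compound-target networks whose nodes split into two classes.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, float | None], ...]
    bipartite_flag: bool = False
    compound_nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float | None] = {}
        nodes = set(self.nodes)
        for a, b, score in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValidationError(
                    f"edge ({a}, {b}) score {score} outside [0, 1]"
                )
            key = (a, b) if a <= b else (b, a)
            canon[key] = score
            nodes.add(a)
            nodes.add(b)
        object.__setattr__(
            self, "edges", tuple((a, b, s) for (a, b), s in sorted(canon.items()))
        )
        object.__setattr__(self, "nodes", frozenset(nodes))
        object.__setattr__(self, "compound_nodes", frozenset(self.compound_nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b, score in self.edges:
            if score is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, score=score)
        return g


def build_compound_target_network(
    mapping: CompoundTargetMap, keep_targets: TargetSet | None = None
) -> InteractionNetwork:
    """Build the bipartite compound-target network.

    When ``keep_targets`` is given, edges to targets outside the set are
    dropped; compounds left isolated by the filter are retained as nodes
    (they remain part of the composition even when target-less).
    """
    edges = []
    for cid, target in mapping.edges:
        if keep_targets is not None and target not in keep_targets:
            continue
        edges.append((f"compound:{cid}", f"target:{target}", None))
    compound_nodes = frozenset(f"compound:{c}" for c in mapping.compounds)
    return InteractionNetwork(
        nodes=compound_nodes,
        edges=tuple(edges),
        bipartite_flag=True,
        compound_nodes=compound_nodes,
    )


def read_ppi_edges(path: str | Path) -> InteractionNetwork:
    """Read a scored PPI edge list (STRING-export compatible).

    Accepts headers ``node_a/node_b[/score]`` or STRING's
    ``node1/node2/combined_score``. Scores above 1 are assumed to sit on
    STRING's 0-999 integer scale and are divided by 1000.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        names = [n.strip() for n in (reader.fieldnames or [])]
        col_a = next((c for c in ("node_a", "node1") if c in names), None)
        col_b = next((c for c in ("node_b", "node2") if c in names), None)
        col_s = next((c for c in ("score", "combined_score") if c in names), None)
        if col_a is None or col_b is None:
            raise FormatError(
                f"{path}: expected node columns node_a/node_b or node1/node2"
            )
        rows = [
            (row[col_a].strip().upper(), row[col_b].strip().upper(),
             row[col_s].strip() if col_s and row[col_s] else None)
            for row in reader
        ]
    raw_scores = [float(s) for _, _, s in rows if s is not None]
    string_scale = any(s > 1.0 for s in raw_scores)
    edges = []
    for a, b, s in rows:
        score = None
        if s is not None:
            score = float(s) / 999.0 if string_scale else float(s)
            score = min(score, 1.0)
        edges.append((a, b, score))
    return InteractionNetwork(nodes=frozenset(), edges=tuple(edges))


def filter_edges_by_score(
    network: InteractionNetwork,
    min_score: float = DEFAULT_MIN_SCORE,
    inclusive: bool = True,
) -> InteractionNetwork:
    """Keep edges with score >= ``min_score`` and drop isolated nodes.

    The boundary is inclusive by default (an edge scoring exactly at the
    threshold survives). Unscored edges under a positive threshold are a
    validation error.
    """
    kept = []
    for a, b, score in network.edges:
        if score is None:
            if min_score > 0:
                raise ValidationError(
                    f"edge ({a}, {b}) has no score; cannot filter at {min_score}"
                )
            kept.append((a, b, score))
            continue
        if (score >= min_score) if inclusive else (score > min_score):
            kept.append((a, b, score))
    connected = {n for a, b, _ in kept for n in (a, b)}
    return InteractionNetwork(
        nodes=frozenset(connected),
        edges=tuple(kept),
        bipartite_flag=network.bipartite_flag,
        compound_nodes=network.compound_nodes & connected,
    )


def degree_centrality(network: InteractionNetwork) -> dict[str, int]:
    """Raw (unnormalized) degree per node."""
    degrees = {n: 0 for n in network.nodes}
    for a, b, _ in network.edges:
        degrees[a] += 1
        degrees[b] += 1
    return degrees


def betweenness_centrality(
    network: InteractionNetwork, normalized: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness on the unweighted undirected graph.

    Unnormalized by default: the raw sum over node pairs of the fraction of
    shortest paths passing through each node (each unordered pair counted
    once). ``normalized=True`` divides by (n-1)(n-2)/2.
    """
    if not network.nodes:
        return {}
    g = network.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=normalized, weight=None))


def filter_hubs_by_mean_degree(
    network: InteractionNetwork,
) -> tuple[InteractionNetwork, float]:
    """Keep nodes whose degree strictly exceeds the network mean degree.

    Returns the induced subgraph on the surviving nodes together with the
    threshold used. Degrees are computed once, on the input network;
    strict ``>`` means a k-regular graph keeps nothing.
    """
    if not network.nodes:
        raise ValidationError("cannot hub-filter an empty network")
    degrees = degree_centrality(network)
    threshold = sum(degrees.values()) / len(degrees)
    survivors = {n for n, d in degrees.items() if d > threshold}
    edges = tuple(
        (a, b, s) for a, b, s in network.edges if a in survivors and b in survivors
    )
    return (
        InteractionNetwork(
            nodes=frozenset(survivors),
            edges=edges,
            bipartite_flag=network.bipartite_flag,
            compound_nodes=network.compound_nodes & survivors,
        ),
        threshold,
    )


def write_edge_list(network: InteractionNetwork, path: str | Path) -> None:
    """Write the network as a TSV edge list (score column when present)."""
    scored = any(s is not None for _, _, s in network.edges)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_a", "node_b", "score"] if scored else ["node_a", "node_b"])
        for a, b, s in network.edges:
            if scored:
                w.writerow([a, b, "" if s is None else f"{s:.3f}"])
            else:
                w.writerow([a, b])


def write_sif(network: InteractionNetwork, path: str | Path, relation: str = "pp") -> None:
    """SIF export: ``node relation node`` per line."""
    lines = [f"{a}\t{relation}\t{b}" for a, b, _ in network.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def network_from_edges(
    edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float | None]],
    nodes: Iterable[str] = (),
) -> InteractionNetwork:
    """Convenience constructor accepting 2- or 3-tuples."""
    norm: list[tuple[str, str, float | None]] = []
    for e in edges:
        if len(e) == 2:
            a, b = e  # type: ignore[misc]
            norm.append((a, b, None))
        else:
            norm.append(tuple(e))  # type: ignore[arg-type]
    return InteractionNetwork(nodes=frozenset(nodes), edges=tuple(norm))
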