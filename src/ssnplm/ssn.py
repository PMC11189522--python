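"""Sequence similarity network construction and cluster analysis.

An SSN has one node per (representative) sequence and an edge between every
pair whose alignment identity reaches the threshold (default 40%).
Connected components of size >= 2 are *main clusters*, ranked 1..K by
decreasing size (ties by lexicographically smallest member id); size-1
components are *singletons*.  Each cluster carries a convergence ratio —
realised edges over possible edges — near 1 for tightly interconnected,
likely isofunctional clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx

from .seqio import SequenceSet
from .similarity import AlignmentParams, align_identity

logger = logging.getLogger(__name__)

__all__ = [
    "SSNParams",
    "SSNGraph",
    "Cluster",
    "ClusterPartition",
    "ClusterLabelSet",
    "build_ssn",
    "find_clusters",
    "top_k_labels",
    "export_graph",
]


@dataclass(frozen=True)
class SSNParams:
    """Edge threshold and alignment scheme for SSN construction."""

    identity_threshold: float = 0.40
    align: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class SSNGraph:
    """Thresholded identity network: nodes, weighted undirected edges."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (id_a, id_b, identity), a < b
    params: SSNParams

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="identity")
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Cluster:
    """A main cluster: a connected component with >= 2 members."""

    cluster_id: int
    members: tuple[str, ...]
    n_edges: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def convergence_ratio(self) -> float:
        """Realised edges / possible edges within the component, in (0, 1]."""
        possible = self.size * (self.size - 1) // 2
        return self.n_edges / possible


@dataclass
class ClusterPartition:
    """Size-ranked main clusters plus singleton nodes; together they
    partition the node set of the graph they were derived from."""

    clusters: list[Cluster]
    singletons: list[str]

    @property
    def n_nodes(self) -> int:
        return sum(c.size for c in self.clusters) + len(self.singletons)

    def cluster_of(self) -> dict[str, int]:
        """Map node id -> cluster_id (singletons absent)."""
        out: dict[str, int] = {}
        for c in self.clusters:
            for m in c.members:
                out[m] = c.cluster_id
        return out


@dataclass
class ClusterLabelSet:
    """Supervised label space: members of the k largest clusters only."""

    k: int
    labels: dict[str, int]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if not (1 <= v <= self.k)}
        if bad:
            raise ValueError(f"labels outside 1..{self.k}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def build_ssn(reps: SequenceSet, params: SSNParams | None = None) -> SSNGraph:
    """All-vs-all alignment identity, thresholded into an undirected graph.

    ``reps`` is expected to be redundancy-reduced; duplicate residue strings
    are only logged, not rejected.
    """
    params = params or SSNParams()
    if len(reps) < 1:
        raise ValueError("build_ssn requires at least one sequence")
    if len({s.residues for s in reps}) < len(reps):
        logger.warning("build_ssn input contains duplicate residue strings; "
                       "was redundancy reduction applied?")
    seqs = list(reps)
    edges: list[tuple[str, str, float]] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            res = align_identity(seqs[i], seqs[j], params.align)
            if res.identity >= params.identity_threshold:
                a, b = sorted((seqs[i].id, seqs[j].id))
                edges.append((a, b, res.identity))
    logger.info("SSN: %d nodes, %d edges at identity >= %.2f",
                len(seqs), len(edges), params.identity_threshold)
    return SSNGraph([s.id for s in seqs], edges, params)


def find_clusters(graph: SSNGraph) -> ClusterPartition:
    """Connected components -> size-ranked main clusters and singletons.

    Components of size >= 2 become clusters with ids 1..K by decreasing
    size, ties broken by the lexicographically smallest member id, so ids
    are stable under node-order permutation of the input.
    """
    g = graph.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    singles = sorted(c[0] for c in comps if len(c) == 1)
    multi = sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), c[0]))
    clusters = [
        Cluster(rank, tuple(members), g.subgraph(members).number_of_edges())
        for rank, members in enumerate(multi, start=1)
    ]
    return ClusterPartition(clusters, singles)


def top_k_labels(partition: ClusterPartition, k: int) -> ClusterLabelSet:
    """Label the members of the k largest clusters with their cluster id.

    Sequences in smaller clusters or singletons stay unlabelled — they are
    excluded from supervised training.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels: dict[str, int] = {}
    for c in partition.clusters[:k]:
        for m in c.members:
            labels[m] = c.cluster_id
    return ClusterLabelSet(k=k, labels=labels)


def export_graph(
    graph: SSNGraph,
    partition: ClusterPartition,
    path: str | Path,
    format: Literal["graphml", "edge-tsv"] = "graphml",
) -> None:
    """Write the SSN for external visualisation (Cytoscape-loadable).

    GraphML: node attribute ``cluster`` (the cluster id as a string, or
    ``"singleton"``) and edge attribute ``identity``.  Edge TSV: columns
    source, target, identity (6 decimals), one row per edge.
    """
    path = Path(path)
    if format == "graphml":
        g = graph.to_networkx()
        by_node = partition.cluster_of()
        for n in g.nodes:
            g.nodes[n]["cluster"] = str(by_node.get(n, "singleton"))
        for u, v, d in g.edges(data=True):
            d["identity"] = float(d.pop("identity"))
        nx.write_graphml(g, path)
    elif format == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tidentity\n")
            for a, b, ident in graph.edges:
                fh.write(f"{a}\t{b}\t{ident:.6f}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
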