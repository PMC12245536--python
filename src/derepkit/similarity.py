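"""Thresholded genome similarity graph and representativeness scores.

Two genomes are connected when their ANI meets the ANI cutoff and the
larger of the pair's two aligned fractions meets the AF cutoff. A
genome's representativeness score is its connectivity (degree in this
graph) multiplied by its assembly N50, so well-assembled genomes that
resemble many others are preferred as representatives.

Cutoff comparisons are inclusive (>=): a user asking for 99.0 keeps
pairs reported at exactly 99.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io_formats import GenomeRecord, SimilarityEdge

__all__ = [
    "DereplicationParams",
    "SimilarityGraph",
    "ScoreTable",
    "build_similarity_graph",
    "compute_scores",
    "connected_components",
]


@dataclass(frozen=True)
class DereplicationParams:
    """Cutoffs driving graph construction and selection.

    ani_cutoff and af_cutoff are percentages on 0-100. In dynamic mode,
    a pair whose two aligned fractions differ by more than
    ``max_af_difference`` points is treated as a containment (a smaller
    genome largely covered by a larger one).
    """

    ani_cutoff: float = 99.0
    af_cutoff: float = 90.0
    max_af_difference: float = 10.0
    mode: str = "greedy"

    def __post_init__(self) -> None:
        for name in ("ani_cutoff", "af_cutoff", "max_af_difference"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.mode not in ("greedy", "dynamic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def edge_qualifies(self, edge: SimilarityEdge) -> bool:
        """A pair is 'similar' when ANI >= cutoff and the maximal of its
        two aligned fractions >= cutoff."""
        return edge.ani >= self.ani_cutoff and edge.max_af >= self.af_cutoff


@dataclass
class SimilarityGraph:
    """Undirected graph over the full roster (isolated nodes included).

    ``edge_data`` keys are sorted unordered pairs; adjacency is kept
    symmetric and free of self-loops by construction.
    """

    nodes: set[str] = field(default_factory=set)
    adjacency: dict[str, set[str]] = field(default_factory=dict)
    edge_data: dict[tuple[str, str], SimilarityEdge] = field(
        default_factory=dict
    )

    def add_node(self, genome_id: str) -> None:
        self.nodes.add(genome_id)
        self.adjacency.setdefault(genome_id, set())

    def add_edge(self, edge: SimilarityEdge) -> None:
        self.add_node(edge.genome_a)
        self.add_node(edge.genome_b)
        self.adjacency[edge.genome_a].add(edge.genome_b)
        self.adjacency[edge.genome_b].add(edge.genome_a)
        self.edge_data[edge.pair] = edge

    def neighbors(self, genome_id: str) -> set[str]:
        return self.adjacency[genome_id]

    def degree(self, genome_id: str) -> int:
        return len(self.adjacency[genome_id])

    @property
    def n_edges(self) -> int:
        return len(self.edge_data)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), e in self.edge_data.items():
            g.add_edge(a, b, ani=e.ani, af_a=e.af_a, af_b=e.af_b)
        return g


@dataclass
class ScoreTable:
    """Per-genome representativeness scores (degree x N50).

    Degree and N50 are both integers, so scores are exact integers and
    sorting ties are reproducible. N50s are carried along because the
    selection algorithms break score ties by N50.
    """

    scores: dict[str, int]
    n50: dict[str, int]
    degree: dict[str, int]


def build_similarity_graph(
    edges: list[SimilarityEdge],
    roster: list[GenomeRecord],
    params: DereplicationParams,
) -> SimilarityGraph:
    """Threshold the edge list into the similarity graph.

    An edge joins a and b iff ani >= ani_cutoff and max(af_a, af_b) >=
    af_cutoff. Roster genomes with no qualifying edge remain isolated
    nodes, so singletons always become their own representatives
    downstream.
    """
    known = {rec.genome_id for rec in roster}
    graph = SimilarityGraph()
    for gid in known:
        graph.add_node(gid)
    for edge in edges:
        unknown = {edge.genome_a, edge.genome_b} - known
        if unknown:
            raise ValueError(
                f"edge references genome(s) absent from roster: "
                f"{sorted(unknown)}"
            )
        if params.edge_qualifies(edge):
            graph.add_edge(edge)
    return graph


def compute_scores(
    graph: SimilarityGraph, roster: list[GenomeRecord]
) -> ScoreTable:
    """score(g) = degree(g) x n50(g); an isolated genome scores 0."""
    n50 = {rec.genome_id: rec.n50 for rec in roster}
    missing = graph.nodes - n50.keys()
    if missing:
        raise ValueError(f"roster missing graph nodes: {sorted(missing)}")
    degree = {g: graph.degree(g) for g in graph.nodes}
    scores = {g: degree[g] * n50[g] for g in graph.nodes}
    return ScoreTable(scores=scores, n50=n50, degree=degree)


def connected_components(graph: SimilarityGraph) -> list[set[str]]:
    """Maximal connected sets of genomes — the coarse transitive
    clusters the dynamic algorithm selects one representative from.

    Components are returned sorted by their smallest member id for
    deterministic output.
    """
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    comps.sort(key=lambda c: min(c))
    return comps
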