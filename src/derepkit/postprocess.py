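"""Secondary clustering, cutoff sweeps and similarity-network export.

After dereplication, each non-representative genome is assigned to its
best-matching representative. Two variants exist: an ANI-tiered rule
(prefer representatives meeting the cutoffs, fall back to the closest
one by raw ANI) and a shared-protein-cluster rule for gene-content
dereplication. The cutoff sweep reruns dereplication over a grid of
ANI/AF cutoffs so users can pick thresholds that yield roughly the
number of representatives they can afford downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .derep_ani import (
    DereplicationResult,
    dynamic_dereplicate,
    greedy_dereplicate,
)
from .io_formats import ClusterMembership, GenomeRecord, SimilarityEdge
from .similarity import (
    DereplicationParams,
    SimilarityGraph,
    build_similarity_graph,
    compute_scores,
)

__all__ = [
    "ClusterAssignment",
    "SweepCell",
    "assign_by_ani",
    "assign_by_clusters",
    "sweep_cutoffs",
    "export_graph",
    "write_clustering_report",
]

logger = logging.getLogger(__name__)

#: Default sweep grids bracketing common dereplication settings.
DEFAULT_ANI_GRID = (95.0, 97.0, 98.0, 99.0, 99.5)
DEFAULT_AF_GRID = (25.0, 50.0, 75.0, 90.0)


@dataclass(frozen=True)
class ClusterAssignment:
    """One non-representative mapped to one representative.

    ``tier`` records how the match was made: "within-cutoffs" (a
    representative satisfying the ANI and AF cutoffs existed),
    "nearest-fallback" (best raw ANI among all representatives) or
    "cluster-overlap" (shared-protein-cluster variant). ANI/AF fields
    are None for the cluster-overlap variant and vice versa.
    """

    nonrep_id: str
    rep_id: str | None
    ani: float | None = None
    af: float | None = None
    shared_cluster_pct: float | None = None
    tier: str = "within-cutoffs"


@dataclass(frozen=True)
class SweepCell:
    ani_cutoff: float
    af_cutoff: float
    mode: str
    n_representatives: int


def _pair_lookup(
    edges: Iterable[SimilarityEdge],
) -> dict[tuple[str, str], SimilarityEdge]:
    return {e.pair: e for e in edges}


def assign_by_ani(
    edges: list[SimilarityEdge],
    representatives: Iterable[str],
    params: DereplicationParams,
    roster: list[GenomeRecord] | None = None,
    rank_by_product: bool = False,
) -> list[ClusterAssignment]:
    """Tiered ANI assignment of non-representatives to representatives.

    Tier 1: among representatives whose pair with the genome meets both
    cutoffs, pick the largest ANI; ties break by larger maximal AF, then
    lexicographically smaller representative id. Tier 2 (when no
    representative meets the cutoffs): the same ranking over *all*
    representatives with any recorded pair. Genomes with no recorded
    pair to any representative are reported unassigned with a warning.

    ``rank_by_product`` switches the ranking within each tier to the
    product of the non-representative's aligned fraction and the ANI,
    an alternative that weighs how much of the genome the
    representative actually covers.

    The roster, when given, fixes the set of genomes to assign;
    otherwise every non-representative genome named in the edge list is
    assigned.
    """
    rep_set = set(representatives)
    lookup = _pair_lookup(edges)
    if roster is not None:
        genomes = {r.genome_id for r in roster}
    else:
        genomes = {g for e in edges for g in (e.genome_a, e.genome_b)}
    assignments: list[ClusterAssignment] = []
    for g in sorted(genomes - rep_set):
        candidates: list[tuple[float, float, float, str]] = []
        for r in rep_set:
            edge = lookup.get(tuple(sorted((g, r))))
            if edge is not None:
                rank = (
                    edge.ani * edge.af_of(g) if rank_by_product else edge.ani
                )
                candidates.append((edge.ani, edge.max_af, rank, r))
        if not candidates:
            logger.warning("no recorded pair between %s and any representative", g)
            assignments.append(
                ClusterAssignment(nonrep_id=g, rep_id=None, tier="unassigned")
            )
            continue
        within = [
            c
            for c in candidates
            if c[0] >= params.ani_cutoff and c[1] >= params.af_cutoff
        ]
        tier = "within-cutoffs" if within else "nearest-fallback"
        pool = within or candidates
        ani, af, _, rep = min(pool, key=lambda c: (-c[2], -c[1], c[3]))
        assignments.append(
            ClusterAssignment(nonrep_id=g, rep_id=rep, ani=ani, af=af, tier=tier)
        )
    return assignments


def assign_by_clusters(
    membership: ClusterMembership, representatives: Iterable[str]
) -> list[ClusterAssignment]:
    """Assign each non-representative to the representative sharing the
    largest fraction of the non-representative's own protein clusters.

    Ties break by larger representative cluster count, then smaller id.
    A genome with zero clusters cannot be ranked and is reported
    unassigned with a warning.
    """
    rep_set = set(representatives)
    genomes = membership.genome_to_clusters
    assignments: list[ClusterAssignment] = []
    for g in sorted(set(genomes) - rep_set):
        clusters = genomes[g]
        if not clusters:
            logger.warning("genome %s has no protein clusters; unassigned", g)
            assignments.append(
                ClusterAssignment(nonrep_id=g, rep_id=None, tier="unassigned")
            )
            continue
        best = min(
            rep_set,
            key=lambda r: (
                -len(clusters & genomes[r]),
                -len(genomes[r]),
                r,
            ),
        )
        pct = 100.0 * len(clusters & genomes[best]) / len(clusters)
        assignments.append(
            ClusterAssignment(
                nonrep_id=g,
                rep_id=best,
                shared_cluster_pct=pct,
                tier="cluster-overlap",
            )
        )
    return assignments


def sweep_cutoffs(
    edges: list[SimilarityEdge],
    roster: list[GenomeRecord],
    ani_grid: Sequence[float] = DEFAULT_ANI_GRID,
    af_grid: Sequence[float] = DEFAULT_AF_GRID,
    mode: str = "greedy",
    max_af_difference: float = 10.0,
) -> list[SweepCell]:
    """Representative counts over a grid of ANI x AF cutoffs.

    Each cell rebuilds the similarity graph and reruns the requested
    algorithm from scratch, so a cell is guaranteed identical to an
    independent run at those cutoffs.
    """
    if not ani_grid or not af_grid:
        raise ValueError("cutoff grids must be non-empty")
    cells: list[SweepCell] = []
    for ani in ani_grid:
        for af in af_grid:
            params = DereplicationParams(
                ani_cutoff=ani,
                af_cutoff=af,
                max_af_difference=max_af_difference,
                mode=mode,
            )
            graph = build_similarity_graph(edges, roster, params)
            scores = compute_scores(graph, roster)
            if mode == "greedy":
                result = greedy_dereplicate(graph, scores)
            else:
                result = dynamic_dereplicate(edges, graph, scores, params)
            cells.append(
                SweepCell(ani, af, mode, len(result.representatives))
            )
    return cells


def export_graph(
    graph: SimilarityGraph,
    result: DereplicationResult,
    path: str | Path,
    edge_list_path: str | Path | None = None,
) -> None:
    """Write the similarity network as GraphML plus an edge-list TSV.

    Nodes carry is_representative, n50, score and degree attributes;
    edges carry ani and both directional aligned fractions. The GraphML
    file round-trips through networkx, so adjacency can be recovered
    exactly.
    """
    g = graph.to_networkx()
    rep_set = result.representative_set
    for node in g.nodes:
        outcome = result.per_genome.get(node)
        g.nodes[node]["is_representative"] = node in rep_set
        g.nodes[node]["n50"] = outcome.n50 if outcome else 0
        g.nodes[node]["score"] = outcome.score if outcome else 0
        g.nodes[node]["degree"] = graph.degree(node)
    nx.write_graphml(g, path)
    if edge_list_path is not None:
        with open(edge_list_path, "w") as handle:
            handle.write("#genome_a\tgenome_b\tani\taf_a\taf_b\n")
            for pair in sorted(graph.edge_data):
                e = graph.edge_data[pair]
                handle.write(
                    f"{pair[0]}\t{pair[1]}\t{e.ani}\t{e.af_a}\t{e.af_b}\n"
                )


def write_clustering_report(
    assignments: list[ClusterAssignment], path: str | Path
) -> None:
    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.4f}"

    with open(path, "w") as handle:
        handle.write(
            "#nonrep_id\trep_id\tani\taf\tshared_cluster_pct\ttier\n"
        )
        for a in assignments:
            handle.write(
                f"{a.nonrep_id}\t{a.rep_id or ''}\t{fmt(a.ani)}\t"
                f"{fmt(a.af)}\t{fmt(a.shared_cluster_pct)}\t{a.tier}\n"
            )
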