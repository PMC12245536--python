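"""ANI-based representative-genome selection: greedy and dynamic modes.

Greedy mode walks genomes in descending score order, selecting each
genome not already disqualified and disqualifying its neighbours. The
resulting representative set is a maximal independent set of the
similarity graph, which guarantees every non-representative genome has
ANI and AF to at least one representative meeting the cutoffs.

Dynamic mode approximates single-linkage clustering: every qualifying
pair marks one of its two genomes redundant — the more-contained genome
when the pair's aligned fractions differ by more than the containment
threshold, otherwise the lower-scoring genome — and whatever is never
marked becomes a representative. It selects fewer representatives but
gives no per-genome distance guarantee: a genome connected to its
representative only indirectly may sit beyond the cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import SimilarityEdge
from .similarity import (
    DereplicationParams,
    ScoreTable,
    SimilarityGraph,
    connected_components,
)

__all__ = [
    "GenomeOutcome",
    "DereplicationResult",
    "greedy_dereplicate",
    "dynamic_dereplicate",
    "write_representatives",
    "write_derep_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeOutcome:
    """Per-genome selection provenance."""

    status: str  # "rep" or "nonrep"
    score: int
    degree: int
    n50: int
    selection_rank: int | None = None  # 1-based, greedy reps only
    marked_redundant_by: str | None = None  # "score" | "af-containment"


@dataclass
class DereplicationResult:
    """Representatives (in selection order), non-representatives, and
    per-genome provenance. The two sets partition the roster."""

    representatives: list[str]
    nonrepresentatives: set[str]
    per_genome: dict[str, GenomeOutcome] = field(default_factory=dict)

    @property
    def representative_set(self) -> set[str]:
        return set(self.representatives)


def _greedy_order(scores: ScoreTable) -> list[str]:
    # descending score, ties by larger N50 then lexicographically
    # smaller id — determinism is required for reproducible reports
    return sorted(
        scores.scores,
        key=lambda g: (-scores.scores[g], -scores.n50[g], g),
    )


def greedy_dereplicate(
    graph: SimilarityGraph, scores: ScoreTable
) -> DereplicationResult:
    """Select representatives by descending score with neighbour
    disqualification.

    The genome with the greatest score is automatically a
    representative; its neighbours are disqualified. The traversal then
    selects every genome not yet disqualified, disqualifying its
    neighbours in turn. Only neighbours of *selected* genomes are
    disqualified — disqualification does not propagate through already
    disqualified genomes.
    """
    representatives: list[str] = []
    disqualified: set[str] = set()
    for gid in _greedy_order(scores):
        if gid in disqualified:
            continue
        representatives.append(gid)
        disqualified |= graph.neighbors(gid)
    rep_set = set(representatives)
    per_genome = {
        g: GenomeOutcome(
            status="rep" if g in rep_set else "nonrep",
            score=scores.scores[g],
            degree=scores.degree[g],
            n50=scores.n50[g],
            selection_rank=(
                representatives.index(g) + 1 if g in rep_set else None
            ),
        )
        for g in graph.nodes
    }
    return DereplicationResult(
        representatives=representatives,
        nonrepresentatives=graph.nodes - rep_set,
        per_genome=per_genome,
    )


def _lower_score_genome(a: str, b: str, scores: ScoreTable) -> str:
    """The less suitable representative of a qualifying pair: lower
    score, then smaller N50, then lexicographically larger id."""
    key_a = (scores.scores[a], scores.n50[a])
    key_b = (scores.scores[b], scores.n50[b])
    if key_a != key_b:
        return a if key_a < key_b else b
    return max(a, b)


def dynamic_dereplicate(
    edges: list[SimilarityEdge],
    graph: SimilarityGraph,
    scores: ScoreTable,
    params: DereplicationParams,
) -> DereplicationResult:
    """Mark one genome of every qualifying pair redundant; whatever
    survives is a representative.

    For each pair meeting the ANI cutoff with at least one aligned
    fraction meeting the AF cutoff: if the two AFs differ by more than
    ``params.max_af_difference``, the genome with the *higher* AF (the
    more-contained, hence smaller, genome) is marked redundant
    ("af-containment"); otherwise the lower-scoring genome is marked
    ("score"). All pairs are assessed once, in canonical sorted-pair
    order so rule tags are reproducible; the final representative set is
    order-independent because marking never un-marks.

    A connected component can in principle lose all its members to the
    containment rule; such components are reported as warnings rather
    than silently repaired.
    """
    redundant: dict[str, str] = {}  # genome -> rule tag of first marking
    qualifying = {e.pair: e for e in edges if params.edge_qualifies(e)}
    for pair in sorted(qualifying):
        edge = qualifying[pair]
        a, b = pair
        if abs(edge.af_a - edge.af_b) > params.max_af_difference:
            victim = a if edge.af_of(a) > edge.af_of(b) else b
            tag = "af-containment"
        else:
            victim = _lower_score_genome(a, b, scores)
            tag = "score"
        redundant.setdefault(victim, tag)
    rep_set = graph.nodes - redundant.keys()
    for comp in connected_components(graph):
        if not comp & rep_set:
            logger.warning(
                "connected component with no representative (all %d members "
                "marked redundant): %s",
                len(comp),
                sorted(comp)[:5],
            )
    per_genome = {
        g: GenomeOutcome(
            status="rep" if g in rep_set else "nonrep",
            score=scores.scores[g],
            degree=scores.degree[g],
            n50=scores.n50[g],
            marked_redundant_by=redundant.get(g),
        )
        for g in graph.nodes
    }
    return DereplicationResult(
        representatives=sorted(rep_set),
        nonrepresentatives=set(redundant),
        per_genome=per_genome,
    )


def write_representatives(
    result: DereplicationResult, path: str | Path
) -> None:
    """One genome id per line: selection order for greedy results,
    lexicographic for dynamic."""
    with open(path, "w") as handle:
        for gid in result.representatives:
            handle.write(gid + "\n")


def write_derep_report(
    result: DereplicationResult, path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("#genome_id\tstatus\tscore\tdegree\tn50\trule_tag\n")
        for gid in sorted(result.per_genome):
            o = result.per_genome[gid]
            tag = o.marked_redundant_by or ""
            handle.write(
                f"{gid}\t{o.status}\t{o.score}\t{o.degree}\t{o.n50}\t{tag}\n"
            )
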