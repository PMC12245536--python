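"""Protein-cluster-saturation dereplication.

Instead of nucleotide similarity, representatives are chosen to cover
the coding pangenome: the genome with the most distinct protein
clusters seeds the set, and each iteration adds the genome contributing
the most clusters not yet covered (greedy maximum coverage, so marginal
gains along the selection order are non-increasing).

Selection stops when one of three user-adjustable criteria fires:

(i)   the best remaining genome would add fewer than X new clusters
      (checked *before* adding; X defaults to 0, so it is inert —
      gains are never negative);
(ii)  more than Y% of all distinct clusters are covered (checked after
      adding; Y defaults to 90);
(iii) more than Z% of the multi-genome clusters (clusters found in at
      least two genomes) are covered (checked after adding; Z defaults
      to 100, so it is inert).

With the defaults only criterion (ii) is active. Coverage percentages
are compared in exact rational arithmetic so boundary cases (coverage
exactly Y%) are never subject to float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .derep_ani import DereplicationResult, GenomeOutcome
from .io_formats import ClusterMembership

__all__ = [
    "SaturationParams",
    "SaturationStep",
    "SaturationTrace",
    "saturation_dereplicate",
    "incremental_augment",
    "write_saturation_trace",
]


@dataclass(frozen=True)
class SaturationParams:
    min_new_clusters: int = 0  # X
    saturation_pct: float = 90.0  # Y
    multigenome_saturation_pct: float = 100.0  # Z
    incremental_overlap_pct: float = 90.0

    def __post_init__(self) -> None:
        if self.min_new_clusters < 0:
            raise ValueError("min_new_clusters must be >= 0")
        for name in (
            "saturation_pct",
            "multigenome_saturation_pct",
            "incremental_overlap_pct",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class SaturationStep:
    genome_id: str
    marginal_gain: int
    cumulative_clusters: int
    coverage_pct: float
    multigenome_coverage_pct: float
    stop_criterion_fired: str  # none | i | ii | iii | exhausted


@dataclass
class SaturationTrace:
    steps: list[SaturationStep] = field(default_factory=list)
    total_clusters: int = 0
    total_multigenome_clusters: int = 0

    @property
    def stop_criterion(self) -> str:
        return self.steps[-1].stop_criterion_fired if self.steps else "none"


def _exceeds(covered: int, total: int, threshold_pct: float) -> bool:
    """covered/total > threshold_pct/100, evaluated exactly.

    An empty denominator counts as fully (100%) covered, so a criterion
    at threshold 100 never fires vacuously.
    """
    ratio = Fraction(covered, total) if total else Fraction(1)
    return ratio > Fraction(str(threshold_pct)) / 100


def _pct(covered: int, total: int) -> float:
    return 100.0 * covered / total if total else 100.0


def _candidate_order(
    membership: ClusterMembership,
) -> dict[str, tuple[int, str]]:
    """Tie-break key: larger distinct-cluster count, then smaller id."""
    return {
        g: (-len(cl), g) for g, cl in membership.genome_to_clusters.items()
    }


def saturation_dereplicate(
    membership: ClusterMembership, params: SaturationParams | None = None
) -> tuple[DereplicationResult, SaturationTrace]:
    """Greedy maximum-coverage selection over protein clusters.

    The initial representative is the genome with the largest number of
    distinct clusters; each subsequent pick maximises the count of
    clusters not yet covered. Ties break by larger total cluster count,
    then lexicographically smaller genome id.
    """
    if params is None:
        params = SaturationParams()
    if not membership.genome_to_clusters:
        raise ValueError("empty membership: no genomes to dereplicate")

    genomes = membership.genome_to_clusters
    all_clusters = membership.all_clusters
    multi = membership.multigenome_clusters
    total, total_multi = len(all_clusters), len(multi)
    tiebreak = _candidate_order(membership)

    covered: set[str] = set()
    remaining = set(genomes)
    representatives: list[str] = []
    trace = SaturationTrace(
        total_clusters=total, total_multigenome_clusters=total_multi
    )

    while remaining:
        # max gain, ties by larger cluster count then smaller id
        best = min(
            remaining,
            key=lambda g: (-len(genomes[g] - covered), tiebreak[g]),
        )
        gain = len(genomes[best] - covered)
        if representatives and gain < params.min_new_clusters:
            # criterion (i): fires before the candidate is added
            trace.steps[-1] = _restate_stop(trace.steps[-1], "i")
            break
        covered |= genomes[best]
        remaining.discard(best)
        representatives.append(best)

        crit = "none"
        if _exceeds(len(covered), total, params.saturation_pct):
            crit = "ii"
        elif _exceeds(
            len(covered & multi),
            total_multi,
            params.multigenome_saturation_pct,
        ):
            crit = "iii"
        elif not remaining:
            crit = "exhausted"
        trace.steps.append(
            SaturationStep(
                genome_id=best,
                marginal_gain=gain,
                cumulative_clusters=len(covered),
                coverage_pct=_pct(len(covered), total),
                multigenome_coverage_pct=_pct(
                    len(covered & multi), total_multi
                ),
                stop_criterion_fired=crit,
            )
        )
        if crit != "none":
            break

    result = _as_result(representatives, membership)
    return result, trace


def _restate_stop(step: SaturationStep, criterion: str) -> SaturationStep:
    return SaturationStep(
        genome_id=step.genome_id,
        marginal_gain=step.marginal_gain,
        cumulative_clusters=step.cumulative_clusters,
        coverage_pct=step.coverage_pct,
        multigenome_coverage_pct=step.multigenome_coverage_pct,
        stop_criterion_fired=criterion,
    )


def _as_result(
    representatives: list[str], membership: ClusterMembership
) -> DereplicationResult:
    rep_set = set(representatives)
    genomes = membership.genome_to_clusters
    per_genome = {
        g: GenomeOutcome(
            status="rep" if g in rep_set else "nonrep",
            score=len(genomes[g]),
            degree=0,
            n50=0,
            selection_rank=(
                representatives.index(g) + 1 if g in rep_set else None
            ),
        )
        for g in genomes
    }
    return DereplicationResult(
        representatives=list(representatives),
        nonrepresentatives=set(genomes) - rep_set,
        per_genome=per_genome,
    )


def _max_overlap_pct(
    genome_clusters: set[str],
    reps: list[str],
    membership: ClusterMembership,
) -> float:
    """Best shared-cluster percentage of a genome against any
    representative, on the genome's own cluster count."""
    if not genome_clusters:
        return 100.0
    best = 0
    for r in reps:
        best = max(
            best, len(genome_clusters & membership.genome_to_clusters[r])
        )
    return 100.0 * best / len(genome_clusters)


def incremental_augment(
    result: DereplicationResult,
    membership: ClusterMembership,
    params: SaturationParams | None = None,
) -> DereplicationResult:
    """Promote outlier non-representatives to representatives.

    Any non-representative sharing less than
    ``params.incremental_overlap_pct`` of its own clusters with every
    current representative is promoted. Promotion proceeds in rounds
    against the *growing* representative set — largest distinct-cluster
    count first, ties by smaller id — until no genome qualifies, so a
    promoted genome can itself absorb later candidates.
    """
    if params is None:
        params = SaturationParams()
    genomes = membership.genome_to_clusters
    reps = list(result.representatives)
    pool = sorted(
        result.nonrepresentatives, key=lambda g: (-len(genomes[g]), g)
    )
    while True:
        promoted = None
        for g in pool:
            overlap = _max_overlap_pct(genomes[g], reps, membership)
            if overlap < params.incremental_overlap_pct:
                promoted = g
                break
        if promoted is None:
            break
        reps.append(promoted)
        pool.remove(promoted)
    return _as_result(reps, membership)


def write_saturation_trace(trace: SaturationTrace, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "#genome_id\tmarginal_gain\tcumulative_clusters\tcoverage_pct\t"
            "multigenome_coverage_pct\tstop_criterion\n"
        )
        for s in trace.steps:
            handle.write(
                f"{s.genome_id}\t{s.marginal_gain}\t{s.cumulative_clusters}\t"
                f"{s.coverage_pct:.4f}\t{s.multigenome_coverage_pct:.4f}\t"
                f"{s.stop_criterion_fired}\n"
            )
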