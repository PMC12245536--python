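"""Seeded generators for every input the toolkit consumes.

Real inputs are pairwise ANI/AF estimates from an alignment-free ANI
estimator, protein-cluster memberships from a greedy clusterer, and
assemblies on disk. These generators emit the same formats with planted
ground truth so every algorithm is testable without genome downloads:

* :func:`simulate_population` plants clusters of near-identical genomes
  and emits a sparse edge list the way a screened ANI estimator would —
  pairs below the screening threshold are simply absent.
* :func:`simulate_pangenome` plants a core/accessory gene structure.
* :func:`simulate_toy_genomes` writes small random-sequence FASTA files
  with optional MGE intervals in BED.

All generators are pure functions of their parameters and seed;
percentages are drawn from truncated normals so values never leave
[0, 100]. ANI here is asserted, not computed from sequence — sequence-
level realism is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    ClusterMembership,
    GenomeRecord,
    MgeInterval,
    SimilarityEdge,
    compute_n50,
    write_membership_tsv,
    write_roster_tsv,
    write_skani_edges,
)

__all__ = [
    "PlantedPopulation",
    "simulate_population",
    "simulate_pangenome",
    "simulate_toy_genomes",
    "simulate_random_graph_inputs",
    "write_population",
]


@dataclass
class PlantedPopulation:
    """A synthetic genome population with known cluster structure."""

    roster: list[GenomeRecord]
    edges: list[SimilarityEdge]
    truth: dict[str, int]  # genome_id -> planted cluster index
    params: dict = field(default_factory=dict)


def _trunc_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = 0.0,
    high: float = 100.0,
) -> np.ndarray:
    """Normal truncated to [low, high]; degenerate sd=0 returns the mean."""
    if sd <= 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=size, random_state=rng
    )


def _make_roster(
    rng: np.random.Generator, genome_ids: list[str]
) -> list[GenomeRecord]:
    """Single-contig genomes with N50 drawn log-uniform on [1e4, 1e6]."""
    n50s = np.exp(
        rng.uniform(np.log(1e4), np.log(1e6), size=len(genome_ids))
    ).astype(int)
    return [
        GenomeRecord(
            genome_id=gid,
            contig_lengths=(int(n),),
            n50=int(n),
            source_path="<synthetic>",
        )
        for gid, n in zip(genome_ids, n50s)
    ]


def simulate_population(
    n_clusters: int = 3,
    sizes: Sequence[int] | int = 4,
    within_ani_mean: float = 99.8,
    within_ani_sd: float = 0.1,
    between_ani_mean: float = 85.0,
    between_ani_sd: float = 2.0,
    af_mean: float = 95.0,
    af_sd: float = 2.0,
    containment_fraction: float = 0.0,
    seed: int = 0,
    emit_between: bool = False,
) -> PlantedPopulation:
    """Plant ``n_clusters`` clusters of near-identical genomes.

    Within-cluster pairs get ANI ~ N(within_ani_mean, within_ani_sd) and
    symmetric-ish AFs ~ N(af_mean, af_sd), both truncated to [0, 100].
    Between-cluster pairs fall below the estimator's k-mer screening
    threshold and are omitted from the edge list unless ``emit_between``
    is set (useful for stress-testing the cutoff logic).

    A ``containment_fraction`` of genomes per cluster are marked as
    contained: in their within-cluster pairs their own aligned fraction
    is pushed near 100 while the partner's is depressed, producing the
    large AF asymmetry the dynamic algorithm's containment rule targets.
    """
    if within_ani_mean <= between_ani_mean:
        raise ValueError(
            "within-cluster ANI mean must exceed between-cluster mean"
        )
    if isinstance(sizes, int):
        sizes = [sizes] * n_clusters
    if len(sizes) != n_clusters:
        raise ValueError("need one cluster size per cluster")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    if not 0.0 <= containment_fraction <= 1.0:
        raise ValueError("containment_fraction outside [0, 1]")

    rng = np.random.default_rng(seed)
    genome_ids: list[str] = []
    truth: dict[str, int] = {}
    contained: set[str] = set()
    for c, size in enumerate(sizes):
        members = [f"c{c:02d}_g{i:02d}" for i in range(size)]
        genome_ids.extend(members)
        for gid in members:
            truth[gid] = c
        n_contained = int(round(containment_fraction * size))
        # never mark every member contained: a cluster needs a container
        n_contained = min(n_contained, size - 1)
        if n_contained > 0:
            picks = rng.choice(members, size=n_contained, replace=False)
            contained.update(str(p) for p in picks)

    roster = _make_roster(rng, genome_ids)
    within_pairs = [
        (a, b)
        for i, a in enumerate(genome_ids)
        for b in genome_ids[i + 1 :]
        if truth[a] == truth[b]
    ]
    nw = len(within_pairs)
    w_ani = _trunc_normal(rng, within_ani_mean, within_ani_sd, nw)
    w_af_a = _trunc_normal(rng, af_mean, af_sd, nw)
    w_af_b = _trunc_normal(rng, af_mean, af_sd, nw)
    c_hi = _trunc_normal(rng, 99.0, 0.5, nw)
    c_lo = _trunc_normal(rng, 60.0, 3.0, nw)
    edges: list[SimilarityEdge] = []
    for k, (a, b) in enumerate(within_pairs):
        af_a, af_b = float(w_af_a[k]), float(w_af_b[k])
        if a in contained and b not in contained:
            af_a, af_b = float(c_hi[k]), float(c_lo[k])
        elif b in contained and a not in contained:
            af_a, af_b = float(c_lo[k]), float(c_hi[k])
        edges.append(SimilarityEdge(a, b, float(w_ani[k]), af_a, af_b))
    if emit_between:
        between_pairs = [
            (a, b)
            for i, a in enumerate(genome_ids)
            for b in genome_ids[i + 1 :]
            if truth[a] != truth[b]
        ]
        nb = len(between_pairs)
        b_ani = _trunc_normal(rng, between_ani_mean, between_ani_sd, nb)
        b_af_a = _trunc_normal(rng, 30.0, 5.0, nb)
        b_af_b = _trunc_normal(rng, 30.0, 5.0, nb)
        for k, (a, b) in enumerate(between_pairs):
            edges.append(
                SimilarityEdge(
                    a, b, float(b_ani[k]), float(b_af_a[k]), float(b_af_b[k])
                )
            )
    return PlantedPopulation(
        roster=roster,
        edges=edges,
        truth=truth,
        params={
            "n_clusters": n_clusters,
            "sizes": list(sizes),
            "within_ani_mean": within_ani_mean,
            "within_ani_sd": within_ani_sd,
            "between_ani_mean": between_ani_mean,
            "between_ani_sd": between_ani_sd,
            "af_mean": af_mean,
            "af_sd": af_sd,
            "containment_fraction": containment_fraction,
            "seed": seed,
            "emit_between": emit_between,
        },
    )


def simulate_pangenome(
    n_genomes: int = 20,
    core_size: int = 50,
    accessory_pool: int = 200,
    accessory_rate: float = 0.2,
    seed: int = 0,
) -> tuple[ClusterMembership, dict[str, int]]:
    """Plant a core/accessory pangenome.

    Every genome carries all ``core_size`` core clusters plus an
    independent Bernoulli(``accessory_rate``) subset of the accessory
    pool. Returns the membership and the per-cluster genome counts as
    planted truth.
    """
    if n_genomes < 1 or core_size < 0 or accessory_pool < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    membership = ClusterMembership()
    core = [f"core{j:04d}" for j in range(core_size)]
    pool = [f"acc{j:04d}" for j in range(accessory_pool)]
    for i in range(n_genomes):
        gid = f"g{i:03d}"
        clusters = set(core)
        if pool:
            carry = rng.random(len(pool)) < accessory_rate
            clusters |= {p for p, keep in zip(pool, carry) if keep}
        membership.genome_to_clusters[gid] = clusters
    return membership, membership.cluster_genome_counts


def simulate_toy_genomes(
    n: int = 3,
    contig_lengths: Sequence[int] | None = None,
    out_dir: str | Path = ".",
    seed: int = 0,
    mge_fraction: float = 0.3,
) -> tuple[list[Path], Path]:
    """Write ``n`` random-sequence FASTA files plus one BED of planted
    MGE intervals; returns (fasta_paths, bed_path).

    Each genome gets the given contig lengths (default: 3-8 contigs of
    200-2,000 bp drawn per genome). Roughly ``mge_fraction`` of contigs
    receive one random interval covering an interior stretch; intervals
    never overlap because there is at most one per contig.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alphabet = np.array(list("ACGT"))
    fasta_paths: list[Path] = []
    bed_lines: list[str] = []
    for i in range(n):
        gid = f"toy{i:02d}"
        if contig_lengths is None:
            k = int(rng.integers(3, 9))
            lengths = rng.integers(200, 2001, size=k).tolist()
        else:
            lengths = list(contig_lengths)
        path = out_dir / f"{gid}.fasta"
        with open(path, "w") as handle:
            for j, length in enumerate(lengths):
                contig = f"{gid}_ctg{j}"
                seq = "".join(
                    alphabet[rng.integers(0, 4, size=int(length))]
                )
                handle.write(f">{contig}\n")
                # standard 60-column wrapping, so masking pass-through
                # stays byte-identical
                for k in range(0, len(seq), 60):
                    handle.write(seq[k : k + 60] + "\n")
                if length >= 100 and rng.random() < mge_fraction:
                    span = int(rng.integers(20, max(21, length // 3)))
                    start = int(rng.integers(1, length - span))
                    bed_lines.append(f"{contig}\t{start}\t{start + span}")
        fasta_paths.append(path)
    bed_path = out_dir / "mge_regions.bed"
    with open(bed_path, "w") as handle:
        for line in bed_lines:
            handle.write(line + "\n")
    return fasta_paths, bed_path


def simulate_random_graph_inputs(
    n: int,
    edge_prob: float,
    seed: int,
    containment_fraction: float = 0.0,
    ani_cutoff: float = 99.0,
    af_cutoff: float = 90.0,
) -> tuple[list[GenomeRecord], list[SimilarityEdge]]:
    """An Erdos-Renyi-style similarity structure for property testing.

    Each unordered pair independently becomes an edge with probability
    ``edge_prob``; edge ANI/AF values are drawn above the given cutoffs
    so the thresholded graph is exactly the sampled graph. A fraction of
    edges get strongly asymmetric AFs to exercise the containment rule.
    """
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i:03d}" for i in range(n)]
    roster = _make_roster(rng, genome_ids)
    ii, jj = np.triu_indices(n, k=1)
    keep = rng.random(len(ii)) < edge_prob
    ii, jj = ii[keep], jj[keep]
    m = len(ii)
    ani = rng.uniform(ani_cutoff, 100.0, size=m)
    contained = rng.random(m) < containment_fraction
    hi = rng.uniform(max(af_cutoff, 95.0), 100.0, size=m)
    lo = rng.uniform(40.0, 70.0, size=m)
    flip = rng.random(m) < 0.5
    af_a = rng.uniform(af_cutoff, 100.0, size=m)
    af_b = rng.uniform(max(0.0, af_cutoff - 5.0), 100.0, size=m)
    af_a = np.where(contained, np.where(flip, hi, lo), af_a)
    af_b = np.where(contained, np.where(flip, lo, hi), af_b)
    edges = [
        SimilarityEdge(
            genome_ids[a], genome_ids[b],
            float(ani[k]), float(af_a[k]), float(af_b[k]),
        )
        for k, (a, b) in enumerate(zip(ii, jj))
    ]
    return roster, edges


def write_population(pop: PlantedPopulation, out_dir: str | Path) -> dict:
    """Emit a planted population in the exact formats the readers
    consume: skani-dialect edges, roster TSV and a truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.tsv"
    roster_path = out_dir / "roster.tsv"
    truth_path = out_dir / "truth.tsv"
    write_skani_edges(pop.edges, edges_path)
    write_roster_tsv(pop.roster, roster_path)
    with open(truth_path, "w") as handle:
        handle.write("#genome_id\tplanted_cluster\n")
        for gid in sorted(pop.truth):
            handle.write(f"{gid}\t{pop.truth[gid]}\n")
    return {
        "edges": str(edges_path),
        "roster": str(roster_path),
        "truth": str(truth_path),
    }
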