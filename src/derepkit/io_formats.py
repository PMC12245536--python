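"""Readers and writers for the external formats the toolkit touches.

Covers genome assemblies in FASTA (plain or gzipped), sparse pairwise
ANI/AF edge lists in the skani ``triangle`` dialect, CD-HIT ``.clstr``
cluster reports, two-column protein-cluster membership TSVs, and BED
intervals delimiting predicted mobile genetic elements.

All percentage quantities (ANI, aligned fractions) are kept on the 0-100
scale exactly as printed by the upstream tools; nothing in the package
rescales them to 0-1.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

__all__ = [
    "InputFormatError",
    "GenomeRecord",
    "SimilarityEdge",
    "ClusterMembership",
    "MgeInterval",
    "genome_id_from_path",
    "compute_n50",
    "read_genome_roster",
    "parse_skani_edges",
    "write_skani_edges",
    "parse_cdhit_clstr",
    "parse_membership_tsv",
    "write_membership_tsv",
    "read_bed_intervals",
    "read_roster_tsv",
    "write_roster_tsv",
]

#: FASTA extensions stripped when deriving a genome identifier.
FASTA_EXTENSIONS = (".fa", ".fasta", ".fna")


class InputFormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly: identifier, contig lengths and N50.

    ``n50`` is always the value computed from ``contig_lengths``; the
    constructor path in :func:`read_genome_roster` guarantees this.
    """

    genome_id: str
    contig_lengths: tuple[int, ...]
    n50: int
    source_path: str

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths)


@dataclass(frozen=True)
class SimilarityEdge:
    """An unordered genome pair with its ANI and two directional AFs.

    ``af_a`` is the aligned fraction of ``genome_a`` (the percentage of
    genome_a's length covered by alignments to genome_b); AF is not
    symmetric, so ``af_b`` is carried separately.
    """

    genome_a: str
    genome_b: str
    ani: float
    af_a: float
    af_b: float

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise InputFormatError(f"self-pair not allowed: {self.genome_a}")
        for name in ("ani", "af_a", "af_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InputFormatError(f"{name}={v} outside [0, 100]")

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) unordered pair key."""
        a, b = self.genome_a, self.genome_b
        return (a, b) if a <= b else (b, a)

    @property
    def max_af(self) -> float:
        return max(self.af_a, self.af_b)

    def af_of(self, genome_id: str) -> float:
        if genome_id == self.genome_a:
            return self.af_a
        if genome_id == self.genome_b:
            return self.af_b
        raise KeyError(genome_id)


@dataclass
class ClusterMembership:
    """Genome -> protein-cluster sets, plus per-cluster genome counts.

    ``cluster_genome_counts[c]`` is the number of distinct genomes that
    carry cluster ``c`` and is always derivable from
    ``genome_to_clusters``; a cluster present in two or more genomes is a
    multi-genome cluster.
    """

    genome_to_clusters: dict[str, set[str]] = field(default_factory=dict)

    @property
    def cluster_genome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for clusters in self.genome_to_clusters.values():
            for c in clusters:
                counts[c] = counts.get(c, 0) + 1
        return counts

    @property
    def all_clusters(self) -> set[str]:
        out: set[str] = set()
        for clusters in self.genome_to_clusters.values():
            out |= clusters
        return out

    @property
    def multigenome_clusters(self) -> set[str]:
        return {c for c, n in self.cluster_genome_counts.items() if n >= 2}

    def add(self, genome_id: str, cluster_id: str) -> None:
        self.genome_to_clusters.setdefault(genome_id, set()).add(cluster_id)


@dataclass(frozen=True)
class MgeInterval:
    """A 0-based half-open interval on a contig flagged as an MGE."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InputFormatError(
                f"negative coordinate {self.start} on {self.contig_id}"
            )
        if self.start >= self.end:
            raise InputFormatError(
                f"empty or inverted interval {self.start}-{self.end} on "
                f"{self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def genome_id_from_path(path: str | Path) -> str:
    """Derive a genome identifier from an assembly file path.

    The basename is taken, a trailing ``.gz`` is removed, then one final
    extension from ``.fa``/``.fasta``/``.fna`` is stripped. The same rule
    is applied to roster files and to the path columns of skani edge
    lists so that joins between the two never fail silently.
    """
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    for ext in FASTA_EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return name


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50 of an assembly: the largest contig length L such that contigs
    of length >= L together hold at least half the assembly's bases.

    Computed by sorting lengths in descending order and walking the
    cumulative sum until it first reaches half the total.
    """
    if not contig_lengths:
        raise ValueError("cannot compute N50 of an empty assembly")
    if any(length <= 0 for length in contig_lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(contig_lengths, reverse=True)
    half = sum(ordered) / 2
    running = 0
    for length in ordered:
        running += length
        if running >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def _open_fasta(path: Path) -> TextIO:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome_roster(paths: Iterable[str | Path]) -> list[GenomeRecord]:
    """Read assemblies and build the genome roster with N50s.

    Only identifiers and contig lengths are retained; sequences are not
    kept in memory. Duplicate genome identifiers (e.g. ``a.fa`` next to
    ``a.fasta``) are rejected because downstream joins key on the id.
    """
    roster: list[GenomeRecord] = []
    seen: dict[str, str] = {}
    for raw in paths:
        path = Path(raw)
        gid = genome_id_from_path(path)
        if gid in seen:
            raise InputFormatError(
                f"duplicate genome id {gid!r} from {path} (already seen in "
                f"{seen[gid]})"
            )
        try:
            with _open_fasta(path) as handle:
                lengths = tuple(
                    len(rec.seq) for rec in SeqIO.parse(handle, "fasta")
                )
        except OSError as exc:
            raise InputFormatError(f"cannot read {path}: {exc}") from exc
        if not lengths:
            raise InputFormatError(f"no contigs in {path}")
        seen[gid] = str(path)
        roster.append(
            GenomeRecord(
                genome_id=gid,
                contig_lengths=lengths,
                n50=compute_n50(lengths),
                source_path=str(path),
            )
        )
    return roster


# skani triangle sparse output: header then one row per retained pair.
_SKANI_COLUMNS = 5


def parse_skani_edges(path: str | Path) -> list[SimilarityEdge]:
    """Parse a skani ``triangle`` sparse edge list (TSV with header).

    The first five columns are Ref_file, Query_file, ANI,
    Align_fraction_ref, Align_fraction_query; anything beyond is
    ignored. Genome ids are derived from the two path columns with the
    same basename/extension-stripping rule used for the roster. ``af_a``
    is the aligned fraction of the genome in column 1. Self-pairs are
    dropped; a repeated unordered pair is an error rather than a silent
    overwrite.
    """
    path = Path(path)
    edges: list[SimilarityEdge] = []
    seen_pairs: set[tuple[str, str]] = set()
    with open(path) as handle:
        header = handle.readline()
        if not header:
            raise InputFormatError(f"{path}: empty file, expected a header")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < _SKANI_COLUMNS:
                raise InputFormatError(
                    f"{path}:{lineno}: expected >= {_SKANI_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            gid_a = genome_id_from_path(fields[0])
            gid_b = genome_id_from_path(fields[1])
            try:
                ani, af_a, af_b = (float(fields[i]) for i in (2, 3, 4))
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-numeric ANI/AF field"
                ) from exc
            if gid_a == gid_b:
                continue
            try:
                edge = SimilarityEdge(gid_a, gid_b, ani, af_a, af_b)
            except InputFormatError as exc:
                raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
            if edge.pair in seen_pairs:
                raise InputFormatError(
                    f"{path}:{lineno}: duplicate pair {edge.pair}"
                )
            seen_pairs.add(edge.pair)
            edges.append(edge)
    return edges


def write_skani_edges(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    """Write edges back out in the skani triangle sparse dialect."""
    with open(path, "w") as handle:
        handle.write(
            "Ref_file\tQuery_file\tANI\tAlign_fraction_ref\t"
            "Align_fraction_query\n"
        )
        for e in edges:
            handle.write(
                f"{e.genome_a}.fasta\t{e.genome_b}.fasta\t{e.ani}\t"
                f"{e.af_a}\t{e.af_b}\n"
            )


_CLSTR_MEMBER_RE = re.compile(r">(?P<pid>.+?)\.\.\.")


def parse_cdhit_clstr(
    path: str | Path, genome_delimiter: str = "|"
) -> ClusterMembership:
    """Parse a CD-HIT ``.clstr`` cluster report into a membership map.

    Each ``>Cluster N`` header starts a block; member lines carry the
    protein id after ``>`` truncated at ``...``. The genome a protein
    belongs to is the prefix of the protein id before
    ``genome_delimiter`` (CD-HIT is run on proteins concatenated across
    genomes, so headers must be tagged; the tagging convention is
    configurable). Several proteins of one genome in the same cluster
    count once.
    """
    path = Path(path)
    membership = ClusterMembership()
    cluster_id: str | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                # cluster id is the trailing number of the header line
                cluster_id = line[1:].strip().split()[-1]
                continue
            if cluster_id is None:
                raise InputFormatError(
                    f"{path}:{lineno}: member line before any >Cluster header"
                )
            m = _CLSTR_MEMBER_RE.search(line)
            if m is None:
                raise InputFormatError(
                    f"{path}:{lineno}: cannot extract protein id"
                )
            pid = m.group("pid")
            if genome_delimiter not in pid:
                raise InputFormatError(
                    f"{path}:{lineno}: protein id {pid!r} lacks genome "
                    f"delimiter {genome_delimiter!r}"
                )
            genome = pid.split(genome_delimiter, 1)[0]
            membership.add(genome, cluster_id)
    return membership


def parse_membership_tsv(path: str | Path) -> ClusterMembership:
    """Parse a two-column (cluster_id, genome_id) TSV into a membership.

    A headerless direct-input alternative to ``.clstr`` for users who
    already resolved proteins to genomes. Duplicate rows are idempotent.
    """
    path = Path(path)
    membership = ClusterMembership()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise InputFormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            cluster_id, genome_id = fields
            membership.add(genome_id, cluster_id)
    return membership


def write_membership_tsv(
    membership: ClusterMembership, path: str | Path
) -> None:
    with open(path, "w") as handle:
        for genome in sorted(membership.genome_to_clusters):
            for cluster in sorted(membership.genome_to_clusters[genome]):
                handle.write(f"{cluster}\t{genome}\n")


def merge_intervals(intervals: Iterable[MgeInterval]) -> list[MgeInterval]:
    """Union overlapping or touching intervals per contig."""
    by_contig: dict[str, list[MgeInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig_id, []).append(iv)
    merged: list[MgeInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(MgeInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(MgeInterval(contig, cur_start, cur_end))
    return merged


def read_bed_intervals(path: str | Path) -> list[MgeInterval]:
    """Read 0-based half-open BED intervals; overlaps are merged on read
    so downstream masking can assume disjoint intervals."""
    path = Path(path)
    intervals: list[MgeInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: expected >= 3 BED columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            try:
                intervals.append(MgeInterval(fields[0], start, end))
            except InputFormatError as exc:
                raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
    return merge_intervals(intervals)


def read_roster_tsv(path: str | Path) -> list[GenomeRecord]:
    """Read a roster summary TSV (genome_id, comma-separated contig
    lengths) as written by :func:`write_roster_tsv`.

    This is the sequence-free way to feed a roster to the CLI when the
    pairwise edges came from elsewhere and the assemblies themselves are
    not at hand; N50s are recomputed from the stored lengths.
    """
    path = Path(path)
    roster: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}:{lineno}: expected genome_id and contig lengths"
                )
            gid = fields[0]
            if gid in seen:
                raise InputFormatError(
                    f"{path}:{lineno}: duplicate genome id {gid!r}"
                )
            try:
                lengths = tuple(int(x) for x in fields[1].split(",") if x)
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer contig length"
                ) from exc
            if not lengths:
                raise InputFormatError(f"{path}:{lineno}: no contig lengths")
            seen.add(gid)
            roster.append(
                GenomeRecord(gid, lengths, compute_n50(lengths), str(path))
            )
    return roster


def write_roster_tsv(roster: Iterable[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("#genome_id\tcontig_lengths\tn50\n")
        for rec in roster:
            lengths = ",".join(str(x) for x in rec.contig_lengths)
            handle.write(f"{rec.genome_id}\t{lengths}\t{rec.n50}\n")
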