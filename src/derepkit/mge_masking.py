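"""Coordinate surgery to excise mobile genetic elements from assemblies.

Plasmids and prophages evolve faster than chromosomes and tend to lower
the apparent ANI between strains, so users may want them removed before
ANI estimation. Masking splits each scaffold at its flagged intervals
and keeps the flanking segments as separate records.

Order matters in the wider pipeline: splitting scaffolds shreds the
assembly statistic, so N50 must be computed on the *unmasked* assembly.
:func:`apply_masked_roster` enforces that contract — scoring keeps the
original N50 while ANI estimation may consume the masked sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import GenomeRecord, MgeInterval, merge_intervals

__all__ = [
    "MaskingStats",
    "split_sequence",
    "mask_regions",
    "apply_masked_roster",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskingStats:
    """Per-run base accounting; retained + masked always equals the
    original base count, per contig and in total."""

    original_bases: dict[str, int]
    retained_bases: dict[str, int]
    masked_bases: dict[str, int]

    @property
    def total_masked(self) -> int:
        return sum(self.masked_bases.values())


def split_sequence(
    seq: str, intervals: Sequence[MgeInterval]
) -> list[tuple[int, str]]:
    """Cut a sequence at disjoint intervals; return (start, segment)
    pairs for the retained stretches, left to right. Zero-length
    segments are dropped."""
    ordered = sorted(intervals, key=lambda iv: iv.start)
    segments: list[tuple[int, str]] = []
    cursor = 0
    for iv in ordered:
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.start}-{iv.end} beyond contig end "
                f"({len(seq)} bp)"
            )
        if iv.start > cursor:
            segments.append((cursor, seq[cursor : iv.start]))
        cursor = iv.end
    if cursor < len(seq):
        segments.append((cursor, seq[cursor:]))
    return segments


def mask_regions(
    fasta_in: str | Path,
    intervals: Sequence[MgeInterval],
    fasta_out: str | Path,
) -> MaskingStats:
    """Remove the given intervals from an assembly by splitting contigs.

    Retained segments of a cut contig are emitted as
    ``<contig>_part<k>`` with k numbered left to right; contigs without
    intervals pass through unchanged. A contig entirely covered by an
    interval disappears from the output. Intervals are merged before
    cutting, so overlapping inputs are safe.
    """
    merged = merge_intervals(intervals)
    by_contig: dict[str, list[MgeInterval]] = {}
    for iv in merged:
        by_contig.setdefault(iv.contig_id, []).append(iv)

    records = list(SeqIO.parse(str(fasta_in), "fasta"))
    contig_ids = {rec.id for rec in records}
    unknown = set(by_contig) - contig_ids
    if unknown:
        raise ValueError(
            f"intervals reference contigs absent from {fasta_in}: "
            f"{sorted(unknown)}"
        )

    original: dict[str, int] = {}
    retained: dict[str, int] = {}
    out_records: list[SeqRecord] = []
    for rec in records:
        original[rec.id] = len(rec.seq)
        if rec.id not in by_contig:
            retained[rec.id] = len(rec.seq)
            out_records.append(rec)
            continue
        segments = split_sequence(str(rec.seq), by_contig[rec.id])
        retained[rec.id] = sum(len(s) for _, s in segments)
        for k, (_, segment) in enumerate(segments, start=1):
            out_records.append(
                SeqRecord(
                    Seq(segment), id=f"{rec.id}_part{k}", description=""
                )
            )
    SeqIO.write(out_records, str(fasta_out), "fasta")
    masked = {cid: original[cid] - retained[cid] for cid in original}
    return MaskingStats(
        original_bases=original, retained_bases=retained, masked_bases=masked
    )


def apply_masked_roster(
    roster: list[GenomeRecord], masked_paths: Mapping[str, str | Path]
) -> list[GenomeRecord]:
    """Swap assembly paths to their masked versions while keeping the
    N50 computed from the unmasked assemblies.

    Downstream scoring must see the pre-masking N50 so that MGE-rich
    genomes are not penalised as representatives; only the sequence
    source changes. A genome whose masked assembly retained no contigs
    is excluded from the roster with a warning.
    """
    out: list[GenomeRecord] = []
    for rec in roster:
        if rec.genome_id not in masked_paths:
            out.append(rec)
            continue
        masked = Path(masked_paths[rec.genome_id])
        lengths = [len(r.seq) for r in SeqIO.parse(str(masked), "fasta")]
        if not lengths:
            logger.warning(
                "genome %s lost all contigs to masking; excluded",
                rec.genome_id,
            )
            continue
        out.append(
            GenomeRecord(
                genome_id=rec.genome_id,
                contig_lengths=rec.contig_lengths,  # pre-masking
                n50=rec.n50,  # pre-masking, by contract
                source_path=str(masked),
            )
        )
    return out
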