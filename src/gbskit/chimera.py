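"""Detection and removal of chimeric GBS reads.

Restriction-ligation library preparation can join fragments from two or
more biological cut sites into one artificial read. Such reads are
diagnosed by a conjunction of two conditions: (1) the read sequence
contains more than one intact recognition-site motif, and (2) its
alignments cover two or more noncontiguous regions of the genome
(different scaffolds, or blocks separated by more than ``min_gap`` bp).
Both conditions must hold; a multi-motif read with one contiguous
alignment, or a split-aligned read with a single motif, is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .digest import DEFAULT_MOTIF

DEFAULT_MIN_GAP = 100  # read length: blocks further apart cannot come from one fragment
MIN_EVIDENCE_MAPQ = 20


def count_internal_cut_sites(sequence: str, motif: str = DEFAULT_MOTIF) -> int:
    """Number of (possibly overlapping) motif occurrences in a read."""
    count = 0
    i = sequence.find(motif)
    while i != -1:
        count += 1
        i = sequence.find(motif, i + 1)
    return count


def merge_blocks(
    blocks: Iterable[tuple[str, int, int]], min_gap: int
) -> list[tuple[str, int, int]]:
    """Merge aligned blocks that lie within ``min_gap`` bp on one scaffold."""
    merged: list[list] = []
    for scaffold, start, end in sorted(blocks):
        if merged and merged[-1][0] == scaffold and start - merged[-1][2] <= min_gap:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([scaffold, start, end])
    return [tuple(b) for b in merged]


def is_chimeric(
    records: Sequence[pysam.AlignedSegment],
    motif: str = DEFAULT_MOTIF,
    min_gap: int = DEFAULT_MIN_GAP,
    min_mapq: int = MIN_EVIDENCE_MAPQ,
) -> tuple[bool, str]:
    """Apply the two-condition chimera definition to one read's records.

    Returns (flag, evidence note). Records below ``min_mapq`` are ignored
    as alignment evidence; unmapped-only record sets return False with a
    "no-alignment" note.
    """
    seq = next(
        (r.query_sequence for r in records if r.query_sequence), None
    )
    if seq is None:
        return False, "no-sequence"
    n_motifs = count_internal_cut_sites(seq.upper(), motif)
    blocks: list[tuple[str, int, int]] = []
    for rec in records:
        if rec.is_unmapped or rec.mapping_quality < min_mapq:
            continue
        for start, end in rec.get_blocks():
            blocks.append((rec.reference_name, start, end))
    if not blocks:
        return False, "no-alignment"
    regions = merge_blocks(blocks, min_gap)
    flag = n_motifs > 1 and len(regions) >= 2
    return flag, f"motifs={n_motifs};regions={len(regions)}"


@dataclass
class ChimeraReport:
    total_reads: int = 0
    removed_reads: int = 0
    removed_per_sample: dict[str, int] = field(default_factory=dict)
    removed_read_ids: set[str] = field(default_factory=set)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tremoved_reads\n")
            for sample, n in sorted(self.removed_per_sample.items()):
                fh.write(f"{sample}\t{n}\n")


def _read_sample(record: pysam.AlignedSegment) -> str:
    if record.has_tag("RG"):
        return str(record.get_tag("RG"))
    return record.query_name.split(":", 1)[0]


def iter_read_groups(
    alignments: Iterable[pysam.AlignedSegment],
) -> Iterator[list[pysam.AlignedSegment]]:
    """Group consecutive records sharing a query name.

    The input must be grouped by read id (as read-sorted or mapper-emitted
    SAM files are); a read id that reappears after a different read aborts.
    """
    seen: set[str] = set()
    group: list[pysam.AlignedSegment] = []
    for rec in alignments:
        if group and rec.query_name != group[0].query_name:
            yield group
            group = []
        if not group:
            if rec.query_name in seen:
                raise ValueError(
                    f"records for read {rec.query_name!r} are interleaved; "
                    "group the input by read id first"
                )
            seen.add(rec.query_name)
        group.append(rec)
    if group:
        yield group


def filter_chimeras(
    in_sam: str | Path,
    out_sam: str | Path,
    motif: str = DEFAULT_MOTIF,
    min_gap: int = DEFAULT_MIN_GAP,
    min_mapq: int = MIN_EVIDENCE_MAPQ,
) -> ChimeraReport:
    """Remove every record of each chimeric read from a SAM/BAM file."""
    report = ChimeraReport()
    with pysam.AlignmentFile(str(in_sam)) as infile:
        with pysam.AlignmentFile(str(out_sam), "w", template=infile) as outfile:
            for group in iter_read_groups(infile):
                report.total_reads += 1
                flagged, _ = is_chimeric(group, motif, min_gap, min_mapq)
                if flagged:
                    report.removed_reads += 1
                    rid = group[0].query_name
                    report.removed_read_ids.add(rid)
                    sample = _read_sample(group[0])
                    report.removed_per_sample[sample] = (
                        report.removed_per_sample.get(sample, 0) + 1
                    )
                else:
                    for rec in group:
                        outfile.write(rec)
    return report
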