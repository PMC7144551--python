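"""In silico restriction digestion and merged-locus construction.

A GBS library only samples the genome around restriction cut sites, so all
downstream analyses are restricted to the intervals spanning a fixed flank
(default 92 bp) on each side of every recognition-site occurrence.
Overlapping or abutting intervals are merged into single loci; the merged
interval set defines the analyzable genomic fraction.

Coordinates are 0-based half-open throughout, matching BED natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

DEFAULT_MOTIF = "ATGCAT"  # EcoT22I recognition site (palindromic)
DEFAULT_FLANK = 92

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Locus:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    locus_id: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LocusSet:
    """Merged restriction-site flank intervals on a reference."""

    loci: list[Locus]
    flank_bp: int = DEFAULT_FLANK
    enzyme_motif: str = DEFAULT_MOTIF

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    def total_bp(self) -> int:
        return sum(len(l) for l in self.loci)

    def by_scaffold(self) -> dict[str, list[Locus]]:
        out: dict[str, list[Locus]] = {}
        for locus in self.loci:
            out.setdefault(locus.scaffold, []).append(locus)
        return out

    def validate(self, scaffold_lengths: Mapping[str, int] | None = None) -> None:
        """Check sortedness, bounds, non-overlap and locus-id uniqueness."""
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids are not unique")
        for scaffold, loci in self.by_scaffold().items():
            prev_end = -1
            for locus in loci:
                if not 0 <= locus.start < locus.end:
                    raise ValueError(f"bad interval {locus}")
                if locus.start < prev_end:
                    raise ValueError(f"overlapping/unsorted loci on {scaffold}")
                prev_end = locus.end
                if scaffold_lengths is not None and locus.end > scaffold_lengths[scaffold]:
                    raise ValueError(f"{locus} exceeds scaffold length")

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for locus in self.loci:
                fh.write(f"{locus.scaffold}\t{locus.start}\t{locus.end}\t{locus.locus_id}\n")

    @classmethod
    def read_bed(
        cls,
        path: str | Path,
        flank_bp: int = DEFAULT_FLANK,
        enzyme_motif: str = DEFAULT_MOTIF,
    ) -> "LocusSet":
        loci = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                name = fields[3] if len(fields) > 3 else f"locus_{i:06d}"
                loci.append(Locus(fields[0], int(fields[1]), int(fields[2]), name))
        return cls(loci, flank_bp=flank_bp, enzyme_motif=enzyme_motif)


def _scan(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) exact match start positions of motif."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def find_cut_sites(
    genome: Mapping[str, str], motif: str = DEFAULT_MOTIF
) -> dict[str, list[int]]:
    """Locate every recognition-site occurrence per scaffold.

    For a palindromic motif (such as EcoT22I's ATGCAT) only the forward
    strand needs scanning; non-palindromic motifs are scanned on both
    strands and positions deduplicated (reverse-strand hits are reported
    as forward-strand coordinates of the reverse complement).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be uppercase ACGT, got {motif!r}")
    rc = reverse_complement(motif)
    out = {}
    for scaffold, seq in genome.items():
        hits = _scan(seq, motif)
        if rc != motif:
            hits = sorted(set(hits) | set(_scan(seq, rc)))
        out[scaffold] = hits
    return out


def build_merged_loci(
    cut_sites: Mapping[str, Iterable[int]],
    scaffold_lengths: Mapping[str, int],
    flank_bp: int = DEFAULT_FLANK,
    motif: str = DEFAULT_MOTIF,
    include_motif: bool = True,
    min_scaffold_len: int = 0,
) -> LocusSet:
    """Flank every cut site and merge overlapping/abutting intervals.

    Each cut site at ``pos`` yields ``[max(0, pos - flank_bp),
    min(L, pos + len(motif) + flank_bp))`` (the recognition site itself is
    included unless ``include_motif`` is false, in which case the interval
    is ``[pos - flank_bp, pos + flank_bp)``). Scaffolds shorter than
    ``min_scaffold_len`` are dropped entirely, mirroring the restriction of
    the analysis to scaffolds above a minimum assembly size.
    """
    loci: list[Locus] = []
    n = 0
    span = len(motif) if include_motif else 0
    for scaffold, length in scaffold_lengths.items():
        if length < min_scaffold_len:
            continue
        positions = sorted(cut_sites.get(scaffold, []))
        intervals: list[list[int]] = []
        for pos in positions:
            if not 0 <= pos <= length - len(motif):
                raise ValueError(f"cut site {pos} out of bounds on {scaffold}")
            start = max(0, pos - flank_bp)
            end = min(length, pos + span + flank_bp)
            if intervals and start <= intervals[-1][1]:  # overlap or abut
                intervals[-1][1] = max(intervals[-1][1], end)
            else:
                intervals.append([start, end])
        for start, end in intervals:
            loci.append(Locus(scaffold, start, end, f"locus_{n:06d}"))
            n += 1
    locus_set = LocusSet(loci, flank_bp=flank_bp, enzyme_motif=motif)
    locus_set.validate(scaffold_lengths)
    return locus_set


def site_count_table(cut_sites: Mapping[str, list[int]]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {"scaffold": list(cut_sites), "n_sites": [len(v) for v in cut_sites.values()]}
    )
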