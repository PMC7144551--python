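"""Barcode demultiplexing and quality trimming for single-end GBS reads.

GBS reads carry an inline sample barcode followed by the enzyme remnant
left by the restriction cut (TGCAT for EcoT22I). Demultiplexing assigns
each read to the sample whose barcode matches the read prefix within a
mismatch budget (default one mismatch in the barcode and one in the
remnant) and clips the barcode — but not the remnant — from assigned
reads. Trimming removes low-quality and N ends and discards short or
N-rich reads; no adapter clipping is performed because GBS libraries do
not carry the common sequencing adapters at the read start.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

DEFAULT_REMNANT = "TGCAT"


@dataclass
class BarcodeTable:
    """Sample barcodes plus the expected enzyme remnant."""

    barcodes: dict[str, str]
    enzyme_remnant: str = DEFAULT_REMNANT
    control_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("barcodes must be unique")

    def min_pairwise_distance(self) -> int:
        codes = list(self.barcodes.values())
        best = min(
            (
                sum(a != b for a, b in zip(codes[i], codes[j]))
                for i in range(len(codes))
                for j in range(i + 1, len(codes))
            ),
            default=len(codes[0]) if codes else 0,
        )
        return best

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        remnant = df["remnant"].iloc[0] if "remnant" in df else DEFAULT_REMNANT
        controls = set()
        if "is_control" in df:
            controls = set(df.loc[df["is_control"].astype(int) == 1, "sample"])
        return cls(
            barcodes=dict(zip(df["sample"], df["barcode"])),
            enzyme_remnant=remnant,
            control_samples=controls,
        )


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a phred+33 FASTQ file; malformed records abort with the line number."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            lineno += 4
            if not qual:
                raise ValueError(f"truncated FASTQ record ending at line {lineno}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at line {lineno - 3}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"sequence/quality length mismatch at line {lineno - 3}"
                )
            yield FastqRead(header[1:].split()[0], seq, qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_read(
    seq: str,
    table: BarcodeTable,
    max_bc_mismatch: int = 1,
    max_site_mismatch: int = 1,
) -> str | None:
    """Return the sample a read belongs to, or None for non-matches/ties.

    A sample is a candidate when its barcode matches the read prefix within
    ``max_bc_mismatch`` and the enzyme remnant matches the following bases
    within ``max_site_mismatch``. With multiple candidates the read is
    assigned only if a single candidate has the strictly smallest
    (barcode, remnant) mismatch pair; exact ties go to unassigned.
    """
    remnant = table.enzyme_remnant
    candidates: list[tuple[int, int, str]] = []
    for sample, bc in table.barcodes.items():
        if len(seq) < len(bc) + len(remnant):
            continue
        d_bc = _hamming(seq[: len(bc)], bc)
        if d_bc > max_bc_mismatch:
            continue
        d_rem = _hamming(seq[len(bc) : len(bc) + len(remnant)], remnant)
        if d_rem > max_site_mismatch:
            continue
        candidates.append((d_bc, d_rem, sample))
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0][2]
    candidates.sort()
    if candidates[0][:2] == candidates[1][:2]:
        return None
    return candidates[0][2]


@dataclass
class DemuxReport:
    counts: dict[str, int]
    unassigned: int
    total: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\treads\n")
            for sample, n in self.counts.items():
                fh.write(f"{sample}\t{n}\n")
            fh.write(f"__unassigned__\t{self.unassigned}\n")


def demultiplex(
    fastq_path: str | Path,
    table: BarcodeTable,
    out_dir: str | Path,
    max_bc_mismatch: int = 1,
    max_site_mismatch: int = 1,
) -> DemuxReport:
    """Split a FASTQ file into per-sample files plus an unassigned file.

    The barcode (but not the enzyme remnant) is clipped from assigned
    reads. Assigned + unassigned always equals the input read count.
    """
    if table.min_pairwise_distance() < 2 * max_bc_mismatch + 1:
        import warnings

        warnings.warn(
            "barcode set does not guarantee unambiguous assignment at "
            f"{max_bc_mismatch} mismatches",
            stacklevel=2,
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handles = {
        sample: open(out_dir / f"{sample}.fastq", "w") for sample in table.barcodes
    }
    unassigned = open(out_dir / "unassigned.fastq", "w")
    counts = {sample: 0 for sample in table.barcodes}
    n_unassigned = 0
    total = 0
    try:
        for read in parse_fastq(fastq_path):
            total += 1
            sample = assign_read(read.seq, table, max_bc_mismatch, max_site_mismatch)
            if sample is None:
                unassigned.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
                n_unassigned += 1
                continue
            k = len(table.barcodes[sample])
            handles[sample].write(
                f"@{read.id}\n{read.seq[k:]}\n+\n{read.qual[k:]}\n"
            )
            counts[sample] += 1
    finally:
        for fh in handles.values():
            fh.close()
        unassigned.close()
    return DemuxReport(counts=counts, unassigned=n_unassigned, total=total)


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimReport:
    kept: int = 0
    trimmed: int = 0  # kept reads that lost at least one base
    discarded_short: int = 0
    discarded_ns: int = 0

    @property
    def discarded(self) -> int:
        return self.discarded_short + self.discarded_ns


def trim_read(
    read: FastqRead,
    min_quality: int = 15,
    trim_ns: bool = True,
    trim_qualities: bool = True,
) -> FastqRead:
    """Trim low-quality then N runs off both read ends (phred+33)."""
    seq, qual = read.seq, read.qual
    if trim_qualities:
        lo, hi = 0, len(seq)
        while lo < hi and ord(qual[lo]) - 33 < min_quality:
            lo += 1
        while hi > lo and ord(qual[hi - 1]) - 33 < min_quality:
            hi -= 1
        seq, qual = seq[lo:hi], qual[lo:hi]
    if trim_ns:
        lo, hi = 0, len(seq)
        while lo < hi and seq[lo] == "N":
            lo += 1
        while hi > lo and seq[hi - 1] == "N":
            hi -= 1
        seq, qual = seq[lo:hi], qual[lo:hi]
    return FastqRead(read.id, seq, qual)


def trim_reads(
    reads: Iterable[FastqRead],
    min_length: int = 30,
    min_quality: int = 15,
    max_ns: int = 40,
    trim_ns: bool = True,
    trim_qualities: bool = True,
) -> tuple[list[FastqRead], TrimReport]:
    """Quality/N end trimming with length and N-content discard rules.

    Reads shorter than ``min_length`` after trimming, or with more than
    ``max_ns`` remaining Ns, are discarded.
    """
    report = TrimReport()
    kept: list[FastqRead] = []
    for read in reads:
        out = trim_read(read, min_quality, trim_ns, trim_qualities)
        if len(out.seq) < min_length:
            report.discarded_short += 1
            continue
        if out.seq.count("N") > max_ns:
            report.discarded_ns += 1
            continue
        report.kept += 1
        if len(out.seq) != len(read.seq):
            report.trimmed += 1
        kept.append(out)
    return kept, report


def trim_fastq(
    in_path: str | Path,
    out_path: str | Path,
    min_length: int = 30,
    min_quality: int = 15,
    max_ns: int = 40,
    trim_ns: bool = True,
    trim_qualities: bool = True,
) -> TrimReport:
    kept, report = trim_reads(
        parse_fastq(in_path), min_length, min_quality, max_ns, trim_ns, trim_qualities
    )
    write_fastq(kept, out_path)
    return report
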