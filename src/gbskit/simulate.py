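"""Synthetic GBS study generator with complete ground truth.

Everything the pipeline consumes can be generated here: a multi-scaffold
reference with planted EcoT22I (ATGCAT) recognition sites and a motif-free
background, neutral-coalescent diploid genotypes (optionally from two
diverged populations), single-end 100-bp GBS reads with inline barcodes,
Poisson depth, phred-calibrated base errors, planted chimeric reads, and
low-coverage negative-control samples. The :class:`SimTruth` record carries
the exact planted state so every downstream filter can be scored against
truth.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds reproduce byte-identical FASTA/FASTQ/SAM outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .digest import DEFAULT_MOTIF, LocusSet

READ_LENGTH = 100
BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth for a simulated GBS study."""

    cut_positions: dict[str, list[int]] = field(default_factory=dict)
    genotypes: np.ndarray | None = None  # individuals x sites, {0,1,2} minor copies
    site_positions: list[tuple[str, int]] | None = None
    chimeric_read_ids: set[str] = field(default_factory=set)
    sample_barcodes: dict[str, str] = field(default_factory=dict)
    control_samples: set[str] = field(default_factory=set)
    paralog_locus_ids: set[str] = field(default_factory=set)
    read_samples: dict[str, str] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------


def _scrub_accidental_motifs(
    arr: np.ndarray, motif: str, planted: Sequence[int], rng: np.random.Generator
) -> None:
    """Mutate bases until `motif` occurs only at the planted positions.

    Each accidental occurrence gets one of its bases (outside any planted
    motif window) replaced by a different random base; repeated until the
    scan is clean, which makes the planted cut-site list exhaustive.
    """
    m = len(motif)
    planted_cover = set()
    for p in planted:
        planted_cover.update(range(p, p + m))
    planted_set = set(planted)
    while True:
        seq = "".join(arr)
        dirty = [h for h in _find_all(seq, motif) if h not in planted_set]
        if not dirty:
            return
        for h in dirty:
            candidates = [i for i in range(h, h + m) if i not in planted_cover]
            i = candidates[rng.integers(len(candidates))]
            current = arr[i]
            choices = [b for b in "ACGT" if b != current]
            arr[i] = choices[rng.integers(3)]


def _find_all(seq: str, motif: str) -> list[int]:
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def simulate_reference(
    n_scaffolds: int,
    scaffold_lengths: Sequence[int],
    n_planted_sites: int,
    seed: int,
    motif: str = DEFAULT_MOTIF,
    min_spacing: int = 250,
    tail_margin: int = READ_LENGTH,
) -> tuple[dict[str, str], SimTruth]:
    """Emit a random genome whose only motif occurrences are planted.

    ``n_planted_sites`` recognition sites are distributed round-robin over
    the scaffolds and placed at random positions at least ``min_spacing``
    bp apart (wide spacing keeps one cut site per merged locus and keeps
    100-bp reads from running into a neighboring site); ``tail_margin`` bp
    are reserved after the last site so a downstream read always fits. The
    background is scrubbed of accidental motif occurrences so the truth
    list is exhaustive.
    """
    if len(scaffold_lengths) != n_scaffolds:
        raise ValueError("scaffold_lengths must have n_scaffolds entries")
    rng = np.random.default_rng(seed)
    per_scaffold = [n_planted_sites // n_scaffolds] * n_scaffolds
    for i in range(n_planted_sites % n_scaffolds):
        per_scaffold[i] += 1
    genome: dict[str, str] = {}
    cut_positions: dict[str, list[int]] = {}
    m = len(motif)
    for i, (length, k) in enumerate(zip(scaffold_lengths, per_scaffold)):
        name = f"scaffold_{i + 1}"
        slack = length - max(m, tail_margin) - (k - 1) * min_spacing if k > 0 else length
        if k > 0 and slack < 0:
            raise ValueError(
                f"cannot place {k} sites spaced {min_spacing} bp on a "
                f"{length}-bp scaffold"
            )
        if k > 0:
            offsets = np.sort(rng.integers(0, slack + 1, size=k))
            positions = [int(o + j * min_spacing) for j, o in enumerate(offsets)]
        else:
            positions = []
        arr = BASES[rng.integers(0, 4, size=length)].copy()
        for p in positions:
            arr[p : p + m] = list(motif)
        _scrub_accidental_motifs(arr, motif, positions, rng)
        genome[name] = "".join(arr)
        cut_positions[name] = positions
    return genome, SimTruth(cut_positions=cut_positions, seed=seed)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Coalescent genotypes
# ---------------------------------------------------------------------------


@dataclass
class CoalescentSim:
    """Per-locus haplotypes/genotypes from a neutral coalescent."""

    haplotypes: list[np.ndarray]  # each (2N, S_l) in {0,1}
    theta: float
    seed: int

    @property
    def n_diploids(self) -> int:
        return self.haplotypes[0].shape[0] // 2

    @property
    def genotypes(self) -> list[np.ndarray]:
        # consecutive tips (2i, 2i+1) form diploid i
        return [h[0::2] + h[1::2] for h in self.haplotypes]

    def genotype_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate loci; returns (individuals x sites, locus index per site)."""
        gts = self.genotypes
        locus_idx = np.concatenate(
            [np.full(g.shape[1], i, dtype=int) for i, g in enumerate(gts)]
        )
        return np.concatenate(gts, axis=1), locus_idx


def _coalescent_branches(
    n_tips: int,
    rng: np.random.Generator,
    demes: Sequence[int] | None = None,
    split_time: float | None = None,
) -> list[tuple[frozenset[int], float]]:
    """Simulate a Kingman coalescent; return (descendant tip set, length) per branch.

    With ``demes``/``split_time``, lineages coalesce only within their deme
    (rate k_d(k_d-1)/2 per deme) until ``split_time``, after which all
    remaining lineages form a single ancestral pool — a clean two-population
    split with no migration.
    """
    active: list[list] = [[frozenset([i]), 0.0, demes[i] if demes is not None else 0] for i in range(n_tips)]
    branches: list[tuple[frozenset[int], float]] = []
    structured = demes is not None
    t = 0.0
    while len(active) > 1:
        if structured:
            deme_ids = sorted({lin[2] for lin in active})
            rates = []
            for d in deme_ids:
                k = sum(1 for lin in active if lin[2] == d)
                rates.append(k * (k - 1) / 2)
            total = sum(rates)
            dt = rng.exponential(1.0 / total) if total > 0 else math.inf
            if t + dt >= split_time:
                for lin in active:
                    lin[1] += split_time - t
                    lin[2] = 0
                t = split_time
                structured = False
                continue
            d = rng.choice(len(deme_ids), p=np.array(rates) / total)
            pool = [i for i, lin in enumerate(active) if lin[2] == deme_ids[d]]
        else:
            k = len(active)
            dt = rng.exponential(2.0 / (k * (k - 1)))
            pool = list(range(len(active)))
        for lin in active:
            lin[1] += dt
        t += dt
        i, j = sorted(rng.choice(pool, size=2, replace=False))
        lin_j = active.pop(j)
        lin_i = active.pop(i)
        branches.append((lin_i[0], lin_i[1]))
        branches.append((lin_j[0], lin_j[1]))
        active.append([lin_i[0] | lin_j[0], 0.0, lin_i[2]])
    return branches


def _mutate_branches(
    branches: list[tuple[frozenset[int], float]],
    n_tips: int,
    theta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop Poisson(theta * L / 2) infinite-sites mutations on the tree."""
    lengths = np.array([b[1] for b in branches])
    total = lengths.sum()
    n_mut = rng.poisson(theta * total / 2.0) if total > 0 else 0
    hap = np.zeros((n_tips, n_mut), dtype=np.uint8)
    if n_mut:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total)
        for s, b in enumerate(which):
            hap[list(branches[b][0]), s] = 1
    return hap


def simulate_coalescent_genotypes(
    n_diploids: int, n_loci: int, theta: float, seed: int
) -> CoalescentSim:
    """Neutral single-population coalescent loci under the infinite-sites model.

    Per locus a Kingman genealogy on 2*n_diploids tips (exponential waiting
    times with rate k(k-1)/2) receives Poisson(theta * branch_length / 2)
    mutations; haplotypes 2i and 2i+1 are paired into diploid i.
    """
    if n_diploids < 1:
        raise ValueError("n_diploids must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(seed)
    n_tips = 2 * n_diploids
    haps = []
    for _ in range(n_loci):
        branches = _coalescent_branches(n_tips, rng)
        haps.append(_mutate_branches(branches, n_tips, theta, rng))
    return CoalescentSim(haplotypes=haps, theta=theta, seed=seed)


def simulate_two_population_genotypes(
    n_diploids_per_pop: int,
    n_loci: int,
    theta: float,
    split_time: float,
    seed: int,
) -> CoalescentSim:
    """Two-population clean-split coalescent (no migration).

    Tips 0..2n-1 belong to population A, tips 2n..4n-1 to population B;
    diploids 0..n-1 are A, n..2n-1 are B. ``split_time`` is in coalescent
    units; a deep split (>= ~2) yields strongly diverged populations.
    """
    if n_diploids_per_pop < 1:
        raise ValueError("need at least one diploid per population")
    rng = np.random.default_rng(seed)
    n_tips = 4 * n_diploids_per_pop
    demes = [0] * (2 * n_diploids_per_pop) + [1] * (2 * n_diploids_per_pop)
    haps = []
    for _ in range(n_loci):
        branches = _coalescent_branches(n_tips, rng, demes=demes, split_time=split_time)
        haps.append(_mutate_branches(branches, n_tips, theta, rng))
    return CoalescentSim(haplotypes=haps, theta=theta, seed=seed)


# ---------------------------------------------------------------------------
# GBS reads
# ---------------------------------------------------------------------------


def default_barcodes(
    sample_names: Sequence[str], length: int = 6, seed: int = 0, min_distance: int = 3
) -> dict[str, str]:
    """Random equal-length barcodes with pairwise Hamming distance >= 3,
    so one barcode mismatch can never make two samples ambiguous."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    while len(codes) < len(sample_names):
        cand = "".join(BASES[rng.integers(0, 4, size=length)])
        if all(sum(a != b for a, b in zip(cand, c)) >= min_distance for c in codes):
            codes.append(cand)
    return dict(zip(sample_names, codes))


@dataclass
class ReadSimResult:
    """In-memory FASTQ + truth-alignment records plus ground truth."""

    fastq: list[tuple[str, str, str]]  # (read id, sequence, quality string)
    sam: list[dict]
    truth: SimTruth
    scaffold_lengths: dict[str, int]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.fastq:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_sam(self, path: str | Path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted", "GO": "query"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in self.scaffold_lengths.items()
            ],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in self.sam:
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec["name"]
                a.flag = rec["flag"]
                a.reference_name = rec["scaffold"]
                a.reference_start = rec["pos"]
                a.mapping_quality = rec["mapq"]
                a.cigarstring = rec["cigar"]
                a.query_sequence = rec["seq"]
                a.query_qualities = pysam.qualitystring_to_array(rec["qual"])
                a.set_tags(rec["tags"])
                out.write(a)

    def write_barcodes(self, path: str | Path, enzyme_remnant: str = "TGCAT") -> None:
        with open(path, "w") as fh:
            fh.write("sample\tbarcode\tremnant\tis_control\n")
            for sample, bc in self.truth.sample_barcodes.items():
                flag = int(sample in self.truth.control_samples)
                fh.write(f"{sample}\t{bc}\t{enzyme_remnant}\t{flag}\n")

    def write_truth_genotypes(self, path: str | Path) -> None:
        import pandas as pd

        truth = self.truth
        if truth.genotypes is None:
            raise ValueError("no genotypes recorded")
        samples = [
            s for s in truth.sample_barcodes if s not in truth.control_samples
        ]
        df = pd.DataFrame(
            truth.genotypes.T,
            columns=samples,
        )
        df.insert(0, "scaffold", [p[0] for p in truth.site_positions])
        df.insert(1, "pos", [p[1] for p in truth.site_positions])
        df.to_csv(path, sep="\t", index=False)


def _error_quality(error_rate: float) -> int:
    if error_rate <= 0:
        return 41
    return min(41, max(2, round(-10 * math.log10(error_rate))))


def _apply_errors(
    seq_arr: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    protect: tuple[int, int] | None = None,
) -> np.ndarray:
    if error_rate <= 0:
        return seq_arr
    mask = rng.random(seq_arr.size) < error_rate
    if protect is not None:
        mask[protect[0] : protect[1]] = False
    if mask.any():
        seq_arr = seq_arr.copy()
        for i in np.nonzero(mask)[0]:
            choices = [b for b in "ACGT" if b != seq_arr[i]]
            seq_arr[i] = choices[rng.integers(3)]
    return seq_arr


def simulate_gbs_reads(
    genome: Mapping[str, str],
    locus_set: LocusSet,
    coalescent: CoalescentSim | None,
    barcodes: Mapping[str, str],
    mean_depth: float = 10.0,
    error_rate: float = 0.001,
    chimera_rate: float = 0.0,
    seed: int = 0,
    read_length: int = READ_LENGTH,
    control_samples: Sequence[str] = (),
    control_depth_factor: float = 0.02,
    paralog_loci: Mapping[int, float] | None = None,
    motif: str = DEFAULT_MOTIF,
) -> ReadSimResult:
    """Emit single-end GBS reads plus a truth alignment for every read.

    Non-chimeric reads copy ``read_length - len(barcode)`` bases starting
    one base into a cut site (so they begin with the enzyme remnant TGCAT),
    carry the sample's haplotype alleles at the planted segregating sites,
    and accumulate per-base errors at ``error_rate`` with a constant phred
    quality q = -10*log10(error_rate). Depth per sample and locus is
    Poisson(``mean_depth``); negative-control samples are scaled by
    ``control_depth_factor``. A fraction ``chimera_rate`` of reads is
    replaced by chimeras joining fragments from three loci at intact
    cut-site motifs (so each chimera contains two internal motif copies and
    maps to noncontiguous regions); their truth alignments carry one
    primary and two supplementary records tagged ``XC:i:1``.

    ``paralog_loci`` maps locus indexes to depth multipliers emulating
    collapsed repeats (excess global depth).
    """
    if not 0 <= chimera_rate <= 1:
        raise ValueError("chimera_rate must be in [0, 1]")
    bc_lens = {len(b) for b in barcodes.values()}
    if len(bc_lens) != 1:
        raise ValueError("barcodes must share one length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("barcodes must be distinct")
    bc_len = bc_lens.pop()
    seg_len = read_length - bc_len
    rng = np.random.default_rng(seed)
    m = len(motif)
    control_samples = set(control_samples)
    paralog_loci = dict(paralog_loci or {})

    loci = locus_set.loci
    # one cut site per locus (guaranteed by the reference simulator's spacing)
    cuts: list[tuple[str, int]] = []
    for locus in loci:
        hit = genome[locus.scaffold].find(motif, locus.start, locus.end)
        if hit == -1:
            raise ValueError(f"{locus.locus_id} contains no motif")
        cuts.append((locus.scaffold, hit))

    # place each locus's segregating sites at distinct read-covered offsets
    # (after the 5-bp remnant, within the read span)
    truth = SimTruth(
        cut_positions={k: list(v) for k, v in find_positions(genome, motif).items()},
        sample_barcodes=dict(barcodes),
        control_samples=set(control_samples),
        seed=seed,
    )
    site_positions: list[tuple[str, int]] = []
    site_alt: list[str] = []
    locus_sites: list[list[int]] = []  # global site indexes per locus
    locus_offsets: list[np.ndarray] = []
    genotype_cols: list[np.ndarray] = []
    cohort = [s for s in barcodes if s not in control_samples]
    if coalescent is not None:
        if len(coalescent.haplotypes) != len(loci):
            raise ValueError("need one coalescent locus per genomic locus")
        if coalescent.n_diploids != len(cohort):
            raise ValueError("coalescent diploids must match non-control samples")
        genotypes = coalescent.genotypes
        haplotypes = coalescent.haplotypes
    for li, (scaffold, cut) in enumerate(cuts):
        if coalescent is None:
            locus_sites.append([])
            locus_offsets.append(np.array([], dtype=int))
            continue
        n_sites = haplotypes[li].shape[1]
        avail = np.arange(m, seg_len)  # offsets from cut+1, past the remnant
        n_keep = min(n_sites, avail.size)
        offsets = np.sort(rng.choice(avail, size=n_keep, replace=False))
        idxs = []
        for o in offsets:
            pos = cut + 1 + int(o)
            ref = genome[scaffold][pos]
            alts = [b for b in "ACGT" if b != ref]
            site_positions.append((scaffold, pos))
            site_alt.append(alts[rng.integers(3)])
            idxs.append(len(site_positions) - 1)
        locus_sites.append(idxs)
        locus_offsets.append(offsets)
        genotype_cols.append(genotypes[li][:, :n_keep])

    if coalescent is not None:
        truth.genotypes = (
            np.concatenate(genotype_cols, axis=1)
            if genotype_cols
            else np.zeros((len(cohort), 0), dtype=np.uint8)
        )
        truth.site_positions = site_positions

    qual_char = chr(33 + _error_quality(error_rate))
    fastq: list[tuple[str, str, str]] = []
    sam: list[dict] = []
    counter = 0
    n_loci = len(loci)

    def emit_normal(sample: str, si: int | None, li: int) -> None:
        nonlocal counter
        scaffold, cut = cuts[li]
        seg = np.array(list(genome[scaffold][cut + 1 : cut + 1 + seg_len]))
        if si is not None and coalescent is not None:
            hap = haplotypes[li][2 * si + rng.integers(2)]
            offs = locus_offsets[li]
            for k, o in enumerate(offs):
                if hap[k]:
                    seg[o] = site_alt[locus_sites[li][k]]
        read_arr = np.concatenate([np.array(list(barcodes[sample])), seg])
        read_arr = _apply_errors(read_arr, error_rate, rng)
        rid = f"{sample}:{loci[li].locus_id}:{counter}"
        counter += 1
        qual = qual_char * read_length
        fastq.append((rid, "".join(read_arr), qual))
        truth.read_samples[rid] = sample
        sam.append(
            {
                "name": rid,
                "flag": 0,
                "scaffold": scaffold,
                "pos": cut + 1,
                "mapq": 60,
                "cigar": f"{seg_len}M",
                "seq": "".join(read_arr[bc_len:]),
                "qual": qual_char * seg_len,
                "tags": [("XC", 0, "i")],
            }
        )

    def emit_chimera(sample: str, li: int) -> None:
        nonlocal counter
        others = [j for j in range(n_loci) if j != li]
        lb_i, lc_i = rng.choice(others, size=2, replace=False)
        la = int(rng.integers(15, 31))
        lb = int(rng.integers(15, 31))
        lc = seg_len - la - lb - 2 * m
        scaffold_a, cut_a = cuts[li]
        scaffold_b, cut_b = cuts[lb_i]
        scaffold_c, cut_c = cuts[lc_i]
        part_a = genome[scaffold_a][cut_a + 1 : cut_a + 1 + la]
        part_b = genome[scaffold_b][cut_b : cut_b + m + lb]
        part_c = genome[scaffold_c][cut_c : cut_c + m + lc]
        seg = np.array(list(part_a + part_b + part_c))
        read_arr = np.concatenate([np.array(list(barcodes[sample])), seg])
        # keep the two diagnostic motif copies intact: simulated errors never
        # erase the planted chimera signature
        read_arr = _apply_errors(
            read_arr, error_rate, rng, protect=(bc_len + la, bc_len + la + 2 * m + lb)
        )
        rid = f"{sample}:{loci[li].locus_id}:{counter}"
        counter += 1
        qual = qual_char * read_length
        fastq.append((rid, "".join(read_arr), qual))
        truth.read_samples[rid] = sample
        truth.chimeric_read_ids.add(rid)
        seq = "".join(read_arr[bc_len:])
        seg_qual = qual_char * seg_len
        tags = [("XC", 1, "i")]
        sam.append(
            {
                "name": rid,
                "flag": 0,
                "scaffold": scaffold_a,
                "pos": cut_a + 1,
                "mapq": 60,
                "cigar": f"{la}M{seg_len - la}S",
                "seq": seq,
                "qual": seg_qual,
                "tags": tags,
            }
        )
        sam.append(
            {
                "name": rid,
                "flag": 2048,
                "scaffold": scaffold_b,
                "pos": cut_b,
                "mapq": 60,
                "cigar": f"{la}S{m + lb}M{m + lc}S",
                "seq": seq,
                "qual": seg_qual,
                "tags": tags,
            }
        )
        sam.append(
            {
                "name": rid,
                "flag": 2048,
                "scaffold": scaffold_c,
                "pos": cut_c,
                "mapq": 60,
                "cigar": f"{la + m + lb}S{m + lc}M",
                "seq": seq,
                "qual": seg_qual,
                "tags": tags,
            }
        )

    for sample in barcodes:
        is_control = sample in control_samples
        si = None if is_control else cohort.index(sample)
        depth = mean_depth * (control_depth_factor if is_control else 1.0)
        for li in range(n_loci):
            locus_depth = depth * paralog_loci.get(li, 1.0)
            n_reads = rng.poisson(locus_depth)
            for _ in range(n_reads):
                if chimera_rate > 0 and n_loci >= 3 and rng.random() < chimera_rate:
                    emit_chimera(sample, li)
                else:
                    emit_normal(sample, si, li)
    if paralog_loci:
        truth.paralog_locus_ids = {loci[i].locus_id for i in paralog_loci}
    return ReadSimResult(
        fastq=fastq,
        sam=sam,
        truth=truth,
        scaffold_lengths={name: len(seq) for name, seq in genome.items()},
    )


def find_positions(genome: Mapping[str, str], motif: str) -> dict[str, list[int]]:
    return {name: _find_all(seq, motif) for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# Direct pileup-count simulation (for calibration studies)
# ---------------------------------------------------------------------------


def simulate_pileup_counts(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate per-sample read base counts at sites with known genotypes.

    ``genotypes`` is sites x samples in {0,1,2} copies of the minor allele.
    Each sample-site draws Poisson(mean_depth) reads; a read samples one of
    the two chromosomes and is misread to one of the three other bases with
    probability ``error_rate``. Returns arrays ``n_major``, ``n_minor``,
    ``n_other`` and ``depth`` (all sites x samples), the sufficient
    statistics for the genotype-likelihood model.
    """
    g = np.asarray(genotypes, dtype=float)
    e = error_rate
    depth = rng.poisson(mean_depth, size=g.shape)
    p_minor = (g / 2) * (1 - e) + (1 - g / 2) * (e / 3)
    p_major = (1 - g / 2) * (1 - e) + (g / 2) * (e / 3)
    p_other = 2 * e / 3
    n_minor = rng.binomial(depth, p_minor)
    rest = depth - n_minor
    denom = p_major + p_other
    n_major = rng.binomial(rest, np.divide(p_major, denom, out=np.ones_like(g), where=denom > 0))
    n_other = rest - n_major
    return {"n_major": n_major, "n_minor": n_minor, "n_other": n_other, "depth": depth}
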