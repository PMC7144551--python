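"""Depth-based paralog exclusion and presence/absence sample QC.

Two orthogonal quality controls operate on the merged locus set:

* **Paralog filtering.** Collapsed repeats attract reads from several
  genomic copies, inflating the global depth (GD, per-bp depth summed over
  a sample set) far beyond its roughly Poisson expectation. Loci whose GD
  summary exceeds a cutoff (default 800x, or a Poisson upper quantile of
  the mean) are excluded.

* **Failed-sample detection.** A presence/absence matrix (locus present in
  a sample when covered by >= 3 reads) is built; samples are hierarchically
  clustered (average linkage, Jaccard distance) and the smallest clade
  containing all negative-control samples is flagged as failed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import poisson

from .digest import Locus, LocusSet


@dataclass
class DepthProfile:
    """Per-locus per-bp global depth and per-sample read counts."""

    locus_ids: list[str]
    per_locus_depth: list[np.ndarray]  # per-bp depth within each locus
    read_counts: pd.DataFrame  # samples x loci

    def gd_summary(self, mode: str = "max") -> np.ndarray:
        if mode == "max":
            return np.array([d.max() if d.size else 0 for d in self.per_locus_depth])
        if mode == "mean":
            return np.array([d.mean() if d.size else 0.0 for d in self.per_locus_depth])
        raise ValueError(f"unknown GD summary mode {mode!r}")


def _read_sample(record: pysam.AlignedSegment) -> str:
    if record.has_tag("RG"):
        return str(record.get_tag("RG"))
    return record.query_name.split(":", 1)[0]


def compute_global_depth(
    sam_path: str | Path,
    locus_set: LocusSet,
    sample_set: Sequence[str] | None = None,
    min_mapq: int = 20,
) -> DepthProfile:
    """Accumulate per-bp depth and per-sample read counts over the loci.

    Only aligned blocks of records with mapping quality >= ``min_mapq``
    contribute. A read is counted for a locus when any of its blocks
    overlaps it; depth contributions are clipped to the locus interval.
    """
    by_scaffold: dict[str, list[Locus]] = locus_set.by_scaffold()
    starts = {s: [l.start for l in ll] for s, ll in by_scaffold.items()}
    depth = [np.zeros(len(l), dtype=np.int64) for l in locus_set.loci]
    index = {l.locus_id: i for i, l in enumerate(locus_set.loci)}
    counts: dict[str, dict[str, int]] = {}
    samples_wanted = set(sample_set) if sample_set is not None else None
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            sample = _read_sample(rec)
            if samples_wanted is not None and sample not in samples_wanted:
                continue
            scaffold = rec.reference_name
            if scaffold not in by_scaffold:
                continue
            loci = by_scaffold[scaffold]
            locus_starts = starts[scaffold]
            touched: set[str] = set()
            for bstart, bend in rec.get_blocks():
                # candidate loci: the one starting at or before the block,
                # plus any later locus starting before the block end
                k = bisect.bisect_right(locus_starts, bstart) - 1
                k = max(k, 0)
                while k < len(loci) and loci[k].start < bend:
                    locus = loci[k]
                    lo = max(bstart, locus.start)
                    hi = min(bend, locus.end)
                    if lo < hi:
                        depth[index[locus.locus_id]][
                            lo - locus.start : hi - locus.start
                        ] += 1
                        touched.add(locus.locus_id)
                    k += 1
            for lid in touched:
                counts.setdefault(sample, {})[lid] = (
                    counts.setdefault(sample, {}).get(lid, 0) + 1
                )
    locus_ids = [l.locus_id for l in locus_set.loci]
    all_samples = (
        list(sample_set) if sample_set is not None else sorted(counts)
    )
    table = pd.DataFrame(0, index=all_samples, columns=locus_ids, dtype=int)
    for sample, row in counts.items():
        for lid, n in row.items():
            table.loc[sample, lid] = n
    return DepthProfile(locus_ids=locus_ids, per_locus_depth=depth, read_counts=table)


def paralog_filter(
    profile: DepthProfile,
    locus_set: LocusSet,
    max_gd: float = 800.0,
    mode: str = "max",
    poisson_quantile: float | None = None,
) -> tuple[LocusSet, list[str]]:
    """Exclude loci whose GD summary exceeds the cutoff.

    With ``poisson_quantile`` q the cutoff is the upper-q quantile of a
    Poisson with rate equal to the mean GD summary, instead of ``max_gd``.
    Returns (kept LocusSet, excluded locus ids); the two partition the
    input exactly.
    """
    if not profile.locus_ids:
        raise ValueError("empty depth profile")
    gd = profile.gd_summary(mode)
    cutoff = max_gd
    if poisson_quantile is not None:
        cutoff = poisson.ppf(1.0 - poisson_quantile, gd.mean())
    keep_ids = {
        lid for lid, g in zip(profile.locus_ids, gd) if g <= cutoff
    }
    kept = [l for l in locus_set.loci if l.locus_id in keep_ids]
    excluded = [l.locus_id for l in locus_set.loci if l.locus_id not in keep_ids]
    return (
        LocusSet(kept, flank_bp=locus_set.flank_bp, enzyme_motif=locus_set.enzyme_motif),
        excluded,
    )


@dataclass
class PresenceMatrix:
    """Samples x loci presence booleans with negative-control flags."""

    matrix: pd.DataFrame  # bool, samples x loci
    control_samples: set[str]
    min_reads: int = 3


def presence_matrix(
    read_counts: pd.DataFrame,
    min_reads: int = 3,
    control_samples: Sequence[str] = (),
) -> PresenceMatrix:
    """Presence = locus covered by ``min_reads`` or more reads."""
    return PresenceMatrix(
        matrix=read_counts >= min_reads,
        control_samples=set(control_samples),
        min_reads=min_reads,
    )


# ---------------------------------------------------------------------------
# k-means locus clustering (heatmap compression)
# ---------------------------------------------------------------------------


def _kmeans_pp_init(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(len(X))]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[i] = X[rng.integers(len(X))]
            continue
        centers[i] = X[rng.choice(len(X), p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[i]) ** 2).sum(1))
    return centers


def cluster_loci_kmeans(
    pmatrix: PresenceMatrix | np.ndarray,
    k: int = 300,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Lloyd's k-means over locus presence profiles (loci as points).

    Uses k-means++ seeding with a fixed seed and asserts that the
    within-cluster sum of squares is non-increasing across iterations.
    Returns (labels per locus, within-cluster sum of squares).
    """
    if isinstance(pmatrix, PresenceMatrix):
        X = pmatrix.matrix.to_numpy(dtype=float).T  # loci x samples
    else:
        X = np.asarray(pmatrix, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of loci ({n})")
    rng = np.random.default_rng(seed)
    best_labels, best_wcss = None, np.inf
    for _ in range(n_init):
        centers = _kmeans_pp_init(X, k, rng)
        prev = np.inf
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(2)
            labels = d2.argmin(1)
            wcss = d2[np.arange(n), labels].sum()
            assert wcss <= prev + 1e-9, "k-means objective increased"
            if prev - wcss < 1e-12:
                break
            prev = wcss
            for c in range(k):
                members = X[labels == c]
                if len(members):
                    centers[c] = members.mean(0)
                else:  # re-seed empty cluster at the farthest point
                    centers[c] = X[d2[np.arange(n), labels].argmax()]
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, labels
    return best_labels, float(best_wcss)


# ---------------------------------------------------------------------------
# Failed-sample detection
# ---------------------------------------------------------------------------


@dataclass
class FailedSampleResult:
    flagged: list[str]  # failed non-control samples
    clade: list[str]  # all samples in the flagged clade (incl. controls)
    linkage: np.ndarray
    sample_order: list[str]
    newick: str


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def flag_failed_samples(
    pmatrix: PresenceMatrix,
    method: str = "average",
    metric: str = "euclidean",
) -> FailedSampleResult:
    """Flag the dendrogram tip branch holding all the negative controls.

    Samples are clustered on their presence rows (average linkage on
    Euclidean distance between the 0/1 rows by default, i.e. the square
    root of the Hamming distance, as heatmap clustering conventionally
    uses). Jaccard distance is available via ``metric`` but is a poor
    default here: it ignores shared absences, which are exactly what makes
    failed samples and water controls resemble each other.

    The flagged clade is the child of the dendrogram root that contains
    every control — the "tip branch" a reader would cut off the heatmap.
    Because controls are near-empty, this branch also captures failed
    samples that merged with the controls before the final join; when the
    data are clean it contains the controls alone. If the controls
    straddle the root the smallest clade containing all of them is used
    instead. The returned ``flagged`` list holds the clade's non-control
    members.
    """
    controls = pmatrix.control_samples & set(pmatrix.matrix.index)
    if not controls:
        raise ValueError("at least one negative control sample is required")
    samples = list(pmatrix.matrix.index)
    X = pmatrix.matrix.to_numpy(dtype=float if metric == "euclidean" else bool)
    dist = pdist(X, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # identical all-absent rows
    Z = hierarchy.linkage(dist, method=method)
    tree = hierarchy.to_tree(Z)
    control_idx = {samples.index(c) for c in controls}

    def leaves(node) -> set[int]:
        if node.is_leaf():
            return {node.id}
        return leaves(node.left) | leaves(node.right)

    best: set[int] | None = None
    for child in (tree.left, tree.right):
        if control_idx <= leaves(child):
            best = leaves(child)
            break
    if best is None:  # controls straddle the root: every sample is suspect
        best = leaves(tree)
    clade = [samples[i] for i in sorted(best)]
    flagged = [s for s in clade if s not in controls]
    return FailedSampleResult(
        flagged=flagged,
        clade=clade,
        linkage=Z,
        sample_order=samples,
        newick=_linkage_to_newick(Z, samples),
    )
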