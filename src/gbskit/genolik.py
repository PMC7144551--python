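"""Genotype likelihoods, allele-frequency EM, SNP calling and site filters.

The core model treats reads as independent draws from a diploid genotype
g in {0, 1, 2} copies of the minor allele:

    P(base b | g) = ((2 - g) / 2) * P(b | major) + (g / 2) * P(b | minor)
    P(b | a) = 1 - e  if b == a,  else e / 3,  with e = 10^(-q / 10)

Per-site minor allele frequencies are estimated by EM under Hardy-
Weinberg equilibrium; variants are called with a likelihood-ratio test of
maf = 0 against the EM estimate (chi-square with one degree of freedom),
and genotypes are called from posterior probabilities under a uniform or
HWE prior, subject to a posterior cutoff and minimum depth. A cascade of
site filters (missingness, depth cap, minor allele frequency, SNP
p-value) reproduces the standard genotype-likelihood workflow.

Bases with quality below ``min_base_q`` (default 20) and records with
mapping quality below ``min_mapq`` (default 30) are excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

DEFAULT_MIN_BASE_Q = 20
DEFAULT_MIN_MAPQ = 30
GENO_DOSAGE = np.array([0.0, 1.0, 2.0])
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def phred_to_error(q: np.ndarray | float) -> np.ndarray | float:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def normalize_gl(log_gl: np.ndarray) -> np.ndarray:
    """Max-normalize log-likelihood triples (last axis) to 0."""
    return log_gl - log_gl.max(axis=-1, keepdims=True)


def genotype_likelihood(
    bases: Sequence[str],
    quals: Sequence[int],
    major: str,
    minor: str,
    mapqs: Sequence[int] | None = None,
    min_base_q: int = DEFAULT_MIN_BASE_Q,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[np.ndarray, int]:
    """Log genotype-likelihood triple for one sample at one site.

    Returns (max-normalized log triple ordered hom-major/het/hom-minor,
    number of reads used). Zero usable depth yields (0, 0, 0) and depth 0,
    to be flagged missing by the caller.
    """
    log_gl = np.zeros(3)
    depth = 0
    for i, (b, q) in enumerate(zip(bases, quals)):
        if q < min_base_q:
            continue
        if mapqs is not None and mapqs[i] < min_mapq:
            continue
        if b not in _BASE_INDEX:
            continue
        e = phred_to_error(q)
        p_major = (1 - e) if b == major else e / 3
        p_minor = (1 - e) if b == minor else e / 3
        # P(b|g) for g = 0, 1, 2 copies of the minor allele
        probs = np.array(
            [p_major, 0.5 * p_major + 0.5 * p_minor, p_minor]
        )
        log_gl += np.log(probs)
        depth += 1
    return normalize_gl(log_gl), depth


def gl_from_counts(
    n_major: np.ndarray,
    n_minor: np.ndarray,
    n_other: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Vectorized log GL triples from base counts at a uniform error rate.

    Bases other than the major/minor alleles have probability e/3 under
    every genotype, so they contribute a genotype-independent factor that
    cancels after max-normalization. Output shape is input shape + (3,),
    max-normalized to 0.
    """
    e = error_rate
    n_major, n_minor, n_other = (
        np.asarray(a, dtype=float) for a in (n_major, n_minor, n_other)
    )
    log_gl = np.stack(
        [
            n_major * np.log(1 - e) + n_minor * np.log(e / 3),
            (n_major + n_minor) * np.log(0.5 * (1 - e) + 0.5 * e / 3),
            n_major * np.log(e / 3) + n_minor * np.log(1 - e),
        ],
        axis=-1,
    )
    log_gl += (n_other * np.log(e / 3))[..., None] if e > 0 else 0.0
    return normalize_gl(log_gl)


def choose_major_minor(base_counts: np.ndarray) -> tuple[int, int]:
    """Two most frequent bases (indexes into ACGT), ties broken alphabetically."""
    counts = np.asarray(base_counts)
    order = np.lexsort((np.arange(4), -counts))  # stable: alphabetical on ties
    return int(order[0]), int(order[1])


# ---------------------------------------------------------------------------
# Minor-allele-frequency EM and the SNP LRT
# ---------------------------------------------------------------------------


@dataclass
class MafResult:
    f: float
    loglik: float
    loglik_null: float
    n_iter: int
    n_informative: int


@dataclass
class SiteStats:
    site: int
    maf: float
    f: float
    lrt: float
    pval: float
    n_informative: int
    mean_depth: float


def hwe_prior(f: np.ndarray | float) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def _informative_likelihoods(
    gl: np.ndarray, missing: np.ndarray
) -> np.ndarray:
    """Linear-scale likelihoods with missing samples replaced by flat (1,1,1)."""
    lik = np.exp(np.asarray(gl, dtype=float))
    lik = np.where(missing[..., None], 1.0, lik)
    return lik


def hwe_loglik(gl: np.ndarray, missing: np.ndarray, f: np.ndarray | float) -> np.ndarray:
    """Log-likelihood of allele frequency f per site (sites x samples x 3 GLs)."""
    lik = _informative_likelihoods(gl, missing)
    prior = hwe_prior(f)
    if prior.ndim == 1:
        prior = np.broadcast_to(prior, lik.shape[:1] + (3,))
    persample = (lik * prior[:, None, :]).sum(-1)
    persample = np.where(missing, 1.0, persample)
    with np.errstate(divide="ignore"):  # data can rule a frequency out entirely
        return np.log(persample).sum(-1)


def estimate_maf_em_batch(
    gl: np.ndarray,
    missing: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    f0: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM estimate of per-site allele frequency under HWE, vectorized.

    ``gl`` is sites x samples x 3 max-normalized log-likelihoods.
    The update is f' = sum_s E[g_s | GL_s, HWE(f)] / (2 * N_informative);
    the per-site log-likelihood is asserted non-decreasing every step.
    Returns (f per site, final log-likelihood per site, iterations used).
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim == 2:
        gl = gl[None]
    n_sites, n_samples, _ = gl.shape
    if missing is None:
        missing = np.zeros((n_sites, n_samples), dtype=bool)
    n_inf = (~missing).sum(1)
    if np.any(n_inf == 0):
        raise ValueError("all-missing site passed to the MAF EM")
    lik = _informative_likelihoods(gl, missing)
    f = np.full(n_sites, f0)
    prev_ll = np.full(n_sites, -np.inf)
    iters = np.zeros(n_sites, dtype=int)
    active = np.ones(n_sites, dtype=bool)
    ll = prev_ll.copy()
    for _ in range(max_iter):
        prior = hwe_prior(f)
        w = lik * prior[:, None, :]
        wsum = w.sum(-1)
        wsum = np.where(missing, 1.0, wsum)
        ll = np.log(wsum).sum(-1)
        assert np.all(ll[active] >= prev_ll[active] - 1e-8), "EM log-likelihood decreased"
        e_g = (w @ GENO_DOSAGE) / np.maximum(w.sum(-1), 1e-300)
        e_g = np.where(missing, 0.0, e_g)
        f_new = e_g.sum(1) / (2 * n_inf)
        moved = np.abs(f_new - f) >= tol
        f = np.where(active, f_new, f)
        prev_ll = np.where(active, ll, prev_ll)
        iters += active
        active = active & moved
        if not active.any():
            break
    return f, prev_ll, iters


def estimate_maf_em(
    gl: np.ndarray,
    missing: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    f0: float = 0.1,
) -> MafResult:
    """Single-site wrapper around :func:`estimate_maf_em_batch`."""
    gl = np.asarray(gl, dtype=float)
    miss = None if missing is None else np.asarray(missing, dtype=bool)[None]
    f, ll, iters = estimate_maf_em_batch(gl[None], miss, tol, max_iter, f0)
    miss1 = (
        np.zeros(gl.shape[0], dtype=bool) if missing is None else np.asarray(missing)
    )
    ll0 = hwe_loglik(gl[None], miss1[None], np.array([0.0]))[0]
    return MafResult(
        f=float(f[0]),
        loglik=float(ll[0]),
        loglik_null=float(ll0),
        n_iter=int(iters[0]),
        n_informative=int((~miss1).sum()),
    )


def snp_lrt_batch(
    gl: np.ndarray,
    missing: np.ndarray,
    f: np.ndarray,
    loglik: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LRT = 2 * (l(f_hat) - l(0)) against chi-square(1), vectorized."""
    if loglik is None:
        loglik = hwe_loglik(gl, missing, f)
    ll0 = hwe_loglik(gl, missing, np.zeros_like(f))
    lrt = np.maximum(0.0, 2.0 * (loglik - ll0))
    pval = chi2.sf(lrt, df=1)
    pval = np.where(lrt <= 0, 1.0, pval)
    return lrt, pval


def snp_lrt(gl: np.ndarray, maf_result: MafResult, site: int = 0) -> SiteStats:
    """Site statistics for one site from its GLs and EM frequency estimate."""
    lrt = max(0.0, 2.0 * (maf_result.loglik - maf_result.loglik_null))
    pval = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    f = maf_result.f
    return SiteStats(
        site=site,
        maf=min(f, 1 - f),
        f=f,
        lrt=lrt,
        pval=pval,
        n_informative=maf_result.n_informative,
        mean_depth=float("nan"),
    )


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

MISSING = -1


@dataclass
class GenotypeCalls:
    """Called genotypes (0/1/2, -1 = missing) with posteriors and depth."""

    calls: np.ndarray  # sites x samples, int8
    posteriors: np.ndarray  # sites x samples (posterior of the called genotype)
    depth: np.ndarray  # sites x samples
    samples: list[str] = field(default_factory=list)


def genotype_posteriors(
    gl: np.ndarray,
    prior: str | np.ndarray = "uniform",
    f: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior genotype probabilities (sum to 1 on the last axis)."""
    lik = np.exp(np.asarray(gl, dtype=float))
    if isinstance(prior, str):
        if prior == "uniform":
            w = lik
        elif prior == "hwe":
            if f is None:
                raise ValueError("HWE prior requires allele frequencies f")
            w = lik * hwe_prior(f)[..., None, :]
        else:
            raise ValueError(f"unknown prior {prior!r}")
    else:
        w = lik * np.asarray(prior)
    return w / w.sum(-1, keepdims=True)


def call_genotypes(
    gl: np.ndarray,
    depth: np.ndarray,
    missing: np.ndarray | None = None,
    prior: str = "uniform",
    f: np.ndarray | None = None,
    post_cutoff: float = 0.95,
    geno_min_depth: int = 3,
    samples: Sequence[str] = (),
) -> GenotypeCalls:
    """Call the argmax-posterior genotype where it is confident and covered.

    A call is emitted only when the maximum posterior reaches
    ``post_cutoff`` and the sample's depth at the site reaches
    ``geno_min_depth``; otherwise the genotype is missing.
    """
    post = genotype_posteriors(gl, prior=prior, f=f)
    best = post.argmax(-1).astype(np.int8)
    best_p = np.take_along_axis(post, best[..., None].astype(int), axis=-1)[..., 0]
    ok = (best_p >= post_cutoff) & (np.asarray(depth) >= geno_min_depth)
    if missing is not None:
        ok &= ~np.asarray(missing, dtype=bool)
    calls = np.where(ok, best, np.int8(MISSING)).astype(np.int8)
    return GenotypeCalls(
        calls=calls, posteriors=best_p, depth=np.asarray(depth), samples=list(samples)
    )


# ---------------------------------------------------------------------------
# Site filter cascade
# ---------------------------------------------------------------------------


def site_filter_cascade(
    stats: pd.DataFrame,
    n_samples: int,
    min_ind_frac: float = 0.95,
    min_maf: float = 0.005,
    max_depth_per_ind: float = 275.0,
    snp_pval: float = 1e-6,
    require_snp: bool = True,
) -> tuple[np.ndarray, dict[str, int]]:
    """Apply the standard site filters in cascade order.

    ``stats`` needs columns ``n_informative``, ``total_depth``, ``maf``
    and ``pval``. A site is kept iff informative individuals >=
    ceil(min_ind_frac * N), total depth <= max_depth_per_ind * N, maf >=
    min_maf, and (when SNP calling is requested) pval < snp_pval. The
    attrition report charges each removed site to the first rule it fails,
    in that order.
    """
    n_sites = len(stats)
    keep = np.ones(n_sites, dtype=bool)
    attrition: dict[str, int] = {}
    min_ind = int(np.ceil(min_ind_frac * n_samples))
    rules = [
        ("min_ind", stats["n_informative"].to_numpy() >= min_ind),
        ("max_depth", stats["total_depth"].to_numpy() <= max_depth_per_ind * n_samples),
        ("min_maf", stats["maf"].to_numpy() >= min_maf),
    ]
    if require_snp:
        rules.append(("snp_pval", stats["pval"].to_numpy() < snp_pval))
    for name, passed in rules:
        removed = keep & ~passed
        attrition[name] = int(removed.sum())
        keep &= passed
    return keep, attrition


# ---------------------------------------------------------------------------
# Pileup construction from alignments
# ---------------------------------------------------------------------------


@dataclass
class SitePileup:
    """Per-sample read observations at one candidate site."""

    scaffold: str
    pos: int
    bases: list[list[str]]  # per sample
    quals: list[list[int]]
    mapqs: list[list[int]]


@dataclass
class GLMatrix:
    """Per-site per-sample genotype likelihoods with site metadata."""

    sites: pd.DataFrame  # scaffold, pos, major, minor
    gl: np.ndarray  # sites x samples x 3, max-normalized logs
    depth: np.ndarray  # sites x samples
    missing: np.ndarray  # sites x samples bool
    samples: list[str]

    def write_beagle(self, path: str | Path) -> None:
        """Beagle-style genotype-likelihood text table."""
        with open(path, "w") as fh:
            cols = "\t".join(
                "\t".join([s, s, s]) for s in self.samples
            )
            fh.write(f"marker\tallele1\tallele2\t{cols}\n")
            lik = np.exp(self.gl)
            lik = lik / lik.sum(-1, keepdims=True)
            for i, row in self.sites.reset_index(drop=True).iterrows():
                vals = "\t".join(
                    "\t".join(f"{v:.6f}" for v in lik[i, j]) for j in range(len(self.samples))
                )
                fh.write(
                    f"{row.scaffold}_{row.pos}\t{_BASE_INDEX[row.major]}\t"
                    f"{_BASE_INDEX[row.minor]}\t{vals}\n"
                )


def pileup_candidate_sites(
    sam_path: str | Path,
    locus_set,
    samples: Sequence[str],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_base_q: int = DEFAULT_MIN_BASE_Q,
    min_minor_count: int = 2,
) -> list[SitePileup]:
    """Two-pass pileup over the loci returning candidate variable sites.

    Pass 1 accumulates per-position base counts (numpy tensors) to find
    columns where a non-major base is observed at least
    ``min_minor_count`` times; pass 2 collects exact per-read base/quality
    observations at those columns only.
    """
    import pysam

    from .locus_qc import _read_sample

    sample_index = {s: i for i, s in enumerate(samples)}
    loci = locus_set.loci
    offsets = np.cumsum([0] + [len(l) for l in loci])
    total_bp = int(offsets[-1])
    spans: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for scaffold, group in locus_set.by_scaffold().items():
        idx = [i for i, l in enumerate(loci) if l.scaffold == scaffold]
        starts = np.array([loci[i].start for i in idx])
        ends = np.array([loci[i].end for i in idx])
        offs = np.array([offsets[i] for i in idx])
        order = np.argsort(starts)
        spans[scaffold] = (starts[order], ends[order], offs[order])

    # base codes: A/C/G/T -> 0..3, anything else -> -1
    base_code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_code[ord(b)] = i

    def columns_of(rec) -> tuple[np.ndarray, np.ndarray]:
        """(global column, query offset) arrays for aligned positions in loci."""
        here = spans.get(rec.reference_name)
        if here is None:
            return np.array([], dtype=int), np.array([], dtype=int)
        starts, ends, offs = here
        pairs = np.asarray(rec.get_aligned_pairs(matches_only=True), dtype=int)
        if pairs.size == 0:
            return np.array([], dtype=int), np.array([], dtype=int)
        qpos, rpos = pairs[:, 0], pairs[:, 1]
        k = np.searchsorted(starts, rpos, side="right") - 1
        valid = (k >= 0) & (rpos < ends[np.clip(k, 0, None)])
        k = k[valid]
        return offs[k] + rpos[valid] - starts[k], qpos[valid]

    counts = np.zeros((total_bp, 4), dtype=np.int32)
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_supplementary or rec.mapping_quality < min_mapq:
                continue
            if _read_sample(rec) not in sample_index:
                continue
            cols, qpos = columns_of(rec)
            if cols.size == 0:
                continue
            seq_codes = base_code[np.frombuffer(rec.query_sequence.encode(), dtype=np.uint8)]
            quals = np.asarray(rec.query_qualities)
            ok = (quals[qpos] >= min_base_q) & (seq_codes[qpos] >= 0)
            np.add.at(counts, (cols[ok], seq_codes[qpos[ok]]), 1)
    total = counts.sum(1)
    minor_mass = total - counts.max(1)
    candidate_cols = set(np.nonzero(minor_mass >= min_minor_count)[0].tolist())
    if not candidate_cols:
        return []

    col_meta: dict[int, tuple[str, int]] = {}
    for i, locus in enumerate(loci):
        for j in range(len(locus)):
            col = int(offsets[i]) + j
            if col in candidate_cols:
                col_meta[col] = (locus.scaffold, locus.start + j)
    pileups: dict[int, SitePileup] = {
        col: SitePileup(
            scaffold=meta[0],
            pos=meta[1],
            bases=[[] for _ in samples],
            quals=[[] for _ in samples],
            mapqs=[[] for _ in samples],
        )
        for col, meta in col_meta.items()
    }
    candidate_arr = np.array(sorted(pileups), dtype=int)
    with pysam.AlignmentFile(str(sam_path)) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_supplementary or rec.mapping_quality < min_mapq:
                continue
            sample = _read_sample(rec)
            if sample not in sample_index:
                continue
            si = sample_index[sample]
            cols, qpos = columns_of(rec)
            if cols.size == 0:
                continue
            hit = np.isin(cols, candidate_arr)
            if not hit.any():
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            for col, qp in zip(cols[hit], qpos[hit]):
                p = pileups[int(col)]
                p.bases[si].append(seq[qp])
                p.quals[si].append(int(quals[qp]))
                p.mapqs[si].append(rec.mapping_quality)
    return [pileups[col] for col in sorted(pileups)]


def gl_matrix_from_pileups(
    pileups: Sequence[SitePileup],
    samples: Sequence[str],
    min_base_q: int = DEFAULT_MIN_BASE_Q,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> GLMatrix:
    """Compute major/minor alleles and GL triples for each candidate site."""
    n_sites, n_samples = len(pileups), len(samples)
    gl = np.zeros((n_sites, n_samples, 3))
    depth = np.zeros((n_sites, n_samples), dtype=int)
    rows = []
    for i, p in enumerate(pileups):
        site_counts = np.zeros(4, dtype=int)
        for si in range(n_samples):
            for b, q in zip(p.bases[si], p.quals[si]):
                if q >= min_base_q and b in _BASE_INDEX:
                    site_counts[_BASE_INDEX[b]] += 1
        major_i, minor_i = choose_major_minor(site_counts)
        major, minor = _BASES[major_i], _BASES[minor_i]
        rows.append(
            {"scaffold": p.scaffold, "pos": p.pos, "major": major, "minor": minor}
        )
        for si in range(n_samples):
            triple, d = genotype_likelihood(
                p.bases[si], p.quals[si], major, minor,
                mapqs=p.mapqs[si], min_base_q=min_base_q, min_mapq=min_mapq,
            )
            gl[i, si] = triple
            depth[i, si] = d
    missing = depth == 0
    return GLMatrix(
        sites=pd.DataFrame(rows),
        gl=gl,
        depth=depth,
        missing=missing,
        samples=list(samples),
    )
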