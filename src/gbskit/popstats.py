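"""Site-frequency-spectrum estimation and diversity statistics.

From per-individual genotype likelihoods, the per-site sample allele
frequency (SAF) likelihood P(data | k derived copies among 2N) is obtained
by convolving the individual likelihood triples with hypergeometric
weights; an EM over sites then estimates the unfolded global SFS. From an
SFS (or directly from haplotypes) the standard diversity summaries follow:
the number of segregating sites S, Watterson's theta (S / a1), nucleotide
diversity pi (mean pairwise difference), and Tajima's D, with the
normalizing constants computed from the sample size at full floating
precision. Observed heterozygosity per sample is the percentage of
heterozygous calls among non-missing calls.

Without an outgroup, the major allele stands in for the ancestral state;
pi, theta_w and Tajima's D are unaffected by mispolarization (they depend
on the folded combination k <-> n-k), only the unfolded SFS shape is.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genolik import MISSING

GENOTYPE_WEIGHTS = np.array([1.0, 2.0, 1.0])  # C(2, g) arrangements per genotype


@dataclass
class SFS:
    """Unfolded site-frequency spectrum for N diploids (2N chromosomes)."""

    counts: np.ndarray  # length 2N+1, expected site counts per derived count
    n_diploids: int
    polarization: str = "major-as-ancestral"

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_diploids

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"derived_count": np.arange(len(self.counts)), "sites": self.counts}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DiversityEntry:
    """Per-population diversity summary."""

    population: str
    n_chromosomes: int
    segregating_sites: float
    theta_w: float
    pi: float
    tajima_d: float | None


def saf_per_site(gl: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Log-likelihood vector over derived-allele counts 0..2N for one site.

    ``gl`` is N x 3 max-normalized log genotype likelihoods ordered
    (hom-ancestral, het, hom-derived). Missing individuals are excluded;
    the returned vector spans the informative individuals' chromosomes.
    The convolution of L_i(g) * C(2, g) over individuals, divided by
    C(2N, k), is the probability of the data given k derived copies in
    the sample; returned max-normalized in log space.
    """
    gl = np.asarray(gl, dtype=float)
    if missing is not None:
        gl = gl[~np.asarray(missing, dtype=bool)]
    n = gl.shape[0]
    if n == 0:
        raise ValueError("all individuals missing at this site")
    lik = np.exp(gl)
    h = np.array([1.0])
    log_scale = 0.0
    for i in range(n):
        h = np.convolve(h, lik[i] * GENOTYPE_WEIGHTS)
        peak = h.max()
        h /= peak
        log_scale += np.log(peak)
    k = np.arange(2 * n + 1)
    denom = np.array([comb(2 * n, int(j)) for j in k], dtype=float)
    with np.errstate(divide="ignore"):  # impossible counts legitimately have L=0
        log_saf = np.log(h) + log_scale - np.log(denom)
    return log_saf - log_saf.max()


def estimate_sfs_em(
    saf: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """EM for the SFS mixture weights over frequency classes.

    ``saf`` is sites x (2N+1) log SAF vectors. The update is
    w_k' = mean over sites of w_k L_s(k) / sum_j w_j L_s(j); the total
    log-likelihood is asserted non-decreasing. Returns (expected site
    counts summing to the number of sites, final log-likelihood).
    """
    saf = np.asarray(saf, dtype=float)
    if saf.ndim != 2 or saf.shape[0] == 0:
        raise ValueError("need at least one site")
    n_sites, n_classes = saf.shape
    lik = np.exp(saf - saf.max(1, keepdims=True))
    w = np.full(n_classes, 1.0 / n_classes)
    prev_ll = -np.inf
    for _ in range(max_iter):
        num = lik * w
        persite = num.sum(1)
        ll = float(np.log(persite).sum())
        assert ll >= prev_ll - 1e-9, "SFS EM log-likelihood decreased"
        post = num / persite[:, None]
        w_new = post.mean(0)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            prev_ll = ll
            break
        w = w_new
        prev_ll = ll
    return w * n_sites, prev_ll


def sfs_from_genotypes(genotypes: np.ndarray, n_diploids: int | None = None) -> SFS:
    """Exact derived-count histogram from called genotypes (no missing)."""
    g = np.asarray(genotypes)
    n = g.shape[1] if n_diploids is None else n_diploids
    counts = np.bincount(g.sum(1), minlength=2 * n + 1).astype(float)
    return SFS(counts=counts, n_diploids=n)


def heterozygosity(calls: np.ndarray) -> float | None:
    """Observed heterozygosity: percent heterozygous among non-missing calls."""
    calls = np.asarray(calls)
    informative = calls != MISSING
    n = int(informative.sum())
    if n == 0:
        return None
    return 100.0 * float((calls[informative] == 1).sum()) / n


def tajima_constants(n: int) -> dict[str, float]:
    """Normalizing constants for Tajima's D at sample size n chromosomes."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def diversity_stats(
    sfs: SFS | np.ndarray,
    n_chromosomes: int | None = None,
    population: str = "pop",
) -> DiversityEntry:
    """S, Watterson's theta, pi and Tajima's D from an (unfolded) SFS.

    D is reported as missing (None) when its variance term is zero, which
    includes S = 0 and the n = 2 case where the constants vanish.
    """
    if isinstance(sfs, SFS):
        counts = sfs.counts
        n = sfs.n_chromosomes
    else:
        counts = np.asarray(sfs, dtype=float)
        n = len(counts) - 1 if n_chromosomes is None else n_chromosomes
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    k = np.arange(len(counts))
    S = float(counts[1:-1].sum())
    consts = tajima_constants(n)
    theta_w = S / consts["a1"]
    pi = float((k * (n - k) * counts).sum()) / comb(n, 2)
    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
    tajima_d = (pi - theta_w) / np.sqrt(var) if var > 0 else None
    return DiversityEntry(
        population=population,
        n_chromosomes=n,
        segregating_sites=S,
        theta_w=theta_w,
        pi=pi,
        tajima_d=tajima_d,
    )


def diversity_from_haplotypes(
    haplotypes: np.ndarray, population: str = "pop"
) -> DiversityEntry:
    """Diversity summary straight from a 2N x S 0/1 haplotype matrix."""
    hap = np.asarray(haplotypes)
    n = hap.shape[0]
    derived = hap.sum(0)
    counts = np.bincount(derived, minlength=n + 1).astype(float)
    return diversity_stats(counts, n_chromosomes=n, population=population)


def diversity_report(
    entries: Sequence[DiversityEntry],
    het_by_sample: dict[str, float | None] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "population": e.population,
                "n_chromosomes": e.n_chromosomes,
                "S": e.segregating_sites,
                "theta_w": e.theta_w,
                "pi": e.pi,
                "tajima_d": e.tajima_d,
            }
            for e in entries
        ]
    )
    if het_by_sample is not None:
        het = pd.DataFrame(
            [{"sample": s, "ho_percent": v} for s, v in het_by_sample.items()]
        )
        return df, het
    return df
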