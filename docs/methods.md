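# Methods

This note documents the models and procedures implemented in `gbskit`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## The GBS model of the genome

A restriction enzyme with a palindromic recognition site (EcoT22I,
`ATGCAT`) determines which genomic fraction a GBS library can observe:
100-bp single-end reads start at cut sites, so only the sequence within a
read length of a site is analyzable. `digest` formalizes this as intervals
of `flank_bp = 92` on each side of every motif occurrence (the motif
itself included by default; `include_motif=False` drops it). Intervals
that overlap or abut after flanking are merged, which is equivalent to
merging sites closer than the flank for the geometry at hand; coordinates
are 0-based half-open so BED output is native. A `min_scaffold_len`
cutoff (1 kb in the CLI default) drops short scaffolds whose assembly is
typically unreliable. For palindromic motifs only the forward strand is
scanned; non-palindromic motifs are scanned on both strands and positions
deduplicated.

## Read preparation

Demultiplexing matches the read prefix against each sample barcode
(≤ `max_bc_mismatch = 1` mismatches) and the following bases against the
enzyme remnant `TGCAT` (≤ `max_site_mismatch = 1`). Among candidates
passing both thresholds, the read is assigned only when one candidate has
the strictly smallest (barcode, remnant) mismatch pair; exact ties go to
the unassigned pool. This conservative tie-break is a design choice — the
classic demultiplexers do not document theirs — and with barcode sets of
pairwise Hamming distance ≥ 3 (the generator's guarantee, warned about
otherwise) ties cannot occur at one allowed mismatch. Only the barcode is
clipped; the remnant is genomic sequence and stays.

Trimming removes, from both read ends, first runs of bases below quality
15 and then runs of `N` (the order is documented because the upstream
tools do not fix it); reads shorter than 30 bp after trimming, or with
more than 40 remaining `N`s, are discarded. Adapter clipping is
deliberately absent: GBS inserts do not start with the common sequencing
adapters. Collapse/paired-end options would be no-ops for single-end data
and are omitted.

## Chimeric reads

Restriction-ligation chemistry can concatenate fragments from different
cut sites into one artificial read. A read is chimeric iff both
conditions hold: (1) its sequence contains more than one intact
recognition motif (an internal intact motif is the ligation signature —
counting uses the full motif, not the post-cut remnant), and (2) its
alignment records cover at least two noncontiguous regions. "Noncontiguous"
is operationalized as merged aligned blocks separated by more than
`min_gap = 100` bp (one read length — blocks further apart cannot come
from a single contiguous template) or on different scaffolds; records
with mapping quality < 20 are ignored as evidence. The filter removes all
records of a flagged read, partitioning the input exactly.

The simulator plants chimeras as barcode + remnant-started prefix from
one locus followed by two motif-started fragments from two other loci.
This three-part construction keeps every planted chimera demultiplexable
(it begins with barcode + remnant like a real GBS read) while carrying
exactly two intact internal motifs and three noncontiguous alignment
blocks, so both detection conditions hold by construction; simulated base
errors are not applied inside the two diagnostic motif copies, so planted
truth is recoverable exactly at any error rate. A two-fragment
construction cannot satisfy both the prefix contract and the two-motif
signature simultaneously.

## Locus and sample QC

**Paralog exclusion.** Collapsed repeats attract reads from several
genomic copies, so their global depth (GD; per-bp depth summed over a
sample set, mapq ≥ 20) far exceeds its roughly Poisson expectation. The
per-locus GD summary is the maximum per-bp depth within the locus — the
conservative aggregation, since a single collapsed segment suffices to
corrupt a locus; mean aggregation is available. Loci with summary above
`max_gd = 800` are excluded; alternatively `poisson_quantile=q` places
the cutoff at the upper-q quantile of Poisson(mean GD).

**Failed samples.** The presence/absence matrix marks a locus present in
a sample when covered by ≥ 3 reads. Samples are clustered by average
linkage on the Euclidean distance between presence rows. Euclidean on 0/1
rows (the square root of the Hamming distance, and what heatmap tools
default to) was chosen over Jaccard deliberately: Jaccard ignores shared
absences, which are exactly what makes failed samples and water controls
resemble each other — under Jaccard a control with a single present locus
is *closer to every rich sample* than to an all-empty fellow control, and
the control clade degenerates to the whole tree. The flagged set is the
root's child-clade containing all negative controls — the dendrogram "tip
branch" one would cut off a heatmap. Near-empty failed samples merge with
the controls before the final join and are captured; with clean data the
branch contains the controls alone. (The smallest clade containing all
controls would not work: two water controls always pair off first, so
that clade can never capture a failed sample.) Locus k-means (Lloyd's
algorithm, k-means++ seeding, fixed seed, `K = 300` by default) is
provided to compress the matrix for heatmap display; the within-cluster
sum of squares is asserted non-increasing at every iteration.

## Genotype likelihoods and SNP calling

Reads are independent draws from a diploid genotype `g ∈ {0,1,2}` copies
of the minor allele:

    P(b | g) = ((2−g)/2)·P(b | major) + (g/2)·P(b | minor)
    P(b | a) = 1−e  if b = a,  else e/3,   e = 10^(−q/10)

Bases below quality 20 and records below mapping quality 30 are excluded.
This is the plain independent-error genotype-likelihood model; the
error-dependency corrections and mapping-quality adjustments some callers
layer on top are intentionally not reimplemented. Major/minor alleles are
the two most frequent bases at the site, ties broken alphabetically.
Likelihood triples are max-normalized in log space; zero-depth
sample-sites are missing, not errors.

**Allele frequency.** EM under Hardy–Weinberg:
`f' = Σ_s E[g_s | GL_s, HWE(f)] / (2·N_informative)`, initialized at
`f₀ = 0.1` (an interior point), converged at `|Δf| < 10⁻⁶`; the observed
log-likelihood is asserted non-decreasing at every step. The estimate
lives in [0,1]; the reported MAF is `min(f̂, 1−f̂)`.

**SNP test.** `LRT = 2(ℓ(f̂) − ℓ(0))` referred to χ²₁; a site is a SNP at
`p < 10⁻⁶`. Because the null value `f = 0` lies on the boundary of the
parameter space, the χ²₁ reference is conservative: the asymptotic null is
the ½δ₀ + ½χ²₁ mixture at best, and at realistic per-site error
information the observed null rejection rate is far below nominal (on
simulated monomorphic panels, ~10⁻³ at a 0.05 threshold and zero at
10⁻⁶). This conservativeness is a property of the method, favoring
specificity over calibrated p-values.

**Genotype calls.** Posterior ∝ prior × likelihood with a uniform prior
by default (an HWE(f̂) prior is selectable — both are offered because
either can reasonably feed the distance matrix); a call is emitted iff
the maximum posterior reaches 0.95 and depth reaches 3, else missing.

**Site filters.** In cascade order: informative individuals
≥ ⌈0.95·N⌉, total depth ≤ 275·N (the per-individual depth cap applied to
the site total, with an override), MAF ≥ 0.005, and SNP `p < 10⁻⁶` when
SNP calling is requested. The attrition report charges each removed site
to the first rule it fails.

## SFS and diversity

The per-site sample-allele-frequency (SAF) likelihood
`P(data | k derived among 2N)` is the convolution over individuals of
`L_i(g)·C(2,g)`, divided by `C(2N,k)` — computed by sequential
convolution with per-step renormalization to avoid underflow. The global
unfolded SFS is the EM mixture estimate over frequency classes
(`w_k' = mean_s w_k L_s(k) / Σ_j w_j L_s(j)`, log-likelihood asserted
non-decreasing, tolerance 10⁻⁸). Without an outgroup the major allele
stands in for the ancestral state; this mispolarization folds the SFS
shape but leaves π, θ_w and Tajima's D unchanged (they depend only on the
k ↔ n−k combination), which the tests check numerically.

From an SFS on n chromosomes: `S = Σ_{0<k<n} SFS_k`, `θ_w = S/a₁`,
`π = Σ_k k(n−k)·SFS_k / C(n,2)`, and `D = (π − θ_w)/√(e₁S + e₂S(S−1))`
with the standard constants computed at full floating precision from n.
D is reported missing when the variance term vanishes — including S = 0
and n = 2, where c₁ = c₂ = 0 analytically. Observed heterozygosity is
100 × heterozygous calls / non-missing calls per sample. Per-population
statistics default to populations with ≥ 5 individuals, since these
estimators are population quantities.

Note that the per-locus mean of Tajima's D under strict neutrality is not
exactly zero: D is a ratio statistic and its finite-sample expectation is
slightly negative (about −0.07 at n = 10 chromosomes and θ = 5,
consistent with independent coalescent simulators). Calibration checks on
the mean of D over loci should expect this small offset.

## Distances, trees, MDS

The distance between samples i and j is the posterior expectation of the
allelic mismatch fraction, `Σ_{g,h} P_i(g)P_j(h)·|g−h|/2`, averaged over
the sites where both samples are informative (pairwise deletion);
per-pair usable-site counts are reported, and pairs sharing no sites are
flagged undefined. The |g−h|/2 kernel is the package's documented default
where upstream tools leave the kernel unspecified; it is pluggable.

Neighbor joining follows Saitou–Nei: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, with the standard
branch-length and distance-update formulas; ties are broken by the first
minimal pair in row-major scan order, the final three nodes join at a
trifurcating root by the three-point formula, and negative branch lengths
are clamped to zero with the deficit moved to the sister branch
(preserving the joined pair's path length). On additive matrices the
algorithm is exact, which the tests exploit as an oracle. Bootstrap
support resamples sites (columns) with replacement — locus-block
resampling is available via a block-size option — recomputes distance
matrix and tree per replicate, and scores each internal split of the
full-data tree by the percentage of replicates containing it. A
maximum-likelihood tree search is intentionally out of scope; the NJ tree
is the deliverable, and ML engines are established external tools.

Classical MDS double-centers the squared distances
(`B = −½·J·D²·J`), takes the top-k eigenpairs, and scales eigenvectors by
the square roots of the eigenvalues; dimensions with non-positive
eigenvalues are suppressed with a warning and the full eigenvalue vector
is returned for diagnostics.

## The synthetic-data generator

The generator emulates the study conditions end to end: a multi-scaffold
reference whose background is rejection-scrubbed of accidental motif
occurrences (so the planted cut-site list is exhaustive and digestion
checks can be exact), planted sites spaced ≥ 250–300 bp apart (one site
per merged locus; reads never run into a neighboring site), Kingman
coalescent genealogies (exponential waiting times at rate k(k−1)/2) with
Poisson(θ·L/2) infinite-sites mutations, consecutive haplotype pairing
into diploids, and an optional clean two-population split (within-deme
coalescence only until the split time, then a common ancestral pool).
Reads carry barcode + remnant + flank sequence with Poisson per-locus
depth, constant phred quality `q = −10·log₁₀(e)` matching the error rate,
and per-base errors; negative controls are barcode-only lanes at 2% of
normal depth; collapsed paralogs are emulated by a per-locus depth
multiplier (default 10×). Chimeras are planted as described above, with
one primary and two supplementary truth-SAM records and an `XC:i:1` tag.
The truth SAM stands in for the mapping step, which is out of scope
(alignments are consumed, not produced).

What the generator does *not* emulate — PCR duplicates, indels,
paired-end reads, fragment-size selection, mapping error, base-quality
miscalibration, reference bias — bounds what passing tests show: they
validate the statistical machinery against its own model assumptions and
exact combinatorial oracles, not robustness to artifacts absent from the
model.

Default cohort conditions (`workflow.CohortConfig`): 6 diploids per
population + 2 controls, 500 loci on 4 scaffolds, θ = 3 per locus, split
time 2.0 (deeply diverged), depth 8×, error 10⁻³ (q30), 2% chimeras, one
10× paralog locus. These sizes keep a full pipeline run around a minute
while leaving every filter with real work to do; validation statistics
elsewhere use 10,000 sites (LRT null), 1,000 loci (diversity recovery),
200 matrices (NJ), as stated in the test docstrings.

## Numerical notes and limitations

- EM monotonicity (MAF and SFS) is asserted at every iteration with a
  10⁻⁸/10⁻⁹ slack for round-off; SAF convolutions renormalize per step.
- k-means handles empty clusters by re-seeding at the farthest point;
  the objective assertion tolerates 10⁻⁹ round-off.
- The boundary-conservative SNP LRT (above) means published nominal
  thresholds act as specificity floors, not calibrated error rates.
- Distances from posteriors are biased upward by genotype uncertainty at
  low depth (the expected mismatch of two noisy posteriors exceeds that
  of the true genotypes); bootstrap supports are valid for the tree built
  from the same posteriors.
- `simulate_gbs_reads` drops segregating sites beyond the read-covered
  span of a locus (more sites than available positions is only reachable
  at extreme θ); truth records only the planted sites.
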