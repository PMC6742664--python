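# Methods

This note documents the models, parameter choices and numerical decisions
behind `fitsel`, in the spirit of a methods appendix: what each stage
assumes, what the synthetic data do and do not emulate, and where the
design was genuinely open.

## Receptor-level model

Per-neuron TRKC levels are gamma-Poisson: X ~ Poisson(Λ) with
Λ ~ Gamma(1/φ, μφ), giving E[X] = μ and Var[X] = μ(1 + φμ). The biological
observation being emulated is a "Poisson-like" right-skewed distribution of
receptor levels whose mean splits the population into High and Low classes;
no distributional parameters are published, so μ = 20 (arbitrary intensity
units) and φ = 0.15 are free defaults chosen to give a clearly overdispersed
but unimodal distribution with a High fraction near 40–45% under the
mean split. The pure-Poisson limit φ = 0 is exact (the generator draws
Poisson directly), and Var ≥ mean holds for every φ ≥ 0.

RUNX3→TRKC coupling is linear with additive Gaussian noise truncated at
zero: T = max(aR + ε, 0). The implied Pearson correlation
r = a·sd(R)/√(a²var(R) + σ²) is used as a closed-form oracle in tests.
Subgroup structure (the two transcriptomic PSN states) enters as a
two-component mixture on the RUNX3 mean with ratio 2.2; the mixture weight
defaults to 0.5, consistent with a survival fraction near one half.

## smFISH scenes and spot calling

Scenes are rendered as isotropic 2-D Gaussian spots (σ = 1.1 px, peak
amplitude 8) in one z-plane each, over a low-frequency Gaussian random
field (σ = 40 px, amplitude 2 plus a positive baseline) with i.i.d. read
noise (σ = 1; peak SNR 8) and clipping at zero. The FL channel's
ground-truth spots are a per-cell binomial thinning of the pan spots at
rate 0.68, the measured in-vivo share of full-length transcript. Cells are
discs of radius 40 px placed on a jittered grid; 200 cells in a
1500×1500×4 stack with a mean of 6 spots per cell is the default scene.
That density is deliberately in the resolvable regime: detection runs on
the maximum projection, so two molecules closer than ~2σ in (y, x) merge
irrecoverably, and the generator warns when the configured density exceeds
the resolvable bound. Tissue-realistic crowding, 3-D PSF shape, chromatic
shifts and autofluorescence are out of scope; consequently the measured
recall/precision characterize the detector in the sparse single-molecule
regime, not performance on saturated tissue.

The detection chain is: max projection → subtraction of a large-kernel
Gaussian estimate of background (σ = 10 px; absorbs any constant offset) →
scale-normalized LoG response, implemented as −σ²·Laplace(Gaussian(img, σ))
with the *discrete* 5-point Laplacian so that constant images map to
exactly zero → local maxima above an absolute threshold (default 1.5,
calibrated once on synthetic scenes since no published value exists) with
minimum separation 2σ (rounded to the nearest pixel) → rejection of maxima
inside thresholded connected components larger than 25× the area of a 2σ
disc ("significantly larger than a dot"; the factor is an order-of-magnitude
separation, declared rather than inferred). Peak positions are refined by
per-axis quadratic interpolation (≤ 0.5 px), which brings localization
error well under the 1-px matching radius used for scoring. ROI membership
is boundary-inclusive point-in-polygon with the first-listed ROI winning
shared-boundary ties; self-intersecting polygons are rejected.

Isoform arithmetic is exact bookkeeping: t = max(pan − FL, 0) per cell,
cells with FL > pan (counting noise) are clipped and flagged, and the
pooled FL share is Σ FL / Σ pan.

## Intensity quantification

Corrected intensity is density-minus-control-density:
I = D(exp) − mean over the same section's marker-negative cells of D(ctrl),
with D = RawIntDensity/Area. Negative values are retained (clipping would
bias section means) and flagged. Sections, not cells, are the replicate
unit: genotype summaries average section means with equal weight.
High/Low classification thresholds at the cohort mean with ties going High
(a deterministic, documented rule). Correlations report Pearson (the
primary, since published panels show linear fits) alongside Spearman; the
variance-spread F test places the larger variance in the numerator and
doubles the upper tail for a two-sided p. One published figure legend
reports "F = 0.0009", almost certainly a p-value mislabeled as F; the
function returns both the statistic and p so either reading can be checked.

## Selection simulator

The simulator is a single discrete death event between two censuses, which
matches the short (~12 h) death window; there are no continuous-time
dynamics.

**Labeling.** Dose-limited CreER recombination is a power law in receptor
level, p_i = min(1, c·L_i^k). c is calibrated by bisection (relative
tolerance 10⁻⁶ — the scale can be arbitrarily small, so absolute tolerances
are wrong here) so that E[labeled fraction] hits the target (11%); k is
calibrated by an outer bisection so that the expected share of labeled
cells above the population mean hits 75%. With the default population both
constraints are met simultaneously (k ≈ 1.7). The level-independent control
tracer is k = 0.

**Survival.** The published account specifies no survival law, only
competition for a limited supply. The default is therefore a quota model:
exactly round(S·N) survivors sampled without replacement with weights
L^m (Gumbel top-k), giving a tunable stochastic→deterministic continuum
(m = 0 neutral, m→∞ = top-S-by-level with ties broken by lower index). A
per-cell logistic law with the threshold tuned so E[alive] = S is provided
behind `survival_law="logistic"`; neither law is claimed canonical.
S defaults to 0.5 ("survival approximates 50%"); the death-blockade fold
change is 1/S exactly by construction, and equals 2.28 at the survival
fraction implied by the printed census means (100 vs 228% of wild type).

**Enrichment.** The tracing experiment reports pre- and post-death labeled
fractions and their ratio. In the deterministic-selection limit the ratio
has the closed form (labeled mass above the survival cutoff)/(S × total
labeled mass), used as a simulation oracle. The printed in-vivo enrichment
(11.6% → 20.9%) is treated as a qualitative direction — ratio > 1 for the
level-biased tracer, = 1 for controls — not a fitted target: the three
printed numbers (11%, 75% above mean, 1.88-fold) are not jointly consistent
with a unique parameterization of this model family, and the extreme-
selection bound caps the achievable ratio near 1.55 under the calibrated
labeling.

**siRNA knockdown.** A level-independent 7% of cells is labeled and their
receptor level multiplied by 0.2; both arms share the population, labels
and survival random stream, so pre-death labeled counts are identical by
construction and the loss readout is paired. The selection strength m is
calibrated by bisection on simulated expectation (monotone in m) so that
the labeled loss relative to the control arm reaches 80%; the calibrated
m ≈ 1.3 then serves all selective-survival defaults.

**Upstream induction.** RA→RUNX3 is a Hill curve with no basal expression
(cultures without RA show none); RALDH-deficient mode zeroes induction in
29% of cells. NT3 dose–response is a Hill function of an effective dose
conc·(L/L_ref)^s anchored so a reference-level cell is at half-maximal
survival at 1 ng/ml (the measured EC50), and low-level cells at a
saturating 50 ng/ml survive above baseline but below reference cells.

Randomness uses independent named streams (population, labeling, survival)
spawned from one seed, so every experiment is bit-reproducible and arms of
paired designs can share streams.

## Single-cell pipeline

The rule set is implemented directly on sparse gene×cell counts:

- QC: cells kept iff gate-gene (Pou4f1) count > 5 AND ≥ 4000 detected
  genes; genes expressed in < 3 retained cells dropped, after the cell
  filter.
- Normalization: y = ln(1 + x/Z·10⁴). The published formula is a plain log,
  undefined at zero; the log1p convention of the toolchain it names is
  adopted deliberately.
- Variable genes: dispersion = variance/mean of expm1(y); log-dispersions
  z-scored within 20 equal-frequency mean bins; keep mean ≥ 0.0125 and
  z ≥ 0.5. Whether the published 0.5 cutoff is raw or z-scored is unstated;
  z-scored is the default and the raw mode sits behind a flag, and the
  accession benchmark reports both.
- Covariate regression: per-gene OLS on percent-mito, residuals centered
  and unit-scaled; rows whose residual is numerically zero (constant genes
  or genes exactly linear in the covariate) are set to zero rather than
  amplifying float noise (relative floor 10⁻¹⁰ of the data scale).
- PCA: SVD of the centered cell×gene matrix, sign fixed so the largest-
  magnitude loading is positive; degenerate rank truncates with a warning.
- JackStraw: per replicate, 1% of genes are permuted across cells and their
  loading magnitudes pooled as the null (100 replicates). A PC is called
  significant when the share of genes with empirical p < 0.05 exceeds 0.05
  by a calibrated margin: the proportion's variance includes both the
  binomial term 1/n_genes and the shared-null quantile-estimation term
  1/n_null, and the z is Bonferroni-thresholded across tested PCs at
  familywise 0.01. A plain binomial proportion test is miscalibrated here
  (the small shared null overdisperses the count), and a two-sample rank
  test lacks power when a component is carried by a few percent of genes;
  the calibrated proportion keeps both error control on pure noise and
  power for sparse components. Like the original implementation, it remains
  liberal on real (compositionally correlated) data.
- Clustering: union-symmetrized Euclidean kNN graph (k = 20, first 6 PCs),
  Louvain modularity with a seeded RNG, labels renumbered by size. The
  resolution default is 0.5: at resolution 1.0, modularity on an unweighted
  kNN graph overpartitions dense homogeneous blobs (two far-separated
  Gaussian blobs come back as four communities), while 0.5 recovers both
  the blob base case and the planted two-cluster matrix exactly.
- Markers: candidates must be detected in > 25% of the target cluster with
  mean normalized-expression difference > 0.1; the test is the bimodal
  likelihood-ratio (point mass at zero + normal on positive log values;
  χ², df 3 — the detection rate and the two positive-component moments),
  with Wilcoxon rank-sum as the alternative; BH-adjusted p, sorted
  ascending.
- Velocity-style prefilters: cells ≥ 150,000 reads and not hemoglobin-
  dominated (> 10% hemoglobin share marks a red blood cell; the published
  account says "extremely high" without a number); genes ≥ 38 total and
  ≥ 18 in at least one cell. Feature ranking fits log CV² vs log mean by
  least squares and ranks positive residuals; the original tool's exact
  noise-model form is unpublished, so the log-log linear fit is a declared
  stand-in with the same intent. The velocity vector-field estimation
  itself is out of scope.
- Enrichment: one-sided hypergeometric tail per term over a declared
  universe, BH FDR, keep p < 0.001 and Q < 0.05, connect kept terms with
  Jaccard ≥ 0.25 edges. Annotations are accepted as plain term→gene tables;
  OBO parsing is out of scope.

## Synthetic count matrices

Default matrices plant 350 cells: two sensory clusters (120 + 110,
Pou4f1-high, ~20 marker genes each at 8-fold enrichment plus graded
Runx3/Ntrk3 at 3-fold), 50 Pou4f1-negative contaminants, 40 low-complexity
wells (5,000-read libraries, < 4000 detected genes), and 30 red blood cells
(~83% hemoglobin share), over 6,000 genes with ~300,000-read libraries and
a per-cell mitochondrial fraction drawn from [0.01, 0.10]. The generator
reproduces the statistical *gates* the pipeline tests (complexity,
contamination, hemoglobin dominance, planted markers), not realistic
transcriptome covariance, dropout kinetics or batch structure — passing
tests demonstrate rule correctness and planted-structure recovery, not
performance on real plates.

## Problem sizes and tolerances

Test and acceptance runs use sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 20 scenes of 36 cells plus one 200-cell
scene for spot calling (pooled recall/precision ≥ 0.95, FL share ± 0.03),
10⁴–10⁵ neurons and 10–50 seeds for simulator statistics (labeling ± 2 pp,
control enrichment ± 0.05, closed form within 3 MC SE), and 350-cell
matrices for the single-cell stage (ARI ≥ 0.9). Statistical assertions are
framed in standard errors wherever a closed form exists; fixed seeds make
every run reproducible.

## Known limitations

- 2-D detection cannot separate molecules closer than ~2σ in projection;
  crowded-tissue counting is approximate by design.
- The quota survival law enforces an exact survivor count; real death
  counts fluctuate around S·N.
- The labeling power law is one of many monotone dose models consistent
  with the observations; only its calibrated statistics are identified.
- The bimodal marker test treats positive expression as log-normal; heavy
  tails inflate its LR slightly relative to the Wilcoxon alternative.
- Synthetic count matrices have independent genes given cluster identity;
  co-expression modules beyond the planted markers are absent.
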