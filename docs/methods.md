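# Methods

This note documents the models, the synthetic data they are validated
on, the numerical choices, and the limits of what the tests show.

## The synthetic study

The generator (`concreta.simulate`) emulates a two-year concrete
weathering experiment. Its defaults are the study design itself: 15
time points × 2 series × 3 replicates of concrete (90 samples),
triplicate extractions of four precursor materials (12), and triplicate
negative controls (3) — 105 samples. Water contributes to the community
mixture but is not sampled, matching a design in which tap-water
amplicon data were unavailable; its contribution is recovered as part
of the Unknown source.

**Community model.** Each precursor source (plus an "unknown"
environmental pool) has a Dirichlet base profile over a partially
disjoint subset of the 120 true taxa (each source holds an exclusive
block plus a shared block). A concrete sample of series *s* at month
*t* mixes the source profiles with series-specific weights (defaults
chosen to echo a gravel-dominated attribution: gravel 0.32/0.25, cement
0.14/0.18, fly ash 0.07/0.12, sand 0.02, water 0.06, unknown
0.39/0.37). Richness declines by a nested-extinction rule: each taxon
has a uniform "robustness" score and survives while the target alive
fraction — 1 − 0.03·months + 0.15·z(temperature) — exceeds it, so
warm months transiently resurrect taxa, mirroring summertime diversity
increases. Temperature is an annual sinusoid (13 ± 11 °C peaking near
day-of-year 200) with observation noise.

**Counts.** Compositions are realized hierarchically: the true
community, the reagent profile, and the lab profile are each drawn
Dirichlet(c·profile) with concentration c = 500, then blended, then one
multinomial draw at a log-normal library size (median ≈ 49k reads).
Applying the overdispersion per component rather than to the blended
library matters: scaling the true community's concentration by the
retained fraction (~0.15 at the default contaminant load) would make
every sample's true profile so noisy that source attribution collapses
into the Unknown source.

**Contaminants.** Reagent contaminants (25) appear in every
negative-control library (guaranteed by construction; library-size
bookkeeping keeps column sums exact) and occupy, together with lab
contaminants, a logit-normal per-sample load centred on 0.85 —
mirroring a study in which only ~15% of reads survived decontamination.
The load's spread (logit sd 1.0) is what makes contaminants mutually
positively correlated on the simplex. Five reagent contaminants are
negatives-only (never seeded into real samples). Lab contaminants (15)
share a log-normal batch factor (sd 0.8), the planted analogue of
day-to-day lab contamination intensity; five of them are copied from
the emitted laboratory-strain reference FASTA with ≤3 substitutions
(>99% identity over 420 nt). Ten edit variants sit exactly one
substitution from a random contaminant parent and ride inside the
parent's profile at 3% of its weight, emulating residual sequencing
error. Indicator taxa (8) follow a logistic presence model in the
reactive series (logit = −1.5 + 0.35·months) against a flat 0.15
baseline in the mitigated series; the baseline is deliberately
non-degenerate so the planted interaction is estimable by maximum
likelihood at n = 90.

**What the generator does not emulate:** raw reads, chimeras, primer or
GC bias, taxonomic structure (sequences are i.i.d. random DNA except
the planted relations), phylogenetic signal in abundances (the tree has
random topology), and batch structure beyond the single lab factor.
Passing tests therefore demonstrate correct and well-calibrated
machinery on data with the assumed statistical structure, not
performance guarantees on real amplicon data.

## Co-occurrence inference

SparCC follows the variation-matrix formulation: fractions are
estimated by averaging `iterations` (default 50) Dirichlet(counts + 1)
posterior draws (`iterations=0` selects the plug-in estimate, used when
exactness matters, e.g. oracle tests); t_ij = var log(f_i/f_j) comes
from one log-covariance computation; basis variances solve the
sparse-approximation linear system, and up to `exclusion_rounds`
(default 10, the algorithm's conventional setting) most-correlated
pairs above `exclusion_threshold` = 0.1 are removed from the system and
the solve repeated. A singular post-exclusion system falls back, with a
warning, to the no-exclusion solve. With strongly correlated blocks the
default ten rounds are insufficient — benchmarks that plant ~90
correlated pairs raise `exclusion_rounds` to let the exclusion converge,
after which a planted basis correlation of 0.8 is recovered to within
about 0.02.

Permutation p-values shuffle each taxon's counts across samples
independently and recompute the correlation matrix with the
posterior-mean (pseudocount) fraction estimate and no pair exclusion;
p = (1 + exceedances)/(1 + permutations), two-sided. Null datasets skip
the Dirichlet resampling and exclusions for tractability — under the
null both choices only remove noise, and the measured false-positive
rate of the significance mask (|ρ| > 0.35 and p < 0.05) on fully
shuffled data is below 1%.

Taxa with zero counts across the analysed samples are marked undefined
in both metrics (score 0, never significant): their pseudocount-implied
fractions are a deterministic function of library size and would
correlate perfectly with each other.

The classifier's networks are computed on real samples only. The three
negative controls otherwise inject a dominant shared presence pattern —
every taxon absent from negatives (i.e. all genuine taxa and all lab
contaminants) co-varies through those three extreme log-ratio values,
which flags abundant genuine taxa as lab-correlated. Negative-control
*presence* still feeds the core-cluster rule, as intended.

## Contaminant classifier

Stage order and first-stage-wins category assignment: prevalence →
reagent (core cluster, negatives-only, expansion) → laboratory
(identity seeds, expansion) → secondary screen → edit-distance
propagation. All rule inequalities are strict. The prevalence score is
a one-sided 2×2 test (Fisher's exact when any expected cell < 5,
otherwise chi-square without continuity correction) with the permissive
decision threshold p ≤ 0.33 — the method is a screen, not a test at
conventional levels. Edit propagation is single-pass (neighbours of the
pre-propagation set); a transitive mode exists behind a flag. Ties in
the parent match resolve by smallest distance, then lexicographic id.
`flagged_by` accumulates across stages so method-overlap (Euler-plot
style) accounting can be reconstructed from the calls alone.

On the default synthetic study the classifier reaches recall 0.96–1.0
on planted contaminants with a false-flag rate of 0.03–0.10 across
seeds. The residual false flags are rare, mostly-extinct genuine taxa
whose pseudocount-driven log-fractions track library size — an
intrinsic hazard of compositional correlation on sparse counts that the
aggressive screening philosophy accepts.

## Community metrics

Shannon uses base 2 by default (natural log by argument). Faith's PD
and the UniFrac family require a rooted tree whose leaves cover the
observed taxa. Generalized UniFrac is computed from per-branch
descending proportions; α = 1 reproduces weighted-normalized UniFrac to
machine precision (cross-checked against scikit-bio's implementation,
which also backs Bray-Curtis, Jaccard, unweighted/weighted UniFrac and
the Mantel test here). Rarefaction subsamples without replacement
(multivariate hypergeometric) and drops under-depth samples with a
report.

PCoA is the eigendecomposition of the Gower-centred matrix −½ J d² J;
negative eigenvalues are reported uncorrected and their axes carry zero
coordinates. PERMANOVA uses the McArdle–Anderson trace partition with
hat matrices from QR decompositions; terms enter in order (sequential)
or each-last (marginal); p-values permute raw sample rows (999 by
default), Laplace-corrected. The dispersion check follows the
betadisper construction: centroid distances in the full PCoA space with
negative-eigenvalue axes contributing negatively to squared distances,
an ANOVA F on the distances, and a permutation p. In the pipeline the
dispersion check runs on the categorical series term; continuous terms
would require an arbitrary binning, which is left to the user.

## Temporal inference

IndVal.g uses group-mean-equalized specificity
A_C = Σ_{g∈C} ā_g / Σ_g ā_g and presence-based sensitivity B; the
statistic is √(A·B), the permutation p is the exceedance of the best
combination per taxon (the all-groups combination is excluded), and
Benjamini–Hochberg-adjusted p-values are reported alongside raw ones.
Taxa must show more than 5 observations in more than 5 samples.

The interval detector replaces smoothing-spline ANOVA machinery with a
fully specified construction: per-group cubic least-squares B-splines
(df = 4, knots from the pooled time design) of relative abundance over
months; maximal constant-sign runs of the fitted difference at the
observed time points are candidate intervals scored by summed
|difference|; the null permutes group labels within time points and
records the maximal interval area, giving familywise-calibrated
Laplace-corrected p-values. `reaches_end` marks intervals that include
the final time point — the signature of indicators whose differential
abundance persists.

The seasonal model approximates a cyclic cubic spline with two harmonic
sin/cos pairs of day-of-year (equal effective degrees of freedom for a
k = 4 cyclic smooth, closed-form and dependency-free) plus a linear
months term, fitted by OLS to Hellinger-transformed abundance. The
seasonal block is tested jointly by F-test; the peak day-of-year is the
grid argmax of the fitted seasonal component.

## Source tracking

The collapsed Gibbs sampler is the classical mixture-of-known-sources
model: fixed multinomial taxon distributions for known sources
(smoothing α₁ = 0.01), a self-estimated distribution for the Unknown
(α₂ = 1), and a symmetric Dirichlet(τ = 1) prior on mixing proportions.
Sources are pooled by summation per material and rarefied to 8,000
reads; sinks are rarefied to 635 (both configurable; the defaults are
the depths the emulated study used). Chains run 10 restarts × (100
burn-in + 25 draws at thinning 10); estimates are means over all
retained draws, with posterior standard deviations reported. The inner
loop is numba-compiled with an identical pure-Python fallback. Burn-in,
thinning, restarts and τ follow the original source-tracking
publication's conventions; only α₁, α₂ and the depths are pinned by the
emulated configuration.

On disjoint synthetic sources the sampler recovers (0.5, 0.3, 0.2)
mixtures to within ~0.015 mean absolute error at sink depth 635–1000;
sinks of alien taxa attribute ≥ 0.9 to Unknown; leave-one-out on
disjoint sources leaves off-diagonal known attribution at ~0. On the
full synthetic study the Unknown share is large by construction (the
environmental pool plus unsampled water plus extinction drift).

## Reproducibility

Every stochastic routine takes a seed; the pipeline expands one global
seed into per-stage seeds via `numpy.random.SeedSequence`, and a re-run
with the same config is byte-identical. Permutation p-values are always
Laplace-corrected, so the smallest attainable p is 1/(permutations+1).
Problem sizes in the test-suite benchmarks (e.g. 200 samples × 50 taxa
for the correlation benchmark, 200 replicates for permutation-test
calibration, 5 seeds for mixture recovery) were chosen as the smallest
designs at which the planted effects are comfortably identifiable.
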