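# concreta

Analysis toolkit for **longitudinal, low-biomass 16S amplicon studies**,
built around the workflow used to characterize bacterial communities in
weathering concrete: two series of cylinders (one prone to the
alkali-silica reaction, one mitigated with fly ash) sampled over ~2
years alongside their precursor materials (gravel, sand, cement powder,
fly ash) and negative-control extractions.

Low-biomass specimens yield nanogram-scale DNA, so reagent and
laboratory contaminant sequences can rival or exceed the genuine
signal, and amplicon counts are compositional — only relative
information survives sequencing. The package therefore combines:

* **Compositional co-occurrence inference.**
  SparCC estimates correlations of latent (basis) abundances from
  log-ratio variances t_ij = var log(f_i/f_j) under a sparsity
  assumption, solving Σ_j t_ij ≈ (D−1)ω_i + Σ_{j≠i} ω_j for basis
  variances ω and forming ρ_ij = (ω_i + ω_j − t_ij) / 2√(ω_i ω_j), with
  iterative exclusion of strongly correlated pairs and permutation
  p-values. Proportionality rho is ρ_ij = 1 − var(a_i − a_j)/(var a_i +
  var a_j) on centred-log-ratio transformed counts.
* **A multi-stage contaminant classifier.** A permissive one-sided 2×2
  prevalence test against negative controls; a core cluster of mutually
  positively correlated ASVs observed in negatives, expanded through
  co-occurrence rules; BLAST-style >99% identity to known laboratory
  strains, expanded likewise; a secondary screen against the master
  contaminant list; and propagation to single-substitution (Levenshtein
  distance 1) sequence variants.
* **Community metrics.** Shannon diversity, Faith's phylogenetic
  diversity, rarefaction, Bray-Curtis/Jaccard and the UniFrac family
  including generalized UniFrac
  d = Σ b_i (p_iA+p_iB)^α |p_iA−p_iB|/(p_iA+p_iB) / Σ b_i (p_iA+p_iB)^α,
  PCoA, multi-term sequential/marginal PERMANOVA with a betadisper-style
  dispersion check, Mantel tests, replicate-similarity Welch tests, and
  occurrence-frequency entropies.
* **Bioindicator detection.** Group-size-corrected indicator values
  IndVal.g = √(A·B) with permutation significance, presence/absence
  logistic regression (presence ~ series × scale(months)), B-spline
  interval tests for time windows of differential abundance, and a
  harmonic seasonal + linear trend decomposition of Hellinger-transformed
  abundances.
* **Bayesian source tracking.** A collapsed Gibbs sampler estimating
  what fraction of each concrete ("sink") community derives from each
  precursor ("source") community plus an Unknown source:
  P(z_i = v) ∝ φ_v(t_i)·(n_v^{−i} + τ), with known-source φ fixed from
  rarefied source profiles (pseudo-count α₁ = 0.01) and the Unknown's φ
  estimated from its current assignments (α₂ = 1).
* **A synthetic-study generator** that emulates the full design — 105
  samples (15 time points × 2 series × 3 replicates, triplicate
  precursors, triplicate negative controls), planted reagent/lab
  contaminants and edit variants, declining diversity with seasonal
  modulation, and known source mixtures — so every stage is testable
  against ground truth without any sequencing data.

## Worked example

Run the whole pipeline on a synthetic study:

```bash
concreta run-all --seed 1 --outdir demo
```

From `demo/report.json` (seed 1):

* Decontamination flags 56 of 170 ASVs: 20 core reagent + 22 expanded,
  8 by prevalence, 2 lab seeds + 3 expanded, 1 edit-distance neighbour —
  recall 0.98 on the 50 planted contaminants with a false-flag rate of
  0.058 on the 120 genuine taxa (`truth.json` carries the labels).
* PERMANOVA on generalized (α = 0.5) UniFrac distances of the
  rarefied, decontaminated concrete samples (sequential:
  `distance ~ temperature + months + series`): temperature R² = 0.197,
  F = 31.6, p = 0.001; months R² = 0.251, F = 40.2, p = 0.001; series
  R² = 0.020, p = 0.027, with no dispersion difference between series
  (p = 0.92). Time and temperature dominate; the series effect is an
  order of magnitude smaller — the planted structure.
* Replicate extractions are more similar than unrelated samples
  (mean within-replicate similarity 0.834 vs 0.675 between; one-sided
  Welch p ≈ 1e-91).
* Source tracking of the first and last sinks attributes 10.8% to
  gravel, 5.3% to cement, 4.7% to fly ash, 0.5% to sand and 79% to the
  Unknown source (which absorbs the planted environmental community and
  the unsampled water).

Artifacts (`contaminant_calls.tsv`, `network_*.tsv`,
`alpha_diversity.tsv`, `distance_matrix.tsv`, `pcoa.tsv`, `indval.tsv`,
`intervals.tsv`, `source_proportions.tsv`) are plain TSV; a re-run with
the same seed and config reproduces them byte-for-byte.

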