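# Methods

This note documents the models, conventions and numerical choices behind
`herbdissect`, and what the synthetic benchmark does and does not establish.

## 1. The synthetic experiment

The generator (`synthetic_data`) emulates a five-treatment early-herbivory
design: control, W_W (wounding), W_ABOS (wounding + antibiotic-treated oral
secretion), W_OS (wounding + intact oral secretion), and actual herbivory,
with 4 replicates per treatment by default (the emulated design reports 3–5;
4 is the midpoint).

**Counts.**  Gene g in sample s is drawn NB with mean
μ_gs = f_s · b_g · 2^(δ_t(g)) and variance μ + φμ², where

- b_g ~ LogNormal(5.0, 1.5) (natural-log scale) — a typical bulk RNA-seq
  abundance spread with median ≈ 150 counts;
- φ_g = a₀ + a₁/b_g with a₀ = 0.05, a₁ = 5.0 — a DESeq2-like dispersion
  trend (φ ≈ 0.05 for abundant genes, inflated at low counts);
- f_s ~ LogNormal with mean 1 and CV 0.2 — library-size variation;
- δ_t(g) is the cumulative planted shift for treatment t.

**Cumulative inheritance.**  A gene's planted truth is a pattern code
(d₁, d₂, d₃), dᵢ ∈ {−1, 0, +1}, with per-digit log₂ magnitudes drawn from
[2, 4] (well above the 1.5 call threshold, so the truth is recoverable in
principle).  Treatments inherit effects along the component chain:
δ_control = 0, δ_WW = c₁, δ_WABOS = c₁+c₂, δ_WOS = c₁+c₂+c₃.  The
actual-herbivory group mirrors the full W_OS effect scaled by an
attenuation factor (default 0.74, configurable), encoding the observation
that the real stimulus evokes the same responses at a slightly lower level.

**Default planted design.**  The seven module archetypes — (+1,0,0),
(0,±1,0), (0,0,±1), (0,+1,−1), (0,−1,+1) — at 400 genes each (2,800 of
5,000 genes responsive).

**Annotation.**  200 flat terms of 10–50 genes; 30% of terms are planted as
module-enriched (round-robin over planted modules, 80% of members from the
module's gene set, the rest background); the remainder sample genes
uniformly.  Terms are flat gene sets: no GO DAG, no term hierarchy.

**What a green test establishes.**  That the pipeline recovers planted
trichotomous structure from NB counts with realistic dispersion and
library-size noise.  It does not establish robustness to features of real
data the generator omits: outlier samples, batch effects, correlated genes,
isoform-level length effects, GO-DAG redundancy, or deviations from the NB
model.

## 2. Differential expression

The DE engine is intentionally internal rather than a DESeq2 wrapper, so
the package is self-contained; it is behaviourally comparable (calibration
and power tests define correctness), not numerically identical.

- **Size factors:** median of ratios to the per-gene geometric mean over
  all-positive genes; falls back to total-count ratios if none exist.
- **Dispersions:** pooled within-group method-of-moments estimate
  φ̂ = max(0, (s² − x̄)/x̄²) on normalized counts, least-squares fit of the
  trend φ(μ) = a₀ + a₁/μ over positive estimates, then linear shrinkage
  φ = (1−w)φ̂ + w·trend with w = 0.5 and floor 1e−8.
- **Test:** per-group NB log-link MLE via vectorized Newton iterations on
  β = log q with expected information Σ μ/(1+φμ); Wald
  z = (β_test − β_ref)/SE, SE² = 1/I_ref + 1/I_test; two-sided normal p.
  Non-converged genes get p = 1, call 0 and a `converged=False` flag.
- **Multiplicity:** step-up Benjamini–Hochberg over tested genes.
- **Calls:** +1/−1 when |log₂FC| > 1.5 (log₂ scale, i.e. fold change
  > 2^1.5) and adjusted p < 0.05.
- **Count filter:** mean read count < 10 removes a gene.  The standalone
  `nb_wald_test` applies it to the two contrasted groups' samples; the
  pipeline applies it once over all samples before the three contrasts —
  a per-contrast filter would censor strongly suppressed genes (their
  counts fall below 10 in the two suppressed groups of a later contrast)
  from the pattern universe.

No independent filtering, Cook's-distance outlier handling, or shrunken
fold-change estimators; single-factor two-group designs only.

## 3. QC: PCA, outliers, RDPI

- **PCA:** genes centered and scaled to unit variance (constant genes
  dropped), SVD of the sample matrix; explained-variance fractions are
  component variances over the number of scaled genes (sum ≤ 1).
- **Outliers:** average-linkage hierarchical clustering on Euclidean
  distance over all genes is computed for the record; flagging is per
  treatment — a replicate whose mean distance to its peers exceeds 2.0× the
  treatment median of those means is flagged (reported, not auto-removed).
  The factor 2.0 is a stand-in for an unstated rule; treatments with < 3
  replicates are skipped.
- **RDPI:** for each (control replicate i, treatment replicate j) pair, the
  mean over genes with x_gi + x_gj > 0 of |x_gj − x_gi|/(x_gj + x_gi);
  computed on TPM after the TPM < 1 filter.  The trait-level index is
  generalized per-gene and averaged; whether the original analysis used
  TPM, counts or logs is not recoverable, so this convention is documented
  rather than asserted.  TPM filtering uses the mean across samples
  (per-sample available via a flag).

## 4. Patterns and modules

Pattern codes are the call triples over the three cumulative contrasts;
genes missing from any contrast form an `untested` stratum (a trichotomous
code needs all three tests).  Pattern indices: the null code is pattern 1;
the remaining 26 codes take indices 2–27 in base-3 rank order (−1 < 0 < +1);
the full table is emitted with outputs.  Modules are the non-null codes
with ≥ 300 genes (inclusive), labelled `module_1`, `module_2`, … by
descending size (ties broken by pattern index).  Actual-herbivory samples
are not part of the cumulative contrasts; they enter only the similarity
analyses.

The report includes a clearly-labelled *interpretive* mapping from module
labels to codes (wound-specific, HAC-induced/suppressed,
OSB-induced/suppressed, and the two opposite-reversal codes); it is a
reading of module descriptions, not ground truth.

## 5. Enrichment and the functional network

- **Enrichment:** upper-tail hypergeometric p = P[X ≥ k] with
  X ~ HG(N, K, n) against the universe of tested genes with ≥ 1 annotation;
  BH per module across its tested terms (the adjustment scope of the
  original run is unstated; per-module is the configurable default).
  Terms with zero overlap are not reported.
- **Top terms:** 15 per module, ascending p; ties break by larger overlap
  k, then lexical term id.
- **Network:** one node per (term, module) selection — a term picked by two
  modules appears twice, and the duplicates' J = 1 edge links them; a
  `dedupe` flag collapses duplicates to the best-p module.  Edge iff
  J > 0.2, strictly.
- **Connectivity:** Cᵢ = 2eᵢ/(kᵢ(kᵢ−1)), defined 0 when kᵢ < 2 (the formula
  is 0/0 there); module C = mean Cᵢ.  "Extramodular connectivity" is read
  as the summed cross-module degree (contrasting with the intramodular
  statistic); the unrestricted total degree is also reported.
- **TOM:** the unsigned Ravasz-style formula on the unweighted J-thresholded
  adjacency, TOM_ij = (l + a)/(min(k) + 1 − a), diagonal 1, 0 where the
  denominator degenerates.  Other TOM variants exist; this one is stated so
  results are reproducible.
- **Module clustering:** module–module dissimilarity = mean (1 − TOM) over
  cross-module node pairs, average linkage, tree cut at 4 clusters.

## 6. Similarity analyses

Signed DEG vectors take a term's full gene list (sorted; untested genes get
0 — zeros change neither the dot product nor the norm).  Cosine similarity
is the standard dot-product form; a zero-norm vector makes the similarity
*undefined* (NA), a distinct state from 0, since "no DEG at all" is not
"orthogonal response".  The global comparison is unweighted OLS of one
contrast's per-gene log₂FC on the other's over shared filtered genes
(slope/intercept/R²/slope-p); a constant regressor raises an error.

## 7. Determinism and budgets

All randomness flows from one integer seed through
`numpy.random.default_rng`; the annotation generator continues the same
stream (or derives seed+1 when called standalone).  Identical configs give
byte-identical outputs.  The full 5,000-gene pipeline runs in ~1 s on one
CPU; the test suite in well under a minute.
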