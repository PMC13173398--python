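# Methods

## Scope and model

`ecmopt` models bulk gene expression of organoids grown in synthetic
matrices as a quadratic response surface over three peptide molarities and
searches that surface ensemble for compositions enriching a target gene
program. The pipeline stages and their assumptions are documented here; the
package's own tests and `scripts/acceptance.py` compute every number this
note refers to.

## Experimental design

The design is a face-centered central composite design (CCD): 2³ factorial
corners, 6 axial points with axial distance α = 1 (on the box faces), and a
configurable number of replicated center points (default 9, total 23 runs).
α = 1 is forced by the constraint that each factor take exactly three
levels: low, center = arithmetic midpoint, high. Default factor ranges are
C ∈ [0.75, 1.5] mM and F, L ∈ [0.15, 0.375] mM with peptide B constant at
0.2625 mM; the corresponding center levels are 1.125 and 0.2625 mM. Run ids
are assigned before randomization so the canonical design remains
recoverable. Confirmation compositions are drawn uniformly and
independently per factor inside the box (redrawn in the measure-zero event
of hitting a lattice point) and are never used in fitting.

## Normalization

* **Filter**: keep genes whose raw count strictly exceeds 10 in at least 6
  samples. The source description of this filter is grammatically ambiguous
  ("sum of raw counts more than 10 in at least six samples"); the
  per-sample reading is the default and a `total_sum` mode implements the
  alternative.
* **Depth transform**: median-of-ratios size factors (computed on the
  unfiltered matrix, over genes positive in all samples), then
  `log2(count/size_factor + 1)`. This is a deliberate, documented surrogate
  for a dispersion-trend-based variance-stabilizing transform: it preserves
  the depth normalization and approximate log-scale the downstream
  quadratic models need, and an externally produced transformed matrix can
  be substituted at the same stage.
* **Reference normalization**: the gene minimizing CV = sd(n−1)/mean across
  all samples (all donors pooled) divides every gene within each sample;
  ties break lexicographically and a configured reference can be pinned.
* **Averaging**: arithmetic mean over technical replicates per experimental
  condition, per donor.

Stages are tagged on the matrix (`raw → depth_transformed →
reference_normalized → condition_averaged`) and can only advance.

## Response-surface fitting

Factors are coded to [−1, 1] internally (standard RSM practice; raw-unit
coefficients are recovered exactly by expanding the affine substitution,
since the 10-term quadratic basis is closed under affine maps). Weighted
least squares uses weights 1/(number of design runs sharing the exact
composition), so the 9 center replicates enter the normal equations exactly
as their average would once — verified algebraically in the tests. The 23-run
design matrix has full column rank 10, so noiseless quadratic data are
interpolated exactly (machine precision).

Backward stepwise deletion uses
`AIC = n ln(2π·RSS_w/n) + n − Σ ln w_i + 2(p+1)` — the convention of R's
`AIC()` on a weighted `lm`, whose model-to-model differences equal those of
`stepAIC`. At each step the deletion most decreasing AIC is taken; ties
(within 1e−12) delete the term latest in the fixed basis order
(1, C, F, L, CF, CL, FL, C², F², L²). Three hierarchy modes exist:

* `marginality` (default): a main effect is not deletable while an
  interaction containing it remains — the behavior of R's backward
  `stepAIC` on a formula model, adopted because that is the procedure this
  workflow standardizes; the unit tests verify exact term-set agreement
  with `MASS::stepAIC` on shared data.
* `none`: any non-intercept term is deletable.
* `strong`: a pure quadratic additionally protects its main effect.

A caution established during validation: with n = 23 observations, backward
AIC is permissive — on pure-noise responses it almost never reduces to the
intercept-only model (1–2% of fits, identical under `MASS::stepAIC`),
because the effective per-term retention threshold at small n is well below
the asymptotic χ² > 2 rule. Model reliability should therefore come from
adjusted R², not from term membership.

Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p) with weighted sums of squares and
p counting all coefficients including the intercept; a zero-variance
response scores 1 when fitted exactly, else 0. Confirmation validation
predicts held-out compositions without refitting and reports pooled R² and
RMSE.

## Multiobjective optimization

Decision variables are the raw peptide molarities, box-constrained to the
design region. Each target gene contributes one objective: its predicted
expression, negated for genes to be upregulated, so all objectives are
minimized. The optimizer is canonical generational NSGA-II: fast
non-dominated sorting, crowding distance, binary tournament on (rank,
crowding), elitist (μ+λ) truncation; simulated binary crossover
(probability 0.9, η = 15, per-variable rate 0.5) and bounded polynomial
mutation (probability 0.5 per variable, η = 20). Population size defaults
to max(100, 20 × objectives) rounded up to a multiple of 4; the stopping
rule is a fixed generation budget (default 200) for reproducibility. One
root seed spawns independent streams for initialization, tournament,
crossover and mutation, so changing one operator's internals cannot
silently shift another's draws; results are bit-identical per seed.

The returned set is the non-dominated subset of the final population with
exact duplicates removed. The ideal point is the column-wise minimum and
the nadir the column-wise maximum over that set (not a payoff table —
stated because nadir estimation changes ASF selection); degenerate
objectives are widened by ε = 1e−6 with a warning.

**ASF selection.** Objective deviations are normalized to
`(f − ideal)/(nadir − ideal)`; weights (per-gene adjusted R², clipped to
[0.05, 1], normalized to sum 1) multiply the normalized deviation — a more
reliable model constrains the choice more. The augmented form adds
ρ Σ deviations with ρ = 1e−6 to break weak-Pareto ties deterministically.
The division convention used by some libraries is available via
`asf_convention="divide"`.

**Control selection.** Candidates (final front plus Latin-hypercube samples
of the box) are kept when their ASF value exceeds the front's best by at
most `front_gap_max` (default 0.12, measured on the normalized objective
scale); among those whose normalized Chebyshev distance to the ASF solution
lies in `cheb_range` (default 0.2–0.6) the most distant is returned and
re-verified against both constraints.

**Convergence characteristics.** On a two-objective ZDT1-style benchmark
(10 decision variables on the unit box — a size at which the stated budget
of population 100 × 100 generations converges; the classic 30-variable
version needs ~250 generations) the front reaches IGD ≈ 0.01–0.03 against
the analytic front. On many-objective gene specs (≥ 5 objectives) the
non-dominated subset of a finite final population is known to retain a few
dominance-resistant stragglers: measured against a 51³ exhaustive grid of
the box, a small fraction of returned points (∼1–5%) can be dominated by a
grid composition with per-objective margins on the order of 1e−4 (objective
spans ∼0.4–0.6), and this plateau does not shrink with more generations or
an archive over all evaluated points. The ASF-selected solution itself is
unaffected — its scalarized value matches or beats the grid minimum — but
downstream consumers of the *full* front should treat boundary members as
approximately optimal.

## Synthetic data generator

The generator emulates what the analysis assumes, at desk scale:

* **Surfaces**: each gene's log2 expected expression is an exact quadratic
  in the coded factors. EMT-up genes share a common concave program surface
  (random interior optimum in the coded sub-box [−0.6, 0.6]³, per-factor
  curvature 0.5–1.5, mild interactions), scaled per gene by an amplitude in
  [0.6, 1.4] (≈ one twofold change across the box) plus small idiosyncratic
  terms (sd 0.05); EMT-down genes get the negated surface. This coordinated
  structure is what makes "the program's optimal composition" well defined;
  the planted optimum is recorded as the argmax of the mean up-minus-down
  surface on a 51³ coded grid. Subtype markers respond independently
  (coefficient sd 0.25); housekeeping genes are flat; remaining genes are
  intercept-only nulls.
* **Counts**: NB (gamma-Poisson) with variance μ + αμ², gene-wise
  α ∈ [0.02, 0.1] (housekeeping 0.002), matching the mean-variance form of
  count-model RNA-seq processing. Depth factors are log-uniform in
  [0.7, 1.4]. Donors shift gene intercepts (sd 0.2) and never the surface
  shape, so the program optimum is donor-invariant. Baselines are
  log2-uniform: 3–10 generally, 6–10 for program genes (keeping the +1
  pseudo-count distortion small where it matters).
* **Noiseless mode**: counts are rounded means; for exactness tests the
  pipeline's `noise=False` path instead reads the exact surfaces directly,
  because rounding and the +1 pseudo-count would otherwise break
  machine-precision recovery.
* **Spheroids**: log-normal volumes and signals; nuclei Poisson with rate
  proportional to volume.

What passing tests on this generator do **not** show about real data:
no batch structure beyond depth, no dispersion-mean trend, no correlated
gene-gene noise, no donor × composition interactions, and real gene
programs are not exact scaled copies of one surface. Effect-size
distributions are config-exposed choices, not estimates from the study's
(unavailable) data.

## Permutation test for gene–PC association

Zero-variance genes are dropped, PCA is computed on samples, and each
gene's Pearson (optionally Spearman) correlation with the PC scores is
tested by permuting the gene's sample order; empirical
p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1), BH-adjusted per PC,
significant below 0.25. Two schemes are provided:

* `loo` (default): each gene is tested against PCs computed with that gene
  left out. The gene then never shapes its own reference scores, the
  permutation is exact under exchangeability, and null p-values are
  uniform (verified over 100 seeded null matrices: the fraction of runs
  with any BH-0.25 discovery stays at or below the nominal level).
* `fixed`: all genes are tested against the full-matrix PCs — the cheaper,
  literal construction. On matrices whose leading PCs are noise-driven it
  is strongly anti-conservative (every gene contributes to the PCs it is
  tested against); it remains available because on signal-dominated PCs
  the bias is modest and it matches the simplest reading of the original
  procedure.

## Other scores

SFI = N_spheroids / (median volume × total nuclei); vinculin density =
signal/volume per spheroid; Moffitt-style score = mean(basal) −
mean(classical) per sample on depth-transformed values, positive labelled
basal-like and an exact zero labelled classical (configurable — the
convention is defined only for strict signs). Δ scores subtract the donor's
baseline (e.g. Matrigel) score. The DE filter BH-adjusts supplied raw
p-values and keeps |log2FC| > 0.58 AND adjusted p < 0.05, both strict; a
Welch t-test on transformed values is provided as a simple effect/p source
for synthetic end-to-end runs (count-model Wald testing is out of scope).

## Problem sizes and reproducibility

Simulation-based checks run at desk scale chosen as the package's standard
test conditions: 300–500 genes, 23-run CCD + 5 confirmation runs, 3
replicates, 1–3 donors; optimizer budgets of population 100–400 over
60–300 generations; 25–100 seeds for recovery and calibration rates. Under
these conditions the end-to-end pipeline recovers the planted optimal
composition within 10% of the factor range in ≈ 85–90% of seeds, and the
planted housekeeping gene wins the CV selection in ≈ 100 of 100 seeds. All
randomness flows from explicit seeds (the pipeline fans one root seed out
to fixed per-stage seeds); reports contain no timestamps, so identical
configs reproduce byte-identical reports.

## Known limitations

* The depth transform is a log2 surrogate, not a dispersion-trend VST;
  differences matter most for low-count genes.
* Weighted AIC selection at n = 23 over-retains terms (see above); the
  pipeline treats adjusted R² as the reliability signal.
* The full Pareto front carries a small fraction of near-optimal
  stragglers intrinsic to dominance-based EAs on ≥ 5 objectives; the
  ASF-selected composition is robust to this.
* The Moffitt-style score is a signature-mean difference, not the original
  factorization-based classifier.
* Donor handling is intercept-only in simulation; donor-specific response
  shapes (donor × composition interactions) are out of scope.
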