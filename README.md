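# ecmopt

Design-of-experiments response-surface modelling and multiobjective
optimization of synthetic extracellular-matrix (ECM) compositions for
programming organoid transcriptional states.

## The problem

Synthetic PEG hydrogels presenting adhesion peptides (here called C, F, L,
plus a constant peptide B) can steer the transcriptional state of patient
pancreatic-cancer organoids. Given bulk RNA-seq of organoids grown across a
planned grid of peptide molarities, the question is: **which composition of
the matrix enriches a chosen gene program** (for example the
epithelial–mesenchymal-transition, EMT, program)?

`ecmopt` implements the full bottom-up workflow:

1. **Design** — a face-centered central composite design (CCD) over the three
   peptide molarities, three levels per factor (low, center = midpoint,
   high), with replicated center points and out-of-design confirmation
   compositions: `n = 2³ + 2·3 + n_center` runs (23 with 9 centers).
2. **Normalization** — low-count gene filtering, median-of-ratios depth
   normalization with a log2 transform, division of every gene by the most
   stable (minimum coefficient-of-variation) gene within each sample, and
   technical-replicate averaging.
3. **Response surfaces** — per gene *g*, weighted least squares on the full
   second-order model in coded factors
   `y_g = β₀ + β_C C + β_F F + β_L L + β_CF CF + β_CL CL + β_FL FL + β_C² C² + β_F² F² + β_L² L²`,
   with weights 1/(runs sharing the composition) so the replicated center
   counts once, followed by backward stepwise deletion on AIC (the
   convention of R's `stepAIC` on a weighted `lm`). Adjusted R² on the
   training runs is the model's reliability.
4. **Optimization** — NSGA-II (SBX crossover p = 0.9, η = 15; polynomial
   mutation p = 0.5, η = 20) over the composition box, one objective per
   target gene (up-genes maximized, down-genes minimized). The final
   non-dominated set is normalized between its ideal and nadir points and a
   single composition is selected by an augmented achievement scalarizing
   function (ASF) weighted by each model's adjusted R²; a near-front
   "control" composition at 20–60% normalized Chebyshev distance from the
   selection supports falsification experiments.
5. **Scores** — spheroid formation index `SFI = N_s / (V_med · n_nuclei)`,
   vinculin density (signal per volume), Moffitt-style subtype score
   (mean basal − mean classical expression; positive = basal-like), a
   leave-one-out permutation test for gene–principal-component association
   with Benjamini–Hochberg control, and the differential-expression filter
   (|log2FC| > 0.58, BH p < 0.05).

Because no public organoid dataset accompanies the workflow, a first-class
**synthetic-data module** generates negative-binomial counts around known
quadratic composition-response surfaces with planted gene programs and a
planted optimal composition, so every stage is testable end to end.

## Worked example

`examples/06_end_to_end_pipeline.py` runs the whole workflow on a simulated
experiment (300 genes, 23-run CCD + 5 confirmation runs, 3 replicates,
default negative-binomial noise):

```
reference gene: g0037 (CV 0.00667)
adjusted R^2: median 0.512 [0.317, 0.669] over 300 genes
ASF composition: C=1.2234 F=0.2069 L=0.3135 mM
planted optimum: C=1.2000 F=0.2040 L=0.3075 mM
recovery error: 3.1% of range
confirmation validation: R^2 0.980, RMSE 0.0263
```

Reading this: the data-driven reference pick lands on a planted housekeeping
gene with a CV of a few thousandths; fitted surfaces interpolate held-out
confirmation compositions at R² ≈ 0.98 without refitting; and the
ASF-selected composition lands within ~3% of the factor range of the
composition that truly maximizes the planted EMT program. The other scripts
in `examples/` exercise each capability separately (design construction,
normalization, fitting, optimization, state scores).

A thin CLI mirrors the library:
`ecmopt design|simulate|normalize|fit|optimize|score|run --help`.

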