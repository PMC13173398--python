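"""Fit per-gene quadratic response surfaces with backward-AIC term selection.

Each gene's condition-averaged expression is regressed on the 10-term
quadratic basis in the coded peptide factors, weighted 1/9 for the
replicated center runs, then pruned by backward stepwise AIC. Adjusted R^2
on the training runs is the per-gene reliability used later as ASF weight.
"""

import numpy as np

import ecmopt as e

bounds = e.default_bounds()
design = e.randomize_runs(e.build_ccd(bounds, 9), seed=1)
conf = e.confirmation_design(bounds, 5, seed=2)
truth = e.simulate_ground_truth(300, bounds, seed=7)
experiment = e.simulate_counts(truth, e.concat_designs(design, conf), n_reps=3, seed=8)

raw = e.ExpressionMatrix(experiment.counts, "raw")
vst = e.depth_normalize_transform(raw).subset_genes(e.filter_genes(raw))
ref_gene, _ = e.select_reference_gene(vst)
averaged = e.average_replicates(
    e.reference_normalize(vst, ref_gene),
    experiment.samples.set_index("sample")["run_id"],
)

fit_expr = e.ExpressionMatrix(averaged.data[list(design.runs["run_id"])],
                              "condition_averaged")
models = e.fit_all_genes(fit_expr, design)
r2 = np.array([m.adjusted_r2 for m in models.values() if m.status == "ok"])
emt = truth.program_genes("emt_up") + truth.program_genes("emt_down")
r2_emt = np.array([models[g].adjusted_r2 for g in emt])

table, summary = e.validate_confirmation(
    models, averaged.data[list(conf.runs["run_id"])], conf
)
print(f"fitted {len(models)} genes; adjusted R^2 median {np.median(r2):.3f} "
      f"(EMT program genes: {np.median(r2_emt):.3f})")
print(f"held-out confirmation runs: R^2 = {summary['r2']:.3f}, "
      f"RMSE = {summary['rmse']:.4f} over {summary['n_pairs']} predictions")
example = models[emt[0]]
print(f"example model {example.gene}: terms {example.terms}, "
      f"adjusted R^2 {example.adjusted_r2:.3f}")
# High confirmation R^2 with no refitting shows the surfaces interpolate the
# design region; program genes fit better than unresponsive background genes.
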