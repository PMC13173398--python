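"""Simulate an organoid-like RNA-seq experiment and normalize it.

Counts follow negative-binomial noise around gene-specific quadratic
composition-response surfaces. Normalization: median-of-ratios depth
correction with a log2 transform, then division by the most stable
(minimum-CV) gene per sample, then technical-replicate averaging.
"""

import ecmopt as e

bounds = e.default_bounds()
design = e.randomize_runs(e.build_ccd(bounds, 9), seed=1)
truth = e.simulate_ground_truth(300, bounds, seed=7)
experiment = e.simulate_counts(truth, design, n_reps=3, seed=8)

raw = e.ExpressionMatrix(experiment.counts, "raw")
kept = e.filter_genes(raw)  # per-sample count > 10 in >= 6 samples
vst = e.depth_normalize_transform(raw).subset_genes(kept)
ref_gene, cv = e.select_reference_gene(vst)
normed = e.reference_normalize(vst, ref_gene)
averaged = e.average_replicates(normed, experiment.samples.set_index("sample")["run_id"])

print(f"simulated counts: {experiment.counts.shape[0]} genes x "
      f"{experiment.counts.shape[1]} samples; {len(kept)} genes pass the filter")
print(f"reference gene: {ref_gene} (CV = {cv:.6f}; planted housekeeping genes: "
      f"{truth.program_genes('housekeeping')})")
print(f"condition-averaged matrix: {averaged.data.shape[0]} genes x "
      f"{averaged.data.shape[1]} design runs")
# A CV of a few thousandths marks a gene as stable as the study's reference;
# recovering a planted housekeeping gene shows the selection works.
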