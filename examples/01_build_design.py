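"""Build the study's 23-run face-centered central composite design.

Three peptide factors (C, F, L) each take three molarity levels — low,
center (midpoint) and high — giving 8 factorial corners, 6 face-centered
axial points and 9 replicated center runs; peptide B stays constant.
"""

import ecmopt as e

bounds = e.default_bounds()
design = e.randomize_runs(e.build_ccd(bounds, n_center=9), seed=1)
confirmation = e.sample_confirmation_runs(bounds, k=5, seed=2)

print(design.runs.to_string(index=False))
print(f"\ntotal runs: {design.n_runs} (8 factorial + 6 axial + 9 center)")
print("\nconfirmation compositions (uniform draws inside the box, used only "
      "for out-of-sample validation):")
for comp in confirmation:
    print(f"  C={comp.c:.4f}  F={comp.f:.4f}  L={comp.l:.4f}  B={comp.b} mM")
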