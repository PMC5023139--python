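"""Experimental-design scan: which tracer and platform to buy time on?

Evaluates a small grid of glucose labeling strategies x measurement
platforms for two B. subtilis flux ratios, all sharing one flux cohort so
cells differ only in the experimental setup.  Each cell's number is the
held-out test MAE of a predictor trained for that setup (smaller is
better); feature selection runs per cell to level the feature counts.

Scaled down (2 tracers x 2 platforms, ~3 min); widen the grids to scan
all eight tracers and four platforms.
"""

import fluxforest as ff

model = ff.load_reference_model("bsubtilis_ccm")
ratios = [model.ratio("glycolysis_vs_ppp"), model.ratio("pyr_from_malic_enzyme")]

cohort = ff.multi_ratio_cohort(model.network, ratios, 10, 150, 1.0, seed=3)
grid = ff.scan_designs(
    model.network, cohort,
    tracers={k: ff.glucose_tracer(k) for k in ("1", "5,6")},
    platforms={p: model.spec(p) for p in ("gcms", "lcms")},
    ratio_defs=ratios, seed=4, noise_level=0.01,
)

for rd in ratios:
    print(f"\n{rd.name}: test MAE by tracer (rows) and platform (columns)")
    print(grid.pivot(rd.name).round(3).to_string())
# Reading the tables: the doubly-labeled [5,6-13C] glucose and LC-based
# platforms generally win for these ratios — the cheapest cell below your
# accuracy cut-off is the experiment to run.
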