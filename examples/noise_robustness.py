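"""How wrong noise assumptions in the surrogate data bias flux estimates.

Trains Entner-Doudoroff ratio predictors at four assumed noise levels and
tests each against data at every noise level (same flux maps, same
train/test split throughout, exchange bound fixed at 1).  The matrix shows
the textbook pattern: under-estimating noise during training degrades
accuracy on noisier data, over-estimating it is benign.  ~2 min.
"""

import fluxforest as ff

model = ff.load_reference_model("ecoli_ccm")
res = ff.sensitivity_grid(
    model.network, [model.ratio("pyr_from_ed")],
    seed=11, tracer=ff.glucose_tracer("1"), spec=model.spec("gcms"),
    cohort_per_bin=200, components=("noise_mismatch",),
)
piv = res["pyr_from_ed"]["noise_mismatch"].pivot(
    index="train_noise", columns="test_noise", values="mae"
)
print("test MAE; rows = training noise, columns = test-data noise")
print(piv.round(4).to_string())
print(
    "\nbelow-diagonal cells (train noise < test noise) exceed the matched\n"
    "diagonal: a too-optimistic error model inflates estimation error."
)

# the interval-width diagnostic flags the same mismatch from predictions alone
nm = res["pyr_from_ed"]["noise_mismatch"]
w_match = nm.query("train_noise == 0.05 and test_noise == 0.05").iqr.iloc[0]
w_bad = nm.query("train_noise == 0.0 and test_noise == 0.05").iqr.iloc[0]
p = ff.iqr_diagnostic(w_bad, w_match)
print(f"\nrank-sum p (mismatched intervals wider): {p:.2e}")
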