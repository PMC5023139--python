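"""Experimental-design scans and noise/exchange sensitivity analysis.

``scan_designs`` evaluates a grid of tracer x measurement-platform setups
on one shared flux cohort, reporting the held-out test MAE of a forest
predictor per (tracer, platform, ratio) cell — the in-silico screen used
to pick labeling strategy and analytics before running an experiment.

``sensitivity_grid`` quantifies how measurement noise and the assumed
exchange-flux magnitude affect accuracy: matched train/test conditions on
a 4x4 grid, plus mismatch matrices where the training assumption differs
from the test data (the train/test split is held fixed across all cells
so differences come only from the varied parameter).

``iqr_diagnostic`` compares the [10%, 90%] prediction-interval widths of
two prediction sets with a right-tailed Wilcoxon-Mann-Whitney rank-sum
test — wider intervals than expected flag a mismatch between simulated
and measured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FluxForestError, PredictorError
from .forest import evaluate_mae, make_training_set, select_features, train
from .measurements import add_noise
from .pipeline import get_emu_system, simulate_measurements
from .sampling import (
    assign_exchange,
    ratio_values,
    sample_net_fluxes,
    stratified_cohort,
    FluxCohort,
)

__all__ = ["DesignGrid", "scan_designs", "sensitivity_grid", "iqr_diagnostic"]


@dataclass
class DesignGrid:
    """Long-format design-scan results: one row per (tracer, platform, ratio)."""

    table: pd.DataFrame
    failures: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def mae(self, tracer: str, platform: str, ratio: str) -> float:
        t = self.table
        row = t[(t.tracer == tracer) & (t.platform == platform) & (t.ratio == ratio)]
        if row.empty:
            raise FluxForestError(
                f"no design cell ({tracer}, {platform}, {ratio})"
            )
        return float(row.mae.iloc[0])

    def pivot(self, ratio: str) -> pd.DataFrame:
        t = self.table[self.table.ratio == ratio]
        return t.pivot(index="tracer", columns="platform", values="mae")


def scan_designs(
    network,
    cohort: FluxCohort,
    tracers: dict,
    platforms: dict,
    ratio_defs: list,
    seed: int = 0,
    *,
    noise_level: float = 0.01,
    n_bins: int = 10,
    train_per_bin: int | None = None,
    ntree: int = 100,
    mtry: int = 20,
    feature_selection: bool = True,
) -> DesignGrid:
    """Tracer x platform x ratio MAE grid on a shared flux cohort.

    All cells reuse ``cohort`` so they differ only in tracer and platform.
    Per-cell failures are recorded and the scan continues.  Feature
    selection (importance-ranked, CV-chosen fraction) runs before training
    in every cell to compensate for very different feature counts.
    """
    rng = np.random.SeedSequence(seed)
    rows, failures = [], []
    for rd in ratio_defs:
        if rd.name not in cohort.ratios:
            cohort.ratios[rd.name] = ratio_values(rd, network, cohort.net)
    for tname, tracer in tracers.items():
        for pname, spec in platforms.items():
            sub_seed = int(rng.spawn(1)[0].generate_state(1)[0] % 2**31)
            try:
                X = simulate_measurements(
                    network, cohort, tracer, spec,
                    noise_level=noise_level, seed=sub_seed,
                )
            except FluxForestError as e:
                for rd in ratio_defs:
                    failures.append(
                        {"tracer": tname, "platform": pname, "ratio": rd.name,
                         "error": str(e)}
                    )
                continue
            for rd in ratio_defs:
                try:
                    from .sampling import infeasible_bin_indices

                    ds = make_training_set(
                        X, cohort.ratios[rd.name], n_bins=n_bins,
                        n_per_bin=train_per_bin, seed=sub_seed,
                        manifest=spec.manifest, ratio_name=rd.name,
                        exclude_bins=infeasible_bin_indices(
                            cohort, rd.name, n_bins
                        ),
                    )
                    subset = None
                    n_kept = X.shape[1]
                    if feature_selection:
                        subset, _ = select_features(
                            ds, seed=sub_seed, ntree=ntree, mtry=mtry
                        )
                        n_kept = len(subset)
                    pred = train(
                        ds, ntree=ntree, mtry=mtry, seed=sub_seed,
                        feature_subset=subset,
                    )
                    rows.append(
                        {
                            "tracer": tname,
                            "platform": pname,
                            "ratio": rd.name,
                            "mae": evaluate_mae(pred, ds),
                            "n_features_selected": n_kept,
                            "n_train": ds.n_train,
                        }
                    )
                except FluxForestError as e:
                    failures.append(
                        {"tracer": tname, "platform": pname, "ratio": rd.name,
                         "error": str(e)}
                    )
    return DesignGrid(
        pd.DataFrame(rows),
        failures,
        {"seed": seed, "noise_level": noise_level, "n_cohort": len(cohort)},
    )


def sensitivity_grid(
    network,
    ratio_defs: list,
    noise_levels=(0.0, 0.01, 0.05, 0.1),
    exch_bounds=(0.1, 1.0, 10.0, 100.0),
    seed: int = 0,
    *,
    tracer=None,
    spec=None,
    n_bins: int = 10,
    cohort_per_bin: int = 300,
    train_per_bin: int | None = None,
    ntree: int = 100,
    mtry: int = 20,
    fixed_exch: float = 1.0,
    fixed_noise: float = 0.01,
    components=("matched", "noise_mismatch", "exch_mismatch"),
) -> dict:
    """Noise x exchange sensitivity on one net-flux cohort.

    One set of net fluxes is sampled once (stratified on the first ratio);
    for each exchange bound the exchange fluxes are redrawn and labeling
    re-simulated; for each noise level noise is superimposed.  The same
    balanced subset and train/test split is used for every cell.  Returns
    a dict with DataFrames:

    - ``matched``: MAE with train and test under the same (noise, exch);
    - ``noise_mismatch``: exch fixed, MAE of predictors trained at noise i
      and tested at noise j (rows = train, cols = test);
    - ``exch_mismatch``: noise fixed, analogous over exchange bounds;
    - plus per-cell interval widths for the IQR diagnostic.
    """
    if tracer is None or spec is None:
        raise FluxForestError("sensitivity_grid needs a tracer and a spec")
    ss = np.random.SeedSequence(seed)
    s_cohort, s_exch, s_noise, s_split = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )
    from .sampling import infeasible_bin_indices, multi_ratio_cohort

    base = multi_ratio_cohort(
        network, list(ratio_defs), n_bins, cohort_per_bin, 0.0, s_cohort
    )
    # features per exchange bound (same net fluxes, redrawn exchange)
    all_bounds = sorted(set(list(exch_bounds) + [fixed_exch]))
    feats: dict[float, np.ndarray] = {}
    for i, b in enumerate(all_bounds):
        exch = assign_exchange(network, base.net, b, s_exch + i)
        cohort_b = FluxCohort(network, base.net, exch, base.ratios, base.metadata)
        feats[b] = simulate_measurements(network, cohort_b, tracer, spec)

    all_noise = sorted(set(list(noise_levels) + [fixed_noise]))

    def noised(b, eps, tag):
        import zlib

        sub = s_noise + zlib.crc32(tag.encode()) % 10000
        return add_noise(feats[b], eps, sub, spec)

    results: dict = {"metadata": {
        "seed": seed, "noise_levels": list(noise_levels),
        "exch_bounds": list(exch_bounds), "n_cohort": len(base),
    }}
    for rd in ratio_defs:
        y = base.ratios[rd.name]
        # one split shared by every cell (indices into the cohort)
        ref = make_training_set(
            np.arange(len(y))[:, None].astype(float), y,
            n_bins=n_bins, n_per_bin=train_per_bin, seed=s_split,
            exclude_bins=infeasible_bin_indices(base, rd.name, n_bins),
        )
        tr_idx = ref.X_train[:, 0].astype(int)
        te_idx = ref.X_test[:, 0].astype(int)
        res: dict = {}

        def fit(b, eps, tag):
            Xn = noised(b, eps, tag)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return Xn, train((Xn[tr_idx], y[tr_idx]),
                                 ntree=ntree, mtry=mtry, seed=s_split)

        if "matched" in components:
            rows = []
            for b in exch_bounds:
                for eps in noise_levels:
                    Xn, pred = fit(b, eps, f"m{b}-{eps}")
                    rows.append({"exch_bound": b, "noise": eps,
                                 "mae": evaluate_mae(pred, (Xn[te_idx], y[te_idx]))})
            res["matched"] = pd.DataFrame(rows)
        if "noise_mismatch" in components:
            preds = {eps: fit(fixed_exch, eps, f"n{eps}") for eps in all_noise}
            rows = []
            for eps_tr in noise_levels:
                _, pred = preds[eps_tr]
                for eps_te in noise_levels:
                    X_te = noised(fixed_exch, eps_te, f"n{eps_te}")
                    iq = pred.predict_quantiles(X_te[te_idx], (0.1, 0.9))
                    rows.append({
                        "train_noise": eps_tr, "test_noise": eps_te,
                        "mae": evaluate_mae(pred, (X_te[te_idx], y[te_idx])),
                        "iqr": iq[:, 1] - iq[:, 0],
                    })
            res["noise_mismatch"] = pd.DataFrame(rows)
        if "exch_mismatch" in components:
            preds = {b: fit(b, fixed_noise, f"e{b}") for b in exch_bounds}
            rows = []
            for b_tr in exch_bounds:
                _, pred = preds[b_tr]
                for b_te in exch_bounds:
                    X_te = noised(b_te, fixed_noise, f"e{b_te}")
                    iq = pred.predict_quantiles(X_te[te_idx], (0.1, 0.9))
                    rows.append({
                        "train_exch": b_tr, "test_exch": b_te,
                        "mae": evaluate_mae(pred, (X_te[te_idx], y[te_idx])),
                        "iqr": iq[:, 1] - iq[:, 0],
                    })
            res["exch_mismatch"] = pd.DataFrame(rows)
        results[rd.name] = res
    return results


def iqr_diagnostic(predictions_a, predictions_b) -> float:
    """Right-tailed rank-sum p-value on [10%, 90%] interval widths.

    ``predictions_a``/``b`` are (n, >=2) quantile arrays whose first and
    last columns are the 10% and 90% quantiles, or 1-D arrays of widths.
    Small p supports H1: widths of ``a`` are stochastically larger than
    those of ``b`` (i.e. set ``a`` is the suspect/incompatible one).
    """
    def widths(p):
        p = np.asarray(p, dtype=float)
        if p.ndim == 1:
            return p
        return p[:, -1] - p[:, 0]

    wa, wb = widths(predictions_a), widths(predictions_b)
    if len(wa) < 3 or len(wb) < 3:
        raise PredictorError("iqr_diagnostic needs at least 3 samples per group")
    if np.ptp(wa) == 0 and np.ptp(wb) == 0 and wa[0] == wb[0]:
        return 0.5  # identical constant widths: no evidence of a shift
    method = "exact" if (len(wa) <= 20 and len(wb) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(wa, wb, alternative="greater", method=method)
    return float(res.pvalue)
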