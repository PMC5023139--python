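"""Random-forest flux-ratio predictors with quantile-forest intervals.

The predictor maps measurable 13C feature vectors to a flux ratio in
[0, 1].  Training data come from the surrogate simulation pipeline: the
ratio labels of a flux cohort are binned into equal segments, an equal
number of samples is drawn from each bin without replacement (so the label
is uniform over its feasible range), and the draw is split 2:1 into train
and test subsets.  Hyperparameter defaults are ntree = 100 trees and
mtry = 20 candidate split features.

Prediction intervals follow the quantile regression forest algorithm: for
a query point, every training point receives a weight proportional to how
often the two co-occupy a terminal node (normalized per tree, averaged
over trees); quantiles are read off the weighted empirical CDF of the
training labels.  The median (50% quantile) is the reported estimate and
[10%, 90%] the prediction interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import PredictorError

__all__ = [
    "SimulatedDataset",
    "RatioPredictor",
    "make_training_set",
    "train",
    "predict_quantiles",
    "evaluate_mae",
    "cross_validate",
    "select_features",
]

DEFAULT_NTREE = 100
DEFAULT_MTRY = 20
MIN_TRAIN_POINTS = 100


@dataclass
class SimulatedDataset:
    """Balanced, split surrogate dataset for one flux ratio."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    manifest: list[str] = field(default_factory=list)
    ratio_name: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    @property
    def n_test(self) -> int:
        return len(self.y_test)


def _bin_indices(y: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.minimum((y * n_bins).astype(int), n_bins - 1)
    return idx


def make_training_set(
    X: np.ndarray,
    y: np.ndarray,
    n_bins: int = 10,
    n_per_bin: int | None = None,
    seed: int | np.random.Generator = 0,
    *,
    manifest: list[str] | None = None,
    ratio_name: str = "",
    exclude_bins: list[int] | None = None,
) -> SimulatedDataset:
    """Bin labels, draw equal per-bin counts without replacement, split 2:1.

    Labels must lie in [0, 1]; NaN labels (undefined ratios) are dropped
    up front.  Raises when a bin holds fewer than the requested count.
    ``exclude_bins`` skips bin indices known to be structurally infeasible
    for the ratio (so the balanced draw covers only the feasible range).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    X, y = X[ok], y[ok]
    if np.any(y < 0) or np.any(y > 1):
        raise PredictorError("ratio labels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bins = _bin_indices(y, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    use_bins = [b for b in range(n_bins) if b not in set(exclude_bins or [])]
    if not use_bins:
        raise PredictorError("all ratio bins excluded")
    if n_per_bin is None:
        n_per_bin = int(min(counts[b] for b in use_bins))
        if n_per_bin == 0:
            b = min(b for b in use_bins if counts[b] == 0)
            raise PredictorError(
                f"ratio bin [{b / n_bins:.2f}, {(b + 1) / n_bins:.2f}] holds 0 "
                "samples (structurally infeasible? pass exclude_bins)"
            )
    short = [(b, int(counts[b])) for b in use_bins if counts[b] < n_per_bin]
    if short:
        b, have = short[0]
        raise PredictorError(
            f"ratio bin [{b / n_bins:.2f}, {(b + 1) / n_bins:.2f}] holds {have} "
            f"samples but {n_per_bin} were requested"
        )
    chosen = []
    for b in use_bins:
        members = np.flatnonzero(bins == b)
        chosen.append(rng.choice(members, size=n_per_bin, replace=False))
    chosen = np.concatenate(chosen)
    rng.shuffle(chosen)
    n_total = len(chosen)
    n_train = int(round(n_total * 2 / 3))
    tr, te = chosen[:n_train], chosen[n_train:]
    return SimulatedDataset(
        X[tr], y[tr], X[te], y[te],
        manifest=list(manifest or []),
        ratio_name=ratio_name,
        metadata={"n_bins": n_bins, "n_per_bin": n_per_bin},
    )


@dataclass
class RatioPredictor:
    """A trained forest plus everything needed for quantile prediction."""

    forest: RandomForestRegressor
    manifest: list[str]
    ratio_name: str
    train_leaves: np.ndarray        # (n_train, ntree) terminal-node ids
    y_train: np.ndarray
    metadata: dict = field(default_factory=dict)

    def _check_manifest(self, manifest):
        if manifest is not None and self.manifest and list(manifest) != self.manifest:
            raise PredictorError(
                "feature manifest mismatch between predictor and input data"
            )

    def predict(self, X, manifest=None) -> np.ndarray:
        """Median (50% quantile) estimate, clipped to [0, 1]."""
        self._check_manifest(manifest)
        return self.predict_quantiles(X, quantiles=(0.5,))[:, 0]

    def predict_quantiles(
        self, X, quantiles=(0.1, 0.5, 0.9), manifest=None, chunk: int = 512
    ) -> np.ndarray:
        """Quantile-forest conditional quantiles, shape (n, len(quantiles))."""
        self._check_manifest(manifest)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        q = np.asarray(quantiles, dtype=float)
        order = np.argsort(self.y_train, kind="stable")
        y_sorted = self.y_train[order]
        n_train = len(y_sorted)
        ntree = self.train_leaves.shape[1]
        # per-tree leaf occupancy of the training set
        leaf_counts = []
        for t in range(ntree):
            leaves = self.train_leaves[:, t]
            counts = np.bincount(leaves)
            leaf_counts.append(counts)
        out = np.empty((X.shape[0], len(q)))
        for lo in range(0, X.shape[0], chunk):
            hi = min(lo + chunk, X.shape[0])
            new_leaves = self.forest.apply(X[lo:hi])  # (b, ntree)
            W = np.zeros((hi - lo, n_train), dtype=np.float64)
            for t in range(ntree):
                counts = leaf_counts[t]
                same = self.train_leaves[:, t][None, :] == new_leaves[:, t][:, None]
                denom = counts[new_leaves[:, t]].astype(float)
                denom[denom == 0] = np.inf
                W += same / denom[:, None]
            W /= ntree
            Wc = np.cumsum(W[:, order], axis=1)
            Wc /= Wc[:, -1:]
            for k, qq in enumerate(q):
                pos = np.argmax(Wc >= qq - 1e-12, axis=1)
                out[lo:hi, k] = y_sorted[pos]
        return np.clip(out, 0.0, 1.0)

    def feature_importances(self) -> np.ndarray:
        return self.forest.feature_importances_

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        import joblib

        path = str(path)
        joblib.dump(
            {
                "forest": self.forest,
                "train_leaves": self.train_leaves,
                "y_train": self.y_train,
            },
            path,
        )
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "ratio_name": self.ratio_name,
                    "manifest": self.manifest,
                    "metadata": self.metadata,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "RatioPredictor":
        import joblib

        path = str(path)
        blob = joblib.load(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(
            blob["forest"],
            meta["manifest"],
            meta["ratio_name"],
            blob["train_leaves"],
            blob["y_train"],
            meta["metadata"],
        )


def train(
    train_set: SimulatedDataset | tuple,
    ntree: int = DEFAULT_NTREE,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    *,
    feature_subset: np.ndarray | None = None,
) -> RatioPredictor:
    """Fit a ratio predictor (defaults ntree=100, mtry=20)."""
    if isinstance(train_set, SimulatedDataset):
        X, y = train_set.X_train, train_set.y_train
        manifest = train_set.manifest
        name = train_set.ratio_name
    else:
        X, y = train_set
        manifest, name = [], ""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_subset is not None:
        X = X[:, feature_subset]
        manifest = [manifest[j] for j in feature_subset] if manifest else []
    if len(y) < MIN_TRAIN_POINTS:
        raise PredictorError(
            f"{len(y)} training points; at least {MIN_TRAIN_POINTS} required"
        )
    if mtry > X.shape[1]:
        warnings.warn(
            f"mtry={mtry} exceeds {X.shape[1]} features; lowering to "
            f"{X.shape[1]}",
            stacklevel=2,
        )
        mtry = X.shape[1]
    forest = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    leaves = forest.apply(X)
    train_mae = float(np.mean(np.abs(forest.predict(X) - y)))
    return RatioPredictor(
        forest,
        list(manifest),
        name,
        leaves,
        y.copy(),
        metadata={
            "ntree": ntree,
            "mtry": mtry,
            "seed": int(seed),
            "n_train": len(y),
            "train_mae": train_mae,
            "feature_subset": (
                None if feature_subset is None else [int(j) for j in feature_subset]
            ),
        },
    )


def predict_quantiles(
    predictor: RatioPredictor, features, quantiles=(0.1, 0.5, 0.9)
) -> np.ndarray:
    return predictor.predict_quantiles(features, quantiles=quantiles)


def evaluate_mae(predictor: RatioPredictor, test_set) -> float:
    """Mean absolute error of the median prediction on a held-out set."""
    if isinstance(test_set, SimulatedDataset):
        X, y = test_set.X_test, test_set.y_test
    else:
        X, y = test_set
    if len(y) == 0:
        raise PredictorError("empty test set")
    sub = predictor.metadata.get("feature_subset")
    X = np.asarray(X, dtype=float)
    if sub is not None:
        X = X[:, sub]
    med = predictor.predict_quantiles(X, quantiles=(0.5,))[:, 0]
    return float(np.mean(np.abs(med - np.asarray(y))))


def _stratified_folds(y, k, rng, n_bins=10):
    bins = _bin_indices(np.asarray(y), n_bins)
    folds = np.empty(len(y), dtype=int)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        rng.shuffle(members)
        folds[members] = np.arange(len(members)) % k
    return folds


def cross_validate(
    train_set: SimulatedDataset | tuple,
    ntree_grid=(DEFAULT_NTREE,),
    mtry_grid=(DEFAULT_MTRY,),
    k: int = 5,
    seed: int = 0,
):
    """k-fold CV over an (ntree, mtry) grid.

    Folds are stratified by ratio bins.  Returns (best (ntree, mtry),
    DataFrame of mean CV-MAE per grid cell); ties break toward smaller
    ntree, then smaller mtry.
    """
    import pandas as pd

    if k < 2:
        raise PredictorError("k must be >= 2")
    if not len(ntree_grid) or not len(mtry_grid):
        raise PredictorError("empty hyperparameter grid")
    if isinstance(train_set, SimulatedDataset):
        X, y = train_set.X_train, train_set.y_train
    else:
        X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    rows = []
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            maes = []
            for f in range(k):
                tr, va = folds != f, folds == f
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pred = train((X[tr], y[tr]), ntree=ntree, mtry=mtry, seed=seed)
                maes.append(evaluate_mae(pred, (X[va], y[va])))
            rows.append(
                {"ntree": ntree, "mtry": mtry, "cv_mae": float(np.mean(maes))}
            )
    table = pd.DataFrame(rows)
    best_row = min(
        rows, key=lambda r: (round(r["cv_mae"], 12), r["ntree"], r["mtry"])
    )
    return (best_row["ntree"], best_row["mtry"]), table


def select_features(
    train_set: SimulatedDataset | tuple,
    fractions=(1.0, 0.5, 0.25, 0.10, 0.05),
    seed: int = 0,
    *,
    ntree: int = DEFAULT_NTREE,
    mtry: int = DEFAULT_MTRY,
    k: int = 5,
):
    """Importance-ranked feature selection by cross-validated MAE.

    Fit on all features, rank by importance, re-fit on the top fraction for
    each candidate fraction, and keep the fraction with the smallest CV-MAE
    (ties go to the larger fraction).  Returns (selected column indices,
    DataFrame of fraction vs CV-MAE).
    """
    import pandas as pd

    if isinstance(train_set, SimulatedDataset):
        X, y = train_set.X_train, train_set.y_train
    else:
        X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = train((X, y), ntree=ntree, mtry=mtry, seed=seed)
    rank = np.argsort(full.feature_importances())[::-1]
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    rows = []
    for frac in fractions:
        n_keep = max(1, int(round(frac * X.shape[1])))
        cols = np.sort(rank[:n_keep])
        maes = []
        for f in range(k):
            tr, va = folds != f, folds == f
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = train(
                    (X[tr][:, cols], y[tr]), ntree=ntree, mtry=mtry, seed=seed
                )
            maes.append(evaluate_mae(pred, (X[va][:, cols], y[va])))
        rows.append(
            {"fraction": frac, "n_features": n_keep, "cv_mae": float(np.mean(maes))}
        )
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (round(r["cv_mae"], 12), -r["fraction"]))
    n_keep = best["n_features"]
    return np.sort(rank[:n_keep]), table
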