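"""Hold-out evaluation, regression/classification metrics and benchmarks.

Regression models are compared on a single seeded hold-out split (~70/30 by
default, matching a 110/48 split of 158 plots) with RMSE, MAE and R^2, and
paired differences in absolute validation error are tested with the
two-sided Wilcoxon signed-rank test.  Thematic-map accuracy uses the
standard remote-sensing vocabulary: producer's accuracy (per-class recall),
user's accuracy (per-class precision), overall accuracy and Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HoldoutSplit",
    "split_holdout",
    "regression_metrics",
    "paired_significance",
    "confusion_metrics",
    "ConfusionReport",
    "benchmark_suite",
    "EvalReport",
]


@dataclass(frozen=True)
class HoldoutSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    train_fraction: float
    seed: int | None


def split_holdout(n: int, train_fraction: float = 0.7, seed: int | None = None) -> HoldoutSplit:
    """Seeded random hold-out split of ``n`` rows.

    The training size is ``floor(train_fraction * n)`` — the rule that maps
    158 plots at 70% onto the canonical 110/48 split.
    """
    if n < 2:
        raise ValueError("need at least two rows to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n_train = int(np.floor(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return HoldoutSplit(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:]),
        train_fraction=train_fraction,
        seed=seed,
    )


def regression_metrics(pred: np.ndarray, obs: np.ndarray) -> dict[str, float]:
    """RMSE, MAE and R^2 (about the observed mean; may be negative)."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be nonempty and the same length")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn("observations have zero variance; R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return {"rmse": rmse, "mae": mae, "r2": r2}


def paired_significance(errors_a: np.ndarray, errors_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired validation errors.

    Returns (V, p) where V is the signed-rank statistic.  Exact null
    distribution for n <= 25, normal approximation beyond.  Identical error
    vectors short-circuit to (0, 1) with a warning.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired samples of equal length, n >= 5")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test degenerate")
        return 0.0, 1.0
    method = "exact" if a.size <= 25 and not np.any(d == 0) else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Classification accuracy


@dataclass
class ConfusionReport:
    labels: list
    matrix: np.ndarray  # rows = truth, cols = predicted
    producers_accuracy: dict
    users_accuracy: dict
    overall_accuracy: float
    kappa: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)
        df.index.name = "truth"
        df.columns.name = "predicted"
        return df


def confusion_metrics(truth, predicted, labels=None) -> ConfusionReport:
    """Confusion matrix with producer's/user's accuracy, OA and Cohen's kappa."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth and predicted must be nonempty and the same length")
    if labels is None:
        labels = sorted(set(truth.tolist()))
    index = {lab: i for i, lab in enumerate(labels)}
    unseen = set(truth.tolist()) | set(predicted.tolist())
    unseen -= set(labels)
    if unseen:
        raise ValueError(f"labels outside the class registry: {sorted(unseen)}")

    n = len(labels)
    matrix = np.zeros((n, n), dtype=int)
    for t, p in zip(truth, predicted):
        matrix[index[t], index[p]] += 1

    total = matrix.sum()
    row = matrix.sum(axis=1)  # truth totals
    col = matrix.sum(axis=0)  # predicted totals
    diag = np.diag(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = {lab: float(diag[i] / row[i]) if row[i] else float("nan") for lab, i in index.items()}
        users = {lab: float(diag[i] / col[i]) if col[i] else float("nan") for lab, i in index.items()}
    oa = float(diag.sum() / total)
    pe = float((row * col).sum() / total**2)
    kappa = float((oa - pe) / (1.0 - pe)) if pe < 1.0 else 1.0
    return ConfusionReport(list(labels), matrix, producers, users, oa, kappa)


# ---------------------------------------------------------------------------
# Benchmark suite


@dataclass
class EvalReport:
    """Per-model, per-feature-set regression metrics plus significance tests."""

    metrics: pd.DataFrame  # index (feature_set, model), columns rmse/mae/r2
    significance: pd.DataFrame  # Wilcoxon V and p per (feature_set, model)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.metrics[self.metrics["mae"] > self.metrics["rmse"] + 1e-9]
        if len(bad):
            raise AssertionError("MAE exceeded RMSE — metric computation broken")


def _benchmark_models(seed: int, n_trees: int, svr_grid: dict | None):
    from sklearn.ensemble import BaggingRegressor, RandomForestRegressor
    from sklearn.model_selection import GridSearchCV
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    grid = svr_grid or {"svr__C": [0.1, 1, 10, 100], "svr__gamma": [0.001, 0.01, 0.1, 1]}
    svr = GridSearchCV(
        make_pipeline(StandardScaler(), SVR(kernel="rbf")).set_output(transform="default"),
        param_grid=grid,
        cv=3,
        scoring="neg_root_mean_squared_error",
    )
    return {
        "SVR": svr,
        "MLP": make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(32,), max_iter=2000, random_state=seed),
        ),
        "RF": RandomForestRegressor(n_estimators=n_trees, random_state=seed),
        "RS": BaggingRegressor(  # random subspace: feature bagging, no row bootstrap
            DecisionTreeRegressor(random_state=seed),
            n_estimators=50,
            bootstrap=False,
            max_features=0.75,
            random_state=seed,
        ),
    }


def benchmark_suite(
    table: pd.DataFrame,
    masks: dict[str, list[str]],
    seed: int = 0,
    target_column: str = "agb",
    train_fraction: float = 0.7,
    n_trees: int = 500,
    svr_grid: dict | None = None,
    asoanfis_kwargs: dict | None = None,
) -> EvalReport:
    """Fit SVR/MLP/RF/random-subspace and the ASO-ANFIS on identical splits.

    ``masks`` maps a feature-set name (e.g. a selection method) to the list
    of predictor columns it retains.  Every model sees the same seeded
    hold-out split; the report collects validation RMSE/MAE/R^2 and the
    Wilcoxon comparison of each benchmark's absolute errors against the
    ASO-ANFIS on the same validation rows.
    """
    from .estimators import ASOANFISRegressor

    y = table[target_column].to_numpy(float)
    split = split_holdout(len(table), train_fraction, seed)
    rows, sig_rows = [], []
    for set_name, feats in masks.items():
        X = table[list(feats)].to_numpy(float)
        Xtr, Xva = X[split.train_idx], X[split.val_idx]
        ytr, yva = y[split.train_idx], y[split.val_idx]

        abs_errors = {}
        anfis = ASOANFISRegressor(random_state=seed, **(asoanfis_kwargs or {}))
        anfis.fit(Xtr, ytr, X_val=Xva, y_val=yva)
        pred = anfis.predict(Xva)
        abs_errors["ASO-ANFIS"] = np.abs(pred - yva)
        rows.append({"feature_set": set_name, "model": "ASO-ANFIS", **regression_metrics(pred, yva)})

        for name, model in _benchmark_models(seed, n_trees, svr_grid).items():
            try:
                model.fit(Xtr, ytr)
                pred = np.asarray(model.predict(Xva), float)
            except Exception as exc:  # adapter failure: skip, keep the report
                warnings.warn(f"model {name} skipped on {set_name}: {exc}")
                continue
            abs_errors[name] = np.abs(pred - yva)
            rows.append({"feature_set": set_name, "model": name, **regression_metrics(pred, yva)})

        for name, err in abs_errors.items():
            if name == "ASO-ANFIS":
                continue
            V, p = paired_significance(abs_errors["ASO-ANFIS"], err)
            sig_rows.append({"feature_set": set_name, "model": name, "V": V, "p_value": p})

    metrics = pd.DataFrame(rows).set_index(["feature_set", "model"])
    significance = pd.DataFrame(sig_rows)
    if not significance.empty:
        significance = significance.set_index(["feature_set", "model"])
    return EvalReport(metrics, significance, metadata={"seed": seed, "n_trees": n_trees})
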