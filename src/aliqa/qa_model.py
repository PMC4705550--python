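"""Epsilon-SVR (RBF kernel) mapping alignment features to GDT-TS.

The regressor has three tuned hyperparameters: the epsilon tube width
``w`` (residuals smaller than ``w`` are not penalized), the
regularization constant ``c`` and the RBF kernel width ``g`` in
``k(u, v) = exp(-g * ||u - v||^2)``.  The default tuning grids are the
6 x 6 x 8 pairwise-scheme grid searched with 5-fold cross-validation and
the 6 x 6 x 9 multi-scheme grid searched with 10-fold cross-validation;
the triple with the lowest mean held-out RMSE wins (ties: lower mean ABS,
then smaller ``g``, smaller ``c``, larger ``w``).

Features are min-max scaled to [0, 1] using the training extremes before
the kernel is applied — the mean-BLOSUM feature has a different dynamic
range than the [0, 1] features and RBF kernels are scale-sensitive.  The
scaling is stored inside the model artifact, and cross-validation refits
it on each training fold so no information leaks into the held-out fold.
Fitting is delegated to libsvm (scikit-learn's SVR); prediction is
computed from the stored support vectors and dual coefficients so that a
saved-and-reloaded model predicts bit-identically.  Predictions are
clipped to [0, 1] because GDT-TS is bounded and raw SVR output is not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVR

__all__ = [
    "HyperParams",
    "LabeledDataset",
    "TrainedModel",
    "CVReport",
    "SchemaMismatchError",
    "PAIRWISE_GRID",
    "MULTI_GRID",
    "DEFAULT_FOLDS",
    "fit_svr",
    "grid_search_cv",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "aliqa-model/1"

#: Default tuning grids, one per feature scheme.
PAIRWISE_GRID = {
    "w": (0.5, 0.2, 0.1, 0.05, 0.02, 0.01),
    "c": (2.0, 1.0, 0.5, 0.1, 0.05, 0.01),
    "g": (0.5, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001),
}
MULTI_GRID = {
    "w": (0.1, 0.08, 0.06, 0.05, 0.02, 0.01),
    "c": (2.0, 1.0, 0.5, 0.1, 0.05, 0.01),
    "g": (0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001),
}
DEFAULT_FOLDS = {"pairwise": 5, "multi": 10}

DEFAULT_MATRIX_IDS = {
    "pairwise": ("BLOSUM62",),
    "multi": ("BLOSUM62", "GONNET160"),
}


class SchemaMismatchError(ValueError):
    """Raised when a model is applied to features of another schema."""


@dataclass(frozen=True)
class HyperParams:
    """SVR hyperparameters: epsilon tube width, regularization, RBF gamma."""

    w: float
    c: float
    g: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.c > 0 and self.g > 0):
            raise ValueError(f"hyperparameters must be strictly positive: {self}")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature vectors with GDT-TS labels in [0, 1], grouped by target."""

    record_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    X: np.ndarray  # (n, d)
    y: np.ndarray  # (n,)
    schema: str
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.record_ids)
        if not (len(self.target_ids) == n and self.X.shape[0] == n and len(self.y) == n):
            raise ValueError("dataset fields have inconsistent lengths")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match feature names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("labels must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.record_ids)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            record_ids=tuple(self.record_ids[i] for i in idx),
            target_ids=tuple(self.target_ids[i] for i in idx),
            X=self.X[idx],
            y=self.y[idx],
            schema=self.schema,
            feature_names=self.feature_names,
        )


@dataclass(frozen=True)
class TrainedModel:
    """A fitted epsilon-SVR plus everything needed to apply it elsewhere."""

    schema: str
    feature_names: tuple[str, ...]
    hyperparams: HyperParams
    scale_min: np.ndarray  # per-feature training minimum
    scale_max: np.ndarray  # per-feature training maximum
    support_vectors: np.ndarray  # (m, d), in scaled feature space
    dual_coef: np.ndarray  # (m,)
    intercept: float
    matrix_ids: tuple[str, ...] = ()

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.scale_max - self.scale_min
        span = np.where(span == 0, 1.0, span)
        return (X - self.scale_min) / span


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome: per-fold errors of the best triple and the grid."""

    fold_rmse: tuple[float, ...]
    fold_abs: tuple[float, ...]
    mean_rmse: float
    mean_abs: float
    grid_results: tuple[tuple[HyperParams, float, float], ...]  # (hp, rmse, abs)
    best: HyperParams
    k: int
    seed: int


def fit_svr(
    data: LabeledDataset, hp: HyperParams, matrix_ids: tuple[str, ...] | None = None
) -> TrainedModel:
    """Fit an epsilon-SVR with RBF kernel on min-max scaled features."""
    if len(data) < 2:
        raise ValueError("need at least 2 rows to fit")
    scale_min = data.X.min(axis=0)
    scale_max = data.X.max(axis=0)
    span = np.where(scale_max - scale_min == 0, 1.0, scale_max - scale_min)
    Xs = (data.X - scale_min) / span
    svr = SVR(kernel="rbf", C=hp.c, epsilon=hp.w, gamma=hp.g, tol=1e-4, cache_size=64)
    svr.fit(Xs, data.y)
    return TrainedModel(
        schema=data.schema,
        feature_names=data.feature_names,
        hyperparams=hp,
        scale_min=scale_min,
        scale_max=scale_max,
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coef=np.asarray(svr.dual_coef_, dtype=float).ravel(),
        intercept=float(svr.intercept_[0]),
        matrix_ids=matrix_ids or DEFAULT_MATRIX_IDS.get(data.schema, ()),
    )


def predict(
    model: TrainedModel,
    features: np.ndarray,
    schema: str | None = None,
    matrix_ids: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Apply a trained model; output is clipped to the GDT-TS range [0, 1].

    ``schema``/``matrix_ids`` describe how the features were built and are
    checked against the model's provenance when given.
    """
    if schema is not None and schema != model.schema:
        raise SchemaMismatchError(
            f"model expects schema {model.schema!r}, received {schema!r}"
        )
    if matrix_ids is not None and tuple(matrix_ids) != tuple(model.matrix_ids):
        warnings.warn(
            f"features built with matrices {tuple(matrix_ids)} but the model was "
            f"trained with {tuple(model.matrix_ids)}",
            stacklevel=2,
        )
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise SchemaMismatchError(
            f"model expects {len(model.feature_names)} features, received {X.shape[1]}"
        )
    Xs = model._scale(X)
    sq = ((Xs[:, None, :] - model.support_vectors[None, :, :]) ** 2).sum(axis=2)
    raw = np.exp(-model.hyperparams.g * sq) @ model.dual_coef + model.intercept
    return np.clip(raw, 0.0, 1.0)


def _fold_assignment(
    data: LabeledDataset, k: int, seed: int, group_by_target: bool
) -> np.ndarray:
    """Fold index per row: random by record, or keeping each target together."""
    rng = np.random.default_rng(seed)
    n = len(data)
    if group_by_target:
        targets = sorted(set(data.target_ids))
        order = rng.permutation(len(targets))
        fold_of_target = {targets[j]: i % k for i, j in enumerate(order)}
        return np.array([fold_of_target[t] for t in data.target_ids])
    folds = np.empty(n, dtype=int)
    folds[rng.permutation(n)] = np.arange(n) % k
    return folds


def _cv_errors(
    data: LabeledDataset, hp: HyperParams, folds: np.ndarray, k: int
) -> tuple[list[float], list[float]]:
    fold_rmse, fold_abs = [], []
    for fold in range(k):
        train_idx = np.flatnonzero(folds != fold)
        test_idx = np.flatnonzero(folds == fold)
        if len(train_idx) < 2:
            raise ValueError(f"fold {fold} leaves fewer than 2 training rows")
        model = fit_svr(data.subset(train_idx), hp)
        pred = predict(model, data.X[test_idx])
        err = pred - data.y[test_idx]
        fold_rmse.append(float(np.sqrt(np.mean(err**2))))
        fold_abs.append(float(np.mean(np.abs(err))))
    return fold_rmse, fold_abs


def grid_search_cv(
    data: LabeledDataset,
    grid: dict[str, tuple[float, ...]] | None = None,
    k: int | None = None,
    seed: int = 0,
    group_by_target: bool = False,
    repeats: int = 1,
) -> CVReport:
    """k-fold cross-validated grid search over (w, c, g) triples.

    Every triple is scored by the mean held-out RMSE over the folds (and
    over ``repeats`` independent fold assignments when ``repeats`` > 1);
    feature scaling is refit inside each training fold.  Deterministic for
    fixed inputs and seed.
    """
    if grid is None:
        grid = PAIRWISE_GRID if data.schema == "pairwise" else MULTI_GRID
    if k is None:
        k = DEFAULT_FOLDS.get(data.schema, 5)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(data) < k:
        raise ValueError(f"fewer rows ({len(data)}) than folds ({k})")
    if not (grid.get("w") and grid.get("c") and grid.get("g")):
        raise ValueError("grid must provide non-empty w, c and g value lists")

    fold_sets = [
        _fold_assignment(data, k, seed + r, group_by_target) for r in range(repeats)
    ]
    results: list[tuple[HyperParams, float, float, list[float], list[float]]] = []
    for w in grid["w"]:
        for c in grid["c"]:
            for g in grid["g"]:
                hp = HyperParams(w=w, c=c, g=g)
                all_rmse: list[float] = []
                all_abs: list[float] = []
                for folds in fold_sets:
                    fr, fa = _cv_errors(data, hp, folds, k)
                    all_rmse.extend(fr)
                    all_abs.extend(fa)
                results.append(
                    (hp, float(np.mean(all_rmse)), float(np.mean(all_abs)), all_rmse, all_abs)
                )
    best = min(results, key=lambda r: (r[1], r[2], r[0].g, r[0].c, -r[0].w))
    return CVReport(
        fold_rmse=tuple(best[3]),
        fold_abs=tuple(best[4]),
        mean_rmse=best[1],
        mean_abs=best[2],
        grid_results=tuple((hp, r, a) for hp, r, a, _, _ in results),
        best=best[0],
        k=k,
        seed=seed,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a versioned single-file JSON model artifact."""
    payload = {
        "format": MODEL_FORMAT,
        "schema": model.schema,
        "feature_names": list(model.feature_names),
        "hyperparams": {"w": model.hyperparams.w, "c": model.hyperparams.c, "g": model.hyperparams.g},
        "scale_min": model.scale_min.tolist(),
        "scale_max": model.scale_max.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "matrix_ids": list(model.matrix_ids),
    }
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(json.dumps(payload))
    tmp.replace(path)


def load_model(path: str | Path) -> TrainedModel:
    """Read a model artifact written by :func:`save_model` (bit-exact round trip)."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a parsable model file ({exc})") from exc
    fmt = payload.get("format")
    if fmt != MODEL_FORMAT:
        raise ValueError(f"{path}: unsupported model format {fmt!r}, expected {MODEL_FORMAT!r}")
    hp = payload["hyperparams"]
    return TrainedModel(
        schema=payload["schema"],
        feature_names=tuple(payload["feature_names"]),
        hyperparams=HyperParams(w=hp["w"], c=hp["c"], g=hp["g"]),
        scale_min=np.asarray(payload["scale_min"], dtype=float),
        scale_max=np.asarray(payload["scale_max"], dtype=float),
        support_vectors=np.asarray(payload["support_vectors"], dtype=float),
        dual_coef=np.asarray(payload["dual_coef"], dtype=float),
        intercept=float(payload["intercept"]),
        matrix_ids=tuple(payload["matrix_ids"]),
    )
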