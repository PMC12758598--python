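"""Blending ensemble with a KAN meta-classifier.

Layer 1: a registry of base classifiers is fit per signal kind on a 7:3
stratified split with 10:1 positive:negative sample weights.  Hard-label
(0/1) predictions of each base classifier on the holdout become meta-features,
stacked column-wise per signal and concatenated across signals.

Layer 2: a KAN is trained on the merged meta-features under stratified 5-fold
cross-validation and finally refit on all holdout rows.
"""

from __future__ import annotations

import inspect
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .kan import (
    KANNetwork,
    TrainConfig,
    default_widths,
    init_kan,
    kan_predict_proba,
    kan_train,
)
from .metrics import classification_metrics
from .regions import SignalMatrix

__all__ = [
    "BaseClassifierRegistry",
    "BlendingModel",
    "EvalReport",
    "default_registry",
    "fast_registry",
    "blend_split",
    "train_base",
    "hard_label_meta_features",
    "merge_signals",
    "train_meta_cv",
    "train_blending",
    "predict_regions",
]


@dataclass
class BaseClassifierRegistry:
    """Ordered, named base-classifier factories; order fixes meta-feature columns."""

    entries: list[tuple[str, Callable[[int], BaseEstimator]]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if not names:
            raise ValueError("registry needs at least one entry")
        if len(set(names)) != len(names):
            raise ValueError("registry names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


def default_registry() -> BaseClassifierRegistry:
    """Eight-family default standing in for an auto-generated model zoo."""
    return BaseClassifierRegistry(
        entries=[
            ("gbdt_hist", lambda s: HistGradientBoostingClassifier(
                max_iter=100, max_depth=6, learning_rate=0.1, random_state=s)),
            ("gbdt_shallow", lambda s: GradientBoostingClassifier(
                n_estimators=60, max_depth=2, random_state=s)),
            ("random_forest", lambda s: RandomForestClassifier(
                n_estimators=100, random_state=s, n_jobs=1)),
            ("extra_trees", lambda s: ExtraTreesClassifier(
                n_estimators=100, random_state=s, n_jobs=1)),
            ("logistic", lambda s: make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=2000, random_state=s))),
            ("knn", lambda s: KNeighborsClassifier(n_neighbors=15)),
            ("mlp", lambda s: MLPClassifier(
                hidden_layer_sizes=(32,), max_iter=400, random_state=s)),
            ("naive_bayes", lambda s: GaussianNB()),
        ]
    )


def fast_registry() -> BaseClassifierRegistry:
    """Small registry for tests and sweeps."""
    return BaseClassifierRegistry(
        entries=[
            ("logistic", lambda s: make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=1000, random_state=s))),
            ("extra_trees", lambda s: ExtraTreesClassifier(
                n_estimators=40, random_state=s, n_jobs=1)),
            ("naive_bayes", lambda s: GaussianNB()),
        ]
    )


@dataclass
class EvalReport:
    accuracy: float
    auroc: float
    auprc: float
    fold_accuracy: list[float]
    fold_auroc: list[float]
    fold_auprc: list[float]
    accuracy_std: float
    auroc_std: float
    auprc_std: float
    folds: int = 5


@dataclass
class BlendingModel:
    registry_names: list[str]
    fitted_models: dict[str, list[tuple[str, BaseEstimator]]]  # signal -> models
    meta: KANNetwork
    signal_kinds: list[str]
    split_seed: int
    threshold: float = 0.5

    @property
    def meta_input_width(self) -> int:
        return len(self.registry_names) * len(self.signal_kinds)


def blend_split(
    m: SignalMatrix, ratio: float = 0.7, seed: int = 0
) -> tuple[SignalMatrix, SignalMatrix]:
    """Stratified row split of a SignalMatrix into (train, holdout)."""
    classes = np.unique(m.y)
    if len(classes) < 2:
        raise ValueError("both classes must be present for a stratified split")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    idx_train, idx_hold = train_test_split(
        np.arange(m.n_samples),
        train_size=ratio,
        stratify=m.y,
        random_state=seed,
    )
    idx_train, idx_hold = np.sort(idx_train), np.sort(idx_hold)

    def take(idx: np.ndarray) -> SignalMatrix:
        return SignalMatrix(
            X=m.X[idx],
            y=m.y[idx],
            signal_kinds=list(m.signal_kinds),
            region_index=[m.region_index[i] for i in idx],
            bins_per_region=m.bins_per_region,
        )

    return take(idx_train), take(idx_hold)


def _fit_supports_weights(est: BaseEstimator) -> bool:
    fit = est.fit
    try:
        return "sample_weight" in inspect.signature(fit).parameters
    except (TypeError, ValueError):
        return False


def train_base(
    registry: BaseClassifierRegistry,
    train: SignalMatrix,
    signal_kind: str,
    class_weight_ratio: tuple[float, float] = (10.0, 1.0),
    seed: int = 0,
) -> list[tuple[str, BaseEstimator]]:
    """Fit every registry entry on one signal's 400-column block.

    Positive samples get weight ``class_weight_ratio[0]``, negatives
    ``class_weight_ratio[1]``.  Entries that fail to fit are skipped with a
    warning; an empty result is an error.
    """
    X = train.block(signal_kind)
    y = train.y
    w = np.where(y == 1, class_weight_ratio[0], class_weight_ratio[1]).astype(float)
    fitted: list[tuple[str, BaseEstimator]] = []
    for name, factory in registry.entries:
        est = factory(seed)
        try:
            if hasattr(est, "steps"):
                # pipelines: route weights to the final step when supported
                final = est.steps[-1]
                if _fit_supports_weights(final[1]):
                    est.fit(X, y, **{f"{final[0]}__sample_weight": w})
                else:
                    est.fit(X, y)
            elif _fit_supports_weights(est):
                est.fit(X, y, sample_weight=w)
            else:
                est.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - registry entries are user code
            warnings.warn(
                f"base classifier {name!r} failed on {signal_kind}: {exc}",
                stacklevel=2,
            )
            continue
        fitted.append((name, est))
    if not fitted:
        raise RuntimeError(f"all base classifiers failed for signal {signal_kind}")
    return fitted


def hard_label_meta_features(
    fitted: Sequence[tuple[str, BaseEstimator]], X_block: np.ndarray
) -> np.ndarray:
    """0/1 predictions of each fitted model, one column per model in order."""
    cols = []
    for name, est in fitted:
        try:
            pred = est.predict(X_block)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"model {name!r} is not usable: {exc}") from exc
        pred = np.asarray(pred)
        if not np.isin(pred, (0, 1)).all():
            raise ValueError(f"model {name!r} emitted non-binary labels")
        cols.append(pred.astype(np.int64))
    return np.column_stack(cols)


def merge_signals(
    per_signal: dict[str, np.ndarray], signal_order: Sequence[str]
) -> np.ndarray:
    """Horizontally concatenate per-signal meta-feature matrices in order."""
    mats = []
    n_rows = None
    for kind in signal_order:
        mat = per_signal[kind]
        if n_rows is None:
            n_rows = mat.shape[0]
        elif mat.shape[0] != n_rows:
            raise ValueError(
                f"row mismatch: {kind} has {mat.shape[0]} rows, expected {n_rows}"
            )
        mats.append(mat)
    return np.concatenate(mats, axis=1)


def train_meta_cv(
    meta_features: np.ndarray,
    y: np.ndarray,
    kan_cfg: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    grid_size: int = 5,
    spline_order: int = 3,
    input_range: tuple[float, float] = (-1.0, 3.0),
) -> tuple[KANNetwork, EvalReport]:
    """Stratified k-fold CV of the KAN meta-classifier, then refit on all rows."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    meta_features = np.asarray(meta_features, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if kan_cfg is None:
        kan_cfg = TrainConfig(seed=seed)
    widths = default_widths(meta_features.shape[1])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, aurocs, auprcs = [], [], []
    for fold_i, (tr, va) in enumerate(skf.split(meta_features, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"fold {fold_i} contains a single class")
        net = init_kan(widths, grid_size, spline_order, input_range, seed=seed + fold_i)
        net, _ = kan_train(net, meta_features[tr], y[tr], kan_cfg)
        prob = kan_predict_proba(net, meta_features[va])
        rep = classification_metrics(y[va], prob)
        accs.append(rep["accuracy"])
        aurocs.append(rep["auroc"])
        auprcs.append(rep["auprc"])
    final = init_kan(widths, grid_size, spline_order, input_range, seed=seed)
    final, _ = kan_train(final, meta_features, y, kan_cfg)
    report = EvalReport(
        accuracy=float(np.mean(accs)),
        auroc=float(np.mean(aurocs)),
        auprc=float(np.mean(auprcs)),
        fold_accuracy=[float(a) for a in accs],
        fold_auroc=[float(a) for a in aurocs],
        fold_auprc=[float(a) for a in auprcs],
        accuracy_std=float(np.std(accs)),
        auroc_std=float(np.std(aurocs)),
        auprc_std=float(np.std(auprcs)),
        folds=folds,
    )
    return final, report


def _meta_features_for(
    fitted_models: dict[str, list[tuple[str, BaseEstimator]]],
    m: SignalMatrix,
    signal_kinds: Sequence[str],
) -> np.ndarray:
    per_signal = {
        kind: hard_label_meta_features(fitted_models[kind], m.block(kind))
        for kind in signal_kinds
    }
    return merge_signals(per_signal, signal_kinds)


def train_blending(
    m: SignalMatrix,
    registry: BaseClassifierRegistry | None = None,
    ratio: float = 0.7,
    class_weight_ratio: tuple[float, float] = (10.0, 1.0),
    kan_cfg: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[BlendingModel, EvalReport]:
    """Full blending pipeline: split, fit layer 1, build meta-features, fit KAN."""
    if registry is None:
        registry = default_registry()
    train, holdout = blend_split(m, ratio=ratio, seed=seed)
    fitted_models = {
        kind: train_base(registry, train, kind, class_weight_ratio, seed=seed)
        for kind in m.signal_kinds
    }
    merged = _meta_features_for(fitted_models, holdout, m.signal_kinds)
    # every CV fold needs both classes; cap folds by the minority count
    minority = int(min((holdout.y == 1).sum(), (holdout.y == 0).sum()))
    eff_folds = max(2, min(folds, minority))
    meta, report = train_meta_cv(
        merged, holdout.y, kan_cfg=kan_cfg, folds=eff_folds, seed=seed
    )
    model = BlendingModel(
        registry_names=registry.names,
        fitted_models=fitted_models,
        meta=meta,
        signal_kinds=list(m.signal_kinds),
        split_seed=seed,
    )
    return model, report


def predict_regions(
    model: BlendingModel, m: SignalMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, binary calls) for each row of ``m``.

    ``m`` must carry every signal kind the model was trained on; extra
    signals are ignored.
    """
    for kind in model.signal_kinds:
        if kind not in m.signal_kinds:
            raise KeyError(f"input matrix is missing signal kind {kind!r}")
    merged = _meta_features_for(model.fitted_models, m, model.signal_kinds)
    prob = kan_predict_proba(model.meta, merged)
    return prob, (prob >= model.threshold).astype(np.int64)
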