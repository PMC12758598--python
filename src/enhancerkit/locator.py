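"""Boundary localization inside positive 4000 bp regions.

Regions are segmented into 200 bp windows at a 50 bp step (77 windows for a
4000 bp region).  Window sequences are embedded (k-mer frequencies by
default, or externally supplied embeddings), scored by a stacking ensemble
(gradient-boosted level-1 learner producing out-of-fold meta-features that
are concatenated to the original features for a selected meta-learner), and
the per-window probabilities are converted into a single boundary call:
retain windows with probability >= mean - 0.3*std (population std), merge
consecutive retained windows, and return the run with the highest mean
probability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .regions import GenomicRegion

__all__ = [
    "WindowSet",
    "Embedder",
    "StackingModel",
    "EnhancerCall",
    "make_windows",
    "kmer_embed",
    "load_external_embeddings",
    "oof_meta_features",
    "train_stacking",
    "predict_window_probs",
    "dynamic_threshold_call",
]

WINDOW_LENGTH = 200
WINDOW_STEP = 50
THRESHOLD_MULTIPLIER = 0.3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class WindowSet:
    """Sliding windows over a parent region, with optional per-window probs."""

    parent: GenomicRegion
    windows: list[tuple[int, int]]  # offsets relative to parent.start
    window_length: int = WINDOW_LENGTH
    step: int = WINDOW_STEP
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=np.float64)
            if len(self.probs) != len(self.windows):
                raise ValueError("probs do not align with windows")
            if ((self.probs < 0) | (self.probs > 1)).any():
                raise ValueError("probs must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(
    region_length: int,
    window: int = WINDOW_LENGTH,
    step: int = WINDOW_STEP,
    parent: GenomicRegion | None = None,
) -> WindowSet:
    """Windows at offsets 0, step, 2*step, ... while offset+window <= length."""
    if window > region_length:
        raise ValueError(
            f"window ({window}) exceeds region length ({region_length})"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    offsets = range(0, region_length - window + 1, step)
    if parent is None:
        parent = GenomicRegion("window_parent", 0, region_length)
    return WindowSet(
        parent=parent,
        windows=[(o, o + window) for o in offsets],
        window_length=window,
        step=step,
    )


def kmer_embed(seq: str, k: int = 6) -> np.ndarray:
    """Normalized k-mer frequency vector of length 4^k.

    k-mers containing non-ACGT characters are skipped; a sequence with no
    valid k-mer maps to the zero vector.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k ({k})")
    counts = np.zeros(4**k, dtype=np.float64)
    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    valid = codes >= 0
    # rolling base-4 encoding
    idx = 0
    run = 0  # consecutive valid bases ending here
    mod = 4 ** (k - 1)
    for i in range(len(seq)):
        if valid[i]:
            idx = (idx % mod) * 4 + codes[i]
            run += 1
        else:
            idx = 0
            run = 0
        if run >= k:
            counts[idx] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


@dataclass
class Embedder:
    """Maps window sequences (or indices) to fixed-dimension vectors."""

    kind: str = "kmer"  # kmer | external
    k: int = 6
    matrix: np.ndarray | None = None  # external mode: one row per window

    @property
    def dim(self) -> int:
        return 4**self.k if self.kind == "kmer" else self.matrix.shape[1]

    def embed_sequences(self, seqs: Sequence[str]) -> np.ndarray:
        if self.kind == "kmer":
            return np.stack([kmer_embed(s, self.k) for s in seqs])
        if self.matrix.shape[0] != len(seqs):
            raise ValueError(
                f"external embeddings have {self.matrix.shape[0]} rows but "
                f"{len(seqs)} windows were requested"
            )
        return self.matrix


def load_external_embeddings(path: str | Path) -> Embedder:
    """Load a delimited text matrix (one row per window) as an Embedder."""
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", "\t").split()
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ValueError(
                    f"{path}: line {lineno}: {len(fields)} columns, expected {ncols}"
                )
            rows.append([float(v) for v in fields])
    if not rows:
        raise ValueError(f"{path}: empty embedding file")
    return Embedder(kind="external", matrix=np.asarray(rows, dtype=np.float64))


# ---------------------------------------------------------------------------
# Stacking ensemble
# ---------------------------------------------------------------------------

def default_level1(seed: int = 0) -> BaseEstimator:
    return HistGradientBoostingClassifier(
        max_iter=200, max_depth=6, learning_rate=0.05, random_state=seed
    )


def default_meta_candidates() -> list[tuple[str, Callable[[int], BaseEstimator]]]:
    return [
        ("gbdt", lambda s: HistGradientBoostingClassifier(
            max_iter=100, max_depth=6, learning_rate=0.1, random_state=s)),
        ("logistic", lambda s: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=s))),
        ("random_forest", lambda s: RandomForestClassifier(
            n_estimators=100, random_state=s, n_jobs=1)),
    ]


@dataclass
class StackingModel:
    fold_models: list[BaseEstimator]
    meta: BaseEstimator
    meta_name: str
    feature_dim: int
    folds: int = 10

    def level1_feature(self, X: np.ndarray) -> np.ndarray:
        """Inference-time meta-feature: mean class-1 probability over fold models."""
        probs = np.stack([m.predict_proba(X)[:, 1] for m in self.fold_models])
        return probs.mean(axis=0)[:, None]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        expanded = np.hstack([X, self.level1_feature(X)])
        return self.meta.predict_proba(expanded)[:, 1]


def oof_meta_features(
    level1_factory: Callable[[int], BaseEstimator],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, list[BaseEstimator]]:
    """Out-of-fold class-1 probabilities of the level-1 learner.

    Row i's meta-feature comes from the fold model whose training fold
    excluded i; the per-fold predictions are assembled into one column.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        # constant labels: meta-feature is the constant class probability
        return np.full((len(y), 1), float(y[0])), []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=np.float64)
    models: list[BaseEstimator] = []
    for fold_i, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold_i} training split has a single class")
        model = level1_factory(seed + fold_i)
        model.fit(X[tr], y[tr])
        oof[va] = model.predict_proba(X[va])[:, 1]
        models.append(model)
    return oof[:, None], models


def train_stacking(
    X: np.ndarray,
    y: np.ndarray,
    level1_factory: Callable[[int], BaseEstimator] | None = None,
    meta_candidates: list[tuple[str, Callable[[int], BaseEstimator]]] | None = None,
    folds: int = 10,
    holdout_fraction: float = 0.2,
    seed: int = 0,
) -> StackingModel:
    """Level-1 OOF meta-features + original features -> selected meta-learner.

    Each meta-candidate is fit on the expanded features of a stratified 80%
    split and scored on the 20% holdout; the best is refit on everything.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if level1_factory is None:
        level1_factory = default_level1
    if meta_candidates is None:
        meta_candidates = default_meta_candidates()
    oof, fold_models = oof_meta_features(level1_factory, X, y, folds=folds, seed=seed)
    expanded = np.hstack([X, oof])
    tr, va = train_test_split(
        np.arange(len(y)),
        test_size=holdout_fraction,
        stratify=y,
        random_state=seed,
    )
    best: tuple[float, str, BaseEstimator] | None = None
    failures = []
    for name, factory in meta_candidates:
        try:
            cand = factory(seed)
            cand.fit(expanded[tr], y[tr])
            score = float((cand.predict(expanded[va]) == y[va]).mean())
        except Exception as exc:  # noqa: BLE001
            failures.append((name, exc))
            continue
        if best is None or score > best[0]:
            best = (score, name, factory)
    if best is None:
        raise RuntimeError(f"all meta-candidates failed: {failures}")
    _, name, factory = best
    meta = factory(seed)
    meta.fit(expanded, y)
    return StackingModel(
        fold_models=fold_models,
        meta=meta,
        meta_name=name,
        feature_dim=X.shape[1],
        folds=folds,
    )


def predict_window_probs(
    model: StackingModel,
    embedder: Embedder,
    windows: WindowSet,
    seq: str,
) -> WindowSet:
    """Score each window of ``seq`` and return a WindowSet carrying probs."""
    if len(seq) != windows.parent.length:
        raise ValueError(
            f"sequence length {len(seq)} != parent region length "
            f"{windows.parent.length}"
        )
    subseqs = [seq[s:e] for s, e in windows.windows]
    X = embedder.embed_sequences(subseqs)
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"embedding dim {X.shape[1]} != model feature dim {model.feature_dim}"
        )
    probs = model.predict_proba(X)
    return WindowSet(
        parent=windows.parent,
        windows=list(windows.windows),
        window_length=windows.window_length,
        step=windows.step,
        probs=probs,
    )


@dataclass
class EnhancerCall:
    parent: GenomicRegion
    call_start: int  # absolute bp
    call_end: int
    mean_prob: float
    threshold: float
    retained_mask: np.ndarray
    n_candidate_regions: int


def dynamic_threshold_call(
    ws: WindowSet, multiplier: float = THRESHOLD_MULTIPLIER
) -> EnhancerCall:
    """Mean − multiplier·std retention, consecutive-window merge, best-run call."""
    if ws.probs is None or len(ws.probs) == 0:
        raise ValueError("window set carries no probabilities")
    probs = ws.probs
    t = float(probs.mean() - multiplier * probs.std())  # population std
    retained = probs >= t
    # merge runs of consecutive retained window indices
    runs: list[tuple[int, int]] = []  # [first_idx, last_idx] inclusive
    for keep, group in itertools.groupby(range(len(probs)), key=lambda i: retained[i]):
        idxs = list(group)
        if keep:
            runs.append((idxs[0], idxs[-1]))
    # max(probs) >= mean >= t, so at least one window is always retained
    best_run = max(runs, key=lambda r: (probs[r[0] : r[1] + 1].mean(), -r[0]))
    first, last = best_run
    call_start = ws.parent.start + ws.windows[first][0]
    call_end = ws.parent.start + ws.windows[last][1]
    return EnhancerCall(
        parent=ws.parent,
        call_start=call_start,
        call_end=call_end,
        mean_prob=float(probs[first : last + 1].mean()),
        threshold=t,
        retained_mask=retained,
        n_candidate_regions=len(runs),
    )


def call_to_bed6(call: EnhancerCall, name: str = "enhancer") -> str:
    """BED6 line: chrom, start, end, name, round(1000*mean_prob), strand '.'"""
    return "\t".join(
        [
            call.parent.chrom,
            str(call.call_start),
            str(call.call_end),
            name,
            str(int(round(1000 * call.mean_prob))),
            ".",
        ]
    )
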