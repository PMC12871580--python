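"""Bagged-tree classification under nested cross-validation.

Protocol: stratified outer K-fold (default 10).  Within each outer fold
the training portion is split 50/50 once (stratified); every grid point is
fit on the first half and scored by plain classification accuracy at the
0.5 probability threshold on the second half; the best grid point (ties
broken by grid declaration order) is refit on the full outer-training
portion and predicts the held-out fold.  Each outer fold selects its
hyperparameters independently, and the pooled out-of-fold probabilities
cover every row exactly once.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = ["CVConfig", "FoldResult", "CVResult", "nested_cv", "binarize", "StratificationError"]


class StratificationError(ValueError):
    """A fold or inner split ended up with a single class."""


DEFAULT_GRID = {"n_estimators": [100], "max_depth": [8, None]}


@dataclass
class CVConfig:
    """Nested cross-validation settings."""

    n_outer_folds: int = 10
    inner_split_fraction: float = 0.5
    grid: dict[str, list] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    probability_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_outer_folds < 2:
            raise ValueError("n_outer_folds must be >= 2")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability_threshold must lie in (0, 1)")
        if not (0.0 < self.inner_split_fraction < 1.0):
            raise ValueError("inner_split_fraction must lie in (0, 1)")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be nonempty")

    def grid_points(self) -> list[dict]:
        """Expand the grid in declaration order (keys, then value order)."""
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class FoldResult:
    fold_index: int
    selected_params: dict
    val_indices: np.ndarray
    probabilities: np.ndarray
    auroc: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled_probabilities: np.ndarray
    encounter_ids: list[str] | None
    feature_set_id: str | None
    config: CVConfig

    @property
    def fold_aurocs(self) -> np.ndarray:
        return np.array([f.auroc for f in self.folds])

    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_set_id": self.feature_set_id,
            "fold_aurocs": self.fold_aurocs.tolist(),
            "selected_params": [f.selected_params for f in self.folds],
            "n_rows": int(len(self.pooled_probabilities)),
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probability >= threshold -> 1 (the boundary value counts positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def _fit_forest(params: dict, X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    model.fit(X, y)
    return model


def _positive_proba(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    pos = list(model.classes_).index(1)
    return model.predict_proba(X)[:, pos]


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig | None = None,
    encounter_ids: list[str] | None = None,
    feature_set_id: str | None = None,
) -> CVResult:
    """Run the nested cross-validation protocol on one design matrix."""
    config = config or CVConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise StratificationError("both classes must be present")
    if len(y) < 2 * config.n_outer_folds:
        raise ValueError("need at least 2 rows per outer fold")

    ss = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_outer_folds + 1)]
    outer = StratifiedKFold(
        n_splits=config.n_outer_folds, shuffle=True, random_state=fold_seeds[-1]
    )
    pooled = np.full(len(y), np.nan)
    folds: list[FoldResult] = []
    grid_points = config.grid_points()
    for k, (train_idx, val_idx) in enumerate(outer.split(X, y)):
        seed_k = fold_seeds[k]
        X_tr, y_tr = X[train_idx], y[train_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y[val_idx])) < 2:
            raise StratificationError(f"outer fold {k} is single-class")
        try:
            in_tr, in_val = train_test_split(
                np.arange(len(train_idx)),
                train_size=config.inner_split_fraction,
                random_state=seed_k,
                stratify=y_tr,
            )
        except ValueError as exc:
            raise StratificationError(f"inner split failed in fold {k}: {exc}") from exc
        best_params, best_acc = None, -np.inf
        for params in grid_points:  # declaration order breaks ties
            model = _fit_forest(params, X_tr[in_tr], y_tr[in_tr], seed_k)
            proba = _positive_proba(model, X_tr[in_val])
            acc = float(np.mean(binarize(proba, config.probability_threshold) == y_tr[in_val]))
            if acc > best_acc:
                best_params, best_acc = params, acc
        model = _fit_forest(best_params, X_tr, y_tr, seed_k)
        proba = _positive_proba(model, X[val_idx])
        pooled[val_idx] = proba
        folds.append(
            FoldResult(k, dict(best_params), val_idx.copy(), proba,
                       float(roc_auc_score(y[val_idx], proba)))
        )
    assert not np.isnan(pooled).any()
    return CVResult(folds, pooled, encounter_ids, feature_set_id, config)
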