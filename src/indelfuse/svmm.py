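"""SVM-M: screen multi-caller InDel candidates with an RBF-kernel classifier.

Each candidate InDel is encoded as a five-attribute eigenvector — which
callers detected it (one indicator per caller), the variation type, the
variation size, the repeat class of the surrounding region, and the number
of supporting reads (a single caller's value, or the sum when several
callers detected it).  A C-SVC with the radial basis kernel

    RBF(u, v) = exp(-gamma * ||u - v||^2)

is trained on truth-labeled candidates (TP = +1, FP = -1); C and gamma come
from a cross-validated grid search.  Features are min-max scaled to [0, 1]
on the training set, the scaling stored with the model.  Training is capped
(default 100,000 candidates) by label-stratified subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .callset_io import REPEAT_CLASSES
from .errors import ConfigError, TrainingError
from .matching import MergedCall

_RT_INDEX = {name: i for i, name in enumerate(REPEAT_CLASSES)}


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||u - v||^2); 1 exactly when u == v, always in (0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    d = u - v
    return float(np.exp(-gamma * float(d @ d)))


def feature_names(callers: Sequence[str]) -> list[str]:
    return (
        [f"ds_{c}" for c in callers]
        + ["st"]
        + ["ss"]
        + [f"rt_{c}" for c in REPEAT_CLASSES]
        + ["reads"]
    )


def build_features(
    candidates: Sequence[MergedCall], callers: Sequence[str]
) -> np.ndarray:
    """Encode candidates as eigenvectors.

    DS: one 0/1 indicator per caller (at least one set); ST: 0 for deletions,
    1 for insertions; SS: size in bp; RT: one-hot over the seven repeat
    classes; reads: supporting reads summed over the detecting callers.
    """
    callers = list(callers)
    index = {c: i for i, c in enumerate(callers)}
    n_ds = len(callers)
    width = n_ds + 1 + 1 + len(REPEAT_CLASSES) + 1
    x = np.zeros((len(candidates), width))
    for row, cand in enumerate(candidates):
        if not cand.reads_by_caller:
            raise ConfigError("candidate with no detecting caller")
        for name, _ in cand.reads_by_caller:
            try:
                x[row, index[name]] = 1.0
            except KeyError:
                raise ConfigError(f"caller {name!r} not in the caller roster")
        x[row, n_ds] = 1.0 if cand.vtype == "INS" else 0.0
        x[row, n_ds + 1] = cand.size
        x[row, n_ds + 2 + _RT_INDEX[cand.repeat_class]] = 1.0
        x[row, -1] = cand.reads
    return x


#: Default search grids: powers-of-four ladders spanning the ranges the
#: libsvm practical guide recommends for a first coarse search.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 4))


@dataclass(frozen=True)
class SvmConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    folds: int = 5
    max_training: int = 100_000
    seed: int = 0
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ConfigError("C and gamma grids must be non-empty")
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ConfigError("C and gamma must be positive")
        if self.folds < 2:
            raise ConfigError("cross-validation needs >= 2 folds")
        if self.max_training < 1:
            raise ConfigError("max_training must be >= 1")


@dataclass
class SvmModel:
    """Trained screening classifier with its scaling and chosen (C, gamma)."""

    pipeline: Pipeline
    callers: tuple[str, ...]
    chosen_c: float
    chosen_gamma: float
    cv_accuracy: float
    config: SvmConfig = field(default_factory=SvmConfig)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(features)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(features)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str) -> "SvmModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ConfigError(f"{path} does not contain an SvmModel")
        return model


def subsample_training(
    features: np.ndarray,
    labels: np.ndarray,
    cap: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified random subset of at most *cap* training rows.

    Keeps the positive/negative ratio within one item of the full set's and
    is reproducible under the seed.  Returns everything when under the cap.
    """
    if cap < 1:
        raise ConfigError("cap must be >= 1")
    n = len(labels)
    if n <= cap:
        return features, labels
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    take: list[np.ndarray] = []
    # largest-remainder apportionment of the cap across classes
    sizes = {c: int(np.sum(labels == c)) for c in classes}
    quotas = {c: cap * sizes[c] / n for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    remainder = cap - sum(alloc.values())
    for c in sorted(classes, key=lambda c: quotas[c] - np.floor(quotas[c]), reverse=True):
        if remainder <= 0:
            break
        alloc[c] += 1
        remainder -= 1
    for c in classes:
        idx = np.flatnonzero(labels == c)
        chosen = rng.choice(idx, size=min(alloc[c], len(idx)), replace=False)
        take.append(np.sort(chosen))
    keep = np.concatenate(take)
    return features[keep], labels[keep]


def grid_search_train(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig,
    callers: Sequence[str],
) -> SvmModel:
    """Cross-validated grid search over (C, gamma), refit on the full subset.

    Accuracy is estimated with stratified k-fold CV at every grid point; the
    best point is refit on all training rows.  Min-max scaling is fitted
    inside each fold (and finally on the whole training set), so no
    information leaks from validation folds.  Deterministic under the seed.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    if len(present) < 2:
        raise TrainingError(
            "training needs both TP and FP examples; got only "
            f"{present.tolist()}"
        )
    features, labels = subsample_training(
        features, labels, config.max_training, config.seed
    )
    min_class = int(min(np.sum(labels == c) for c in np.unique(labels)))
    folds = max(2, min(config.folds, min_class))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    pipe = Pipeline(
        [
            ("scale", MinMaxScaler()),
            (
                "svc",
                SVC(kernel="rbf", class_weight=config.class_weight, random_state=0),
            ),
        ]
    )
    search = GridSearchCV(
        pipe,
        param_grid={
            "svc__C": list(config.c_grid),
            "svc__gamma": list(config.gamma_grid),
        },
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(features, labels)
    return SvmModel(
        pipeline=search.best_estimator_,
        callers=tuple(callers),
        chosen_c=float(search.best_params_["svc__C"]),
        chosen_gamma=float(search.best_params_["svc__gamma"]),
        cv_accuracy=float(search.best_score_),
        config=config,
    )


def train(
    candidates: Sequence[MergedCall],
    labels: Sequence[str],
    callers: Sequence[str],
    config: SvmConfig | None = None,
) -> SvmModel:
    """Featurize labeled candidates and train the screening classifier."""
    config = config or SvmConfig()
    x = build_features(candidates, callers)
    y = np.array([1 if lab == "TP" else -1 for lab in labels])
    return grid_search_train(x, y, config, callers)


def classify(
    model: SvmModel, candidates: Sequence[MergedCall]
) -> tuple[list[MergedCall], list[MergedCall]]:
    """Partition candidates into accepted (predicted TP) and rejected."""
    if not candidates:
        return [], []
    x = build_features(candidates, model.callers)
    pred = model.predict(x)
    accepted = [c for c, p in zip(candidates, pred) if p > 0]
    rejected = [c for c, p in zip(candidates, pred) if p <= 0]
    return accepted, rejected
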