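"""Balanced, permuted, cross-validated RBF-SVM evaluation protocol.

The cohort is imbalanced (more euvolemic than blood-loss recordings), so
the majority class is randomly undersampled to the minority size.  Because
both the subsample and the row order can sway 4-fold cross-validation on a
small dataset, the protocol repeats the whole evaluation over
``n_resamples`` balanced datasets x ``n_permutations`` row orders (default
10 x 10 = 100 runs) and averages overall accuracy (OA), sensitivity and
specificity per (gamma, C) grid cell.  Blood loss (BL) is the positive
class: sensitivity is the true-BL detection rate.

The SVM is the standard soft-margin binary classifier with Gaussian kernel
``K(x, y) = exp(-gamma * ||x - y||^2)`` and regularization ``C``
(delegated to the libsvm solver behind scikit-learn); the grid spans 7
gamma values and 58 C values covering 0.01 up to 5e18.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .exceptions import ConfigError, RecordError
from .io import validate_features

FEATURE_ORDER = ("r2", "slope", "pct_change", "abs_change")

#: iteration cap per SVM fit, to bound worst-case solver time at extreme C
_SVM_MAX_ITER = 200_000


@dataclass(frozen=True)
class ParamGrid:
    """The (gamma, C) grid of the evaluation protocol."""

    gamma_values: tuple[float, ...]
    c_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if min(self.gamma_values) <= 0 or min(self.c_values) <= 0:
            raise ConfigError("gamma and C must be positive")


def build_param_grid() -> ParamGrid:
    """Full default grid: 7 gammas; C = 0.01 plus {1,2,5}*10^i, i=0..18."""
    gammas = (0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2)
    cs = {0.01}
    for i in range(19):
        for m in (1.0, 2.0, 5.0):
            cs.add(m * 10.0 ** i)
    return ParamGrid(gamma_values=gammas, c_values=tuple(sorted(cs)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol shape: resamples x permutations runs of k-fold CV."""

    n_resamples: int = 10
    n_permutations: int = 10
    n_folds: int = 4
    seed: int = 0
    scaling: str = "none"
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.n_resamples < 1 or self.n_permutations < 1:
            raise ConfigError("need >= 1 resample and >= 1 permutation")
        if self.scaling not in ("none", "standardize"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")

    @property
    def n_runs(self) -> int:
        return self.n_resamples * self.n_permutations


@dataclass
class ConfusionCounts:
    """Accumulated CV confusion counts, BL positive."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __iadd__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        self.tp += other.tp
        self.fn += other.fn
        self.tn += other.tn
        self.fp += other.fp
        return self

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def overall_accuracy(self) -> float:
        n = self.tp + self.fn + self.tn + self.fp
        return 100.0 * (self.tp + self.tn) / n if n else 0.0


def balance_dataset(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Undersample the majority class to the minority size.

    Uniform draw without replacement, deterministic given ``seed``.  The
    output holds 2 x minority-size rows (original row order preserved
    within each class).
    """
    features = validate_features(features)
    counts = features["label"].value_counts()
    if len(counts) != 2 or (counts < 1).any():
        raise RecordError("balancing needs rows from both classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for label, group in features.groupby("label", sort=True):
        if len(group) > n_min:
            keep = np.sort(rng.choice(len(group), size=n_min, replace=False))
            group = group.iloc[keep]
        parts.append(group)
    return pd.concat(parts).reset_index(drop=True)


def _design(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    features = validate_features(features)
    X = features[list(FEATURE_ORDER)].to_numpy(float)
    y = (features["label"] == "BL").to_numpy().astype(int)
    return X, y


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator,
                      stratified: bool = True) -> list[np.ndarray]:
    """Disjoint test-fold index sets covering every record exactly once."""
    n = len(y)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    if stratified:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for k, i in enumerate(idx):
                folds[k % n_folds].append(int(i))
    else:
        idx = rng.permutation(n)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _cv_counts(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray],
               gamma: float, C: float, scaling: str = "none",
               K: np.ndarray | None = None) -> ConfusionCounts:
    """One k-fold CV pass; ``K`` may carry a precomputed RBF Gram matrix."""
    if not np.all(np.isfinite(X)):
        raise RecordError("non-finite feature value")
    counts = ConfusionCounts()
    all_idx = np.arange(len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for test in folds:
            if len(test) == 0:  # tiny datasets can leave a fold empty
                continue
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            if len(np.unique(y[train])) < 2:
                raise RecordError("training fold contains a single class; "
                                  "use stratified folds")
            if scaling == "standardize":
                mu = X[train].mean(axis=0)
                sd = X[train].std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="rbf", gamma=gamma, C=C,
                          max_iter=_SVM_MAX_ITER)
                clf.fit((X[train] - mu) / sd, y[train])
                pred = clf.predict((X[test] - mu) / sd)
            elif K is not None:
                clf = SVC(kernel="precomputed", C=C, max_iter=_SVM_MAX_ITER)
                clf.fit(K[np.ix_(train, train)], y[train])
                pred = clf.predict(K[np.ix_(test, train)])
            else:
                clf = SVC(kernel="rbf", gamma=gamma, C=C,
                          max_iter=_SVM_MAX_ITER)
                clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
            counts += ConfusionCounts(
                tp=int(((pred == 1) & (y[test] == 1)).sum()),
                fn=int(((pred == 0) & (y[test] == 1)).sum()),
                tn=int(((pred == 0) & (y[test] == 0)).sum()),
                fp=int(((pred == 1) & (y[test] == 0)).sum()))
    return counts


def run_cv(dataset: pd.DataFrame, gamma: float, C: float, n_folds: int = 4,
           seed: int = 0, scaling: str = "none",
           stratified: bool = True) -> ConfusionCounts:
    """Stratified k-fold CV of one (gamma, C) cell on one dataset."""
    X, y = _design(dataset)
    folds = _stratified_folds(y, n_folds, np.random.default_rng(seed),
                              stratified)
    return _cv_counts(X, y, folds, gamma, C, scaling)


@dataclass
class GridSearchResult:
    """Averaged metrics per grid cell plus the optimal cell and raw counts.

    ``counts`` has shape ``(n_runs, n_gamma, n_C, 4)`` (tp, fn, tn, fp per
    run); metric grids are percentages averaged over runs.
    """

    gamma_values: tuple[float, ...]
    c_values: tuple[float, ...]
    oa: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    counts: np.ndarray
    optimal_gamma: float
    optimal_c: float
    run_seeds: list[dict] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return self.counts.shape[0]

    def optimal_metrics(self) -> dict:
        gi = self.gamma_values.index(self.optimal_gamma)
        ci = self.c_values.index(self.optimal_c)
        return {
            "gamma": self.optimal_gamma,
            "C": self.optimal_c,
            "overall_accuracy_pct": float(self.oa[gi, ci]),
            "sensitivity_pct": float(self.sensitivity[gi, ci]),
            "specificity_pct": float(self.specificity[gi, ci]),
        }


def _iter_runs(features_bl: pd.DataFrame, features_nbl: pd.DataFrame,
               config: ExperimentConfig):
    """Yield one permuted, balanced dataset plus its fold seed per run.

    Seeds derive from the master seed via a splittable counter scheme so
    the whole experiment is a pure function of its inputs.
    """
    if len(features_bl) == 0 or len(features_nbl) == 0:
        raise RecordError("both classes must be non-empty")
    combined = pd.concat([validate_features(features_bl),
                          validate_features(features_nbl)],
                         ignore_index=True)
    root = np.random.SeedSequence(config.seed)
    for r in range(config.n_resamples):
        balance_seed = int(root.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
        balanced = balance_dataset(combined, balance_seed)
        for p in range(config.n_permutations):
            state = root.spawn(1)[0].generate_state(2) & 0x7FFFFFFF
            perm_seed, fold_seed = int(state[0]), int(state[1])
            order = np.random.default_rng(perm_seed).permutation(len(balanced))
            yield (balanced.iloc[order].reset_index(drop=True),
                   {"resample": r, "permutation": p,
                    "balance_seed": balance_seed, "perm_seed": perm_seed,
                    "fold_seed": fold_seed})


def run_experiment(features_bl: pd.DataFrame, features_nbl: pd.DataFrame,
                   config: ExperimentConfig = ExperimentConfig(),
                   grid: ParamGrid | None = None) -> GridSearchResult:
    """The full protocol: every grid cell evaluated in every run.

    For each of the ``n_resamples * n_permutations`` runs the balanced,
    permuted dataset and its fold partition are fixed, then every
    (gamma, C) cell is cross-validated on it.  Metrics are averaged over
    runs per cell; the optimal cell maximizes mean OA with ties broken by
    smaller C, then smaller gamma.
    """
    grid = grid or build_param_grid()
    n_g, n_c = len(grid.gamma_values), len(grid.c_values)
    counts = np.zeros((config.n_runs, n_g, n_c, 4), dtype=np.int64)
    run_seeds = []

    for run_idx, (dataset, seeds) in enumerate(
            _iter_runs(features_bl, features_nbl, config)):
        run_seeds.append(seeds)
        X, y = _design(dataset)
        folds = _stratified_folds(y, config.n_folds,
                                  np.random.default_rng(seeds["fold_seed"]),
                                  config.stratified)
        D = None
        if config.scaling == "none":
            D = squareform(pdist(X, metric="sqeuclidean"))
        for gi, gamma in enumerate(grid.gamma_values):
            K = np.exp(-gamma * D) if D is not None else None
            for ci, C in enumerate(grid.c_values):
                cc = _cv_counts(X, y, folds, gamma, C, config.scaling, K)
                counts[run_idx, gi, ci] = (cc.tp, cc.fn, cc.tn, cc.fp)

    tp, fn, tn, fp = (counts[..., i].astype(float) for i in range(4))
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.nan_to_num(100.0 * tp / (tp + fn)).mean(axis=0)
        spec = np.nan_to_num(100.0 * tn / (tn + fp)).mean(axis=0)
        oa = (100.0 * (tp + tn) / (tp + fn + tn + fp)).mean(axis=0)

    best = None
    for gi, gamma in enumerate(grid.gamma_values):
        for ci, C in enumerate(grid.c_values):
            key = (-oa[gi, ci], C, gamma)
            if best is None or key < best[0]:
                best = (key, gamma, C)
    return GridSearchResult(
        gamma_values=tuple(grid.gamma_values), c_values=tuple(grid.c_values),
        oa=oa, sensitivity=sens, specificity=spec, counts=counts,
        optimal_gamma=best[1], optimal_c=best[2], run_seeds=run_seeds)


def report(result: GridSearchResult) -> tuple[dict, str]:
    """Results JSON dict plus a human-readable confusion table.

    The 2x2 table is column-normalized (columns True BL / True NBL each
    sum to 100%): predicted-BL|true-BL is the sensitivity, predicted-NBL |
    true-NBL the specificity.
    """
    opt = result.optimal_metrics()
    sens = opt["sensitivity_pct"]
    spec = opt["specificity_pct"]
    payload = {
        "optimal": opt,
        "n_runs": result.n_runs,
        "gamma_values": list(result.gamma_values),
        "c_values": list(result.c_values),
        "overall_accuracy_pct": result.oa.tolist(),
        "sensitivity_pct": result.sensitivity.tolist(),
        "specificity_pct": result.specificity.tolist(),
        "confusion_matrix_pct": {
            "true_BL": {"predicted_BL": sens, "predicted_NBL": 100.0 - sens},
            "true_NBL": {"predicted_NBL": spec, "predicted_BL": 100.0 - spec},
        },
    }
    table = "\n".join([
        f"optimal gamma={opt['gamma']:g}  C={opt['C']:g}  "
        f"(averaged over {result.n_runs} runs)",
        "                 True BL    True NBL",
        f"Predicted BL   {sens:8.2f}%  {100.0 - spec:8.2f}%",
        f"Predicted NBL  {100.0 - sens:8.2f}%  {spec:8.2f}%",
        f"OA             {opt['overall_accuracy_pct']:8.2f}%",
    ])
    return payload, table


def result_to_json(result: GridSearchResult) -> str:
    payload, _ = report(result)
    return json.dumps(payload, indent=2, sort_keys=True)
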