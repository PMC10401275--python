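"""Random grid search and the gradient-boosting stacked ensemble.

Hyperparameter tuning draws up to 50 distinct combinations uniformly
without replacement from the algorithm's finite grid and scores each with a
shared 10-fold cross-validation by mean squared out-of-fold error; the
lowest MSE wins (ties to sampling order).

The stacked ensemble ranks the tuned models by CV MSE and trains a ridge
super learner on the out-of-fold prediction matrix of the best k models for
k in {5, 10, ..., 50}; k is chosen by the Pearson correlation between the
response and the super learner's own out-of-fold predictions (reusing the
same folds), ties to the smallest k.  The super learner never sees a base
model's in-fold predictions.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import Ridge

from hybfact.features import FeatureTable
from hybfact.learners import ModelSpec, enumerate_space, fit_predict, space_size

logger = logging.getLogger(__name__)

DEFAULT_N_MODELS = 50
DEFAULT_FOLDS = 10
DEFAULT_KS = tuple(range(5, 51, 5))
RIDGE_LAMBDA_GRID = tuple(np.geomspace(1e-4, 1e2, 13))


@dataclass
class GridSearchResult:
    specs: list[ModelSpec]
    cv_mse: np.ndarray                # nan for failed specs
    oof_predictions: np.ndarray       # n_specs x n_train, nan rows for failures
    fold_assignment: np.ndarray       # training row -> fold index 0..folds-1
    failed: list[int] = field(default_factory=list)

    @property
    def best_index(self) -> int:
        ok = np.where(np.isfinite(self.cv_mse))[0]
        if len(ok) == 0:
            raise RuntimeError("every spec failed during grid search")
        return int(ok[np.argmin(self.cv_mse[ok])])

    @property
    def best_spec(self) -> ModelSpec:
        return self.specs[self.best_index]

    def ranked_indices(self) -> list[int]:
        """Non-failed spec indices by ascending CV MSE (stable in sampling order)."""
        ok = [i for i in range(len(self.specs)) if np.isfinite(self.cv_mse[i])]
        return sorted(ok, key=lambda i: (self.cv_mse[i], i))


def sample_hyperparameters(
    algorithm: str, n: int = DEFAULT_N_MODELS, seed: int = 0
) -> list[ModelSpec]:
    """Sample up to ``n`` distinct hyperparameter combinations uniformly
    without replacement; a space with <= n combinations is returned whole
    (in randomized order)."""
    rng = np.random.default_rng(seed)
    total = space_size(algorithm)
    if total <= n:
        combos = enumerate_space(algorithm)
        rng.shuffle(combos)
        return [ModelSpec(algorithm, params, seed=seed) for params in combos]
    space = {k: list(v) for k, v in _space(algorithm).items()}
    names = list(space)
    sizes = [len(space[k]) for k in names]
    flat = rng.choice(total, size=n, replace=False)
    specs = []
    for f in flat:
        params = {}
        for name, size in zip(names, sizes):
            f, r = divmod(f, size)
            params[name] = space[name][r]
        specs.append(ModelSpec(algorithm, params, seed=seed))
    return specs


def _space(algorithm: str) -> dict:
    from hybfact.learners import HYPERPARAMETER_SPACES

    return HYPERPARAMETER_SPACES[algorithm]


def make_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """One shared random partition of n rows into ``folds`` near-equal folds."""
    rng = np.random.default_rng(seed)
    assignment = np.tile(np.arange(folds), -(-n // folds))[:n]
    rng.shuffle(assignment)
    return assignment


def run_grid_search(
    specs: list[ModelSpec],
    X_train: FeatureTable,
    y_train: np.ndarray,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    fit_predict_fn=fit_predict,
) -> GridSearchResult:
    """Score every spec by 10-fold out-of-fold MSE on one shared partition.

    A learner failure on any fold flags the whole spec as failed (logged,
    excluded from ranking) rather than aborting the search.
    ``fit_predict_fn`` allows oracle injection in tests.
    """
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} training rows")
    assignment = make_folds(n, folds, seed)
    oof = np.full((len(specs), n), np.nan)
    mse = np.full(len(specs), np.nan)
    failed: list[int] = []
    for s, spec in enumerate(specs):
        try:
            for f in range(folds):
                te = assignment == f
                Xtr = _subset(X_train, ~te)
                Xte = _subset(X_train, te)
                oof[s, te] = fit_predict_fn(spec, Xtr, y[~te], Xte)
            mse[s] = float(np.mean((y - oof[s]) ** 2))
        except Exception as exc:  # noqa: BLE001 - spec-level failure isolation
            logger.warning("spec %d (%s) failed: %s", s, spec.algorithm, exc)
            failed.append(s)
            oof[s] = np.nan
            mse[s] = np.nan
    return GridSearchResult(list(specs), mse, oof, assignment, failed)


def _subset(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    keys = [k for k, m in zip(table.row_keys, mask) if m]
    return FeatureTable(keys, table.table.loc[mask], table.encoding_kind)


@dataclass
class StackedEnsemble:
    base_specs: list[ModelSpec]       # ranked by cv_mse, best first
    k: int
    super_intercept: float
    super_coefs: np.ndarray
    ridge_lambda: float
    cv_r_by_k: dict[int, float]
    base_indices: list[int]           # positions in the originating grid

    def combine(self, base_predictions: np.ndarray) -> np.ndarray:
        """Apply the super learner to a targets x k base-prediction matrix."""
        if base_predictions.shape[1] != self.k:
            raise ValueError(f"expected {self.k} base prediction columns")
        return self.super_intercept + base_predictions @ self.super_coefs


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant predictions: correlation scored as 0")
        return 0.0
    return float(sps.pearsonr(a, b).statistic)


def _ridge_lambda_cv(Z: np.ndarray, y: np.ndarray, seed: int = 0) -> float:
    """Pick the ridge penalty by internal 5-fold CV over a geometric grid."""
    n = len(y)
    inner = make_folds(n, min(5, n), seed)
    best_lam, best_err = RIDGE_LAMBDA_GRID[0], np.inf
    for lam in RIDGE_LAMBDA_GRID:
        err = 0.0
        for f in range(inner.max() + 1):
            te = inner == f
            model = Ridge(alpha=lam).fit(Z[~te], y[~te])
            err += float(np.sum((y[te] - model.predict(Z[te])) ** 2))
        if err < best_err - 1e-12:
            best_err, best_lam = err, lam
    return float(best_lam)


def build_stacked_ensemble(
    grid: GridSearchResult,
    y_train: np.ndarray,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> StackedEnsemble:
    """Rank base models and pick the ensemble size by out-of-fold Pearson r."""
    y = np.asarray(y_train, dtype=float)
    ranked = grid.ranked_indices()
    feasible = [k for k in ks if k <= len(ranked)]
    if not feasible:
        if not ranked:
            raise RuntimeError("no non-failed base models to stack")
        feasible = [len(ranked)]  # fewer models than the smallest requested k
    assignment = grid.fold_assignment
    folds = int(assignment.max()) + 1

    results: dict[int, tuple[float, float, float, np.ndarray]] = {}
    cv_r_by_k: dict[int, float] = {}
    for k in feasible:
        top = ranked[:k]
        Z = grid.oof_predictions[top].T  # n x k, leakage-safe by construction
        if np.allclose(Z.var(axis=0), 0.0):
            warnings.warn(f"k={k}: constant out-of-fold base predictions, scored 0")
            final = Ridge(alpha=RIDGE_LAMBDA_GRID[0]).fit(Z, y)
            cv_r_by_k[k] = 0.0
            results[k] = (0.0, RIDGE_LAMBDA_GRID[0], float(final.intercept_), final.coef_.copy())
            continue
        lam = _ridge_lambda_cv(Z, y)
        oof_super = np.full(len(y), np.nan)
        for f in range(folds):
            te = assignment == f
            model = Ridge(alpha=lam).fit(Z[~te], y[~te])
            oof_super[te] = model.predict(Z[te])
        r = _safe_pearson(y, oof_super)
        final = Ridge(alpha=lam).fit(Z, y)
        cv_r_by_k[k] = r
        results[k] = (r, lam, float(final.intercept_), final.coef_.copy())

    k_star = max(feasible, key=lambda k: (cv_r_by_k[k], -k))
    r, lam, intercept, coefs = results[k_star]
    return StackedEnsemble(
        base_specs=[grid.specs[i] for i in ranked[:k_star]],
        k=k_star,
        super_intercept=intercept,
        super_coefs=coefs,
        ridge_lambda=lam,
        cv_r_by_k=cv_r_by_k,
        base_indices=ranked[:k_star],
    )


def predict_ensemble(
    se: StackedEnsemble,
    X_train: FeatureTable,
    y_train: np.ndarray,
    X_test: FeatureTable,
    fit_predict_fn=fit_predict,
) -> np.ndarray:
    """Refit the k base models on the full training data and combine them
    with the ridge super learner."""
    y = np.asarray(y_train, dtype=float)
    base_preds = np.column_stack(
        [fit_predict_fn(spec, X_train, y, X_test) for spec in se.base_specs]
    )
    return se.combine(base_preds)


def hyperparameter_mse_correlations(grid: GridSearchResult) -> dict[str, float | None]:
    """Pearson r between each numeric hyperparameter and CV MSE across the
    non-failed grid entries; constant columns report ``None``."""
    ok = [i for i in range(len(grid.specs)) if np.isfinite(grid.cv_mse[i])]
    if len(ok) < 3:
        raise ValueError("need at least 3 non-failed grid entries")
    mse = grid.cv_mse[ok]
    names = sorted({name for i in ok for name in grid.specs[i].params})
    out: dict[str, float | None] = {}
    for name in names:
        vals = [grid.specs[i].params.get(name) for i in ok]
        if any(v is None or isinstance(v, str) for v in vals):
            continue  # non-numeric hyperparameter
        arr = np.asarray(vals, dtype=float)
        if np.ptp(arr) == 0 or np.std(mse) == 0:
            out[name] = None
        else:
            out[name] = float(sps.pearsonr(arr, mse).statistic)
    return out
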