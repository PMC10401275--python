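"""Uniform fit/predict interface over the base regression algorithms.

Algorithms
----------
``gb``
    Gradient boosting on parentage or yield features (LightGBM backend,
    learning rate fixed at 0.1).  Categorical parent columns are grouped
    into at most ``nbins_cats`` target-mean-ordered bins before split
    search (histogram boosting on high-cardinality factors).
``gb-marker``
    Gradient boosting tuned for marker matrices: fixed 1000 trees with
    early stopping, tuned learning rate, pruning parameter gamma and
    per-tree column subsampling.
``rf``
    Random forest (same parameters as ``gb`` minus the learning rate).
``svm``
    Epsilon-insensitive support vector regression with linear, polynomial
    or radial kernel; parentage is one-hot expanded, missing values are
    imputed with training-column means, columns are standardized.
``rkhs``
    Gaussian multi-kernel regression: three kernels exp(-h D) at
    bandwidths 0.1/0.5/2.5 on the scaled squared marker distance, with
    per-kernel variances estimated by REML (no tuning).
``mf``
    Matrix factorization of the parents1 x parents2 yield matrix by SGD
    with L1 penalties; learning rate 0.05 and 500 epochs are fixed, no
    bias terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from hybfact.features import FeatureTable
from hybfact.reml import fit_reml

ALGORITHMS = ("gb", "gb-marker", "rf", "svm", "rkhs", "mf")

RKHS_BANDWIDTHS = (0.1, 0.5, 2.5)
GB_LEARN_RATE = 0.1
MF_LRATE = 0.05
MF_NITERS = 500
GB_MARKER_N_TREES = 1000
GB_MARKER_PATIENCE = 10


@dataclass
class ModelSpec:
    """One algorithm + hyperparameter combination."""

    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        space = HYPERPARAMETER_SPACES.get(self.algorithm, {})
        for name, value in self.params.items():
            if name not in space:
                raise ValueError(f"{self.algorithm} has no hyperparameter {name!r}")
            if value not in space[name]:
                raise ValueError(f"{name}={value!r} outside the declared space")

    def key(self) -> tuple:
        return (self.algorithm, tuple(sorted(self.params.items())))


#: finite per-parameter grids for the random grid search
HYPERPARAMETER_SPACES: dict[str, dict[str, list]] = {
    "gb": {
        "n_trees": [50, 100, 200, 400, 800],
        "max_depth": list(range(2, 13)),
        "min_rows": [1, 2, 5, 10, 20],
        "sample_rate": [0.5, 0.632, 0.8, 1.0],
        "nbins_cats": [8, 16, 32, 64, 128, 256, 512, 1024],
    },
    "gb-marker": {
        "learn_rate": [0.01, 0.05, 0.1, 0.3],
        "gamma": [0, 0.1, 1, 10],
        "colsample": [0.3, 0.5, 0.8, 1.0],
    },
    "rf": {
        "n_trees": [50, 100, 200, 400, 800],
        "max_depth": list(range(2, 13)),
        "min_rows": [1, 2, 5, 10, 20],
        "sample_rate": [0.5, 0.632, 0.8, 1.0],
        "nbins_cats": [8, 16, 32, 64, 128, 256, 512, 1024],
    },
    "svm": {
        "C": [0.1, 1, 10, 100],
        "epsilon": [0.01, 0.1, 0.5],
        "kernel": ["linear", "poly2", "poly3", "poly4", "radial"],
    },
    "mf": {
        "dim": [2, 4, 8, 16, 32],
        "costp_l1": [0, 0.001, 0.01, 0.1],
        "costq_l1": [0, 0.001, 0.01, 0.1],
    },
    "rkhs": {},
}


def space_size(algorithm: str) -> int:
    space = HYPERPARAMETER_SPACES[algorithm]
    return int(np.prod([len(v) for v in space.values()])) if space else 1


def enumerate_space(algorithm: str) -> list[dict]:
    space = HYPERPARAMETER_SPACES[algorithm]
    names = list(space)
    return [dict(zip(names, combo)) for combo in itertools.product(*space.values())]


# ---------------------------------------------------------------------------
# preprocessing helpers
# ---------------------------------------------------------------------------

def _bin_categoricals(
    train: pd.DataFrame, test: pd.DataFrame, y: np.ndarray, nbins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Target-mean-ordered binning of categorical columns to ordinal codes.

    Levels are ranked by their training target mean and grouped into at
    most ``nbins`` bins; levels unseen in training become missing.  Numeric
    columns pass through unchanged.
    """
    def one(df_tr: pd.Series, df_te: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        means = pd.Series(y, index=df_tr.index).groupby(df_tr, observed=True).mean()
        order = means.sort_values(kind="stable").index
        rank = {lvl: r for r, lvl in enumerate(order)}
        width = max(1, int(np.ceil(len(order) / nbins)))
        bin_of = {lvl: r // width for lvl, r in rank.items()}
        tr = df_tr.map(bin_of).to_numpy(dtype=float)
        te = df_te.map(bin_of).to_numpy(dtype=float)
        return tr, te

    tr_cols, te_cols = [], []
    for col in train.columns:
        if isinstance(train[col].dtype, pd.CategoricalDtype) or train[col].dtype == object:
            tr, te = one(train[col], test[col])
        else:
            tr = train[col].to_numpy(dtype=float)
            te = test[col].to_numpy(dtype=float)
        tr_cols.append(tr)
        te_cols.append(te)
    return np.column_stack(tr_cols), np.column_stack(te_cols)


def _numeric_matrices(
    X_train: FeatureTable, X_test: FeatureTable, y: np.ndarray, nbins: int | None
) -> tuple[np.ndarray, np.ndarray]:
    if X_train.column_names != X_test.column_names:
        raise ValueError("train/test feature schemas differ")
    nbins = nbins or 1024
    return _bin_categoricals(X_train.table, X_test.table, y, nbins)


def _categorical_code_matrices(
    X_train: FeatureTable, X_test: FeatureTable
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Integer-code categorical columns and report their indices.

    Category sets are fixed on the FeatureTable (the factorial's parent
    lists), so train and test codes are consistent.  Used by the GB wrapper,
    whose backend splits categorical features natively.
    """
    if X_train.column_names != X_test.column_names:
        raise ValueError("train/test feature schemas differ")

    def codes(df: pd.DataFrame, reference: pd.DataFrame):
        cols, cat_idx = [], []
        for k, col in enumerate(df.columns):
            ref = reference[col]
            if isinstance(ref.dtype, pd.CategoricalDtype):
                aligned = df[col].cat.set_categories(ref.cat.categories)
                c = aligned.cat.codes.to_numpy(dtype=float)
                c[c < 0] = np.nan
                cols.append(c)
                cat_idx.append(k)
            elif ref.dtype == object:
                mapping = {v: i for i, v in enumerate(pd.unique(ref.dropna()))}
                cols.append(df[col].map(mapping).to_numpy(dtype=float))
                cat_idx.append(k)
            else:
                cols.append(df[col].to_numpy(dtype=float))
        return np.column_stack(cols), cat_idx

    tr, cat_idx = codes(X_train.table, X_train.table)
    te, _ = codes(X_test.table, X_train.table)
    return tr, te, cat_idx


def _onehot_matrices(X_train: FeatureTable, X_test: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """One-hot expand categorical columns (category sets are fixed by the
    factorial, so train and test expand identically)."""
    def expand(df: pd.DataFrame) -> pd.DataFrame:
        parts = []
        for col in df.columns:
            if isinstance(df[col].dtype, pd.CategoricalDtype) or df[col].dtype == object:
                parts.append(pd.get_dummies(df[col], prefix=col, dtype=float))
            else:
                parts.append(df[[col]].astype(float))
        return pd.concat(parts, axis=1)

    tr, te = expand(X_train.table), expand(X_test.table)
    te = te.reindex(columns=tr.columns, fill_value=0.0)
    return tr.to_numpy(), te.to_numpy()


def _impute_standardize(tr: np.ndarray, te: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-column-mean imputation then z-scaling (training statistics)."""
    mean = np.nanmean(tr, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    tr = np.where(np.isnan(tr), mean, tr)
    te = np.where(np.isnan(te), mean, te)
    sd = tr.std(axis=0)
    sd[sd == 0] = 1.0
    return (tr - mean) / sd, (te - mean) / sd


# ---------------------------------------------------------------------------
# individual learners
# ---------------------------------------------------------------------------

def _fit_predict_gb(spec: ModelSpec, Xtr, ytr, Xte, cat_idx: list[int] | None = None) -> np.ndarray:
    p = spec.params
    n_trees = p.get("n_trees", 100)
    if n_trees == 0:
        return np.full(len(Xte), float(np.mean(ytr)))
    sample_rate = float(p.get("sample_rate", 1.0))
    params = {
        "objective": "regression",
        "learning_rate": GB_LEARN_RATE,
        "max_depth": int(p.get("max_depth", 6)),
        "num_leaves": int(min(2 ** min(int(p.get("max_depth", 6)), 12), 128)),
        "min_data_in_leaf": int(p.get("min_rows", 1)),
        "min_sum_hessian_in_leaf": 0.0,
        "num_threads": 1,
        "verbose": -1,
        "seed": spec.seed,
        "deterministic": True,
        "force_col_wise": True,
    }
    if cat_idx:
        # nbins_cats bounds the number of level groups a categorical split
        # may consider (histogram treatment of high-cardinality factors);
        # parent lines can have very few crosses, so the per-group floor is
        # lifted and min_rows alone governs leaf sizes
        params["max_cat_threshold"] = int(p.get("nbins_cats", 1024))
        params["min_data_per_group"] = 1
    if sample_rate < 1.0:
        params.update({"bagging_fraction": sample_rate, "bagging_freq": 1})
    ds = lgb.Dataset(
        Xtr, label=ytr,
        categorical_feature=cat_idx or "auto",
        params={"verbose": -1, "min_data_in_bin": 1},
    )
    booster = lgb.train(params, ds, num_boost_round=int(n_trees))
    return booster.predict(Xte)


def _fit_predict_gb_marker(spec: ModelSpec, Xtr, ytr, Xte, rng) -> np.ndarray:
    p = spec.params
    n = len(ytr)
    # deterministic 10% carve-out for early stopping
    val_idx = rng.choice(n, size=max(1, n // 10), replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[val_idx] = True
    params = {
        "objective": "regression",
        "learning_rate": float(p.get("learn_rate", 0.1)),
        "min_split_gain": float(p.get("gamma", 0.0)),
        "feature_fraction": float(p.get("colsample", 1.0)),
        "num_threads": 1,
        "verbose": -1,
        "seed": spec.seed,
        "deterministic": True,
        "force_col_wise": True,
    }
    ds_tr = lgb.Dataset(Xtr[~mask], label=ytr[~mask], params={"verbose": -1, "min_data_in_bin": 1})
    ds_val = lgb.Dataset(
        Xtr[mask], label=ytr[mask], reference=ds_tr,
        params={"verbose": -1, "min_data_in_bin": 1},
    )
    booster = lgb.train(
        params,
        ds_tr,
        num_boost_round=GB_MARKER_N_TREES,
        valid_sets=[ds_val],
        callbacks=[lgb.early_stopping(GB_MARKER_PATIENCE, verbose=False)],
    )
    return booster.predict(Xte, num_iteration=booster.best_iteration)


def _fit_predict_rf(spec: ModelSpec, Xtr, ytr, Xte) -> np.ndarray:
    p = spec.params
    sample_rate = float(p.get("sample_rate", 1.0))
    model = RandomForestRegressor(
        n_estimators=int(p.get("n_trees", 200)),
        max_depth=int(p.get("max_depth", 6)),
        min_samples_leaf=int(p.get("min_rows", 1)),
        max_samples=None if sample_rate >= 1.0 else sample_rate,
        random_state=spec.seed,
        n_jobs=1,
    )
    # sklearn forests do not accept missing values
    mean = np.nanmean(Xtr, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    model.fit(np.where(np.isnan(Xtr), mean, Xtr), ytr)
    return model.predict(np.where(np.isnan(Xte), mean, Xte))


def _fit_predict_svm(spec: ModelSpec, Xtr, ytr, Xte) -> np.ndarray:
    p = spec.params
    kernel = p.get("kernel", "radial")
    degree = 3
    if kernel.startswith("poly"):
        degree = int(kernel[4:])
        kernel = "poly"
    elif kernel == "radial":
        kernel = "rbf"
    model = SVR(C=float(p.get("C", 1.0)), epsilon=float(p.get("epsilon", 0.1)),
                kernel=kernel, degree=degree)
    model.fit(Xtr, ytr)
    return model.predict(Xte)


def fit_mf(
    matrix: np.ndarray,
    dim: int,
    costp_l1: float = 0.0,
    costq_l1: float = 0.0,
    lrate: float = MF_LRATE,
    niters: int = MF_NITERS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """SGD matrix factorization of a partially observed yield matrix.

    ``matrix`` is parents1 x parents2 with ``nan`` for unobserved cells.
    Minimizes sum over observed cells of (y_ij - P_i . Q_j)^2 plus L1
    penalties on P and Q; no bias terms.  Returns (P, Q, history) where
    ``history`` is the mean squared training error after each epoch (a
    held-in monitor; non-increasing up to SGD noise).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    obs = ~np.isnan(matrix)
    if not obs.any(axis=1).all() or not obs.any(axis=0).all():
        raise ValueError("every row and column needs at least one observed cell")
    n1, n2 = matrix.shape
    rows, cols = np.where(obs)
    vals = matrix[rows, cols]
    rng = np.random.default_rng(seed)
    # initialize so that P_i . Q_j starts near the grand mean of the
    # observed cells, which stabilizes SGD on uncentered yields
    m = float(vals.mean())
    base = np.sqrt(abs(m) / dim) if m != 0 else 0.0
    P = np.sign(m or 1.0) * base + rng.normal(0.0, 0.05, (n1, dim))
    Q = base + rng.normal(0.0, 0.05, (n2, dim))
    history: list[float] = []
    order = np.arange(len(vals))
    for _ in range(niters):
        rng.shuffle(order)
        for t in order:
            i, j, v = rows[t], cols[t], vals[t]
            e = v - P[i] @ Q[j]
            p_old = P[i].copy()
            P[i] += lrate * (e * Q[j] - costp_l1 * np.sign(P[i]))
            Q[j] += lrate * (e * p_old - costq_l1 * np.sign(Q[j]))
        resid = vals - np.einsum("ij,ij->i", P[rows], Q[cols])
        history.append(float(np.mean(resid**2)))
    return P, Q, history


def _fit_predict_mf(spec: ModelSpec, X_train: FeatureTable, ytr, X_test: FeatureTable) -> np.ndarray:
    p1_levels = list(dict.fromkeys([i for i, _ in X_train.row_keys + X_test.row_keys]))
    p2_levels = list(dict.fromkeys([j for _, j in X_train.row_keys + X_test.row_keys]))
    i1 = {p: k for k, p in enumerate(p1_levels)}
    i2 = {p: k for k, p in enumerate(p2_levels)}
    matrix = np.full((len(p1_levels), len(p2_levels)), np.nan)
    for (i, j), v in zip(X_train.row_keys, ytr):
        matrix[i1[i], i2[j]] = v
    # rows/columns observed only in test carry no training signal; give
    # them the grand mean via a zero-information pseudo-cell
    mean_y = float(np.mean(ytr))
    for k in range(matrix.shape[0]):
        if np.isnan(matrix[k]).all():
            matrix[k, 0] = mean_y
    for k in range(matrix.shape[1]):
        if np.isnan(matrix[:, k]).all():
            matrix[0, k] = mean_y
    p = spec.params
    P, Q, _ = fit_mf(
        matrix,
        dim=int(p.get("dim", 8)),
        costp_l1=float(p.get("costp_l1", 0.0)),
        costq_l1=float(p.get("costq_l1", 0.0)),
        seed=spec.seed,
    )
    return np.array([P[i1[i]] @ Q[i2[j]] for i, j in X_test.row_keys])


def rkhs_fit_predict(
    K_train_list: list[np.ndarray],
    K_cross_list: list[np.ndarray],
    y_train: np.ndarray,
) -> np.ndarray:
    """Multi-kernel ridge with REML-estimated per-kernel variances.

    Fits y = mu + sum_k u_k + e with u_k ~ N(0, sigma2_k K_k) by REML and
    predicts targets via their cross-covariance rows; linear in y.
    """
    y_train = np.asarray(y_train, dtype=float)
    n = len(y_train)
    X = np.ones((n, 1))
    jittered = [K + 1e-8 * np.eye(n) for K in K_train_list]
    for k, K in enumerate(jittered):
        if np.linalg.eigvalsh(K).min() < -1e-8:
            raise ValueError(f"kernel {k} is not positive semidefinite after jitter")
    fit = fit_reml(y_train, X, jittered)
    pred = np.full(K_cross_list[0].shape[0], float(fit.beta[0]))
    for k, Kc in enumerate(K_cross_list):
        pred = pred + fit.gammas[k] * (Kc @ fit.vinv_resid)
    return pred


def marker_distance_kernels(
    Xtr: np.ndarray, Xte: np.ndarray, bandwidths=RKHS_BANDWIDTHS
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gaussian kernels exp(-h D) on squared marker distance scaled by its
    mean over training pairs."""
    from scipy.spatial.distance import cdist

    D_tr = cdist(Xtr, Xtr, "sqeuclidean")
    scale = D_tr.mean()
    if scale == 0:
        scale = 1.0
    D_tr = D_tr / scale
    D_te = cdist(Xte, Xtr, "sqeuclidean") / scale
    K_train = [np.exp(-h * D_tr) for h in bandwidths]
    K_cross = [np.exp(-h * D_te) for h in bandwidths]
    return K_train, K_cross


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def fit_predict(
    spec: ModelSpec,
    X_train: FeatureTable,
    y_train: np.ndarray,
    X_test: FeatureTable,
) -> np.ndarray:
    """Fit ``spec`` on the training table and predict the test rows.

    Deterministic given ``spec.seed``; raises on schema mismatch or
    non-finite responses.
    """
    if X_train.column_names != X_test.column_names:
        raise ValueError("train/test feature schemas differ")
    y = np.asarray(y_train, dtype=float)
    if len(y) != len(X_train.row_keys):
        raise ValueError("y_train length does not match X_train")
    if not np.isfinite(y).all():
        raise ValueError("non-finite training responses")
    if np.ptp(y) == 0:  # constant response: every regressor returns it
        return np.full(len(X_test.row_keys), float(y[0]))

    alg = spec.algorithm
    rng = np.random.default_rng(spec.seed)
    if alg == "gb":
        Xtr, Xte, cat_idx = _categorical_code_matrices(X_train, X_test)
        return _fit_predict_gb(spec, Xtr, y, Xte, cat_idx=cat_idx)
    if alg == "gb-marker":
        Xtr, Xte = _numeric_matrices(X_train, X_test, y, spec.params.get("nbins_cats"))
        return _fit_predict_gb_marker(spec, Xtr, y, Xte, rng)
    if alg == "rf":
        Xtr, Xte = _numeric_matrices(X_train, X_test, y, spec.params.get("nbins_cats"))
        return _fit_predict_rf(spec, Xtr, y, Xte)
    if alg == "svm":
        Xtr, Xte = _onehot_matrices(X_train, X_test)
        Xtr, Xte = _impute_standardize(Xtr, Xte)
        return _fit_predict_svm(spec, Xtr, y, Xte)
    if alg == "rkhs":
        Xtr, Xte = _onehot_matrices(X_train, X_test)
        Xtr, Xte = _impute_standardize(Xtr, Xte)
        K_train, K_cross = marker_distance_kernels(Xtr, Xte)
        return rkhs_fit_predict(K_train, K_cross, y)
    if alg == "mf":
        return _fit_predict_mf(spec, X_train, y, X_test)
    raise ValueError(f"unknown algorithm {alg!r}")  # pragma: no cover
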