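"""Cross-validation protocol, accuracy metrics, and the benchmark harness.

The protocol repeatedly splits a factorial into 90% training and 10% test
hybrids, removes test hybrids for which either parent is absent from the
training crosses (combining-ability prediction needs both), trains each
requested predictor on the training crosses only — with all test yields
also excluded from any yield-derived feature — and scores the predictions
by Pearson correlation with the observed test yields ("prediction
accuracy") and by the percentage overlap of the 20 best predicted with the
20 best observed hybrids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from hybfact.containers import Factorial, Pair
from hybfact.features import encode_parentage, encode_yield_features
from hybfact.gblup import RelationshipMatrices, fit_gblup, predict_gblup
from hybfact.gca_blup import fit_gca_blup, predict_gca
from hybfact.tuning import (
    DEFAULT_FOLDS,
    DEFAULT_N_MODELS,
    build_stacked_ensemble,
    predict_ensemble,
    run_grid_search,
    sample_hyperparameters,
)

logger = logging.getLogger(__name__)

ML_ALGORITHMS = ("gb", "rf", "svm", "mf")


@dataclass
class CvSplit:
    split_id: int
    train_pairs: list[Pair]
    test_pairs: list[Pair]
    removed_pairs: list[Pair]


def make_cv_splits(
    factorial: Factorial,
    n_splits: int = 100,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> list[CvSplit]:
    """Random 90/10 splits with parent-coverage filtering of the test set.

    A split whose filtered test set is empty is regenerated from a
    perturbed sub-seed (up to 10 attempts, logged).
    """
    pairs = factorial.pairs()
    n = len(pairs)
    if n < 10:
        raise ValueError("need at least 10 realized crosses for 90/10 splits")
    n_test = int(round(test_fraction * n))
    if n_test < 1:
        raise ValueError("test fraction yields an empty test set")
    root = np.random.SeedSequence(seed)
    out: list[CvSplit] = []
    for split_id, child in enumerate(root.spawn(n_splits)):
        for attempt in range(10):
            rng = np.random.default_rng(child if attempt == 0 else np.random.SeedSequence(
                entropy=child.entropy, spawn_key=(*child.spawn_key, 1000 + attempt)))
            test_idx = rng.choice(n, size=n_test, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[test_idx] = True
            train = [p for p, m in zip(pairs, mask) if not m]
            test_all = [p for p, m in zip(pairs, mask) if m]
            tr1 = {i for i, _ in train}
            tr2 = {j for _, j in train}
            test = [(i, j) for i, j in test_all if i in tr1 and j in tr2]
            removed = [p for p in test_all if p not in set(test)]
            if test:
                out.append(CvSplit(split_id, train, test, removed))
                break
            logger.info("split %d attempt %d: empty filtered test set, regenerating", split_id, attempt)
        else:
            raise RuntimeError(f"split {split_id}: filtered test set empty after 10 attempts")
    return out


def prediction_accuracy(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed and predicted yields."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred) or len(y_obs) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(y_obs) == 0:
        raise ValueError("constant observed yields: accuracy undefined")
    if np.std(y_pred) == 0:
        warnings.warn("constant predictions: accuracy scored as 0")
        return 0.0
    return float(sps.pearsonr(y_obs, y_pred).statistic)


def top_k_overlap(y_obs: np.ndarray, y_pred: np.ndarray, k: int = 20) -> float:
    """Percentage overlap of the k best predicted and k best observed
    hybrids (k capped at n; ranking ties broken by stable input order)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise ValueError("length mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, len(y_obs))
    top_obs = set(np.argsort(-y_obs, kind="stable")[:k_eff])
    top_pred = set(np.argsort(-y_pred, kind="stable")[:k_eff])
    return 100.0 * len(top_obs & top_pred) / k_eff


@dataclass
class BenchmarkConfig:
    n_splits: int = 20
    test_fraction: float = 0.10
    n_models: int = DEFAULT_N_MODELS
    folds: int = DEFAULT_FOLDS
    top_k: int = 20
    seed: int = 0
    encoding: str = "parentage"      # parentage | yield-features for ML learners
    reuse_tuning: bool = False       # tune on the first split only (speed switch)


@dataclass
class BenchmarkResult:
    table: pd.DataFrame              # split_id, algorithm, encoding, accuracy, top20_overlap
    failures: list[tuple[int, str, str]] = field(default_factory=list)

    def medians(self) -> pd.DataFrame:
        return (
            self.table.groupby("algorithm")[["accuracy", "top20_overlap"]]
            .median()
            .reset_index()
        )

    def flagged_algorithms(self) -> list[str]:
        """Algorithms failing on more than half of their splits."""
        out = []
        n_fail = pd.Series([a for _, a, _ in self.failures]).value_counts()
        if "algorithm" in self.table.columns:
            n_ok = self.table["algorithm"].value_counts()
        else:
            n_ok = pd.Series(dtype=int)
        for alg, fails in n_fail.items():
            if fails > n_ok.get(alg, 0):
                out.append(alg)
        return out


def _ml_predictions(
    algorithm: str,
    factorial: Factorial,
    split: CvSplit,
    config: BenchmarkConfig,
    seed: int,
    fit_predict_fn=None,
    tuning_cache: dict | None = None,
) -> np.ndarray:
    """Grid search + (for gb-se) stacking on one training set, then predict."""
    from hybfact.learners import fit_predict as default_fit_predict
    from hybfact.tuning import GridSearchResult  # noqa: F401 (typing aid)

    fp = fit_predict_fn or default_fit_predict
    train_f = factorial.subset(split.train_pairs)
    y_tr = train_f.crosses["yield"].to_numpy()

    stacked = algorithm == "gb-se"
    base_alg = "gb" if stacked else algorithm
    if config.encoding == "yield-features":
        exclude = set(split.test_pairs) | set(split.removed_pairs)
        X_all = encode_yield_features(
            factorial, split.train_pairs + split.test_pairs, exclude=exclude
        )
        n_tr = len(split.train_pairs)
        from hybfact.tuning import _subset

        mask = np.arange(len(X_all.row_keys)) < n_tr
        X_tr, X_te = _subset(X_all, mask), _subset(X_all, ~mask)
    else:
        X_tr = encode_parentage(factorial, split.train_pairs)
        X_te = encode_parentage(factorial, split.test_pairs)

    cache_key = (algorithm, config.encoding)
    if (
        not stacked
        and config.reuse_tuning
        and tuning_cache is not None
        and cache_key in tuning_cache
    ):
        # tuned once on an earlier split; only refit the winning spec
        return fp(tuning_cache[cache_key], X_tr, y_tr, X_te)
    specs = sample_hyperparameters(base_alg, n=config.n_models, seed=seed)
    grid = run_grid_search(specs, X_tr, y_tr, folds=config.folds, seed=seed, fit_predict_fn=fp)
    if stacked:
        # stacking needs per-split out-of-fold predictions, so the grid is
        # always re-run even under reuse_tuning
        se = build_stacked_ensemble(grid, y_tr)
        return predict_ensemble(se, X_tr, y_tr, X_te, fit_predict_fn=fp)
    best = grid.best_spec
    if config.reuse_tuning and tuning_cache is not None:
        tuning_cache[cache_key] = best
    return fp(best, X_tr, y_tr, X_te)


def run_benchmark(
    factorial: Factorial,
    algorithms: list[str],
    config: BenchmarkConfig | None = None,
    rel: RelationshipMatrices | None = None,
    oracle_fn=None,
    fit_predict_fn=None,
) -> BenchmarkResult:
    """Fit and score every requested algorithm on every CV split.

    ``algorithms`` may contain ``gca``, ``gblup`` (requires ``rel``),
    ``gb-se``, the base learners ``gb``/``rf``/``svm``/``mf``, and
    ``oracle`` (returns the true test yields; harness integrity check).
    Failures are recorded per (split, algorithm) and skipped.
    """
    config = config or BenchmarkConfig()
    if "gblup" in algorithms and rel is None:
        raise ValueError("gblup requested without relationship matrices")
    splits = make_cv_splits(
        factorial, n_splits=config.n_splits, test_fraction=config.test_fraction, seed=config.seed
    )
    ymap = factorial.yields()
    rows = []
    failures: list[tuple[int, str, str]] = []
    tuning_cache: dict = {}
    for split in splits:
        train_f = factorial.subset(split.train_pairs)
        y_obs = np.array([ymap[p] for p in split.test_pairs])
        split_seed = int(np.random.SeedSequence([config.seed, split.split_id]).generate_state(1)[0] % (2**31))
        for alg in algorithms:
            try:
                if alg == "gca":
                    sol = fit_gca_blup(train_f.trimmed())
                    preds = predict_gca(sol, split.test_pairs)
                    y_pred = np.array([preds[p] for p in split.test_pairs])
                elif alg == "gblup":
                    model = fit_gblup(train_f, rel)
                    preds = predict_gblup(model, split.test_pairs)
                    y_pred = np.array([preds[p] for p in split.test_pairs])
                elif alg == "oracle":
                    y_pred = oracle_fn(split) if oracle_fn else y_obs.copy()
                else:
                    y_pred = _ml_predictions(
                        alg, factorial, split, config, split_seed,
                        fit_predict_fn=fit_predict_fn, tuning_cache=tuning_cache,
                    )
                rows.append(
                    {
                        "split_id": split.split_id,
                        "algorithm": alg,
                        "encoding": _encoding_label(alg, config),
                        "accuracy": prediction_accuracy(y_obs, y_pred),
                        "top20_overlap": top_k_overlap(y_obs, y_pred, k=config.top_k),
                    }
                )
            except Exception as exc:  # noqa: BLE001 - per-split failure isolation
                logger.warning("split %d, %s failed: %s", split.split_id, alg, exc)
                failures.append((split.split_id, alg, str(exc)))
    result = BenchmarkResult(pd.DataFrame(rows), failures)
    for alg in result.flagged_algorithms():
        logger.warning("algorithm %s failed on more than half of its splits", alg)
    return result


def _encoding_label(alg: str, config: BenchmarkConfig) -> str:
    if alg in ("gca", "gblup", "oracle"):
        return "model-based"
    if alg == "mf":
        return "parentage"
    return config.encoding
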