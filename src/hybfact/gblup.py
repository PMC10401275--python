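"""Genomic BLUP for two-group hybrids with a Kronecker SCA kernel.

The model is

    y = 1 b0 + Z1 g1 + Z2 g2 + Z_S s + e

with var(g1) = sigma2_1 G1, var(g2) = sigma2_2 G2 and var(s) = sigma2_s S,
where G1 and G2 are VanRaden genomic relationship matrices computed within
each parent group (G = W W'/c with w_uv = x_uv + 1 - 2 p_v and
c = 2 sum_v p_v (1 - p_v)) and S is the Kronecker product G1 (x) G2
restricted to the realized hybrids.  S is never materialized in full: its
entries are assembled on demand as S[(i,j),(k,l)] = G1[i,k] * G2[j,l].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hybfact.containers import Factorial, MarkerPanel, Pair
from hybfact.reml import RemlFit, fit_reml

logger = logging.getLogger(__name__)

#: diagonal jitter applied to G before factorization; VanRaden matrices
#: built from few markers are frequently rank-deficient
G_JITTER = 1e-6


# ---------------------------------------------------------------------------
# marker preprocessing
# ---------------------------------------------------------------------------

def filter_markers(
    panel: MarkerPanel, min_He: float = 0.10, max_missing: float = 0.01
) -> MarkerPanel:
    """Drop markers with expected heterozygosity 2p(1-p) below ``min_He``
    or with more than ``max_missing`` missing entries; order preserved."""
    if panel.n_markers == 0:
        raise ValueError("empty marker panel")
    p = panel.freqs
    he = 2.0 * p * (1.0 - p)
    keep = (he >= min_He) & (panel.missing_fraction() <= max_missing)
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    kept = [m for m, k in zip(panel.marker_ids, keep) if k]
    logger.info("filter_markers: kept %d of %d markers", len(kept), panel.n_markers)
    return MarkerPanel(panel.parent_ids, kept, panel.matrix[:, keep])


def impute_markers(panel: MarkerPanel) -> MarkerPanel:
    """Replace missing calls by the column mean of the non-missing entries.

    Allele frequencies of the returned panel are pinned to the
    pre-imputation estimates, so that centering in :func:`vanraden_G` uses
    the observed-call frequencies.
    """
    if np.isnan(panel.matrix).all(axis=0).any():
        raise ValueError("a marker has no non-missing entries")
    freqs = panel.freqs.copy()
    matrix = panel.matrix.copy()
    col_means = np.nanmean(matrix, axis=0)
    nan_r, nan_c = np.where(np.isnan(matrix))
    matrix[nan_r, nan_c] = col_means[nan_c]
    out = MarkerPanel(panel.parent_ids, panel.marker_ids, matrix)
    out.set_freqs(freqs)
    return out


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrices:
    """VanRaden matrices of the two parent groups with their scaling constants."""

    G1: np.ndarray
    G2: np.ndarray
    c1: float
    c2: float
    parents1: list[str]
    parents2: list[str]

    def index1(self, parent: str) -> int:
        try:
            return self.parents1.index(parent)
        except ValueError:
            raise KeyError(f"parent {parent!r} not in group-1 kernel") from None

    def index2(self, parent: str) -> int:
        try:
            return self.parents2.index(parent)
        except ValueError:
            raise KeyError(f"parent {parent!r} not in group-2 kernel") from None


def vanraden_G(panel: MarkerPanel) -> tuple[np.ndarray, float]:
    """VanRaden genomic relationship matrix G = W W' / c for one group.

    W centers the -1/1 dosages by the group allele frequencies,
    w_uv = x_uv + 1 - 2 p_v, and c = 2 sum_v p_v (1 - p_v).  When the
    frequencies are estimated from this same panel every row of G sums to
    (numerically) zero.
    """
    if np.isnan(panel.matrix).any():
        raise ValueError("panel must be imputed before computing G")
    p = panel.freqs
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic: c = 0")
    c = float(2.0 * np.sum(p * (1.0 - p)))
    W = panel.matrix + 1.0 - 2.0 * p
    G = (W @ W.T) / c
    return G, c


def relationship_matrices(panel1: MarkerPanel, panel2: MarkerPanel) -> RelationshipMatrices:
    G1, c1 = vanraden_G(panel1)
    G2, c2 = vanraden_G(panel2)
    return RelationshipMatrices(G1, G2, c1, c2, list(panel1.parent_ids), list(panel2.parent_ids))


def sca_kernel_entry(
    G1: np.ndarray, G2: np.ndarray, ij: tuple[int, int], kl: tuple[int, int]
) -> float:
    """One entry of the SCA kernel S = G1 (x) G2 for hybrids (i,j) and (k,l)."""
    i, j = ij
    k, l = kl
    return float(G1[i, k] * G2[j, l])


def sca_kernel(G1: np.ndarray, G2: np.ndarray, hybrids1: np.ndarray, hybrids2: np.ndarray,
               cols1: np.ndarray | None = None, cols2: np.ndarray | None = None) -> np.ndarray:
    """SCA covariance block between hybrid lists, assembled entry-wise.

    ``hybrids1``/``hybrids2`` are the group-1 and group-2 parent indices of
    the row hybrids; ``cols1``/``cols2`` those of the column hybrids
    (defaulting to the rows).  Entry (a, b) is
    G1[hybrids1[a], cols1[b]] * G2[hybrids2[a], cols2[b]], i.e. the
    Kronecker-product entries for exactly the required hybrids -- the full
    n1*n2 x n1*n2 Kronecker product is never formed.
    """
    if cols1 is None:
        cols1, cols2 = hybrids1, hybrids2
    return G1[np.ix_(hybrids1, cols1)] * G2[np.ix_(hybrids2, cols2)]


# ---------------------------------------------------------------------------
# model fit and prediction
# ---------------------------------------------------------------------------

@dataclass
class GblupModel:
    """Fitted GBLUP model with GCA and SCA components."""

    beta0: float
    g1: dict[str, float]
    g2: dict[str, float]
    s: dict[Pair, float]
    sigma2_1: float
    sigma2_2: float
    sigma2_s: float
    sigma2_e: float
    kernels: RelationshipMatrices
    train_pairs: list[Pair]
    reml: RemlFit

    @property
    def vc4(self) -> tuple[float, float, float, float]:
        return (self.sigma2_1, self.sigma2_2, self.sigma2_s, self.sigma2_e)


def _train_indices(train: Factorial, rel: RelationshipMatrices) -> tuple[np.ndarray, np.ndarray]:
    idx1 = np.array([rel.index1(p) for p in train.crosses["parent1"]])
    idx2 = np.array([rel.index2(p) for p in train.crosses["parent2"]])
    return idx1, idx2


def fit_gblup(
    train: Factorial,
    rel: RelationshipMatrices,
    max_evals: int = 3000,
    fixed_variances: tuple[float, float, float, float] | None = None,
) -> GblupModel:
    """REML fit of the GCA+SCA GBLUP model on the realized training crosses.

    ``fixed_variances`` bypasses REML and evaluates BLUPs at the given
    (sigma2_1, sigma2_2, sigma2_s, sigma2_e); used by oracle cross-checks.
    """
    if train.n_realized < 10:
        raise ValueError("need at least 10 crosses to fit GBLUP")
    y = train.crosses["yield"].to_numpy()
    n = len(y)
    idx1, idx2 = _train_indices(train, rel)
    G1 = rel.G1 + G_JITTER * np.eye(rel.G1.shape[0])
    G2 = rel.G2 + G_JITTER * np.eye(rel.G2.shape[0])
    _check_psd(G1, "G1")
    _check_psd(G2, "G2")

    K1 = G1[np.ix_(idx1, idx1)]
    K2 = G2[np.ix_(idx2, idx2)]
    Ks = sca_kernel(G1, G2, idx1, idx2)
    X = np.ones((n, 1))

    if fixed_variances is not None:
        fit = _fit_at_fixed_variances(y, X, [K1, K2, Ks], fixed_variances)
    else:
        fit = fit_reml(y, X, [K1, K2, Ks], max_evals=max_evals)

    beta0 = float(fit.beta[0])
    # effect-level BLUPs: g = sigma2 G Z' V^{-1} r, in gamma units G Z' = G[:, idx]
    u1 = fit.kernel_blup(0, G1[:, idx1])
    u2 = fit.kernel_blup(1, G2[:, idx2])
    s_hat = fit.kernel_blup(2, Ks)
    return GblupModel(
        beta0=beta0,
        g1=dict(zip(rel.parents1, u1.astype(float))),
        g2=dict(zip(rel.parents2, u2.astype(float))),
        s=dict(zip(train.pairs(), s_hat.astype(float))),
        sigma2_1=float(fit.sigma2[0]),
        sigma2_2=float(fit.sigma2[1]),
        sigma2_s=float(fit.sigma2[2]),
        sigma2_e=float(fit.sigma2_e),
        kernels=rel,
        train_pairs=train.pairs(),
        reml=fit,
    )


def _check_psd(G: np.ndarray, name: str) -> None:
    eigmin = float(np.linalg.eigvalsh(G).min())
    if eigmin < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite after jitter (min eig {eigmin:.3g})")


def _fit_at_fixed_variances(y, X, kernels, variances) -> RemlFit:
    """BLUP solution at user-supplied variance components (no REML)."""
    from scipy import linalg

    s1, s2, ss, se = variances
    if se <= 0:
        raise ValueError("sigma2_e must be > 0 for a fixed-variance fit")
    gammas = np.array([s1, s2, ss]) / se
    n = len(y)
    V0 = np.eye(n)
    for g, K in zip(gammas, kernels):
        V0 += g * K
    cho = linalg.cho_factor(V0, lower=True)
    ViX = linalg.cho_solve(cho, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ linalg.cho_solve(cho, y))
    resid = y - X @ beta
    return RemlFit(
        beta=beta,
        sigma2=np.array([s1, s2, ss], dtype=float),
        sigma2_e=float(se),
        gammas=gammas,
        vinv_resid=linalg.cho_solve(cho, resid),
        nll=np.nan,
        n_evals=0,
    )


def predict_gblup(model: GblupModel, pairs: list[Pair]) -> dict[Pair, float]:
    """Predict hybrid yields by multivariate-normal conditioning.

    For each target pair the covariance with the training observations is
    assembled from G1, G2 and the Kronecker SCA rule, and the prediction is
    beta0 + Cov(target, train) V^{-1} (y - beta0).  Parents only need rows
    in the kernels, not training crosses, so untested hybrids of genotyped
    parents are predictable.
    """
    rel = model.kernels
    t1 = np.array([rel.index1(i) for i, _ in pairs])
    t2 = np.array([rel.index2(j) for _, j in pairs])
    idx1 = np.array([rel.index1(i) for i, _ in model.train_pairs])
    idx2 = np.array([rel.index2(j) for _, j in model.train_pairs])
    G1 = rel.G1 + G_JITTER * np.eye(rel.G1.shape[0])
    G2 = rel.G2 + G_JITTER * np.eye(rel.G2.shape[0])

    fit = model.reml
    # covariance in gamma units: gamma1 G1 + gamma2 G2 + gammas S
    C = (
        fit.gammas[0] * G1[np.ix_(t1, idx1)]
        + fit.gammas[1] * G2[np.ix_(t2, idx2)]
        + fit.gammas[2] * sca_kernel(G1, G2, t1, t2, idx1, idx2)
    )
    preds = model.beta0 + C @ fit.vinv_resid
    return dict(zip(pairs, preds.astype(float)))
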