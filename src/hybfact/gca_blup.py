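"""Combining-ability BLUP: the classical mixed model for testcross factorials.

The model for the adjusted entry mean of hybrid (i, j) is

    y_ij = mu + GCA1_i + GCA2_j + SCA_ij

with GCA1 and GCA2 crossed random effects.  With a single entry mean per
hybrid the SCA term is inseparable from residual error, so the model is fit
as y ~ mu + random(GCA1) + random(GCA2) with the residual variance reported
as sigma2_SCA (the error variance is flagged as confounded with SCA), and
SCA_ij is defined as the raw residual y_ij - mu - GCA1_i - GCA2_j.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hybfact.containers import Factorial, Pair
from hybfact.factorial_stats import VarianceComponents
from hybfact.reml import RemlFit, fit_reml


@dataclass
class GcaSolution:
    """REML variance components and BLUPs of the combining-ability model."""

    mu: float
    gca1: dict[str, float]
    gca2: dict[str, float]
    sca: dict[Pair, float]
    vc: VarianceComponents
    reml: RemlFit | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu,
            "gca1": self.gca1,
            "gca2": self.gca2,
            "sca": {f"{i}:{j}": v for (i, j), v in self.sca.items()},
            "variance_components": {
                "sigma2_gca1": self.vc.sigma2_gca1,
                "sigma2_gca2": self.vc.sigma2_gca2,
                "sigma2_sca": self.vc.sigma2_sca,
                "sigma2_e": self.vc.sigma2_e,
                "confounded": self.vc.confounded,
                "tau": self.vc.tau,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _incidence(ids: list[str], column: "np.ndarray") -> np.ndarray:
    index = {p: k for k, p in enumerate(ids)}
    Z = np.zeros((len(column), len(ids)))
    for row, p in enumerate(column):
        Z[row, index[p]] = 1.0
    return Z


def fit_gca_blup(train: Factorial, max_evals: int = 2000) -> GcaSolution:
    """Fit the combining-ability model by REML and solve for the BLUPs.

    Only parents appearing in at least one training cross enter the model;
    a group reduced to a single parent is permitted but flagged with a
    warning since its GCA variance is then poorly identified.
    """
    if train.n_realized < 3:
        raise ValueError("need at least 3 crosses to fit the combining-ability model")
    crosses = train.crosses
    parents1 = [p for p in train.parents1 if p in set(crosses["parent1"])]
    parents2 = [p for p in train.parents2 if p in set(crosses["parent2"])]
    if len(parents1) < len(train.parents1) or len(parents2) < len(train.parents2):
        raise ValueError("every parent must appear in at least one training cross")
    for label, group in (("group 1", parents1), ("group 2", parents2)):
        if len(group) == 1:
            warnings.warn(f"{label} has a single parent; its GCA variance is unidentified")

    y = crosses["yield"].to_numpy()
    n = len(y)
    X = np.ones((n, 1))
    Z1 = _incidence(parents1, crosses["parent1"].to_numpy())
    Z2 = _incidence(parents2, crosses["parent2"].to_numpy())
    fit = fit_reml(y, X, [Z1 @ Z1.T, Z2 @ Z2.T], max_evals=max_evals)

    mu = float(fit.beta[0])
    u1 = fit.kernel_blup(0, Z1.T)
    u2 = fit.kernel_blup(1, Z2.T)
    gca1 = dict(zip(parents1, u1.astype(float)))
    gca2 = dict(zip(parents2, u2.astype(float)))
    fitted = mu + Z1 @ u1 + Z2 @ u2
    sca = dict(zip(train.pairs(), (y - fitted).astype(float)))

    vc = VarianceComponents(
        sigma2_gca1=float(fit.sigma2[0]),
        sigma2_gca2=float(fit.sigma2[1]),
        sigma2_sca=float(fit.sigma2_e),
        sigma2_e=None,
        confounded=True,
    )
    return GcaSolution(mu=mu, gca1=gca1, gca2=gca2, sca=sca, vc=vc, reml=fit)


def predict_gca(solution: GcaSolution, pairs: list[Pair]) -> dict[Pair, float]:
    """Predict hybrid yield as mu + GCA1_i + GCA2_j (no SCA term)."""
    out: dict[Pair, float] = {}
    for i, j in pairs:
        if i not in solution.gca1:
            raise KeyError(f"parent {i!r} has no fitted group-1 GCA")
        if j not in solution.gca2:
            raise KeyError(f"parent {j!r} has no fitted group-2 GCA")
        out[(i, j)] = solution.mu + solution.gca1[i] + solution.gca2[j]
    return out
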