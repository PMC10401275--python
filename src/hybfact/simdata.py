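"""Synthetic unbalanced incomplete factorials with known genetic architecture.

The generator draws two parent groups, a set of realized crosses, and hybrid
yields from the combining-ability decomposition

    y_ij = mu + GCA1_i + GCA2_j + SCA_ij + e_ij

with all effects independent Gaussians at configurable variances.  SCA and
residual error are drawn separately even though a one-observation-per-hybrid
analysis cannot separate them; recovery tests therefore know the true split.
Optionally a pair of inbred marker panels is generated whose additive and
dominance effects *drive* the yields (``marker-driven``), so that
marker-based predictors have signal to find, or which carry no signal at all
(``effects-direct``, a negative control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hybfact.containers import Factorial, MarkerPanel, Pair

ARCHITECTURES = ("effects-direct", "marker-driven")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic factorial.

    Variances are on the squared scale of the yield unit; ``skew`` controls
    how unequal the per-parent cross counts are (0 gives uniform sampling,
    larger values concentrate crosses on few parents via weights
    proportional to rank**skew).
    """

    n1: int = 60
    n2: int = 20
    sigma2_gca1: float = 1.0
    sigma2_gca2: float = 1.0
    sigma2_sca: float = 1.0
    sigma2_e: float = 0.25
    mu: float = 100.0
    n_crosses: int = 600
    skew: float = 1.0
    n_markers: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    architecture: str = "effects-direct"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each parent group needs at least 2 parents")
        if not (0 < self.n_crosses <= self.n1 * self.n2):
            raise ValueError(f"n_crosses must be in (0, {self.n1 * self.n2}]")
        for name in ("sigma2_gca1", "sigma2_gca2", "sigma2_sca", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.skew < 0:
            raise ValueError("skew must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")


@dataclass
class TrueEffects:
    """The generator's ground truth for one simulated factorial."""

    mu: float
    gca1: dict[str, float]
    gca2: dict[str, float]
    sca: dict[Pair, float]
    noise: dict[Pair, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu,
            "gca1": self.gca1,
            "gca2": self.gca2,
            "sca": {f"{i}:{j}": v for (i, j), v in self.sca.items()},
            "noise": {f"{i}:{j}": v for (i, j), v in self.noise.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueEffects":
        payload = json.loads(Path(path).read_text())

        def unkey(d: dict[str, float]) -> dict[Pair, float]:
            return {tuple(k.split(":", 1)): v for k, v in d.items()}

        return cls(
            mu=payload["mu"],
            gca1=payload["gca1"],
            gca2=payload["gca2"],
            sca=unkey(payload["sca"]),
            noise=unkey(payload.get("noise", {})),
        )


def _parent_names(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{k:0{width}d}" for k in range(1, n + 1)]


def sample_crossing_design(
    n1: int, n2: int, n_crosses: int, skew: float = 0.0, seed: int = 0
) -> list[Pair]:
    """Draw ``n_crosses`` distinct parent pairs covering every parent.

    Each parent receives a sampling weight proportional to ``rank**skew``
    (ranks randomly assigned within group), so larger ``skew`` produces a
    longer-tailed distribution of crosses per parent, as seen in real
    breeding factorials.  A coverage pass first guarantees that every parent
    of both groups appears in at least one cross; the remaining pairs are
    sampled without replacement with probability proportional to the product
    of the parental weights.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one parent")
    if n_crosses < max(n1, n2):
        raise ValueError(
            f"n_crosses={n_crosses} < max(n1, n2)={max(n1, n2)}: cannot cover every parent"
        )
    if n_crosses > n1 * n2:
        raise ValueError(f"n_crosses={n_crosses} > n1*n2={n1 * n2}: not enough distinct pairs")

    rng = np.random.default_rng(seed)
    p1 = _parent_names("P1_", n1)
    p2 = _parent_names("P2_", n2)
    w1 = rng.permutation(np.arange(1, n1 + 1, dtype=float)) ** skew
    w2 = rng.permutation(np.arange(1, n2 + 1, dtype=float)) ** skew

    # coverage pass: max(n1, n2) pairs in which every parent of the larger
    # group appears once and the smaller group is cycled through a random
    # permutation, so both groups are fully covered with distinct pairs
    if n1 >= n2:
        big, small, nbig, nsmall = p1, p2, n1, n2
    else:
        big, small, nbig, nsmall = p2, p1, n2, n1
    big_order = rng.permutation(nbig)
    small_order = np.concatenate(
        [rng.permutation(nsmall) for _ in range(-(-nbig // nsmall))]
    )[:nbig]
    if n1 >= n2:
        chosen = {(big[b], small[s]) for b, s in zip(big_order, small_order)}
    else:
        chosen = {(small[s], big[b]) for b, s in zip(big_order, small_order)}

    # weighted sampling without replacement of the remaining pairs
    # (Gumbel-max trick over the complement of the coverage pairs)
    n_extra = n_crosses - len(chosen)
    if n_extra > 0:
        logw = np.log(np.outer(w1, w2)).ravel()
        taken = np.zeros(n1 * n2, dtype=bool)
        idx1 = {p: i for i, p in enumerate(p1)}
        idx2 = {p: j for j, p in enumerate(p2)}
        for i, j in chosen:
            taken[idx1[i] * n2 + idx2[j]] = True
        keys = logw + rng.gumbel(size=n1 * n2)
        keys[taken] = -np.inf
        extra = np.argpartition(-keys, n_extra - 1)[:n_extra]
        for flat in extra:
            chosen.add((p1[flat // n2], p2[flat % n2]))

    assert len(chosen) == n_crosses
    return sorted(chosen)


def simulate_factorial(config: SimulationConfig) -> tuple[Factorial, TrueEffects]:
    """Simulate a factorial with i.i.d. Gaussian GCA, SCA and error effects."""
    rng = np.random.default_rng(config.seed)
    pairs = sample_crossing_design(
        config.n1, config.n2, config.n_crosses, config.skew, seed=config.seed
    )
    p1 = _parent_names("P1_", config.n1)
    p2 = _parent_names("P2_", config.n2)

    gca1 = dict(zip(p1, rng.normal(0.0, np.sqrt(config.sigma2_gca1), config.n1)))
    gca2 = dict(zip(p2, rng.normal(0.0, np.sqrt(config.sigma2_gca2), config.n2)))
    sca = dict(zip(pairs, rng.normal(0.0, np.sqrt(config.sigma2_sca), len(pairs))))
    noise = dict(zip(pairs, rng.normal(0.0, np.sqrt(config.sigma2_e), len(pairs))))

    effects = TrueEffects(mu=config.mu, gca1=gca1, gca2=gca2, sca=sca, noise=noise)
    crosses = _crosses_frame(pairs, effects)
    return Factorial(p1, p2, crosses), effects


def _crosses_frame(pairs: list[Pair], effects: TrueEffects) -> pd.DataFrame:
    rows = [
        (i, j, effects.mu + effects.gca1[i] + effects.gca2[j] + effects.sca[i, j] + effects.noise[i, j])
        for i, j in pairs
    ]
    return pd.DataFrame(rows, columns=["parent1", "parent2", "yield"])


def _draw_panel(rng: np.random.Generator, parents: list[str], markers: list[str], maf_range) -> MarkerPanel:
    lo, hi = maf_range
    p = rng.uniform(lo, hi, len(markers))
    geno = np.where(rng.random((len(parents), len(markers))) < p, 1.0, -1.0)
    return MarkerPanel(parents, markers, geno)


def simulate_markers(
    config: SimulationConfig,
    factorial: Factorial,
    effects: TrueEffects,
) -> tuple[MarkerPanel, MarkerPanel, Factorial, TrueEffects]:
    """Generate inbred marker panels for both parent groups.

    Under ``effects-direct`` the panels are independent of the yields and
    serve as a negative control.  Under ``marker-driven`` the yields are
    regenerated so that the genetic effects are exact functions of the
    markers: per-group additive effects give GCA (GCA1_i = sum_v a1_v x_iv,
    centered within group), dominance effects on heterozygous hybrid loci
    give SCA (SCA_ij = sum_v d_v [x1_iv != x2_jv], centered over realized
    crosses), and both are rescaled so the realized sample variances equal
    the configured components; the returned factorial and effects reflect
    the regenerated truth.
    """
    if config.n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if config.architecture == "marker-driven" and config.n_markers < 10:
        raise ValueError("marker-driven architecture needs >= 10 markers to match the requested variances")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7751]))
    markers = [f"M{v + 1}" for v in range(config.n_markers)]
    panel1 = _draw_panel(rng, factorial.parents1, markers, config.maf_range)
    panel2 = _draw_panel(rng, factorial.parents2, markers, config.maf_range)

    if config.architecture == "effects-direct":
        return panel1, panel2, factorial, effects

    pairs = factorial.pairs()

    def scaled_effects(matrix: np.ndarray, target_var: float) -> np.ndarray:
        """Additive marker scores centered and rescaled to the target sample variance."""
        a = rng.normal(size=matrix.shape[1])
        g = matrix @ a
        g -= g.mean()
        sv = g.var(ddof=1)
        if target_var == 0.0:
            return np.zeros_like(g)
        if sv == 0.0:
            raise ValueError("degenerate panel: marker scores carry no variance between parents")
        return g * np.sqrt(target_var / sv)

    g1 = scaled_effects(panel1.matrix, config.sigma2_gca1)
    g2 = scaled_effects(panel2.matrix, config.sigma2_gca2)
    gca1 = dict(zip(factorial.parents1, g1))
    gca2 = dict(zip(factorial.parents2, g2))

    if config.sigma2_sca == 0.0:
        sca = {pair: 0.0 for pair in pairs}
    else:
        d = rng.normal(size=config.n_markers)
        het = np.array(
            [panel1.row(i) != panel2.row(j) for i, j in pairs], dtype=float
        )
        raw = het @ d
        raw -= raw.mean()
        sv = raw.var(ddof=1)
        if sv == 0.0:
            raise ValueError("degenerate panels: heterozygosity carries no variance for SCA")
        sca = dict(zip(pairs, raw * np.sqrt(config.sigma2_sca / sv)))

    noise = dict(zip(pairs, rng.normal(0.0, np.sqrt(config.sigma2_e), len(pairs))))
    new_effects = TrueEffects(mu=config.mu, gca1=gca1, gca2=gca2, sca=sca, noise=noise)
    new_factorial = Factorial(
        factorial.parents1, factorial.parents2, _crosses_frame(pairs, new_effects)
    )
    return panel1, panel2, new_factorial, new_effects


def simulate(config: SimulationConfig) -> dict:
    """One-call generator: factorial, truth, and (optionally) marker panels."""
    factorial, effects = simulate_factorial(config)
    panel1, panel2, factorial, effects = simulate_markers(config, factorial, effects)
    return {
        "factorial": factorial,
        "effects": effects,
        "panel1": panel1,
        "panel2": panel2,
    }
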