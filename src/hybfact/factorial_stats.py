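"""Descriptive statistics and variance-structure summaries of a factorial.

Summaries mirror the tables reported for experimental testcross factorials:
group sizes, number of possible and realized hybrids, per-parent cross-count
distributions, the SCA share of the total genetic variance

    tau = sigma2_SCA / (sigma2_GCA1 + sigma2_GCA2 + sigma2_SCA),

and the Pearson correlations of GCA sums and SCA deviations with hybrid
yield over realized crosses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats as sps

from hybfact.containers import Factorial

if TYPE_CHECKING:  # pragma: no cover
    from hybfact.gca_blup import GcaSolution


@dataclass
class GroupCrossCounts:
    """Distribution of crosses per parent within one group."""

    counts: dict[str, int]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def median(self) -> float:
        return float(np.median(list(self.counts.values())))

    @property
    def range(self) -> tuple[int, int]:
        vals = list(self.counts.values())
        return (min(vals), max(vals))


@dataclass
class DescriptiveStats:
    n1: int
    n2: int
    n_possible: int
    n_realized: int
    fraction_realized: float
    ratio_groups: float
    group1_counts: GroupCrossCounts
    group2_counts: GroupCrossCounts

    def report(self) -> str:
        """Table-style text report (percentages and means to one decimal)."""
        g1, g2 = self.group1_counts, self.group2_counts
        lines = [
            f"No. of parents in group 1      {self.n1}",
            f"No. of parents in group 2      {self.n2}",
            f"Ratio group 1/group 2          {self.ratio_groups:.1f}",
            f"No. of possible hybrids        {self.n_possible}",
            f"No. of realized hybrids        {self.n_realized}",
            f"Fraction of realized hybrids   {100 * self.fraction_realized:.1f}%",
            f"Group 1 crosses/parent         mean {g1.mean:.1f}  median {g1.median:.1f}  range {g1.range[0]}-{g1.range[1]}",
            f"Group 2 crosses/parent         mean {g2.mean:.1f}  median {g2.median:.1f}  range {g2.range[0]}-{g2.range[1]}",
        ]
        return "\n".join(lines)


@dataclass
class VarianceComponents:
    """GCA/SCA variance components of the combining-ability model.

    With one entry mean per hybrid, SCA variance and residual error are
    inseparable; ``sigma2_e`` is then ``None`` and ``confounded`` is True,
    meaning ``sigma2_sca`` absorbs the residual.
    """

    sigma2_gca1: float
    sigma2_gca2: float
    sigma2_sca: float
    sigma2_e: float | None = None
    confounded: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma2_gca1", "sigma2_gca2", "sigma2_sca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma2_e is not None and self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")

    @property
    def tau(self) -> float:
        return compute_tau(self)


def compute_tau(vc: "VarianceComponents") -> float:
    """SCA share of total genetic variance; undefined when all three are 0."""
    total = vc.sigma2_gca1 + vc.sigma2_gca2 + vc.sigma2_sca
    if total <= 0:
        raise ValueError("tau undefined: all genetic variance components are zero")
    return vc.sigma2_sca / total


def describe_factorial(factorial: Factorial) -> DescriptiveStats:
    """Descriptive statistics of an incomplete two-group factorial."""
    if factorial.n_realized == 0:
        raise ValueError("empty factorial")
    c1 = factorial.crosses["parent1"].value_counts().to_dict()
    c2 = factorial.crosses["parent2"].value_counts().to_dict()
    # parents without any cross count as zero so the coverage gap is visible
    counts1 = {p: int(c1.get(p, 0)) for p in factorial.parents1}
    counts2 = {p: int(c2.get(p, 0)) for p in factorial.parents2}
    return DescriptiveStats(
        n1=factorial.n1,
        n2=factorial.n2,
        n_possible=factorial.n_possible,
        n_realized=factorial.n_realized,
        fraction_realized=factorial.fraction_realized,
        ratio_groups=factorial.n1 / factorial.n2,
        group1_counts=GroupCrossCounts(counts1),
        group2_counts=GroupCrossCounts(counts2),
    )


def gca_sca_yield_correlations(
    factorial: Factorial, solution: "GcaSolution"
) -> tuple[float, float]:
    """Pearson correlations of (GCA1_i + GCA2_j) and SCA_ij with yield.

    Both are computed over the realized hybrids of ``factorial`` using the
    fitted combining-ability solution; SCA is the raw residual
    y_ij - mu - GCA1_i - GCA2_j.
    """
    pairs = factorial.pairs()
    if len(pairs) < 3:
        raise ValueError("need at least 3 realized hybrids")
    y = factorial.crosses["yield"].to_numpy()
    gca_sum = np.array([solution.gca1[i] + solution.gca2[j] for i, j in pairs])
    sca = np.array([solution.sca[p] for p in pairs])
    for name, v in (("yield", y), ("GCA sums", gca_sum), ("SCA", sca)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}: correlation undefined")
    r_gca = float(sps.pearsonr(gca_sum, y).statistic)
    r_sca = float(sps.pearsonr(sca, y).statistic)
    return r_gca, r_sca
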