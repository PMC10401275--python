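"""Predictor-variable encodings for the ML learners.

Three encodings of a hybrid are supported, mirroring the information
actually available to a breeder:

* **parentage** -- the bare identities of the two parents, either as two
  categorical columns or one-hot expanded to n1 + n2 indicators;
* **yield features** -- for hybrid (i, j), the yields of all other realized
  crosses of parent i and of parent j (one column per parent line of the
  factorial), with the hybrid's own yield and any excluded (test) yields
  removed: a sparse, leakage-guarded table;
* **hybrid genotypes** -- the virtual F1 genotype at each marker, the
  midpoint of the two inbred parents' dosages (-1/0/1 for pure panels);

plus the column-wise combination of parentage and marker features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybfact.containers import Factorial, MarkerPanel, Pair

logger = logging.getLogger(__name__)

ENCODING_KINDS = ("parentage", "parentage-onehot", "yield-features", "markers", "combined")


@dataclass
class FeatureTable:
    """A hybrids x features design matrix with row keys and an encoding tag."""

    row_keys: list[Pair]
    table: pd.DataFrame
    encoding_kind: str

    def __post_init__(self) -> None:
        if self.encoding_kind not in ENCODING_KINDS:
            raise ValueError(f"unknown encoding kind {self.encoding_kind!r}")
        if len(self.table) != len(self.row_keys):
            raise ValueError("row_keys and table length differ")
        self.table = self.table.reset_index(drop=True)

    @property
    def column_names(self) -> list[str]:
        return list(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "hybrid", [f"{i}:{j}" for i, j in self.row_keys])
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _check_parents(factorial: Factorial, hybrids: list[Pair]) -> None:
    p1, p2 = set(factorial.parents1), set(factorial.parents2)
    for i, j in hybrids:
        if i not in p1:
            raise KeyError(f"unknown group-1 parent {i!r}")
        if j not in p2:
            raise KeyError(f"unknown group-2 parent {j!r}")


def encode_parentage(
    factorial: Factorial, hybrids: list[Pair], onehot: bool = False
) -> FeatureTable:
    """Parent identities as two categoricals or n1+n2 one-hot indicators."""
    _check_parents(factorial, hybrids)
    if not onehot:
        df = pd.DataFrame(hybrids, columns=["parent1", "parent2"])
        df["parent1"] = pd.Categorical(df["parent1"], categories=factorial.parents1)
        df["parent2"] = pd.Categorical(df["parent2"], categories=factorial.parents2)
        return FeatureTable(list(hybrids), df, "parentage")
    cols1 = {f"p1_{p}": [1.0 if i == p else 0.0 for i, _ in hybrids] for p in factorial.parents1}
    cols2 = {f"p2_{p}": [1.0 if j == p else 0.0 for _, j in hybrids] for p in factorial.parents2}
    df = pd.DataFrame({**cols1, **cols2})
    return FeatureTable(list(hybrids), df, "parentage-onehot")


def decode_parentage_onehot(table: FeatureTable) -> list[Pair]:
    """Recover (parent1, parent2) from a one-hot parentage table."""
    if table.encoding_kind != "parentage-onehot":
        raise ValueError("not a one-hot parentage table")
    pairs: list[Pair] = []
    cols = table.column_names
    for _, row in table.table.iterrows():
        active = [c for c in cols if row[c] == 1.0]
        p1 = [c[3:] for c in active if c.startswith("p1_")]
        p2 = [c[3:] for c in active if c.startswith("p2_")]
        if len(p1) != 1 or len(p2) != 1:
            raise ValueError("row does not encode exactly one parent per group")
        pairs.append((p1[0], p2[0]))
    return pairs


def encode_yield_features(
    factorial: Factorial,
    hybrids: list[Pair],
    exclude: set[Pair] | None = None,
    drop_uninformative: bool = True,
) -> FeatureTable:
    """Yields of the parents' other crosses, one column per parent line.

    For hybrid (i, j) the column of group-2 parent q holds yield(i, q) and
    the column of group-1 parent p holds yield(p, j), each only when that
    cross is realized and not in ``exclude``.  The hybrid's own yield never
    appears in its row (its defining cells are the columns of its own
    parents, which would hold yield(i, j) itself and are masked).  When the
    response rows being predicted are test hybrids, ``exclude`` must
    contain them so no test yield leaks into any training row.  Constant
    and all-missing columns are dropped (logged).
    """
    _check_parents(factorial, hybrids)
    exclude = exclude or set()
    ymap = {p: v for p, v in factorial.yields().items() if p not in exclude}
    by_p1: dict[str, dict[str, float]] = {}
    by_p2: dict[str, dict[str, float]] = {}
    for (i, j), v in ymap.items():
        by_p1.setdefault(i, {})[j] = v
        by_p2.setdefault(j, {})[i] = v

    data = np.full((len(hybrids), factorial.n1 + factorial.n2), np.nan)
    col_of_p1 = {p: k for k, p in enumerate(factorial.parents1)}
    col_of_p2 = {p: factorial.n1 + k for k, p in enumerate(factorial.parents2)}
    for r, (i, j) in enumerate(hybrids):
        for q, v in by_p1.get(i, {}).items():        # crosses of parent i
            if (i, q) != (i, j):
                data[r, col_of_p2[q]] = v
        for p, v in by_p2.get(j, {}).items():        # crosses of parent j
            if (p, j) != (i, j):
                data[r, col_of_p1[p]] = v

    names = [f"g1_{p}" for p in factorial.parents1] + [f"g2_{p}" for p in factorial.parents2]
    df = pd.DataFrame(data, columns=names)
    if drop_uninformative:
        # all-missing columns, and columns constant with no missing entries
        drop = [
            c
            for c in df.columns
            if df[c].notna().sum() == 0
            or (df[c].nunique(dropna=True) == 1 and df[c].notna().all())
        ]
        if drop:
            logger.info(
                "encode_yield_features: dropping %d constant/all-missing columns", len(drop)
            )
            df = df.drop(columns=drop)
    return FeatureTable(list(hybrids), df, "yield-features")


def encode_hybrid_genotypes(
    panel1: MarkerPanel, panel2: MarkerPanel, pairs: list[Pair]
) -> FeatureTable:
    """Virtual F1 genotypes: the midpoint of the two parental dosages.

    For pure -1/1 inbred panels this is exactly -1 (homozygous first
    allele), 0 (heterozygous) or 1 (homozygous second allele); mean-imputed
    fractional parents yield fractional dosages.
    """
    if panel1.marker_ids != panel2.marker_ids:
        raise ValueError("the two panels genotype different marker sets")
    if np.isnan(panel1.matrix).any() or np.isnan(panel2.matrix).any():
        raise ValueError("panels must be imputed before encoding hybrid genotypes")
    rows = [(panel1.row(i) + panel2.row(j)) / 2.0 for i, j in pairs]
    df = pd.DataFrame(np.array(rows).reshape(len(pairs), -1), columns=panel1.marker_ids)
    return FeatureTable(list(pairs), df, "markers")


def combine_features(parentage: FeatureTable, markers: FeatureTable) -> FeatureTable:
    """Column-wise concatenation of a parentage table with a marker table."""
    if parentage.row_keys != markers.row_keys:
        raise ValueError("row keys of the two tables differ")
    left = parentage.table.copy()
    right = markers.table.copy()
    clash = set(left.columns) & set(right.columns)
    if clash:
        right = right.rename(columns={c: f"{c}__mk" for c in clash})
    df = pd.concat([left.reset_index(drop=True), right.reset_index(drop=True)], axis=1)
    return FeatureTable(list(parentage.row_keys), df, "combined")
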