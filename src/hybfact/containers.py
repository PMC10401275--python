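"""Core data containers: crossing factorials and inbred marker panels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

Pair = tuple[str, str]


@dataclass
class Factorial:
    """An incomplete factorial of crosses between two parent groups.

    Parameters
    ----------
    parents1, parents2
        Ordered IDs of the group-1 and group-2 parent lines.
    crosses
        One row per realized hybrid with columns ``parent1``, ``parent2``
        and ``yield`` (adjusted entry means, one value per hybrid).
    """

    parents1: list[str]
    parents2: list[str]
    crosses: pd.DataFrame

    def __post_init__(self) -> None:
        self.parents1 = [str(p) for p in self.parents1]
        self.parents2 = [str(p) for p in self.parents2]
        required = {"parent1", "parent2", "yield"}
        if not required.issubset(self.crosses.columns):
            raise ValueError(f"crosses must have columns {sorted(required)}")
        self.crosses = self.crosses.reset_index(drop=True).astype(
            {"parent1": str, "parent2": str, "yield": float}
        )
        p1 = set(self.parents1)
        p2 = set(self.parents2)
        if len(p1) != len(self.parents1) or len(p2) != len(self.parents2):
            raise ValueError("duplicate parent IDs within a group")
        bad1 = set(self.crosses["parent1"]) - p1
        bad2 = set(self.crosses["parent2"]) - p2
        if bad1 or bad2:
            raise ValueError(f"crosses reference unlisted parents: {sorted(bad1 | bad2)}")
        if self.crosses.duplicated(["parent1", "parent2"]).any():
            raise ValueError("duplicate (parent1, parent2) pairs")
        if not np.isfinite(self.crosses["yield"]).all():
            raise ValueError("non-finite yields")

    # -- basic structure ---------------------------------------------------
    @property
    def n1(self) -> int:
        return len(self.parents1)

    @property
    def n2(self) -> int:
        return len(self.parents2)

    @property
    def n_realized(self) -> int:
        return len(self.crosses)

    @property
    def n_possible(self) -> int:
        return self.n1 * self.n2

    @property
    def fraction_realized(self) -> float:
        return self.n_realized / self.n_possible

    def pairs(self) -> list[Pair]:
        return list(zip(self.crosses["parent1"], self.crosses["parent2"]))

    def yields(self) -> dict[Pair, float]:
        return dict(zip(self.pairs(), self.crosses["yield"]))

    def subset(self, pairs: list[Pair]) -> "Factorial":
        """Restrict to the given realized pairs, keeping the full parent lists."""
        keep = set(pairs)
        mask = [p in keep for p in self.pairs()]
        return Factorial(self.parents1, self.parents2, self.crosses.loc[mask])

    def trimmed(self) -> "Factorial":
        """Drop listed parents that appear in no cross (order preserved)."""
        p1 = set(self.crosses["parent1"])
        p2 = set(self.crosses["parent2"])
        return Factorial(
            [p for p in self.parents1 if p in p1],
            [p for p in self.parents2 if p in p2],
            self.crosses,
        )

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.crosses.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        parents1: list[str] | None = None,
        parents2: list[str] | None = None,
    ) -> "Factorial":
        """Read a ``parent1,parent2,yield`` table; parent lists default to
        the parents observed in the crosses, in order of first appearance."""
        df = pd.read_csv(path, dtype={"parent1": str, "parent2": str})
        if parents1 is None:
            parents1 = list(dict.fromkeys(df["parent1"]))
        if parents2 is None:
            parents2 = list(dict.fromkeys(df["parent2"]))
        return cls(parents1, parents2, df)


@dataclass
class MarkerPanel:
    """SNP genotypes of fully homozygous parent lines, coded -1/1.

    ``matrix`` is parents x markers with ``nan`` for missing calls; after
    mean imputation entries are real dosages in [-1, 1].  ``freqs`` are the
    frequencies of the 1 allele per marker, estimated from non-missing
    entries of this panel (i.e. within the parent group).
    """

    parent_ids: list[str]
    marker_ids: list[str]
    matrix: np.ndarray
    _freqs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.parent_ids = [str(p) for p in self.parent_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.parent_ids), len(self.marker_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.parent_ids)} parents x {len(self.marker_ids)} markers"
            )

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def freqs(self) -> np.ndarray:
        """Frequency of the 1 allele per marker (non-missing entries)."""
        if self._freqs is not None:
            return self._freqs
        # mean dosage m of -1/1 codes satisfies m = 2p - 1; the identity also
        # extends consistently to mean-imputed fractional dosages
        with np.errstate(invalid="ignore"):
            return (np.nanmean(self.matrix, axis=0) + 1.0) / 2.0

    def set_freqs(self, freqs: np.ndarray) -> None:
        """Pin allele frequencies (e.g. pre-imputation estimates)."""
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (self.n_markers,):
            raise ValueError("freqs length must equal number of markers")
        self._freqs = freqs

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.matrix).mean(axis=0)

    def row(self, parent_id: str) -> np.ndarray:
        try:
            i = self.parent_ids.index(str(parent_id))
        except ValueError:
            raise KeyError(f"unknown parent {parent_id!r}") from None
        return self.matrix[i]

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.marker_ids)
        df.insert(0, "parent_id", self.parent_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"parent_id": str})
        if df.columns[0] != "parent_id":
            raise ValueError("first column of a marker TSV must be 'parent_id'")
        return cls(
            parent_ids=list(df["parent_id"]),
            marker_ids=list(df.columns[1:]),
            matrix=df.iloc[:, 1:].to_numpy(float),
        )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "MarkerPanel":
        """Import inbred genotypes from VCF: homozygous REF -> -1, homozygous
        ALT -> 1, heterozygous or missing -> missing."""
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("VCF import requires the cyvcf2 package") from exc
        vcf = VCF(str(path))
        parent_ids = list(vcf.samples)
        marker_ids: list[str] = []
        rows: list[np.ndarray] = []
        for var in vcf:
            marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            col = np.full(len(parent_ids), np.nan)
            col[gt == 0] = -1.0
            col[gt == 3] = 1.0
            rows.append(col)
        matrix = np.column_stack(rows) if rows else np.empty((len(parent_ids), 0))
        return cls(parent_ids, marker_ids, matrix)
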