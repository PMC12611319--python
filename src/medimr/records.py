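"""Core record types shared by every pipeline stage.

A :class:`SummaryStatsSet` wraps a validated :class:`pandas.DataFrame` of
per-SNP association summaries for one trait; :class:`LDReference` holds a
block-diagonal SNP correlation lookup used by clumping; and
:class:`HarmonizedPair` is one allele-aligned exposure/outcome effect pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of a summary-statistics frame
SUMMARY_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n_total", "n_case", "n_control",
]


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-effect-allele effect: log-odds for binary traits,
    trait-SD units for quantitative traits.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n_total: int
    eaf: Optional[float] = None
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def validate(self) -> Optional[str]:
        """Return a reason string if any invariant is violated, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "non_snv_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not np.isfinite(self.beta):
            return "non_finite_beta"
        if not (np.isfinite(self.se) and self.se > 0):
            return "nonpositive_se"
        if not (0 < self.pvalue <= 1):
            return "pvalue_out_of_range"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf_out_of_range"
        if self.n_total is None or self.n_total <= 0:
            return "nonpositive_n"
        if self.n_case is not None and self.n_control is not None:
            if self.n_case <= 0 or self.n_control <= 0:
                return "nonpositive_case_control"
            if self.n_case + self.n_control != self.n_total:
                return "case_control_mismatch"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


class SummaryStatsSet:
    """Per-trait collection of :class:`GwasRecord`, unique by ``snp_id``.

    Backed by a DataFrame (column layout :data:`SUMMARY_COLUMNS`) so the
    selection and estimation stages can stay vectorised.
    """

    def __init__(self, trait_name: str, trait_type: str, frame: pd.DataFrame):
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        frame = frame.reset_index(drop=True)
        if frame["snp_id"].duplicated().any():
            dups = frame.loc[frame["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id values in set: {dups[:5]}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.frame = frame

    @classmethod
    def from_records(cls, trait_name: str, trait_type: str,
                     records: Iterable[GwasRecord]) -> "SummaryStatsSet":
        rows = [{c: getattr(r, c) for c in SUMMARY_COLUMNS} for r in records]
        frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
        return cls(trait_name, trait_type, frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.frame["snp_id"])

    @property
    def snp_ids(self) -> list[str]:
        return self.frame["snp_id"].tolist()

    def record(self, snp_id: str) -> GwasRecord:
        row = self.frame.loc[self.frame["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return self._row_to_record(row.iloc[0])

    def records(self) -> list[GwasRecord]:
        return [self._row_to_record(row) for _, row in self.frame.iterrows()]

    @staticmethod
    def _row_to_record(row: pd.Series) -> GwasRecord:
        def _opt(v, cast):
            return None if pd.isna(v) else cast(v)
        return GwasRecord(
            snp_id=str(row["snp_id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]), other_allele=str(row["other_allele"]),
            beta=float(row["beta"]), se=float(row["se"]), pvalue=float(row["pvalue"]),
            n_total=int(row["n_total"]), eaf=_opt(row.get("eaf"), float),
            n_case=_opt(row.get("n_case"), int), n_control=_opt(row.get("n_control"), int),
        )

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatsSet":
        """New set restricted to ``snp_ids``, preserving the given order."""
        order = {s: i for i, s in enumerate(snp_ids)}
        sub = self.frame[self.frame["snp_id"].isin(order)].copy()
        sub = sub.sort_values("snp_id", key=lambda s: s.map(order))
        return SummaryStatsSet(self.trait_name, self.trait_type, sub)

    def equals(self, other: "SummaryStatsSet", atol: float = 0.0) -> bool:
        if (self.trait_name, self.trait_type) != (other.trait_name, other.trait_type):
            return False
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        a = a.sort_values("snp_id").reset_index(drop=True)
        b = b.sort_values("snp_id").reset_index(drop=True)
        for col in SUMMARY_COLUMNS:
            x, y = a[col], b[col]
            if col in ("snp_id", "chrom", "effect_allele", "other_allele"):
                if not (x.astype(str) == y.astype(str)).all():
                    return False
            else:
                xv = x.astype(float).to_numpy()
                yv = y.astype(float).to_numpy()
                both_nan = np.isnan(xv) & np.isnan(yv)
                close = np.isclose(xv, yv, rtol=0.0, atol=atol, equal_nan=True)
                if not (both_nan | close).all():
                    return False
        return True


class LDReference:
    """Block-diagonal SNP-SNP correlation lookup.

    ``blocks`` is a list of ``(snp_ids, corr_matrix)``; any pair of SNPs
    not sharing a block has r = 0.
    """

    def __init__(self, blocks: list[tuple[list[str], np.ndarray]]):
        self._block_of: dict[str, int] = {}
        self._index_in_block: dict[str, int] = {}
        self.blocks = []
        for b, (ids, mat) in enumerate(blocks):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(ids), len(ids)):
                raise ValueError("block matrix shape does not match member count")
            if not np.allclose(mat, mat.T):
                raise ValueError("block matrix must be symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError("block matrix must have unit diagonal")
            if np.abs(mat).max() > 1.0 + 1e-12:
                raise ValueError("correlations must lie in [-1, 1]")
            self.blocks.append((list(ids), mat))
            for i, s in enumerate(ids):
                self._block_of[s] = b
                self._index_in_block[s] = i

    def r(self, snp_i: str, snp_j: str) -> float:
        """Correlation between two SNPs; 0 for cross-block or unknown pairs."""
        if snp_i == snp_j:
            return 1.0
        bi = self._block_of.get(snp_i)
        bj = self._block_of.get(snp_j)
        if bi is None or bj is None or bi != bj:
            return 0.0
        mat = self.blocks[bi][1]
        return float(mat[self._index_in_block[snp_i], self._index_in_block[snp_j]])

    def r2(self, snp_i: str, snp_j: str) -> float:
        return self.r(snp_i, snp_j) ** 2


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effect pair for one SNP.

    ``action`` records the transformation applied to the outcome record to
    express both effects on the exposure's effect allele.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    action: str = "kept_as_is"
    drop_reason: str = ""

    @property
    def kept(self) -> bool:
        return self.action != "dropped"


def pairs_frame(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Tabular view of harmonized pairs (kept and dropped)."""
    cols = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
            "eaf_exp", "eaf_out", "action", "drop_reason"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in pairs], columns=cols)


def kept_arrays(pairs: list[HarmonizedPair]):
    """(beta_exp, se_exp, beta_out, se_out) arrays over kept pairs."""
    kept = [p for p in pairs if p.kept]
    bx = np.array([p.beta_exp for p in kept], dtype=float)
    sx = np.array([p.se_exp for p in kept], dtype=float)
    by = np.array([p.beta_out for p in kept], dtype=float)
    sy = np.array([p.se_out for p in kept], dtype=float)
    return bx, sx, by, sy
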