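"""Instrument selection: p-value screen, greedy LD clumping, variance
explained, F-statistic strength filter and confounder blacklist.

Thresholds default to the relaxed screen used for molecular-trait GWAS
(p < 5e-5 for lipid and metabolite exposures, p < 5e-6 when the longevity
outcome is treated as the exposure), clumping at a 10,000 kb window with
r^2 < 0.001, and the conventional weak-instrument cut F > 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import ExclusionLog
from .records import GwasRecord, LDReference, SummaryStatsSet

P_THRESHOLD_EXPOSURE = 5e-5
P_THRESHOLD_OUTCOME = 5e-6
CLUMP_WINDOW_KB = 10_000
CLUMP_R2 = 0.001
MIN_F = 10.0


@dataclass
class InstrumentSet:
    """Clumped, strength-screened instruments for one trait."""

    trait_name: str
    snp_ids: list[str]
    per_snp_r2: dict[str, float]
    n_sample: int
    f_stat: float

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @property
    def sum_r2(self) -> float:
        return float(sum(self.per_snp_r2.values()))


def filter_by_pvalue(stats: SummaryStatsSet, threshold: float,
                     log: Optional[ExclusionLog] = None) -> SummaryStatsSet:
    """Keep records with p strictly below ``threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    keep = stats.frame["pvalue"] < threshold
    if log is not None:
        for s in stats.frame.loc[~keep, "snp_id"]:
            log.add(s, "pvalue_filter", f"p_ge_{threshold:g}")
    return SummaryStatsSet(stats.trait_name, stats.trait_type,
                           stats.frame.loc[keep])


def ld_clump(stats: SummaryStatsSet, ld: LDReference,
             window_kb: float = CLUMP_WINDOW_KB, r2_max: float = CLUMP_R2,
             log: Optional[ExclusionLog] = None) -> SummaryStatsSet:
    """Greedy clumping: scan by ascending p, keep a SNP iff its r^2 with
    every already-kept SNP within ``window_kb`` on the same chromosome is
    below ``r2_max``. Ties in p break by ascending position then snp_id.
    """
    frame = stats.frame.sort_values(
        ["pvalue", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0
    kept: list[dict] = []
    kept_ids: list[str] = []
    for _, row in frame.iterrows():
        ok = True
        for kr in kept:
            if kr["chrom"] != row["chrom"]:
                continue
            if abs(int(kr["pos"]) - int(row["pos"])) > window_bp:
                continue
            if ld.r2(kr["snp_id"], row["snp_id"]) >= r2_max:
                ok = False
                break
        if ok:
            kept.append({"snp_id": row["snp_id"], "chrom": row["chrom"],
                         "pos": row["pos"]})
            kept_ids.append(row["snp_id"])
        elif log is not None:
            log.add(row["snp_id"], "ld_clump", "correlated_with_kept")
    return stats.subset(kept_ids)


def snp_r2(record: GwasRecord, method: str = "eaf") -> float:
    """Variance in the trait explained by one SNP.

    ``eaf`` (default): 2 p (1-p) beta^2 assuming unit trait variance;
    ``z``: beta^2 / (beta^2 + N se^2), usable when eaf is missing.
    Clipped to [0, 1).
    """
    if method == "eaf":
        if record.eaf is None:
            raise ValueError(f"{record.snp_id}: eaf required for R^2")
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta ** 2
    elif method == "z":
        r2 = record.beta ** 2 / (record.beta ** 2 + record.n_total * record.se ** 2)
    else:
        raise ValueError(f"unknown R^2 method {method!r}")
    return float(np.clip(r2, 0.0, np.nextafter(1.0, 0.0)))


def f_statistic(sum_r2: float, n_sample: int, k: int) -> float:
    """Instrument-strength F = (R^2/(1-R^2)) * ((N-K-1)/K)."""
    if not (0 <= sum_r2 < 1):
        raise ValueError("sum_r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_sample <= k + 1:
        raise ValueError("need N > K + 1")
    return (sum_r2 / (1.0 - sum_r2)) * ((n_sample - k - 1) / k)


def apply_blacklist(stats: SummaryStatsSet, blacklist: set[str],
                    log: Optional[ExclusionLog] = None) -> SummaryStatsSet:
    """Remove SNPs on a user-supplied confounder blacklist."""
    keep = ~stats.frame["snp_id"].isin(blacklist)
    if log is not None:
        for s in stats.frame.loc[~keep, "snp_id"]:
            log.add(s, "blacklist", "confounder_blacklist")
    return SummaryStatsSet(stats.trait_name, stats.trait_type,
                           stats.frame.loc[keep])


def select_instruments(stats: SummaryStatsSet, ld: LDReference,
                       p_threshold: float = P_THRESHOLD_EXPOSURE,
                       window_kb: float = CLUMP_WINDOW_KB,
                       r2_max: float = CLUMP_R2,
                       min_f: float = MIN_F,
                       f_mode: str = "set",
                       r2_method: str = "eaf",
                       blacklist: Optional[set[str]] = None,
                       log: Optional[ExclusionLog] = None
                       ) -> tuple[SummaryStatsSet, Optional[InstrumentSet]]:
    """Full selection chain: p-screen → blacklist → clump → F filter.

    ``f_mode='set'`` applies F > min_f to the aggregate sum-R^2 form (the
    whole set is rejected when it fails); ``'snp'`` screens each SNP by its
    single-instrument F. Returns the surviving set and its InstrumentSet
    summary (None when nothing survives).
    """
    stage = filter_by_pvalue(stats, p_threshold, log=log)
    if blacklist:
        stage = apply_blacklist(stage, blacklist, log=log)
    stage = ld_clump(stage, ld, window_kb=window_kb, r2_max=r2_max, log=log)
    if len(stage) == 0:
        return stage, None

    per_snp: dict[str, float] = {}
    usable: list[str] = []
    for rec in stage.records():
        try:
            r2 = snp_r2(rec, method=r2_method)
        except ValueError:
            if log is not None:
                log.add(rec.snp_id, "f_filter", "missing_eaf")
            continue
        per_snp[rec.snp_id] = r2
        usable.append(rec.snp_id)
    stage = stage.subset(usable)
    if len(stage) == 0:
        return stage, None

    n_sample = int(stage.frame["n_total"].iloc[0])
    if f_mode == "snp":
        keep = []
        for s in usable:
            f1 = f_statistic(per_snp[s], n_sample, 1)
            if f1 > min_f:
                keep.append(s)
            elif log is not None:
                log.add(s, "f_filter", f"per_snp_F_le_{min_f:g}")
        stage = stage.subset(keep)
        per_snp = {s: per_snp[s] for s in keep}
        if len(stage) == 0:
            return stage, None
        fval = f_statistic(sum(per_snp.values()), n_sample, len(keep))
    elif f_mode == "set":
        fval = f_statistic(sum(per_snp.values()), n_sample, len(usable))
        # single-instrument sets additionally face the per-SNP screen
        if fval <= min_f or (len(usable) == 1 and fval <= min_f):
            if log is not None:
                for s in usable:
                    log.add(s, "f_filter", f"set_F_le_{min_f:g}")
            return stage.subset([]), None
    else:
        raise ValueError(f"unknown f_mode {f_mode!r}")

    inst = InstrumentSet(trait_name=stats.trait_name, snp_ids=stage.snp_ids,
                         per_snp_r2=per_snp, n_sample=n_sample, f_stat=fval)
    return stage, inst
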