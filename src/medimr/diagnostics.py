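"""Heterogeneity, pleiotropy and robustness diagnostics.

Cochran's Q tests instrument heterogeneity around the fixed-effect IVW
fit; MR-PRESSO detects pleiotropic outlier SNPs by comparing leave-one-out
weighted residual sums against a parametric simulation of the no-pleiotropy
null (global, per-SNP outlier and distortion components); leave-one-out
re-estimates IVW with each instrument removed in turn.

A result "fails QC" — is flagged, not errored — when the Egger intercept,
the PRESSO distortion test or Cochran's Q rejects at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MRModel, MRResults
from .records import HarmonizedPair, kept_arrays


@dataclass
class QResult:
    """Cochran's Q heterogeneity test around the fixed-effect IVW fit."""

    Q: float
    df: int
    pvalue: float

    @property
    def homogeneous(self) -> bool:
        return self.pvalue >= 0.05


@dataclass
class PressoResult:
    """MR-PRESSO global / outlier / distortion results."""

    global_rss: float
    global_p: float
    outlier_p: dict[str, float]      # Bonferroni-adjusted per-SNP p-values
    outliers: list[str]
    distortion_p: Optional[float]
    estimate_before: MRResults
    estimate_after: Optional[MRResults]
    n_sim: int
    seed: int

    @property
    def biased(self) -> Optional[bool]:
        return None if self.distortion_p is None else self.distortion_p < 0.05


@dataclass
class LooResult:
    """Leave-one-out IVW estimates and the robustness verdict."""

    table: pd.DataFrame  # left_out, beta, se, ci_low, ci_high, pvalue
    full: MRResults

    @property
    def robust(self) -> bool:
        """No single omission changes the sign or the alpha=0.05 verdict."""
        full_sig = self.full.pvalue < 0.05
        full_sign = np.sign(self.full.beta)
        for _, row in self.table.iterrows():
            if np.sign(row["beta"]) != full_sign:
                return False
            if (row["pvalue"] < 0.05) != full_sig:
                return False
        return True


def cochran_q(pairs: list[HarmonizedPair]) -> QResult:
    """Q = sum w_j (beta_out_j - beta_ivw * beta_exp_j)^2, w = 1/se_out^2."""
    bx, _, by, sy = kept_arrays(pairs)
    if len(bx) < 2:
        raise ValueError("Cochran's Q needs >= 2 pairs")
    w = 1.0 / sy ** 2
    beta = np.sum(w * bx * by) / np.sum(w * bx ** 2)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = len(bx) - 1
    return QResult(Q=q, df=df, pvalue=float(sps.chi2.sf(q, df)))


def _loo_ivw_beta(w, bx, by):
    """Vectorised leave-one-out fixed-effect IVW slopes (length J)."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx ** 2)
    return (s_xy - w * bx * by) / (s_xx - w * bx ** 2)


def mr_presso(pairs: list[HarmonizedPair], n_sim: int = 5000, seed: int = 0,
              alpha: float = 0.05, n_subsets: int = 1000) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    Observed statistic: the weighted residual sum with each SNP's residual
    taken against the IVW fit that excludes it. The null distribution is
    built by redrawing the summary effects from their sampling
    distributions around that leave-one-out fit and recomputing the same
    statistic; ``global_p`` is the upper-tail fraction. Per-SNP outlier
    p-values are Bonferroni-adjusted; when outliers are found, the
    distortion test locates the outlier-free estimate within the
    distribution of estimates from random same-size subsets.
    """
    kept = [p for p in pairs if p.kept]
    if len(kept) < 4:
        raise ValueError("PRESSO needs >= 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = kept_arrays(kept)
    ids = [p.snp_id for p in kept]
    J = len(bx)
    w = 1.0 / sy ** 2

    loo_beta = _loo_ivw_beta(w, bx, by)
    obs_res2 = w * (by - loo_beta * bx) ** 2
    obs_rss = float(np.sum(obs_res2))

    # parametric null: redraw both summary effects around the LOO fit
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(loo_beta * bx, sy, size=(n_sim, J))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim ** 2, axis=1, keepdims=True)
    loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim ** 2)
    sim_res2 = w * (by_sim - loo_sim * bx_sim) ** 2
    sim_rss = np.sum(sim_res2, axis=1)

    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))

    raw_p = (np.sum(sim_res2 >= obs_res2[None, :], axis=0) + 1) / (n_sim + 1)
    adj_p = np.minimum(raw_p * J, 1.0)
    outlier_p = dict(zip(ids, adj_p.astype(float)))
    outliers = [s for s, p in outlier_p.items() if p < alpha]

    before = MRModel(kept).fit("ivw", model="fixed")
    after = None
    distortion_p = None
    if outliers and len(kept) - len(outliers) >= 2:
        keep_mask = np.array([s not in outliers for s in ids])
        after_model = MRModel([p for p, k in zip(kept, keep_mask) if k])
        after = after_model.fit("ivw", model="fixed")
        # distortion: where does the cleaned estimate fall among estimates
        # from random subsets of the same size?
        m = int(keep_mask.sum())
        subset_betas = np.empty(n_subsets)
        for i in range(n_subsets):
            idx = rng.choice(J, size=m, replace=False)
            subset_betas[i] = (np.sum(w[idx] * bx[idx] * by[idx])
                               / np.sum(w[idx] * bx[idx] ** 2))
        frac = (np.sum(subset_betas <= after.beta) + 1) / (n_subsets + 1)
        distortion_p = float(2.0 * min(frac, 1.0 - frac))
    return PressoResult(global_rss=obs_rss, global_p=global_p,
                        outlier_p=outlier_p, outliers=outliers,
                        distortion_p=distortion_p, estimate_before=before,
                        estimate_after=after, n_sim=n_sim, seed=seed)


def leave_one_out(pairs: list[HarmonizedPair],
                  ivw_model: str = "mre") -> LooResult:
    """Re-fit IVW with each instrument excluded in turn."""
    kept = [p for p in pairs if p.kept]
    if len(kept) < 3:
        raise ValueError("leave-one-out needs >= 3 pairs")
    full = MRModel(kept).fit("ivw", model=ivw_model)
    rows = []
    for j in range(len(kept)):
        sub = kept[:j] + kept[j + 1:]
        res = MRModel(sub).fit("ivw", model=ivw_model)
        rows.append({"left_out": kept[j].snp_id, "beta": res.beta,
                     "se": res.se, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "pvalue": res.pvalue})
    return LooResult(table=pd.DataFrame(rows), full=full)


def qc_verdict(q: Optional[QResult], egger_intercept_p: Optional[float],
               presso: Optional[PressoResult], alpha: float = 0.05) -> tuple[bool, list[str]]:
    """Aggregate pass/fail QC with reasons; missing diagnostics don't fail."""
    reasons = []
    if q is not None and q.pvalue < alpha:
        reasons.append("heterogeneity")
    if egger_intercept_p is not None and egger_intercept_p < alpha:
        reasons.append("egger_intercept")
    if presso is not None and presso.distortion_p is not None \
            and presso.distortion_p < alpha:
        reasons.append("presso_distortion")
    return (len(reasons) == 0, reasons)
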