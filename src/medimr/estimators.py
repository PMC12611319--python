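"""Causal-effect estimators on harmonized summary statistics.

:class:`MRModel` is built from harmonized exposure/outcome pairs and its
``fit(method=...)`` returns an :class:`MRResults` carrying the estimate,
its uncertainty, the odds-ratio transform and (for Egger) the intercept
test. The module-level functions ``wald_ratio``, ``ivw``, ``egger`` and
``weighted_median`` are thin wrappers over the same fits.

Methods
-------
wald_ratio
    beta_out / beta_exp for a single instrument, first-order (or optional
    second-order) standard error.
ivw
    Inverse-variance-weighted regression of outcome on exposure effects
    through the origin, weights 1/se_out^2. ``model='fixed'`` uses the
    fixed-effect SE; ``'mre'`` (multiplicative random effects, the default)
    inflates it by max(1, sqrt(Q/(J-1))).
egger
    The same regression with a free intercept; a non-zero intercept is the
    signature of directional horizontal pleiotropy. Slope/intercept SEs use
    the weighted fit with residual inflation max(1, sqrt(RSS_w/(J-2))).
weighted_median
    Median of the weight-ordered per-SNP ratio estimates; consistent when
    at least half the weight comes from valid instruments. SE by seeded
    parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .records import HarmonizedPair, kept_arrays

Z975 = sps.norm.ppf(0.975)


@dataclass
class MRResults:
    """One estimator's causal estimate with uncertainty and transforms."""

    method: str
    beta: float
    se: float
    n_snps: int
    pvalue: float = None  # type: ignore[assignment]
    ci_low: float = None  # type: ignore[assignment]
    ci_high: float = None  # type: ignore[assignment]
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self):
        if self.ci_low is None:
            self.ci_low = self.beta - Z975 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z975 * self.se
        if self.pvalue is None:
            if self.se > 0:
                p = 2.0 * sps.norm.sf(abs(self.beta) / self.se)
            else:
                p = 0.0 if self.beta != 0 else 1.0
            self.pvalue = float(min(max(p, np.finfo(float).tiny), 1.0))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        lo, hi = self.or_ci
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": self.method, "n_snps": self.n_snps,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio, "or_ci_low": lo, "or_ci_high": hi,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
        }

    def summary(self) -> str:
        lo, hi = self.or_ci
        lines = [
            f"MR estimate [{self.method}]  {self.exposure or 'exposure'} -> "
            f"{self.outcome or 'outcome'}",
            f"  n_snps      {self.n_snps}",
            f"  beta        {self.beta:+.5f}  (SE {self.se:.5f})",
            f"  95% CI      [{self.ci_low:+.5f}, {self.ci_high:+.5f}]",
            f"  p-value     {self.pvalue:.3g}",
            f"  OR (95% CI) {self.odds_ratio:.3f} ({lo:.3f}-{hi:.3f})",
        ]
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept {self.egger_intercept:+.5f} "
                f"(SE {self.egger_intercept_se:.5f}, p {self.egger_intercept_p:.3g})")
        return "\n".join(lines)


class MRModel:
    """Two-sample MR model over harmonized instrument pairs.

    Parameters
    ----------
    pairs
        Harmonized pairs; dropped pairs are ignored.
    exposure, outcome
        Trait labels carried through to results tables.
    """

    def __init__(self, pairs: list[HarmonizedPair], exposure: str = "",
                 outcome: str = ""):
        self.pairs = [p for p in pairs if p.kept]
        self.exposure = exposure
        self.outcome = outcome
        self.bx, self.sx, self.by, self.sy = kept_arrays(self.pairs)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    exposure: str = "", outcome: str = "") -> "MRModel":
        pairs = [HarmonizedPair(snp_id=f"snp{i}", beta_exp=float(a),
                                se_exp=float(b), beta_out=float(c),
                                se_out=float(d))
                 for i, (a, b, c, d) in enumerate(zip(beta_exp, se_exp,
                                                      beta_out, se_out))]
        return cls(pairs, exposure=exposure, outcome=outcome)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, exposure: str = "",
                       outcome: str = "") -> "MRModel":
        kept = frame[frame.get("action", "kept_as_is") != "dropped"] \
            if "action" in frame.columns else frame
        return cls.from_arrays(kept["beta_exp"], kept["se_exp"],
                               kept["beta_out"], kept["se_out"],
                               exposure=exposure, outcome=outcome)

    @property
    def n_snps(self) -> int:
        return len(self.bx)

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        fitter = {
            "wald_ratio": self._fit_wald, "ivw": self._fit_ivw,
            "ivw_fe": lambda **kw: self._fit_ivw(model="fixed", **kw),
            "ivw_mre": lambda **kw: self._fit_ivw(model="mre", **kw),
            "egger": self._fit_egger, "weighted_median": self._fit_wm,
        }.get(method)
        if fitter is None:
            raise ValueError(f"unknown method {method!r}")
        res = fitter(**kwargs)
        res.exposure = self.exposure
        res.outcome = self.outcome
        return res

    def fit_all(self, seed: int = 0) -> list[MRResults]:
        """IVW (default model), Egger and weighted median where estimable."""
        out = [self.fit("ivw")]
        if self.n_snps >= 3:
            out.append(self.fit("egger"))
            out.append(self.fit("weighted_median", seed=seed))
        return out

    # --- individual estimators -------------------------------------------

    def _fit_wald(self, second_order: bool = False) -> MRResults:
        if self.n_snps != 1:
            raise ValueError("wald_ratio requires exactly one pair")
        bx, sx, by, sy = self.bx[0], self.sx[0], self.by[0], self.sy[0]
        if bx == 0:
            raise ZeroDivisionError("undefined ratio: beta_exp = 0")
        beta = by / bx
        var = sy ** 2 / bx ** 2
        if second_order:
            var += by ** 2 * sx ** 2 / bx ** 4
        return MRResults(method="wald_ratio", beta=float(beta),
                         se=float(np.sqrt(var)), n_snps=1)

    def _fit_ivw(self, model: str = "mre") -> MRResults:
        if self.n_snps < 1:
            raise ValueError("ivw needs at least one pair")
        if self.n_snps == 1:
            res = self._fit_wald()
            res.method = f"ivw_{'fe' if model == 'fixed' else model}"
            return res
        w = 1.0 / self.sy ** 2
        sxx = float(np.sum(w * self.bx ** 2))
        if sxx == 0:
            raise ZeroDivisionError("all beta_exp are zero")
        beta = float(np.sum(w * self.bx * self.by) / sxx)
        se = float(np.sqrt(1.0 / sxx))
        if model == "mre":
            q = float(np.sum(w * (self.by - beta * self.bx) ** 2))
            se *= max(1.0, np.sqrt(q / (self.n_snps - 1)))
            name = "ivw_mre"
        elif model == "fixed":
            name = "ivw_fe"
        else:
            raise ValueError(f"unknown IVW model {model!r}")
        return MRResults(method=name, beta=beta, se=se, n_snps=self.n_snps)

    def _fit_egger(self, t_dist: bool = False) -> MRResults:
        if self.n_snps < 3:
            raise ValueError("Egger underdetermined: needs >= 3 pairs")
        # orient so every exposure effect is non-negative (InSIDE convention)
        sign = np.where(self.bx < 0, -1.0, 1.0)
        bx, by = self.bx * sign, self.by * sign
        w = 1.0 / self.sy ** 2
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=w).fit()
        dof = self.n_snps - 2
        # multiplicative overdispersion, never deflating below the FE scale
        sigma = max(1.0, np.sqrt(fit.scale))
        if fit.scale > 0:
            base = np.diag(fit.cov_params()) / fit.scale
        else:  # exact fit: fall back to the unscaled (X'WX)^-1
            base = np.diag(np.linalg.inv(X.T @ (w[:, None] * X)))
        se0, se1 = np.sqrt(base) * sigma
        if t_dist:
            p_slope = 2.0 * sps.t.sf(abs(fit.params[1]) / se1, dof)
            p_int = 2.0 * sps.t.sf(abs(fit.params[0]) / se0, dof)
        else:
            p_slope = 2.0 * sps.norm.sf(abs(fit.params[1]) / se1)
            p_int = 2.0 * sps.norm.sf(abs(fit.params[0]) / se0)
        return MRResults(
            method="egger", beta=float(fit.params[1]), se=float(se1),
            pvalue=float(max(p_slope, np.finfo(float).tiny)),
            n_snps=self.n_snps,
            egger_intercept=float(fit.params[0]),
            egger_intercept_se=float(se0),
            egger_intercept_p=float(max(p_int, np.finfo(float).tiny)))

    def point_weighted_median(self, bx=None, by=None, sy=None, sx=None) -> float:
        """Weighted-median point estimate (no bootstrap)."""
        bx = self.bx if bx is None else bx
        by = self.by if by is None else by
        sx = self.sx if sx is None else sx
        sy = self.sy if sy is None else sy
        theta = by / bx
        w = 1.0 / (sy ** 2 / bx ** 2)  # first-order ratio variance
        order = np.argsort(theta)
        theta, w = theta[order], w[order]
        s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
        return float(np.interp(0.5, s, theta))

    def _fit_wm(self, n_boot: int = 1000, seed: int = 0) -> MRResults:
        if self.n_snps < 3:
            raise ValueError("weighted_median needs >= 3 pairs")
        est = self.point_weighted_median()
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            bx = rng.normal(self.bx, self.sx)
            by = rng.normal(self.by, self.sy)
            bx = np.where(bx == 0, np.finfo(float).eps, bx)
            boots[i] = self.point_weighted_median(bx=bx, by=by)
        se = float(np.std(boots, ddof=1))
        return MRResults(method="weighted_median", beta=est, se=se,
                         n_snps=self.n_snps)


# --- op-level wrappers -----------------------------------------------------

def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MRResults:
    return MRModel([pair]).fit("wald_ratio", second_order=second_order)


def ivw(pairs: list[HarmonizedPair], model: str = "mre") -> MRResults:
    return MRModel(pairs).fit("ivw", model=model)


def egger(pairs: list[HarmonizedPair], t_dist: bool = False) -> MRResults:
    return MRModel(pairs).fit("egger", t_dist=t_dist)


def weighted_median(pairs: list[HarmonizedPair], n_boot: int = 1000,
                    seed: int = 0) -> MRResults:
    return MRModel(pairs).fit("weighted_median", n_boot=n_boot, seed=seed)


def estimates_table(results: list[MRResults]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
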