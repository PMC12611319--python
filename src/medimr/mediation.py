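"""Two-step mediation on the MR estimates: the product of coefficients.

The causal diagram has an exposure, a candidate mediator and an outcome:
``a`` is the exposure→mediator effect, ``b`` the mediator→outcome effect,
``c`` the total exposure→outcome effect and ``d`` the reverse
outcome→exposure effect screened in phase 1. The indirect (mediated)
effect is ``a*b`` with the first-order delta-method (Sobel) standard error
sqrt(a^2 se_b^2 + b^2 se_a^2); the direct effect is ``c' = c - a*b`` and
the mediated proportion is ``(a*b)/c``. All algebra is on the log /
log-odds scale; odds ratios are display-only transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .estimators import MRResults, Z975


@dataclass
class ScreenResult:
    passed: bool
    reasons: list[str]


def bidirectional_screen(forward: MRResults,
                         reverse: Optional[MRResults],
                         alpha: float = 0.05) -> ScreenResult:
    """Phase-1 rule: a significant forward effect and no significant
    reverse effect. A reverse leg with no usable instruments counts as no
    evidence of reverse causation (recorded in the reasons)."""
    reasons = []
    if forward.pvalue >= alpha:
        reasons.append("no forward effect")
    if reverse is None:
        reasons.append("reverse leg not estimable (treated as null)")
    elif reverse.pvalue < alpha:
        reasons.append("reverse causation")
    passed = forward.pvalue < alpha and (reverse is None or reverse.pvalue >= alpha)
    return ScreenResult(passed=passed, reasons=reasons)


def mediated_effect(a: MRResults, b: MRResults,
                    second_order: bool = False) -> tuple[float, float, tuple[float, float], float]:
    """Product-of-coefficients indirect effect with delta-method CI.

    Returns (ab, se_ab, (ci_low, ci_high), pvalue). ``second_order`` adds
    the se_a^2 se_b^2 cross term to the Sobel variance.
    """
    ab = a.beta * b.beta
    var = a.beta ** 2 * b.se ** 2 + b.beta ** 2 * a.se ** 2
    if second_order:
        var += a.se ** 2 * b.se ** 2
    se = float(np.sqrt(var))
    ci = (ab - Z975 * se, ab + Z975 * se)
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(ab) / se))
    else:
        p = 1.0 if ab == 0 else 0.0
    return float(ab), se, ci, max(p, np.finfo(float).tiny)


def mediated_proportion(ab: float, c: float) -> tuple[float, bool]:
    """(a*b)/c as a fraction, plus an inconsistent-mediation flag.

    Flagged when the indirect and total effects disagree in sign or the
    proportion exceeds 1 in magnitude; hard error when c = 0.
    """
    if c == 0:
        raise ZeroDivisionError("total effect c is zero")
    prop = ab / c
    inconsistent = (np.sign(ab) != np.sign(c) and ab != 0) or abs(prop) > 1
    return float(prop), bool(inconsistent)


@dataclass
class MediationResults:
    """One exposure→mediator→outcome pathway with all paths populated."""

    exposure: str
    mediator: str
    outcome: str
    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    c: float
    se_c: float
    p_c: float
    mediated: float
    se_mediated: float
    ci_mediated: tuple[float, float]
    p_mediated: float
    proportion: float
    inconsistent: bool
    d: Optional[float] = None
    se_d: Optional[float] = None
    p_d: Optional[float] = None
    included: bool = True
    exclusion_reasons: list[str] = field(default_factory=list)

    @property
    def c_prime(self) -> float:
        """Direct effect; c' + a*b = c holds exactly by construction."""
        return self.c - self.mediated

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_row(self) -> dict:
        lo, hi = self.ci_mediated
        return {
            "exposure": self.exposure, "mediator": self.mediator,
            "outcome": self.outcome,
            "a": self.a, "se_a": self.se_a, "p_a": self.p_a,
            "or_a": float(np.exp(self.a)),
            "b": self.b, "se_b": self.se_b, "p_b": self.p_b,
            "or_b": float(np.exp(self.b)),
            "c": self.c, "se_c": self.se_c, "p_c": self.p_c,
            "or_c": float(np.exp(self.c)),
            "c_prime": self.c_prime,
            "mediated_effect": self.mediated, "se_mediated": self.se_mediated,
            "ci_mediated_low": lo, "ci_mediated_high": hi,
            "p_mediated": self.p_mediated,
            "mediated_proportion_pct": self.proportion_pct,
            "inconsistent_mediation": self.inconsistent,
            "included": self.included,
            "exclusion_reasons": ";".join(self.exclusion_reasons),
        }

    def summary(self) -> str:
        lo, hi = self.ci_mediated
        return "\n".join([
            f"Mediation pathway  {self.exposure} -> {self.mediator} -> {self.outcome}",
            f"  a (exposure->mediator)   {self.a:+.4f} (SE {self.se_a:.4f}, "
            f"OR {np.exp(self.a):.3f}, p {self.p_a:.3g})",
            f"  b (mediator->outcome)    {self.b:+.4f} (SE {self.se_b:.4f}, "
            f"OR {np.exp(self.b):.3f}, p {self.p_b:.3g})",
            f"  c (total effect)         {self.c:+.4f} (SE {self.se_c:.4f}, "
            f"OR {np.exp(self.c):.3f}, p {self.p_c:.3g})",
            f"  c' (direct effect)       {self.c_prime:+.4f}",
            f"  mediated effect a*b      {self.mediated:+.4f} "
            f"(95% CI {lo:+.4f} to {hi:+.4f}, p {self.p_mediated:.3g})",
            f"  mediated proportion      {self.proportion_pct:.2f}%"
            + ("  [inconsistent]" if self.inconsistent else ""),
            f"  included: {self.included}"
            + (f"  ({'; '.join(self.exclusion_reasons)})"
               if self.exclusion_reasons else ""),
        ])


class MediationModel:
    """Assembles a mediation pathway from its three (plus reverse) MR legs.

    Parameters are the fitted :class:`MRResults` for each leg: ``a``
    (exposure→mediator), ``b`` (mediator→outcome), ``c`` (total
    exposure→outcome) and optionally ``reverse`` (outcome→exposure, the
    phase-1 screen leg).
    """

    def __init__(self, a: MRResults, b: MRResults, c: MRResults,
                 reverse: Optional[MRResults] = None,
                 exposure: str = "", mediator: str = "", outcome: str = ""):
        for name, leg in (("a", a), ("b", b), ("c", c)):
            if leg is None:
                raise ValueError(f"missing leg {name!r}")
        self.a, self.b, self.c, self.reverse = a, b, c, reverse
        self.exposure = exposure or a.exposure
        self.mediator = mediator or b.exposure
        self.outcome = outcome or c.outcome

    def fit(self, alpha: float = 0.05, second_order: bool = False,
            qc_pass: bool = True,
            qc_reasons: Optional[list[str]] = None) -> MediationResults:
        """Compute the product-of-coefficients path and the inclusion rule.

        A pathway is included when all three legs are significant at
        ``alpha``, the bidirectional screen passes and QC passed.
        """
        ab, se_ab, ci, p_ab = mediated_effect(self.a, self.b,
                                              second_order=second_order)
        prop, inconsistent = mediated_proportion(ab, self.c.beta)
        screen = bidirectional_screen(self.c, self.reverse, alpha=alpha)

        reasons = []
        if self.a.pvalue >= alpha:
            reasons.append("exposure->mediator not significant")
        if self.b.pvalue >= alpha:
            reasons.append("mediator->outcome not significant")
        if not screen.passed:
            reasons.extend(r for r in screen.reasons
                           if "treated as null" not in r)
        if not qc_pass:
            reasons.extend(f"qc:{r}" for r in (qc_reasons or ["failed"]))

        return MediationResults(
            exposure=self.exposure, mediator=self.mediator,
            outcome=self.outcome,
            a=self.a.beta, se_a=self.a.se, p_a=self.a.pvalue,
            b=self.b.beta, se_b=self.b.se, p_b=self.b.pvalue,
            c=self.c.beta, se_c=self.c.se, p_c=self.c.pvalue,
            mediated=ab, se_mediated=se_ab, ci_mediated=ci, p_mediated=p_ab,
            proportion=prop, inconsistent=inconsistent,
            d=None if self.reverse is None else self.reverse.beta,
            se_d=None if self.reverse is None else self.reverse.se,
            p_d=None if self.reverse is None else self.reverse.pvalue,
            included=len(reasons) == 0, exclusion_reasons=reasons)


def assemble_pathway(a: MRResults, b: MRResults, c: MRResults,
                     reverse: Optional[MRResults] = None,
                     alpha: float = 0.05, qc_pass: bool = True,
                     qc_reasons: Optional[list[str]] = None) -> MediationResults:
    """Op-level wrapper over :class:`MediationModel`."""
    return MediationModel(a, b, c, reverse=reverse).fit(
        alpha=alpha, qc_pass=qc_pass, qc_reasons=qc_reasons)


def path_from_odds_ratios(or_a: float, or_b: float, or_c: float,
                          se_a: float = float("nan"), se_b: float = float("nan"),
                          se_c: float = float("nan")) -> tuple[float, float]:
    """Mediated effect and proportion (fraction) from reported odds ratios.

    Convenience for re-deriving published mediation arithmetic from the
    leg and total odds ratios alone: a = ln(or_a), b = ln(or_b),
    c = ln(or_c); returns (a*b, (a*b)/c).
    """
    a, b, c = np.log(or_a), np.log(or_b), np.log(or_c)
    ab = float(a * b)
    prop, _ = mediated_proportion(ab, float(c))
    return ab, prop
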