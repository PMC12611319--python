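"""End-to-end orchestration of the two-phase mediation MR analysis.

Phase 1 screens the exposure→outcome relationship bidirectionally: the
forward leg must be significant and the reverse leg (outcome treated as
the exposure, at its stricter instrument threshold) must not be. Phase 2
estimates the exposure→mediator (a) and mediator→outcome (b) legs and
assembles the product-of-coefficients pathway with QC from the
heterogeneity, Egger-intercept and PRESSO diagnostics.

Every stage logs excluded SNPs to one machine-readable table; a fixed
config (including seeds) reproduces every output byte for byte.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .diagnostics import (LooResult, PressoResult, QResult, cochran_q,
                          leave_one_out, mr_presso, qc_verdict)
from .estimators import MRModel, MRResults, estimates_table
from .harmonize import harmonize
from .instruments import select_instruments
from .mediation import MediationModel, MediationResults
from .records import LDReference, SummaryStatsSet, pairs_frame
from .simulate import FIXTURES, fixture_config, simulate_mediation_gwas


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the study-design defaults."""

    exposure_path: Optional[str] = None
    mediator_path: Optional[str] = None
    outcome_path: Optional[str] = None
    ld_path: Optional[str] = None
    blacklist_path: Optional[str] = None
    fixture: Optional[str] = None          # alternative to the three paths
    fixture_seed: Optional[int] = None     # overrides the fixture's canonical seed
    p_threshold_exposure: float = 5e-5
    p_threshold_outcome: float = 5e-6
    clump_kb: float = 10_000
    clump_r2: float = 0.001
    min_f: float = 10.0
    f_mode: str = "set"
    alpha: float = 0.05
    ivw_model: str = "mre"
    wm_boot: int = 1000
    presso_nsim: int = 5000
    presso_subsets: int = 1000
    run_presso: bool = True
    run_loo: bool = True
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class LegResult:
    """One MR leg: selection, harmonization, estimates and diagnostics."""

    name: str
    exposure: str
    outcome: str
    estimable: bool
    n_instruments: int = 0
    f_stat: Optional[float] = None
    pairs: list = field(default_factory=list)
    estimates: dict[str, MRResults] = field(default_factory=dict)
    q: Optional[QResult] = None
    presso: Optional[PressoResult] = None
    loo: Optional[LooResult] = None
    note: str = ""

    @property
    def primary(self) -> Optional[MRResults]:
        for key in ("ivw_mre", "ivw_fe", "wald_ratio"):
            if key in self.estimates:
                return self.estimates[key]
        return None

    def qc(self, alpha: float = 0.05):
        egger_p = None
        if "egger" in self.estimates:
            egger_p = self.estimates["egger"].egger_intercept_p
        return qc_verdict(self.q, egger_p, self.presso, alpha=alpha)


@dataclass
class PipelineReport:
    config: RunConfig
    legs: dict[str, LegResult]
    pathway: Optional[MediationResults]
    screen_passed: bool
    screen_reasons: list[str]
    log: gio.ExclusionLog

    @property
    def pathways(self) -> list[MediationResults]:
        return [self.pathway] if (self.pathway is not None
                                  and self.pathway.included) else []

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for leg in self.legs.values():
            for res in leg.estimates.values():
                row = res.to_row()
                row["leg"] = leg.name
                rows.append(row)
        return pd.DataFrame(rows)

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for leg in self.legs.values():
            ok, reasons = leg.qc()
            rows.append({
                "leg": leg.name, "estimable": leg.estimable,
                "n_instruments": leg.n_instruments, "f_stat": leg.f_stat,
                "q": None if leg.q is None else leg.q.Q,
                "q_pvalue": None if leg.q is None else leg.q.pvalue,
                "egger_intercept_p": (leg.estimates["egger"].egger_intercept_p
                                      if "egger" in leg.estimates else None),
                "presso_global_p": (leg.presso.global_p
                                    if leg.presso is not None else None),
                "presso_outliers": (";".join(leg.presso.outliers)
                                    if leg.presso is not None else None),
                "presso_distortion_p": (leg.presso.distortion_p
                                        if leg.presso is not None else None),
                "loo_robust": (leg.loo.robust if leg.loo is not None else None),
                "qc_pass": ok, "qc_reasons": ";".join(reasons),
                "note": leg.note,
            })
        return pd.DataFrame(rows)

    def pathway_frame(self) -> pd.DataFrame:
        rows = [self.pathway.to_row()] if self.pathway is not None else []
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"medimr {__version__} pipeline report", ""]
        for leg in self.legs.values():
            if not leg.estimable:
                lines.append(f"[{leg.name}] not estimable ({leg.note})")
                continue
            p = leg.primary
            lo, hi = p.or_ci
            lines.append(
                f"[{leg.name}] {leg.exposure} -> {leg.outcome}: "
                f"OR {p.odds_ratio:.3f} ({lo:.3f}-{hi:.3f}), p {p.pvalue:.3g}, "
                f"{leg.n_instruments} SNPs, F {leg.f_stat:.1f}")
        lines.append("")
        lines.append(f"bidirectional screen: "
                     f"{'pass' if self.screen_passed else 'fail'}"
                     + (f" ({'; '.join(self.screen_reasons)})"
                        if self.screen_reasons else ""))
        if self.pathway is not None:
            lines.append("")
            lines.append(self.pathway.summary())
        else:
            lines.append("pathway: not estimable")
        return "\n".join(lines)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_table(self.estimates_frame(), outdir / "estimates.tsv")
        gio.write_table(self.diagnostics_frame(), outdir / "diagnostics.tsv")
        gio.write_table(self.pathway_frame(), outdir / "pathways.tsv")
        for name, leg in self.legs.items():
            if leg.pairs:
                gio.write_table(pairs_frame(leg.pairs),
                                outdir / f"harmonized_{name}.tsv")
        self.log.write(outdir / "exclusions.tsv")
        manifest = {"medimr_version": __version__,
                    "config": asdict(self.config)}
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def _load_inputs(config: RunConfig):
    if config.fixture is not None:
        cfg = fixture_config(config.fixture, seed=config.fixture_seed)
        exposure, mediator, outcome, ld, _ = simulate_mediation_gwas(cfg)
    else:
        for name in ("exposure_path", "mediator_path", "outcome_path", "ld_path"):
            if getattr(config, name) is None:
                raise ValueError(f"config needs {name} (or a fixture name)")
        exposure = gio.read_summary_stats(config.exposure_path, "exposure",
                                          "quantitative")
        mediator = gio.read_summary_stats(config.mediator_path, "mediator",
                                          "quantitative")
        outcome = gio.read_summary_stats(config.outcome_path, "outcome",
                                         "binary")
        ld = gio.read_ld_reference(config.ld_path)
    blacklist = (gio.read_blacklist(config.blacklist_path)
                 if config.blacklist_path else set())
    return exposure, mediator, outcome, ld, blacklist


def run_leg(name: str, exp_stats: SummaryStatsSet, out_stats: SummaryStatsSet,
            ld: LDReference, config: RunConfig, p_threshold: float,
            blacklist: set[str], log: gio.ExclusionLog,
            with_diagnostics: bool = True) -> LegResult:
    """Select instruments on the exposure side, harmonize against the
    outcome side, estimate and (optionally) run diagnostics."""
    leg_log = gio.ExclusionLog()
    selected, inst = select_instruments(
        exp_stats, ld, p_threshold=p_threshold, window_kb=config.clump_kb,
        r2_max=config.clump_r2, min_f=config.min_f, f_mode=config.f_mode,
        blacklist=blacklist, log=leg_log)
    leg = LegResult(name=name, exposure=exp_stats.trait_name,
                    outcome=out_stats.trait_name, estimable=False)

    def flush_log():
        # merge into the run-level log with the leg name on the stage
        for row in leg_log.rows:
            log.add(row["snp_id"], f"{name}.{row['stage']}", row["reason"])

    if inst is None:
        leg.note = "no instruments survived selection"
        flush_log()
        return leg
    pairs = harmonize(selected, out_stats, log=leg_log)
    flush_log()
    kept = [p for p in pairs if p.kept]
    leg.pairs = pairs
    if not kept:
        leg.note = "no instruments survived harmonization"
        return leg
    leg.estimable = True
    leg.n_instruments = len(kept)
    leg.f_stat = inst.f_stat

    model = MRModel(kept, exposure=exp_stats.trait_name,
                    outcome=out_stats.trait_name)
    if len(kept) == 1:
        leg.estimates["wald_ratio"] = model.fit("wald_ratio")
    else:
        leg.estimates[f"ivw_{'fe' if config.ivw_model == 'fixed' else config.ivw_model}"] = \
            model.fit("ivw", model=config.ivw_model)
        if len(kept) >= 3:
            leg.estimates["egger"] = model.fit("egger")
            leg.estimates["weighted_median"] = model.fit(
                "weighted_median", n_boot=config.wm_boot,
                seed=config.seed + 7)
    if with_diagnostics:
        if len(kept) >= 2:
            leg.q = cochran_q(kept)
        if config.run_loo and len(kept) >= 3:
            leg.loo = leave_one_out(kept, ivw_model=config.ivw_model)
        if config.run_presso and len(kept) >= 4:
            leg.presso = mr_presso(kept, n_sim=config.presso_nsim,
                                   seed=config.seed + 13,
                                   n_subsets=config.presso_subsets)
        elif config.run_presso:
            leg.note = (leg.note + "; " if leg.note else "") + \
                "PRESSO skipped: fewer than 4 instruments"
            print(f"warning: [{name}] PRESSO skipped, <4 instruments",
                  file=sys.stderr)
    return leg


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute both phases; returns the full report (and writes it when
    ``config.outdir`` is set). Zero surviving instruments on a leg makes
    the pathway "not estimable", never an error."""
    exposure, mediator, outcome, ld, blacklist = _load_inputs(config)
    log = gio.ExclusionLog()

    legs = {
        "total": run_leg("total", exposure, outcome, ld, config,
                         config.p_threshold_exposure, blacklist, log),
        "reverse": run_leg("reverse", outcome, exposure, ld, config,
                           config.p_threshold_outcome, blacklist, log),
        "a": run_leg("a", exposure, mediator, ld, config,
                     config.p_threshold_exposure, blacklist, log),
        "b": run_leg("b", mediator, outcome, ld, config,
                     config.p_threshold_exposure, blacklist, log),
    }

    pathway = None
    screen_passed = False
    screen_reasons: list[str] = []
    c_leg, rev, a_leg, b_leg = (legs["total"], legs["reverse"],
                                legs["a"], legs["b"])
    if not c_leg.estimable:
        screen_reasons.append("total leg not estimable")
    else:
        from .mediation import bidirectional_screen
        screen = bidirectional_screen(
            c_leg.primary, rev.primary if rev.estimable else None,
            alpha=config.alpha)
        screen_passed = screen.passed
        screen_reasons = screen.reasons
        if a_leg.estimable and b_leg.estimable:
            qc_ok, qc_reasons = True, []
            for leg in (c_leg, a_leg, b_leg):
                ok, reasons = leg.qc(alpha=config.alpha)
                if not ok:
                    qc_ok = False
                    qc_reasons.extend(f"{leg.name}:{r}" for r in reasons)
            pathway = MediationModel(
                a_leg.primary, b_leg.primary, c_leg.primary,
                reverse=rev.primary if rev.estimable else None,
                exposure=exposure.trait_name, mediator=mediator.trait_name,
                outcome=outcome.trait_name,
            ).fit(alpha=config.alpha, qc_pass=qc_ok, qc_reasons=qc_reasons)
        else:
            screen_reasons.append("mediation legs not estimable")

    report = PipelineReport(config=config, legs=legs, pathway=pathway,
                            screen_passed=screen_passed,
                            screen_reasons=screen_reasons, log=log)
    if config.outdir:
        report.write(config.outdir)
    return report
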