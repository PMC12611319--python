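"""Summary-level simulation of a three-trait GWAS with planted mediation.

The generator emulates the study design of a two-step mediation MR analysis:
a quantitative exposure (a lipid species), a quantitative mediator (a
circulating metabolite) and a binary outcome (surviving past the 90th
survival percentile), each observed only through GWAS summary statistics.

The causal triangle is parameterised by ``theta_em`` (exposure → mediator,
the *a* path), ``theta_mo`` (mediator → outcome log-odds, the *b* path) and
``theta_eo_direct`` (direct exposure → outcome log-odds, the *c'* path).
Per-SNP latent truth:

    beta_exp,j  = gamma_j
    beta_med,j  = theta_em * gamma_j + delta_j
    beta_out,j  = theta_eo_direct * gamma_j + theta_mo * beta_med,j + alpha_j

where ``gamma_j`` are SNP → exposure effects (zero for a ``prop_null``
fraction), ``delta_j`` are mediator-specific effects planted on a fraction
of the exposure-null SNPs (these give the mediator its own instruments, as
a real metabolite GWAS would), and ``alpha_j`` are direct SNP → outcome
(horizontally pleiotropic) effects carried by the invalid fraction.

Observed effects are the latent truth plus Gaussian noise with the standard
summary-statistic standard errors: ``1/sqrt(2 p (1-p) n)`` for quantitative
traits and ``1/sqrt(2 p (1-p) n_case n_control / n_total)`` for the binary
trait. SNPs inside an LD block share their latent effect and receive
correlated noise, so clumping is consequential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import SUMMARY_COLUMNS, LDReference, SummaryStatsSet
from . import io as gio

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Full generative specification for the three-trait summary statistics.

    Cohort-size defaults mirror the motivating study design: a lipidomics
    cohort of 7,174, a metabolomics cohort of 8,299 and a longevity
    case-control GWAS of 11,262 cases / 25,483 controls.
    """

    n_snps: int = 150
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_mean: float = 0.12          # mean SNP->exposure effect (trait-SD units)
    gamma_sd: float = 0.02
    prop_null: float = 0.5            # fraction of SNPs with gamma = 0
    theta_em: float = 0.2             # exposure->mediator (a)
    theta_mo: float = 0.25            # mediator->outcome log-odds (b)
    theta_eo_direct: float = 0.15     # direct exposure->outcome log-odds (c')
    prop_invalid: float = 0.0         # fraction with direct SNP->outcome effects
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    prop_med_specific: float = 0.6    # fraction of exposure-null SNPs given delta
    delta_mean: float = 0.12          # mediator-specific SNP effect distribution
    delta_sd: float = 0.02
    n_exp: int = 7174
    n_med: int = 8299
    n_case: int = 11262
    n_control: int = 25483
    n_blocks: int = 10                # LD blocks; remaining SNPs are singletons
    block_size: int = 3
    ld_rho: float = 0.8               # within-block correlation
    palindromic_frac: float = 0.05    # fraction of A/T or C/G allele pairs
    flip_frac: float = 0.2            # outcome/mediator rows stored allele-swapped
    strand_frac: float = 0.1          # rows stored on the complementary strand
    n_outliers: int = 0               # SNPs given alpha = outlier_scale * se_out
    outlier_scale: float = 10.0
    seed: int = 0

    def validate(self):
        lo, hi = self.maf_range
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("prop_null", "prop_invalid", "prop_med_specific",
                     "palindromic_frac", "flip_frac", "strand_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_exp", "n_med", "n_case", "n_control"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_blocks * self.block_size > self.n_snps:
            raise ValueError("LD blocks exceed n_snps")

    @property
    def true_total_effect(self) -> float:
        """Total exposure→outcome effect c = c' + a·b."""
        return self.theta_eo_direct + self.theta_em * self.theta_mo

    @property
    def true_mediated_proportion(self) -> float:
        c = self.true_total_effect
        if c == 0:
            return float("nan")
        return (self.theta_em * self.theta_mo) / c


@dataclass
class TruthRecord:
    """All latent quantities behind one simulated dataset."""

    config: SimulationConfig
    per_snp: pd.DataFrame  # snp_id, block, maf, gamma, delta, alpha, true betas

    def frame(self) -> pd.DataFrame:
        return self.per_snp

    def write(self, path):
        gio.write_table(self.per_snp, path)


def _quant_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _binary_se(maf: np.ndarray, n_case: int, n_control: int) -> np.ndarray:
    n_eff = n_case * n_control / (n_case + n_control)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)


def _block_noise(rng, n_snps, block_index, n_blocks, rho):
    """Standard-normal noise, compound-symmetric within each LD block."""
    z = rng.standard_normal(n_snps)
    if rho > 0:
        for b in range(n_blocks):
            members = np.flatnonzero(block_index == b)
            if len(members) < 2:
                continue
            shared = rng.standard_normal()
            z[members] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(len(members))
    return z


def simulate_mediation_gwas(config: SimulationConfig):
    """Generate (exposure, mediator, outcome, LDReference, TruthRecord).

    Deterministic for a fixed config (including its seed). Outcome and
    mediator rows may be stored allele-swapped or strand-complemented
    (``flip_frac`` / ``strand_frac``) — a change of representation only —
    so harmonization is exercised downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    maf = rng.uniform(*config.maf_range, size=J)

    # block structure: first n_blocks*block_size SNPs grouped, rest singleton
    block_index = np.full(J, -1, dtype=int)
    for b in range(config.n_blocks):
        block_index[b * config.block_size:(b + 1) * config.block_size] = b

    # latent effects drawn per "unit" (block or singleton) and shared in-block
    n_units = config.n_blocks + (J - config.n_blocks * config.block_size)
    unit_of = np.empty(J, dtype=int)
    unit_of[:config.n_blocks * config.block_size] = block_index[:config.n_blocks * config.block_size]
    unit_of[config.n_blocks * config.block_size:] = np.arange(
        config.n_blocks, n_units)

    unit_null = rng.random(n_units) < config.prop_null
    unit_gamma = np.where(unit_null, 0.0,
                          rng.normal(config.gamma_mean, config.gamma_sd, n_units))
    # mediator-specific instruments live on exposure-null units
    unit_delta = np.where(
        unit_null & (rng.random(n_units) < config.prop_med_specific),
        rng.normal(config.delta_mean, config.delta_sd, n_units), 0.0)
    unit_alpha = np.where(rng.random(n_units) < config.prop_invalid,
                          rng.normal(config.alpha_mean, config.alpha_sd, n_units), 0.0)

    gamma = unit_gamma[unit_of]
    delta = unit_delta[unit_of]
    alpha = unit_alpha[unit_of]

    se_exp = _quant_se(maf, config.n_exp)
    se_med = _quant_se(maf, config.n_med)
    se_out = _binary_se(maf, config.n_case, config.n_control)

    if config.n_outliers > 0:
        # plant gross pleiotropy on the first non-null units (valid instruments
        # turned invalid), alpha = outlier_scale x that SNP's outcome SE
        candidates = [u for u in range(n_units) if unit_gamma[u] != 0.0]
        for u in candidates[:config.n_outliers]:
            members = np.flatnonzero(unit_of == u)
            alpha[members] = config.outlier_scale * se_out[members]

    beta_exp_true = gamma
    beta_med_true = config.theta_em * gamma + delta
    beta_out_true = (config.theta_eo_direct * gamma
                     + config.theta_mo * beta_med_true + alpha)

    beta_exp = beta_exp_true + se_exp * _block_noise(rng, J, block_index,
                                                     config.n_blocks, config.ld_rho)
    beta_med = beta_med_true + se_med * _block_noise(rng, J, block_index,
                                                     config.n_blocks, config.ld_rho)
    beta_out = beta_out_true + se_out * _block_noise(rng, J, block_index,
                                                     config.n_blocks, config.ld_rho)

    snp_ids = np.array([f"rs{100000 + j}" for j in range(J)])

    # genomic layout: each unit far (> 20 Mb) from its neighbours so the
    # 10,000 kb clumping window only ever binds within a block
    chroms = np.empty(J, dtype=object)
    pos = np.empty(J, dtype=int)
    for j in range(J):
        u = unit_of[j]
        chroms[j] = str(1 + u % 22)
        within = j - np.flatnonzero(unit_of == u)[0]
        pos[j] = 1_000_000 + (u // 22) * 30_000_000 + within * 5_000

    # allele pairs; a configurable fraction palindromic
    n_pal = len(_PALINDROMIC_PAIRS)
    n_nonpal = len(_NONPALINDROMIC_PAIRS)
    is_pal = rng.random(J) < config.palindromic_frac
    pair_idx = rng.integers(0, max(n_pal, n_nonpal), size=J)
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if is_pal[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[pair_idx[j] % len(pool)]

    def two_sided_p(beta, se):
        z = np.abs(beta) / se
        return np.maximum(2.0 * sps.norm.sf(z), np.finfo(float).tiny)

    def build(trait, ttype, beta, se, n_total, n_case=None, n_control=None,
              scramble=True):
        eaf = maf.copy()
        b = beta.copy()
        eff, oth = ea.copy(), oa.copy()
        if scramble:
            swap = rng.random(J) < config.flip_frac
            strand = rng.random(J) < config.strand_frac
            # swapped representation: report the other allele's effect
            b[swap] = -b[swap]
            eaf[swap] = 1.0 - eaf[swap]
            eff[swap], oth[swap] = oth[swap].copy(), eff[swap].copy()
            for j in np.flatnonzero(strand):
                eff[j] = _COMPLEMENT[eff[j]]
                oth[j] = _COMPLEMENT[oth[j]]
        frame = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chroms, "pos": pos,
            "effect_allele": eff, "other_allele": oth,
            "eaf": eaf, "beta": b, "se": se, "pvalue": two_sided_p(b, se),
            "n_total": n_total,
            "n_case": n_case if n_case is not None else np.nan,
            "n_control": n_control if n_control is not None else np.nan,
        }, columns=SUMMARY_COLUMNS)
        return SummaryStatsSet(trait, ttype, frame)

    exposure = build("exposure", "quantitative", beta_exp, se_exp,
                     config.n_exp, scramble=False)
    mediator = build("mediator", "quantitative", beta_med, se_med,
                     config.n_med)
    outcome = build("outcome", "binary", beta_out, se_out,
                    config.n_case + config.n_control,
                    n_case=config.n_case, n_control=config.n_control)

    blocks = []
    for b in range(config.n_blocks):
        members = [snp_ids[j] for j in np.flatnonzero(block_index == b)]
        k = len(members)
        mat = np.full((k, k), config.ld_rho)
        np.fill_diagonal(mat, 1.0)
        blocks.append((members, mat))
    ld = LDReference(blocks)

    truth = TruthRecord(config=config, per_snp=pd.DataFrame({
        "snp_id": snp_ids, "block": block_index, "maf": maf,
        "gamma": gamma, "delta": delta, "alpha": alpha,
        "beta_exp_true": beta_exp_true, "beta_med_true": beta_med_true,
        "beta_out_true": beta_out_true,
        "se_exp": se_exp, "se_med": se_med, "se_out": se_out,
    }))
    return exposure, mediator, outcome, ld, truth


#: named scenarios used throughout the tests and the CLI
FIXTURES: dict[str, dict] = {
    "null": dict(theta_em=0.0, theta_mo=0.0, theta_eo_direct=0.0,
                 prop_null=0.4, seed=101),
    "strong_mediation": dict(seed=202),  # defaults: a=0.2, b=0.25, c'=0.15 -> prop 0.25
    "directional_pleiotropy": dict(prop_invalid=0.3, alpha_mean=0.05,
                                   alpha_sd=0.01, seed=303),
    "one_outlier": dict(n_outliers=1, outlier_scale=10.0, seed=404),
    "palindromic_mix": dict(palindromic_frac=0.3, seed=505),
}


def fixture_config(name: str, seed: Optional[int] = None) -> SimulationConfig:
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; valid names: "
                         f"{sorted(FIXTURES)}")
    cfg = SimulationConfig(**FIXTURES[name])
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def make_fixture(name: str, outdir, seed: Optional[int] = None) -> dict:
    """Write the named scenario's file bundle; returns the path map."""
    cfg = fixture_config(name, seed)
    exposure, mediator, outcome, ld, truth = simulate_mediation_gwas(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "mediator": outdir / "mediator.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld_reference.json",
        "truth": outdir / "truth.tsv",
    }
    gio.write_summary_stats(exposure, paths["exposure"])
    gio.write_summary_stats(mediator, paths["mediator"])
    gio.write_summary_stats(outcome, paths["outcome"])
    gio.write_ld_reference(ld, paths["ld"])
    truth.write(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
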