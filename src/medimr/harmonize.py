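"""Allele harmonization of exposure and outcome summary statistics.

Both effects for a SNP must refer to the same effect allele before any
ratio or regression is meaningful. Per SNP present in both sets:

* identical allele pair → kept as is;
* swapped effect/other alleles → outcome beta sign-flipped, eaf complemented;
* complementary-strand match → strand-flipped, then the two rules above;
* palindromic pair (A/T or C/G, strand unresolvable from alleles) → kept
  only when both allele frequencies are informative (outside the ambiguity
  window, default [0.42, 0.58]) and agree in orientation; otherwise dropped;
* anything irreconcilable → dropped as an allele mismatch.

Dropped SNPs are logged, never silently discarded.
"""

from __future__ import annotations

from typing import Optional

from .io import ExclusionLog
from .records import GwasRecord, HarmonizedPair, SummaryStatsSet

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which a palindromic SNP's strand cannot be inferred
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _ambiguous(eaf: Optional[float], window) -> bool:
    return eaf is None or window[0] <= eaf <= window[1]


def harmonize(exp: SummaryStatsSet, out: SummaryStatsSet,
              palindromic_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
              log: Optional[ExclusionLog] = None) -> list[HarmonizedPair]:
    """Align the outcome set to the exposure's effect alleles.

    Returns one :class:`HarmonizedPair` per SNP in the intersection,
    including dropped pairs (with ``action='dropped'`` and a reason), so
    SNP counts are conserved across the stage.
    """
    out_by_id = {r.snp_id: r for r in out.records()}
    pairs: list[HarmonizedPair] = []

    for e in exp.records():
        o = out_by_id.get(e.snp_id)
        if o is None:
            continue
        pairs.append(_harmonize_one(e, o, palindromic_window))

    if log is not None:
        for p in pairs:
            if not p.kept:
                log.add(p.snp_id, "harmonize", p.drop_reason)
    return pairs


def _harmonize_one(e: GwasRecord, o: GwasRecord, window) -> HarmonizedPair:
    base = dict(snp_id=e.snp_id, beta_exp=e.beta, se_exp=e.se,
                eaf_exp=e.eaf)

    def dropped(reason):
        return HarmonizedPair(**base, beta_out=o.beta, se_out=o.se,
                              eaf_out=o.eaf, action="dropped",
                              drop_reason=reason)

    ea_o, oa_o = o.effect_allele, o.other_allele
    beta_out, eaf_out = o.beta, o.eaf
    action = "kept_as_is"

    pal = _is_palindromic(e.effect_allele, e.other_allele)
    if pal:
        if {ea_o, oa_o} != {e.effect_allele, e.other_allele}:
            return dropped("allele_mismatch")
        # alleles cannot distinguish a strand flip from a swap; the
        # frequency is the sole arbiter, so both eafs must be informative
        if _ambiguous(e.eaf, window) or _ambiguous(eaf_out, window):
            return dropped("palindromic_ambiguous")
        if ea_o != e.effect_allele:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "sign_flipped"
        if (e.eaf < 0.5) != (eaf_out < 0.5):
            # stated alignment contradicts the frequencies: the pair sits on
            # opposite strands, so undo/apply the flip accordingly
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "kept_as_is" if action == "sign_flipped" else "sign_flipped"
        return HarmonizedPair(**base, beta_out=beta_out, se_out=o.se,
                              eaf_out=eaf_out, action=action)

    if {ea_o, oa_o} != {e.effect_allele, e.other_allele}:
        # try the complementary strand
        ea_c, oa_c = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
        if {ea_c, oa_c} != {e.effect_allele, e.other_allele}:
            return dropped("allele_mismatch")
        ea_o, oa_o = ea_c, oa_c
        action = "strand_flipped"

    if ea_o == e.effect_allele:
        pass
    else:
        beta_out = -beta_out
        if eaf_out is not None:
            eaf_out = 1.0 - eaf_out
        action = "sign_flipped" if action == "kept_as_is" else "strand_flipped"

    return HarmonizedPair(**base, beta_out=beta_out, se_out=o.se,
                          eaf_out=eaf_out, action=action)
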