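import numpy as np
import pandas as pd
import pytest

from medimr.records import (SUMMARY_COLUMNS, GwasRecord, HarmonizedPair,
                            SummaryStatsSet)


def make_pairs(beta_exp, se_exp, beta_out, se_out):
    return [HarmonizedPair(snp_id=f"rs{i}", beta_exp=float(a), se_exp=float(b),
                           beta_out=float(c), se_out=float(d))
            for i, (a, b, c, d) in enumerate(zip(beta_exp, se_exp,
                                                 beta_out, se_out))]


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pvalue=1e-6, n_total=7174, **kw):
    return GwasRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                      other_allele=oa, eaf=eaf, beta=beta, se=se,
                      pvalue=pvalue, n_total=n_total, **kw)


def make_set(records, trait_name="exposure", trait_type="quantitative"):
    return SummaryStatsSet.from_records(trait_name, trait_type, records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stats():
    recs = [make_record(snp_id=f"rs{i}", pos=1000 + i * 100,
                        beta=0.1 + 0.01 * i, pvalue=10 ** -(3 + i))
            for i in range(5)]
    return make_set(recs)
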