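"""Reading and writing GWAS summary-statistic tables and LD references.

Files are tab-separated with a header row. The default column map follows
GWAS-Catalog-style headers (variant_id, chromosome, base_pair_location,
effect_allele, other_allele, effect_allele_frequency, beta, standard_error,
p_value, n); pass ``column_map`` to read other dialects. Rows violating
record invariants are dropped, never passed through, and every drop is
logged with its row number and reason.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .records import (SUMMARY_COLUMNS, GwasRecord, LDReference,
                      SummaryStatsSet)

DEFAULT_COLUMN_MAP = {
    "snp_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n_total": "n",
    "n_case": "n_case",
    "n_control": "n_control",
}

MANDATORY_FIELDS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "se", "pvalue", "n_total"]
OPTIONAL_FIELDS = ["eaf", "n_case", "n_control"]


class ExclusionLog:
    """Machine-readable record of every SNP dropped at any stage."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, snp_id: str, stage: str, reason: str):
        self.rows.append({"snp_id": snp_id, "stage": stage, "reason": reason})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["snp_id", "stage", "reason"])

    def write(self, path):
        self.frame().to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.rows)


def read_summary_stats(path, trait_name: str, trait_type: str,
                       column_map: Optional[Mapping[str, str]] = None,
                       log: Optional[ExclusionLog] = None) -> SummaryStatsSet:
    """Read and validate a summary-statistics table.

    Invalid rows (bad alleles, se ≤ 0, out-of-range eaf or p, duplicate
    snp_id) are dropped and logged; a missing mandatory column or an empty
    file is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype={cmap["snp_id"]: str, cmap["chrom"]: str})
    if raw.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    for field in MANDATORY_FIELDS:
        if cmap[field] not in raw.columns:
            raise ValueError(f"missing mandatory column {cmap[field]!r} "
                             f"(for field {field!r}) in {path}")
    log = log if log is not None else ExclusionLog()

    rows = []
    seen: set[str] = set()
    for i, r in raw.iterrows():
        def _get(field, cast, default=None):
            col = cmap[field]
            if col not in raw.columns or pd.isna(r[col]):
                return default
            return cast(r[col])

        snp_id = str(r[cmap["snp_id"]])
        try:
            rec = GwasRecord(
                snp_id=snp_id,
                chrom=str(r[cmap["chrom"]]),
                pos=int(r[cmap["pos"]]),
                effect_allele=str(r[cmap["effect_allele"]]).upper(),
                other_allele=str(r[cmap["other_allele"]]).upper(),
                beta=float(r[cmap["beta"]]),
                se=float(r[cmap["se"]]),
                pvalue=float(r[cmap["pvalue"]]),
                n_total=int(r[cmap["n_total"]]),
                eaf=_get("eaf", float),
                n_case=_get("n_case", int),
                n_control=_get("n_control", int),
            )
        except (TypeError, ValueError):
            log.add(snp_id, "read", f"row_{i}_unparseable")
            continue
        reason = rec.validate()
        if reason is not None:
            log.add(snp_id, "read", f"row_{i}_{reason}")
            continue
        if snp_id in seen:
            log.add(snp_id, "read", f"row_{i}_duplicate")
            continue
        seen.add(snp_id)
        rows.append({c: getattr(rec, c) for c in SUMMARY_COLUMNS})

    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return SummaryStatsSet(trait_name, trait_type, frame)


def write_summary_stats(stats: SummaryStatsSet, path,
                        column_map: Optional[Mapping[str, str]] = None):
    """Write a set in the (mapped) dialect; round-trips through the reader."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = stats.frame.rename(columns=cmap)
    write_table(out, path)


def write_table(frame: pd.DataFrame, path):
    """Tab-separated write with ≥ 10 significant digits on floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ld_reference(ld: LDReference, path):
    """Serialise the block manifest as JSON (member ids + dense matrices)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [{"snp_ids": ids, "corr": mat.tolist()} for ids, mat in ld.blocks]
    path.write_text(json.dumps(payload))


def read_ld_reference(path) -> LDReference:
    payload = json.loads(Path(path).read_text())
    return LDReference([(b["snp_ids"], np.asarray(b["corr"])) for b in payload])


def read_blacklist(path) -> set[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids
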