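"""Summary-statistics readers, writers and quality filters.

The input dialect is the tab-separated, headered table used by common
summary-statistics tooling: one row per variant with an identifier,
chromosome, 1-based position, effect/other alleles, a chi-square (or z)
statistic and the sample size, optionally an imputation info score and a
p-value.  Filters implement the standard pre-analysis rules: drop
strand-ambiguous variants (A/T, C/G), drop poorly imputed variants
(info < 0.9), optionally restrict to a well-imputed SNP list when no info
score is available, drop extreme outliers (p < 1e-16), and collapse groups
of variants in perfect LD to a single representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .ldref import BandLDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "read_sumstats",
    "write_sumstats",
    "filter_sumstats",
    "filter_perfect_ld",
    "match_reference",
    "AMBIGUOUS_PAIRS",
]

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_SYNONYMS = {
    "SNP": {"SNP", "RSID", "ID", "MARKERNAME", "RS"},
    "CHR": {"CHR", "CHROM", "CHROMOSOME"},
    "BP": {"BP", "POS", "POSITION"},
    "A1": {"A1", "EFFECT_ALLELE", "ALLELE1", "ALT"},
    "A2": {"A2", "OTHER_ALLELE", "ALLELE2", "REF"},
    "Z": {"Z", "ZSCORE", "Z_SCORE"},
    "CHISQ": {"CHISQ", "CHI2", "CHISQUARE", "STAT"},
    "N": {"N", "NSAMPLES", "SAMPLE_SIZE"},
    "INFO": {"INFO", "INFO_SCORE"},
    "P": {"P", "PVAL", "PVALUE", "P_VALUE"},
}

_MANDATORY = ("SNP", "CHR", "BP", "A1", "A2", "N")


@dataclass
class FilterReport:
    """Per-rule removal counts; removed + surviving always equals the input."""

    n_input: int
    n_surviving: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_input != self.n_surviving + sum(self.removed.values()):
            raise ValueError("filter report counts do not reconcile")


def _canonical_columns(columns: list[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        up = col.strip().upper()
        for canon, names in _SYNONYMS.items():
            if up in names and canon not in mapping:
                mapping[col] = canon
                break
    return mapping


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a sumstats table into canonical columns.

    Column-name synonyms are resolved (Z is squared into CHISQ); rows with
    malformed values (negative CHISQ, non-ACGT alleles, nonpositive
    positions) are rejected with their line numbers logged.  Missing
    mandatory columns raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_canonical_columns(list(df.columns)))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"sumstats file {path} missing mandatory columns {missing}")
    if "CHISQ" not in df.columns and "Z" not in df.columns:
        raise ValueError(f"sumstats file {path} needs a Z or CHISQ column")

    out = pd.DataFrame(index=df.index)
    out["SNP"] = df["SNP"].astype(str)
    out["CHR"] = df["CHR"].astype(str)
    out["BP"] = pd.to_numeric(df["BP"], errors="coerce")
    out["A1"] = df["A1"].str.upper()
    out["A2"] = df["A2"].str.upper()
    if "CHISQ" in df.columns:
        out["CHISQ"] = pd.to_numeric(df["CHISQ"], errors="coerce")
    else:
        out["CHISQ"] = pd.to_numeric(df["Z"], errors="coerce") ** 2
    out["N"] = pd.to_numeric(df["N"], errors="coerce")
    for opt in ("INFO", "P"):
        if opt in df.columns:
            out[opt] = pd.to_numeric(df[opt], errors="coerce")

    bases = {"A", "C", "G", "T"}
    bad = (
        out["BP"].isna()
        | (out["BP"] <= 0)
        | out["CHISQ"].isna()
        | (out["CHISQ"] < 0)
        | out["N"].isna()
        | ~out["A1"].isin(bases)
        | ~out["A2"].isin(bases)
    )
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +1 header, +1 one-based
        logger.warning("rejected %d malformed sumstats rows at lines %s", bad.sum(), lines)
        out = out[~bad]
    out["BP"] = out["BP"].astype(int)
    return out.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_sumstats(
    df: pd.DataFrame,
    info_min: float = 0.9,
    p_min: float = 1e-16,
    snp_set: set[str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the standard pre-analysis filters.

    Rules are independent predicates, so the surviving set does not depend
    on their order; each removed row is attributed to the first rule it
    violates in the fixed order ambiguous > info > snp_set > p.  The
    ``snp_set`` restriction (a well-imputed id list, e.g. HapMap3) is only
    applied when the table carries no info score.
    """
    n_input = len(df)
    ambiguous = pd.Series(
        [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(df["A1"], df["A2"])], index=df.index
    )
    if "INFO" in df.columns:
        low_info = df["INFO"].notna() & (df["INFO"] < info_min)
        not_in_set = pd.Series(False, index=df.index)
    else:
        low_info = pd.Series(False, index=df.index)
        if snp_set is not None:
            not_in_set = ~df["SNP"].isin(snp_set)
        else:
            not_in_set = pd.Series(False, index=df.index)
    if "P" in df.columns:
        low_p = df["P"].notna() & (df["P"] < p_min)
    else:
        low_p = pd.Series(False, index=df.index)

    removed = {
        "ambiguous": int(ambiguous.sum()),
        "low_info": int((low_info & ~ambiguous).sum()),
        "not_in_set": int((not_in_set & ~ambiguous & ~low_info).sum()),
        "low_p": int((low_p & ~ambiguous & ~low_info & ~not_in_set).sum()),
    }
    keep = ~(ambiguous | low_info | not_in_set | low_p)
    out = df[keep].reset_index(drop=True)
    report = FilterReport(n_input=n_input, n_surviving=len(out), removed=removed)
    logger.info("filter_sumstats: %s", report)
    return out, report


def filter_perfect_ld(
    df: pd.DataFrame, ld: BandLDMatrix, r2_max: float = 0.999
) -> tuple[pd.DataFrame, FilterReport]:
    """Collapse groups of variants in (near-)perfect LD to one representative.

    ``df`` rows must align one-to-one, in order, with the variants of
    ``ld``.  Within each connected group of pairwise r² > ``r2_max``, the
    variant with the smallest position survives; deterministic.
    """
    n = len(df)
    if ld.n_variants != n:
        raise ValueError("sumstats rows must align with the LD matrix variants")
    high = ld.r2 > r2_max
    high.setdiag(False)
    n_comp, labels = connected_components(high, directed=False)
    keep = np.zeros(n, dtype=bool)
    bp = df["BP"].to_numpy()
    order = np.lexsort((np.arange(n), bp))  # by position, then input order
    seen: set[int] = set()
    for idx in order:
        if labels[idx] not in seen:
            seen.add(labels[idx])
            keep[idx] = True
    out = df[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=n, n_surviving=len(out), removed={"perfect_ld": int(n - keep.sum())}
    )
    return out, report


def match_reference(
    df: pd.DataFrame, ld: BandLDMatrix, ref_a1: np.ndarray | None = None,
    ref_a2: np.ndarray | None = None,
) -> tuple[pd.DataFrame, BandLDMatrix, FilterReport]:
    """Match sumstats rows to reference-panel variants by (chr, bp).

    Returns the matched rows (panel order), the corresponding LD submatrix
    and a report of unmatched/allele-mismatched rows.  When panel alleles
    are supplied, rows whose allele pair matches neither directly nor after
    strand complement are dropped (strand flips of unambiguous pairs
    resolve silently; ambiguous pairs should have been filtered already).
    """
    key_to_panel = {
        (str(c), int(b)): i for i, (c, b) in enumerate(zip(ld.chrom, ld.bp))
    }
    panel_idx = np.full(len(df), -1)
    for row, (c, b) in enumerate(zip(df["CHR"], df["BP"])):
        panel_idx[row] = key_to_panel.get((str(c), int(b)), -1)
    matched = panel_idx >= 0
    mismatch = np.zeros(len(df), dtype=bool)
    if ref_a1 is not None and ref_a2 is not None:
        for row in np.flatnonzero(matched):
            i = panel_idx[row]
            pair = {df["A1"].iat[row], df["A2"].iat[row]}
            panel_pair = {str(ref_a1[i]).upper(), str(ref_a2[i]).upper()}
            flipped = {_COMPLEMENT.get(a, "?") for a in pair}
            if pair != panel_pair and flipped != panel_pair:
                mismatch[row] = True
    keep = matched & ~mismatch
    sub = df[keep].copy()
    sub["_panel"] = panel_idx[keep]
    sub = sub.sort_values("_panel")
    indices = sub["_panel"].to_numpy()
    sub = sub.drop(columns="_panel").reset_index(drop=True)
    report = FilterReport(
        n_input=len(df),
        n_surviving=len(sub),
        removed={
            "unmatched": int((~matched).sum()),
            "allele_mismatch": int(mismatch.sum()),
        },
    )
    return sub, ld.submatrix(indices), report
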