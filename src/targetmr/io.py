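"""Reading, validation and harmonization of GWAS and eQTL summary statistics.

Summary statistics live in tab-separated files with a header.  Canonical
column names are ``SNP CHR POS EA OA EAF BETA SE P`` for GWAS tables and
``GENE TISSUE SNP EA OA EAF BETA SE P`` for eQTL best-SNP tables; other
headers are accepted through a dialect mapping (``{file_column: canonical}``).

Harmonization aligns the exposure and outcome records for each shared variant
onto a single effect allele, flipping outcome betas when allele labels are
swapped, complementing strand-flipped records, and resolving palindromic
(A/T, C/G) variants from allele frequencies when both minor allele
frequencies are low enough for the frequency comparison to be informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P"]
EQTL_COLUMNS = ["GENE", "TISSUE", "SNP", "EA", "OA", "EAF", "BETA", "SE", "P"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class ConfigurationError(ValueError):
    """A file or mapping does not provide the mandatory structure."""


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    return _COMPLEMENT.get(ea) == oa


def complement_alleles(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


@dataclass
class ValidationReport:
    """Row-level rejects from reading a summary-statistics file."""

    n_input: int = 0
    n_valid: int = 0
    rejects: list[dict] = field(default_factory=list)

    def add(self, row_number: int, snp: object, reason: str) -> None:
        self.rejects.append({"row": row_number, "SNP": snp, "reason": reason})

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def _apply_dialect(df: pd.DataFrame, dialect: Optional[Mapping[str, str]]) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns=dict(dialect))
    return df


def _validate_rows(df: pd.DataFrame, required: list[str], report: ValidationReport,
                   allow_missing_eaf: bool = True) -> pd.DataFrame:
    """Row-level validation shared by GWAS and eQTL readers.

    Invalid rows are recorded in the report with their 1-based data row number
    and dropped; they are never silently discarded.
    """
    report.n_input = len(df)
    keep = np.ones(len(df), dtype=bool)
    ea = df["EA"].astype(str).str.upper()
    oa = df["OA"].astype(str).str.upper()
    df = df.assign(EA=ea, OA=oa)
    for i, (idx, row) in enumerate(df.iterrows()):
        rownum = i + 1
        if row["EA"] not in _VALID_ALLELES or row["OA"] not in _VALID_ALLELES:
            report.add(rownum, row.get("SNP"), "unparseable allele")
            keep[i] = False
            continue
        if row["EA"] == row["OA"]:
            report.add(rownum, row.get("SNP"), "identical alleles")
            keep[i] = False
            continue
        se = pd.to_numeric(pd.Series([row["SE"]]), errors="coerce").iloc[0]
        beta = pd.to_numeric(pd.Series([row["BETA"]]), errors="coerce").iloc[0]
        pval = pd.to_numeric(pd.Series([row["P"]]), errors="coerce").iloc[0]
        if pd.isna(beta):
            report.add(rownum, row.get("SNP"), "unparseable beta")
            keep[i] = False
            continue
        if pd.isna(se) or se <= 0:
            report.add(rownum, row.get("SNP"), "non-positive SE")
            keep[i] = False
            continue
        if pd.isna(pval) or not (0 < pval <= 1):
            report.add(rownum, row.get("SNP"), "p-value outside (0, 1]")
            keep[i] = False
            continue
        eaf = pd.to_numeric(pd.Series([row.get("EAF")]), errors="coerce").iloc[0]
        if not pd.isna(eaf) and not (0 <= eaf <= 1):
            report.add(rownum, row.get("SNP"), "EAF outside [0, 1]")
            keep[i] = False
            continue
        if pd.isna(eaf) and not allow_missing_eaf:
            report.add(rownum, row.get("SNP"), "missing EAF")
            keep[i] = False
    out = df.loc[keep].copy()
    for col in ("BETA", "SE", "P", "EAF"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    report.n_valid = len(out)
    if report.n_rejected:
        logger.warning("rejected %d of %d rows", report.n_rejected, report.n_input)
        for r in report.rejects:
            logger.info("row %d (%s): %s", r["row"], r["SNP"], r["reason"])
    return out


def read_summary_stats(
    path, dialect: Optional[Mapping[str, str]] = None, strict: bool = True
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a GWAS summary-statistics TSV into a validated DataFrame.

    Parameters
    ----------
    path : file path of a tab-separated table with a header.
    dialect : optional mapping from the file's column names to the canonical
        names ``SNP CHR POS EA OA EAF BETA SE P``.
    strict : raise :class:`ConfigurationError` when a mandatory column is
        missing (EAF is optional).

    Returns
    -------
    (records, report) where ``records`` has canonical columns and ``report``
    lists rejected rows with reasons.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    df = _apply_dialect(df, dialect)
    mandatory = [c for c in GWAS_COLUMNS if c != "EAF"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing and strict:
        raise ConfigurationError(f"missing mandatory column(s): {missing} in {path}")
    if "EAF" not in df.columns:
        df["EAF"] = np.nan
    report = ValidationReport()
    records = _validate_rows(df[GWAS_COLUMNS].copy(), GWAS_COLUMNS, report)
    records["CHR"] = records["CHR"].astype(str)
    records["POS"] = records["POS"].astype(int)
    # duplicate variant ids: keep the smallest p-value, deterministic
    if records["SNP"].duplicated().any():
        dups = records[records["SNP"].duplicated(keep=False)]
        logger.warning("found %d duplicated variant ids; keeping smallest p", dups["SNP"].nunique())
        records = (
            records.sort_values(["P", "POS", "SNP"], kind="mergesort")
            .drop_duplicates("SNP", keep="first")
            .sort_index()
        )
    return records.reset_index(drop=True), report


def read_eqtl(path, dialect: Optional[Mapping[str, str]] = None) -> tuple[pd.DataFrame, ValidationReport]:
    """Read an eQTL best-SNP table (GENE TISSUE SNP EA OA EAF BETA SE P)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "GENE": str, "TISSUE": str})
    df = _apply_dialect(df, dialect)
    missing = [c for c in EQTL_COLUMNS if c not in df.columns and c != "EAF"]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing} in {path}")
    if "EAF" not in df.columns:
        df["EAF"] = np.nan
    report = ValidationReport()
    records = _validate_rows(df[EQTL_COLUMNS].copy(), EQTL_COLUMNS, report)
    return records.reset_index(drop=True), report


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a canonical-column TSV (deterministic float formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = [
    "SNP", "EA", "OA", "BETA_X", "SE_X", "BETA_Y", "SE_Y",
    "EAF_X", "EAF_Y", "palindromic", "proxy_of",
]


@dataclass
class HarmonizeResult:
    """Harmonized variant table plus a full accounting of every input variant.

    ``table`` carries one row per variant usable for estimation; ``dropped``
    records every variant excluded, with a machine-readable reason; ``unmatched``
    lists exposure variants absent from the outcome (candidates for proxy
    search).  Counts always reconcile:
    ``n_exposure == len(table) + len(dropped) + len(unmatched)``.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame
    unmatched: list[str]
    n_exposure: int

    def reconciles(self) -> bool:
        return self.n_exposure == len(self.table) + len(self.dropped) + len(self.unmatched)


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf_max: float = 0.3,
) -> HarmonizeResult:
    """Align exposure and outcome records onto a shared effect allele.

    For each variant present in both tables (join on variant id):

    * identical allele labels — pair as-is;
    * swapped labels — negate the outcome beta and complement its EAF;
    * strand-complementary labels (non-palindromic) — complement the outcome
      alleles, then treat as match or swap;
    * palindromic variants — retained only if the minor allele frequency is
      below ``palindrome_maf_max`` in *both* datasets and both EAFs are
      observed; orientation is inferred from whether the frequencies agree or
      are complementary; otherwise dropped with a reason;
    * irreconcilable allele sets — dropped with reason ``incompatible alleles``.

    Variants found only in the exposure table are returned in ``unmatched`` so
    the caller can attempt proxy substitution before giving up on them.
    """
    exp = exposure.set_index("SNP", drop=False)
    out = outcome.set_index("SNP", drop=False)
    shared = exp.index.intersection(out.index)
    unmatched = [s for s in exp.index if s not in set(out.index)]

    rows: list[dict] = []
    dropped: list[dict] = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_x, oa_x = e["EA"], e["OA"]
        ea_y, oa_y = o["EA"], o["OA"]
        pal = is_palindromic(ea_x, oa_x)
        beta_y, eaf_y = float(o["BETA"]), o["EAF"]

        if pal:
            # strand cannot disambiguate; orientation from allele frequencies
            eaf_x = e["EAF"]
            if {ea_y, oa_y} != {ea_x, oa_x}:
                dropped.append({"SNP": snp, "reason": "incompatible alleles"})
                continue
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                dropped.append({"SNP": snp, "reason": "palindromic, missing EAF"})
                continue
            # compare frequencies on the same label: swap first if labels differ
            eaf_y_cmp = eaf_y if ea_y == ea_x else 1.0 - eaf_y
            if _maf(eaf_x) >= palindrome_maf_max or _maf(eaf_y_cmp) >= palindrome_maf_max:
                dropped.append({"SNP": snp, "reason": "palindromic, MAF >= threshold"})
                continue
            freqs_agree = (eaf_x < 0.5) == (eaf_y_cmp < 0.5)
            flip = (ea_y != ea_x) != (not freqs_agree)  # label swap XOR strand flip
            if not freqs_agree:
                # frequencies indicate the outcome labels sit on the other strand
                eaf_y_cmp = 1.0 - eaf_y_cmp
            rows.append(
                _hrow(snp, ea_x, oa_x, e, beta_y * (-1 if flip else 1),
                      float(o["SE"]), eaf_x, eaf_y_cmp, True, o.get("proxy_of"))
            )
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        else:
            cea, coa = complement_alleles(ea_y, oa_y)
            if (cea, coa) == (ea_x, oa_x):
                flip = False
            elif (cea, coa) == (oa_x, ea_x):
                flip = True
            else:
                dropped.append({"SNP": snp, "reason": "incompatible alleles"})
                continue
        eaf_y_adj = eaf_y if not flip else (1.0 - eaf_y if not pd.isna(eaf_y) else eaf_y)
        rows.append(
            _hrow(snp, ea_x, oa_x, e, beta_y * (-1 if flip else 1),
                  float(o["SE"]), e["EAF"], eaf_y_adj, False, o.get("proxy_of"))
        )

    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    dropped_df = pd.DataFrame(dropped, columns=["SNP", "reason"])
    if len(dropped_df):
        logger.info("harmonization dropped %d variants", len(dropped_df))
    return HarmonizeResult(
        table=table, dropped=dropped_df, unmatched=unmatched, n_exposure=len(exp)
    )


def _hrow(snp, ea, oa, e, beta_y, se_y, eaf_x, eaf_y, pal, proxy_of) -> dict:
    return {
        "SNP": snp,
        "EA": ea,
        "OA": oa,
        "BETA_X": float(e["BETA"]),
        "SE_X": float(e["SE"]),
        "BETA_Y": beta_y,
        "SE_Y": se_y,
        "EAF_X": eaf_x,
        "EAF_Y": eaf_y,
        "palindromic": pal,
        "proxy_of": proxy_of if isinstance(proxy_of, str) else None,
    }


def orient_to_exposure_increasing(h: pd.DataFrame) -> pd.DataFrame:
    """Re-orient every row so the effect allele increases the exposure.

    Rows with a negative exposure beta have both betas negated, allele labels
    swapped and EAFs complemented.  Idempotent; estimates are invariant to it
    except the MR-Egger intercept sign convention, which requires it.
    """
    h = h.copy()
    neg = h["BETA_X"] < 0
    if neg.any():
        h.loc[neg, ["EA", "OA"]] = h.loc[neg, ["OA", "EA"]].to_numpy()
        h.loc[neg, "BETA_X"] = -h.loc[neg, "BETA_X"]
        h.loc[neg, "BETA_Y"] = -h.loc[neg, "BETA_Y"]
        h.loc[neg, "EAF_X"] = 1.0 - h.loc[neg, "EAF_X"]
        h.loc[neg, "EAF_Y"] = 1.0 - h.loc[neg, "EAF_Y"]
    return h
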