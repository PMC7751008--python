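"""LD reference panel, greedy clumping, and proxy-SNP search.

The panel is desk-scale: a variant table (``SNP CHR POS A1 A2 MAF``) plus a
dense symmetric matrix of pairwise allelic correlations *r* (row/column order
matching the variant table).  ``r**2`` between two variants is the square of
the corresponding entry; the sign of *r* records whether the two A1 alleles
travel together on haplotypes, which is what allows a proxy's effect estimate
to be re-oriented onto the variant it stands in for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import is_palindromic

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "MAF"]


@dataclass
class LDPanel:
    """An LD reference panel: variant metadata and a correlation matrix."""

    variants: pd.DataFrame  # columns SNP CHR POS A1 A2 MAF
    r: np.ndarray           # symmetric, unit diagonal, |r| <= 1

    def __post_init__(self) -> None:
        v = self.variants
        missing = [c for c in PANEL_COLUMNS if c not in v.columns]
        if missing:
            raise ValueError(f"panel variants table missing columns {missing}")
        if v["SNP"].duplicated().any():
            raise ValueError("panel contains duplicate variant ids")
        r = np.asarray(self.r, dtype=float)
        n = len(v)
        if r.shape != (n, n):
            raise ValueError(f"correlation matrix shape {r.shape} != ({n}, {n})")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(r) > 1 + 1e-8):
            raise ValueError("|r| > 1 in correlation matrix")
        self.r = r
        self._index = {s: i for i, s in enumerate(v["SNP"])}

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def idx(self, snp: str) -> int:
        return self._index[snp]

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.idx(a), self.idx(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def save(self, variants_path, matrix_path) -> None:
        self.variants[PANEL_COLUMNS].to_csv(variants_path, sep="\t", index=False,
                                            float_format="%.10g")
        pd.DataFrame(self.r, columns=self.variants["SNP"]).to_csv(
            matrix_path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def load(cls, variants_path, matrix_path) -> "LDPanel":
        variants = pd.read_csv(variants_path, sep="\t", dtype={"SNP": str, "CHR": str})
        r = pd.read_csv(matrix_path, sep="\t").to_numpy(dtype=float)
        return cls(variants=variants, r=r)


def clump(
    records: pd.DataFrame,
    panel: LDPanel,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy p-value-ordered clumping to nearly independent variants.

    Variants are sorted by ascending p-value (ties broken by position then
    variant id for determinism).  The top remaining variant becomes an index
    SNP; every remaining variant on the same chromosome within ``window_kb``
    of it with ``r**2 > r2_max`` is removed.  Variants absent from the panel
    cannot be pruned and pass through untouched (logged).

    Returns the retained variant ids in the input's p-value order.
    """
    if records.empty:
        return []
    recs = records.sort_values(["P", "POS", "SNP"], kind="mergesort")
    not_in_panel = [s for s in recs["SNP"] if s not in panel]
    if not_in_panel:
        logger.info("clump: %d variants absent from panel pass through", len(not_in_panel))
    window = window_kb * 1000
    remaining = list(recs[["SNP", "CHR", "POS"]].itertuples(index=False, name=None))
    retained: list[str] = []
    while remaining:
        snp, chrom, pos = remaining.pop(0)
        retained.append(snp)
        if snp not in panel:
            continue
        kept = []
        for other, ochrom, opos in remaining:
            if (
                other in panel
                and str(ochrom) == str(chrom)
                and abs(int(opos) - int(pos)) <= window
                and panel.r2_between(snp, other) > r2_max
            ):
                continue  # pruned by this index SNP
            kept.append((other, ochrom, opos))
        remaining = kept
    return retained


def find_proxy(
    variant_id: str,
    panel: LDPanel,
    available: set[str] | Sequence[str],
    r2_min: float = 0.8,
    palindrome_maf_max: float = 0.3,
) -> Optional[str]:
    """Best available proxy in high LD with a query variant.

    Candidates must be in ``available`` (typically: present in the outcome
    GWAS), have ``r**2 >= r2_min`` with the query, and — if palindromic — have
    panel MAF below ``palindrome_maf_max``.  The candidate with the highest
    r² wins; ties break by smaller genomic distance, then lexicographic id.
    Returns ``None`` when no candidate qualifies or the query is not in the
    panel (logged).
    """
    if variant_id not in panel:
        logger.info("proxy search: query %s absent from panel", variant_id)
        return None
    avail = set(available)
    qi = panel.idx(variant_id)
    qpos = int(panel.variants["POS"].iloc[qi])
    best: Optional[tuple[float, int, str]] = None
    for j, row in panel.variants.iterrows():
        snp = row["SNP"]
        if snp == variant_id or snp not in avail:
            continue
        r2 = float(panel.r[qi, j]) ** 2
        if r2 < r2_min:
            continue
        if is_palindromic(row["A1"], row["A2"]) and row["MAF"] >= palindrome_maf_max:
            continue
        key = (-r2, abs(int(row["POS"]) - qpos), snp)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def substitute_proxies(
    instrument: Sequence[str],
    outcome: pd.DataFrame,
    panel: LDPanel,
    r2_min: float = 0.8,
    palindrome_maf_max: float = 0.3,
) -> pd.DataFrame:
    """Map each instrument variant to itself, a proxy, or ``dropped``.

    Returns a table with columns ``SNP used status r r2``: variants present in
    the outcome GWAS map to themselves (``status='present'``); absent ones map
    to their best proxy (``status='proxy'``, with the signed panel correlation
    used for allele orientation) or to ``status='dropped'`` when no proxy with
    r² >= ``r2_min`` exists.
    """
    present = set(outcome["SNP"])
    rows = []
    for snp in instrument:
        if snp in present:
            rows.append({"SNP": snp, "used": snp, "status": "present", "r": 1.0, "r2": 1.0})
            continue
        proxy = find_proxy(snp, panel, present, r2_min=r2_min,
                           palindrome_maf_max=palindrome_maf_max)
        if proxy is None:
            rows.append({"SNP": snp, "used": None, "status": "dropped",
                         "r": np.nan, "r2": np.nan})
            logger.info("no proxy for %s (r2 >= %.2f)", snp, r2_min)
        else:
            r = panel.r_between(snp, proxy)
            rows.append({"SNP": snp, "used": proxy, "status": "proxy",
                         "r": r, "r2": r * r})
    return pd.DataFrame(rows, columns=["SNP", "used", "status", "r", "r2"])


def apply_proxies(
    substitution: pd.DataFrame,
    outcome: pd.DataFrame,
    panel: LDPanel,
) -> pd.DataFrame:
    """Build outcome records keyed by the *original* instrument variants.

    Rows with ``status='present'`` are passed through.  For a proxy, the
    proxy's outcome association is re-keyed to the original variant: the
    effect allele becomes the original variant's panel A1, with the beta sign
    (and EAF) flipped when either the outcome record's effect allele is the
    proxy's panel A2 or the panel correlation between the two A1 alleles is
    negative.  The returned table carries ``proxy_of`` so downstream reports
    can show the substitution.
    """
    out = outcome.set_index("SNP", drop=False)
    rows = []
    for _, sub in substitution.iterrows():
        if sub["status"] == "present":
            rec = out.loc[sub["SNP"]].to_dict()
            rec["proxy_of"] = None
            rows.append(rec)
        elif sub["status"] == "proxy":
            orig, proxy = sub["SNP"], sub["used"]
            rec = out.loc[proxy].to_dict()
            pv = panel.variants
            prow = pv.iloc[panel.idx(proxy)]
            orow = pv.iloc[panel.idx(orig)]
            flip = (rec["EA"] != prow["A1"]) != (sub["r"] < 0)  # XOR
            beta = -rec["BETA"] if flip else rec["BETA"]
            eaf = rec.get("EAF")
            if eaf is not None and not pd.isna(eaf) and flip:
                eaf = 1.0 - eaf
            rows.append({
                "SNP": orig, "CHR": orow["CHR"], "POS": int(orow["POS"]),
                "EA": orow["A1"], "OA": orow["A2"], "EAF": eaf,
                "BETA": beta, "SE": rec["SE"], "P": rec["P"],
                "proxy_of": proxy,
            })
    cols = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "proxy_of"]
    return pd.DataFrame(rows, columns=cols)
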