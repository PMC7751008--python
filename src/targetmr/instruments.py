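"""Instrument construction for drug-target Mendelian randomization.

Instruments are built three ways, mirroring the three analysis modes:

1. per drug class — the union of validated variants across the protein
   targets of that class;
2. all targets combined — the union across every validated target;
3. agnostic — all genome-wide-significant exposure SNPs, ignoring targets.

A protein target's candidate variants are the eQTL "best SNPs" for its gene
(the variant with the smallest nominal p-value per tissue).  Each candidate is
validated by a Wald-ratio MR of gene expression on the exposure: the SD change
in systolic blood pressure per SD change in RNA expression.  Targets advance
through the statuses ``candidate -> expressed -> validated -> analysed``; a
validated target whose variants all vanish from the outcome GWAS (no proxy
available either) is marked ``excluded_no_outcome_data``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import estimators
from .ld import LDPanel, clump, substitute_proxies

logger = logging.getLogger(__name__)

STATUS_ORDER = [
    "candidate",
    "expressed",
    "validated",
    "excluded_no_outcome_data",
    "analysed",
]


class RegistryError(ValueError):
    """Malformed drug-class registry configuration."""


@dataclass
class DrugClass:
    """An antihypertensive drug class and the genes of its protein targets."""

    name: str
    target_genes: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("drug class with empty name")
        # dedup within class, preserving order
        seen = set()
        self.target_genes = [g for g in self.target_genes if not (g in seen or seen.add(g))]

    @property
    def analysable(self) -> bool:
        return bool(self.target_genes)


@dataclass
class TargetInstrument:
    """A protein-target gene with its candidate and validated variants."""

    gene: str
    candidates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "TISSUE", "P"])
    )
    validated_variants: list[str] = field(default_factory=list)
    validation: Optional[pd.DataFrame] = None  # per-candidate expression->SBP MR
    status: str = "candidate"
    exclusion_reason: Optional[str] = None

    def advance(self, status: str) -> None:
        if STATUS_ORDER.index(status) < STATUS_ORDER.index(self.status):
            raise ValueError(f"status may only move forward: {self.status} -> {status}")
        self.status = status


def load_drug_class_registry(path) -> list[DrugClass]:
    """Load the drug-class -> target-genes registry from YAML or JSON.

    The registry is a list of ``{class: name, genes: [...]}`` entries (or a
    mapping ``name -> [genes]``).  A class listed twice is merged with a
    warning; duplicate genes within a class are deduplicated; a gene may serve
    several classes.  An empty gene list leaves the class unanalysable but
    present, so the report can say so.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        entries = [{"class": k, "genes": v or []} for k, v in raw.items()]
    elif isinstance(raw, list):
        entries = raw
    else:
        raise RegistryError(f"registry must be a list or mapping, got {type(raw).__name__}")
    merged: dict[str, list[str]] = {}
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict) or "class" not in entry:
            raise RegistryError(f"registry entry {i} lacks a 'class' key: {entry!r}")
        name = str(entry["class"])
        genes = entry.get("genes") or []
        if not isinstance(genes, list):
            raise RegistryError(f"genes for class {name!r} must be a list")
        if name in merged:
            logger.warning("class %r listed more than once; merging", name)
            merged[name].extend(str(g) for g in genes)
        else:
            merged[name] = [str(g) for g in genes]
    classes = [DrugClass(name=n, target_genes=g) for n, g in merged.items()]
    for c in classes:
        if not c.analysable:
            logger.warning("class %r has no target genes; unanalysable", c.name)
    return classes


def select_best_snps(
    eqtl: pd.DataFrame,
    gene: str,
    positions: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-tissue best SNPs for a gene, deduplicated across tissues.

    For each tissue, the variant with the smallest nominal p-value for the
    gene is selected; the union over tissues is deduplicated by variant id
    keeping the smallest p.  Ties in p break by smaller genomic position when
    ``positions`` (variant id -> bp) is supplied, then by lexicographic id.

    Returns a DataFrame with the eQTL columns of the winning rows (one per
    retained variant); empty when the gene is absent from the table.
    """
    sub = eqtl[eqtl["GENE"] == gene].copy()
    if sub.empty:
        logger.info("gene %s absent from eQTL table", gene)
        return sub
    if positions:
        sub["_pos"] = sub["SNP"].map(lambda s: positions.get(s, 2**62))
    else:
        sub["_pos"] = 2**62
    sub = sub.sort_values(["P", "_pos", "SNP"], kind="mergesort")
    per_tissue = sub.groupby("TISSUE", sort=False).head(1)
    dedup = (
        per_tissue.sort_values(["P", "_pos", "SNP"], kind="mergesort")
        .drop_duplicates("SNP", keep="first")
        .drop(columns="_pos")
        .reset_index(drop=True)
    )
    return dedup


def validate_target(
    gene: str,
    candidates: pd.DataFrame,
    sbp_gwas: pd.DataFrame,
    alpha: float = 0.05,
) -> TargetInstrument:
    """Validate a target by MR of expression on the exposure, per candidate.

    For each candidate variant the Wald ratio beta_SBP / beta_expr (SD of
    systolic blood pressure per SD of RNA expression) is computed with its
    delta-method SE; candidates with two-sided p < ``alpha`` are retained.
    The target is ``validated`` iff at least one candidate survives, otherwise
    it stays ``expressed``.  Candidates absent from the exposure GWAS are
    dropped with a reason.

    Effect alleles are aligned between the eQTL and exposure records before
    the ratio (swapped labels flip the expression beta's sign).
    """
    ti = TargetInstrument(gene=gene, candidates=candidates[["SNP", "TISSUE", "P"]].copy()
                          if not candidates.empty else None)
    if candidates.empty:
        ti.candidates = pd.DataFrame(columns=["SNP", "TISSUE", "P"])
        ti.exclusion_reason = "no eQTL best SNP in any tissue"
        return ti
    ti.advance("expressed")
    gwas = sbp_gwas.set_index("SNP", drop=False)
    rows = []
    for _, cand in candidates.iterrows():
        snp = cand["SNP"]
        if snp not in gwas.index:
            rows.append({"SNP": snp, "beta": None, "se": None, "pval": None,
                         "retained": False, "reason": "absent from exposure GWAS"})
            continue
        g = gwas.loc[snp]
        b_expr, se_expr = float(cand["BETA"]), float(cand["SE"])
        b_sbp, se_sbp = float(g["BETA"]), float(g["SE"])
        if (cand["EA"], cand["OA"]) == (g["OA"], g["EA"]):
            b_expr = -b_expr
        elif (cand["EA"], cand["OA"]) != (g["EA"], g["OA"]):
            rows.append({"SNP": snp, "beta": None, "se": None, "pval": None,
                         "retained": False, "reason": "allele mismatch with exposure GWAS"})
            continue
        if b_expr == 0:
            rows.append({"SNP": snp, "beta": None, "se": None, "pval": None,
                         "retained": False, "reason": "zero expression beta"})
            continue
        est = estimators.wald_ratio(b_expr, se_expr, b_sbp, se_sbp)
        rows.append({"SNP": snp, "beta": est.beta, "se": est.se, "pval": est.pval,
                     "retained": bool(est.pval < alpha), "reason": None})
    ti.validation = pd.DataFrame(rows)
    ti.validated_variants = list(ti.validation.loc[ti.validation["retained"], "SNP"])
    if ti.validated_variants:
        ti.advance("validated")
    else:
        ti.exclusion_reason = "no candidate with evidence of an exposure effect"
    return ti


def build_class_instrument(
    cls: DrugClass,
    targets: Sequence[TargetInstrument],
    outcome: pd.DataFrame,
    panel: LDPanel,
    exposure: pd.DataFrame,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    proxy_r2: float = 0.8,
    proxy_maf: float = 0.3,
) -> tuple[list[str], pd.DataFrame]:
    """Combine the validated variants of a class's targets into one instrument.

    Union of validated variants, deduplicated, clumped against the panel, then
    proxy-substituted for variants missing from the outcome GWAS.  Targets all
    of whose variants end up dropped are marked ``excluded_no_outcome_data``.

    Returns ``(variant list, substitution table)`` where the variant list
    contains original (pre-proxy) ids retained for analysis.
    """
    for t in targets:
        if t.status not in ("validated", "analysed", "excluded_no_outcome_data"):
            raise ValueError(f"target {t.gene} not validated")
        if t.gene not in cls.target_genes:
            raise ValueError(f"target {t.gene} does not belong to class {cls.name}")
    union: list[str] = []
    seen: set[str] = set()
    for t in targets:
        for v in t.validated_variants:
            if v not in seen:
                seen.add(v)
                union.append(v)
    if not union:
        logger.info("class %r has no validated variants; unanalysable", cls.name)
        return [], pd.DataFrame(columns=["SNP", "used", "status", "r", "r2"])
    exp = exposure.set_index("SNP", drop=False)
    recs = exp.loc[[v for v in union if v in exp.index]].reset_index(drop=True)
    retained = clump(recs, panel, r2_max=clump_r2, window_kb=clump_kb)
    subs = substitute_proxies(retained, outcome, panel,
                              r2_min=proxy_r2, palindrome_maf_max=proxy_maf)
    usable = set(subs.loc[subs["status"] != "dropped", "SNP"])
    for t in targets:
        if t.status == "validated":
            surviving = [v for v in t.validated_variants if v in usable]
            if surviving:
                t.advance("analysed")
            else:
                t.advance("excluded_no_outcome_data")
                t.exclusion_reason = "neither instrument nor suitable proxy in outcome data"
    final = [v for v in retained if v in usable]
    return final, subs


def build_gw_significant_instrument(
    sbp_gwas: pd.DataFrame,
    panel: LDPanel,
    outcome: pd.DataFrame,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    proxy_r2: float = 0.8,
    proxy_maf: float = 0.3,
) -> tuple[list[str], pd.DataFrame]:
    """Instrument from all genome-wide-significant exposure SNPs.

    Filters the exposure GWAS at ``p < p_threshold``, clumps, and substitutes
    proxies for variants missing from the outcome GWAS.  An empty result means
    the analysis mode is unanalysable (reported, not fatal).
    """
    sig = sbp_gwas[sbp_gwas["P"] < p_threshold]
    if sig.empty:
        logger.info("no genome-wide significant exposure SNPs at p < %g", p_threshold)
        return [], pd.DataFrame(columns=["SNP", "used", "status", "r", "r2"])
    retained = clump(sig, panel, r2_max=clump_r2, window_kb=clump_kb)
    subs = substitute_proxies(retained, outcome, panel,
                              r2_min=proxy_r2, palindrome_maf_max=proxy_maf)
    usable = set(subs.loc[subs["status"] != "dropped", "SNP"])
    return [v for v in retained if v in usable], subs


def stage_counts(targets: Sequence[TargetInstrument]) -> dict[str, int]:
    """Filter-chain counts: candidates >= expressed >= validated >= analysed."""
    reached = {s: 0 for s in STATUS_ORDER}
    for t in targets:
        idx = STATUS_ORDER.index(t.status)
        for s in STATUS_ORDER[: idx + 1]:
            reached[s] += 1
    # excluded targets still counted as having been validated
    return {
        "candidates": len(targets),
        "expressed": reached["expressed"],
        "validated": reached["validated"],
        "excluded_no_outcome_data": sum(
            1 for t in targets if t.status == "excluded_no_outcome_data"
        ),
        "analysed": sum(1 for t in targets if t.status == "analysed"),
    }
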