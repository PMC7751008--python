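"""End-to-end orchestration of the three analysis modes.

From one configuration, runs instrument construction, harmonization,
exposure-increasing orientation, estimation, odds-ratio transformation and
sensitivity analyses (MR-Egger at >= ``egger_min_snps`` SNPs, per-target
decomposition for drug classes), and writes a results table, a target-status
table, a drop-reason log, a run manifest and a human-readable report.

Unanalysable classes (no validated target, or no outcome data) are reported
with a reason rather than treated as errors; only missing inputs or a run in
which no mode is analysable are fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    EggerResult,
    MREstimate,
    compare_ivw_egger,
    egger,
    estimate,
    per_target_decomposition,
)
from .instruments import (
    DrugClass,
    TargetInstrument,
    build_class_instrument,
    build_gw_significant_instrument,
    load_drug_class_registry,
    select_best_snps,
    stage_counts,
    validate_target,
)
from .io import harmonize, orient_to_exposure_increasing, read_eqtl, read_summary_stats
from .ld import LDPanel, apply_proxies, clump, find_proxy, substitute_proxies

logger = logging.getLogger(__name__)

ALL_MODES = ("per_class", "all_targets", "all_gw_significant")

RESULT_COLUMNS = [
    "analysis_mode", "class_or_target", "n_snp", "method",
    "beta_sd_scale", "se", "pval",
    "or_per_10mmhg_lower", "or_ci_low", "or_ci_high",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p", "notes",
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode selection for one pipeline run."""

    exposure: str
    outcome: str
    eqtl: str
    registry: str
    panel_variants: str
    panel_matrix: str
    out_dir: str = "results"
    validation_alpha: float = 0.05
    gw_significance_p: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    proxy_r2: float = 0.8
    proxy_maf: float = 0.3
    palindrome_maf_max: float = 0.3
    egger_min_snps: int = 10
    sd_sbp_mmhg: float = 19.3
    ivw_mode: str = "mre"
    seed: int = 0
    modes: tuple = ALL_MODES
    decompose_targets: bool = True  # per-target decomposition within each union

    def __post_init__(self) -> None:
        for name, val, lo, hi in [
            ("validation_alpha", self.validation_alpha, 0, 1),
            ("gw_significance_p", self.gw_significance_p, 0, 1),
            ("clump_r2", self.clump_r2, 0, 1),
            ("proxy_r2", self.proxy_r2, 0, 1),
            ("proxy_maf", self.proxy_maf, 0, 0.5),
            ("palindrome_maf_max", self.palindrome_maf_max, 0, 0.5),
        ]:
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.sd_sbp_mmhg <= 0:
            raise ValueError("sd_sbp_mmhg must be positive")
        unknown = set(self.modes) - set(ALL_MODES)
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")
        self.modes = tuple(self.modes)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class AnalysisInputs:
    """In-memory inputs for the analysis core (file-free entry point)."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    eqtl: pd.DataFrame
    registry: dict  # class name -> [genes]
    panel: LDPanel


@dataclass
class ResultsBundle:
    """Everything one pipeline run produced."""

    results: pd.DataFrame
    target_status: pd.DataFrame
    substitutions: pd.DataFrame
    drops: pd.DataFrame
    per_target: pd.DataFrame
    counts: dict
    verdicts: list = field(default_factory=list)


class PipelineError(RuntimeError):
    """Fatal pipeline condition (missing inputs, nothing analysable)."""


def _est_row(mode: str, label: str, est: MREstimate,
             egger_res: Optional[EggerResult], notes: str = "") -> dict:
    return {
        "analysis_mode": mode,
        "class_or_target": label,
        "n_snp": est.n_snp,
        "method": est.method,
        "beta_sd_scale": est.beta,
        "se": est.se,
        "pval": est.pval,
        "or_per_10mmhg_lower": est.or_per_10mmhg_lower,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "egger_intercept": egger_res.intercept if egger_res else np.nan,
        "egger_intercept_se": egger_res.intercept_se if egger_res else np.nan,
        "egger_intercept_p": egger_res.intercept_pval if egger_res else np.nan,
        "notes": notes,
    }


def _skip_row(mode: str, label: str, reason: str) -> dict:
    return {
        "analysis_mode": mode, "class_or_target": label, "n_snp": 0,
        "method": "none", "beta_sd_scale": np.nan, "se": np.nan, "pval": np.nan,
        "or_per_10mmhg_lower": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan,
        "egger_intercept": np.nan, "egger_intercept_se": np.nan,
        "egger_intercept_p": np.nan, "notes": reason,
    }


def _harmonized_for(
    variant_ids: Sequence[str],
    subs: pd.DataFrame,
    inputs: AnalysisInputs,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize an instrument: proxy-adjusted outcome vs exposure records.

    Returns the oriented harmonized table and the drop log for this instrument.
    """
    exp = inputs.exposure[inputs.exposure["SNP"].isin(set(variant_ids))]
    sub_used = subs[subs["SNP"].isin(set(variant_ids))]
    out_eff = apply_proxies(sub_used, inputs.outcome, inputs.panel)
    hres = harmonize(exp, out_eff, palindrome_maf_max=cfg.palindrome_maf_max)
    h = orient_to_exposure_increasing(hres.table)
    drops = hres.dropped.copy()
    for snp in hres.unmatched:
        drops = pd.concat(
            [drops, pd.DataFrame([{"SNP": snp, "reason": "absent from outcome, no proxy"}])],
            ignore_index=True,
        )
    return h, drops


def _estimate_block(
    mode: str, label: str, h: pd.DataFrame, cfg: PipelineConfig,
    verdicts: list,
) -> dict:
    """Estimate one instrument and attach Egger sensitivity when allowed."""
    est = estimate(h, mode=cfg.ivw_mode, sd_sbp_mmhg=cfg.sd_sbp_mmhg)
    egger_res = None
    notes = ""
    if len(h) >= cfg.egger_min_snps:
        egger_res = egger(h)
        verdict = compare_ivw_egger(est, egger_res)
        verdicts.append({"analysis_mode": mode, "class_or_target": label,
                         "verdict": verdict})
    else:
        notes = f"Egger not computed (<{cfg.egger_min_snps} SNPs)"
    return _est_row(mode, label, est, egger_res, notes)


def analyse(inputs: AnalysisInputs, cfg: PipelineConfig) -> ResultsBundle:
    """Run the selected analysis modes on in-memory inputs.

    The target filter chain is computed once, globally: every gene named by
    the registry is a candidate; genes with an eQTL best SNP in any tissue are
    ``expressed``; genes with a candidate showing evidence of an exposure
    effect are ``validated``; validated genes none of whose variants survive
    in the outcome GWAS (directly or by proxy) are ``excluded_no_outcome_data``
    and the rest are ``analysed``.
    """
    classes = [DrugClass(name=c, target_genes=list(g)) for c, g in inputs.registry.items()]
    genes: list[str] = []
    for c in classes:
        for g in c.target_genes:
            if g not in genes:
                genes.append(g)

    positions = dict(zip(inputs.panel.variants["SNP"], inputs.panel.variants["POS"]))
    targets: dict[str, TargetInstrument] = {}
    for gene in genes:
        cands = select_best_snps(inputs.eqtl, gene, positions=positions)
        targets[gene] = validate_target(gene, cands, inputs.exposure,
                                        alpha=cfg.validation_alpha)

    # global outcome-availability check, before any per-class analysis
    outcome_snps = set(inputs.outcome["SNP"])
    for t in targets.values():
        if t.status != "validated":
            continue
        usable = False
        for vid in t.validated_variants:
            if vid in outcome_snps or find_proxy(
                vid, inputs.panel, outcome_snps,
                r2_min=cfg.proxy_r2, palindrome_maf_max=cfg.proxy_maf,
            ):
                usable = True
                break
        if usable:
            t.advance("analysed")
        else:
            t.advance("excluded_no_outcome_data")
            t.exclusion_reason = "neither instrument nor suitable proxy in outcome data"

    result_rows: list[dict] = []
    all_subs: list[pd.DataFrame] = []
    all_drops: list[pd.DataFrame] = []
    verdicts: list = []
    per_target_rows: list[pd.DataFrame] = []

    def run_union(mode: str, label: str, members: list[TargetInstrument]) -> Optional[MREstimate]:
        cls_like = DrugClass(name=label, target_genes=[t.gene for t in members])
        variant_ids, subs = build_class_instrument(
            cls_like, members, inputs.outcome, inputs.panel, inputs.exposure,
            clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
            proxy_r2=cfg.proxy_r2, proxy_maf=cfg.proxy_maf,
        )
        if not subs.empty:
            s = subs.copy()
            s.insert(0, "analysis_mode", mode)
            s.insert(1, "class_or_target", label)
            all_subs.append(s)
        if not variant_ids:
            result_rows.append(_skip_row(mode, label, "no instrument variant in outcome data"))
            return None
        h, drops = _harmonized_for(variant_ids, subs, inputs, cfg)
        if not drops.empty:
            d = drops.copy()
            d.insert(0, "analysis_mode", mode)
            d.insert(1, "class_or_target", label)
            all_drops.append(d)
        if h.empty:
            result_rows.append(_skip_row(mode, label, "all variants dropped in harmonization"))
            return None
        row = _estimate_block(mode, label, h, cfg, verdicts)
        result_rows.append(row)
        est = estimate(h, mode=cfg.ivw_mode, sd_sbp_mmhg=cfg.sd_sbp_mmhg)
        if not cfg.decompose_targets:
            return est
        # per-target decomposition: each analysed member on its own instrument
        per_t: dict[str, pd.DataFrame] = {}
        for t in members:
            if t.status != "analysed":
                continue
            own_recs = inputs.exposure[inputs.exposure["SNP"].isin(set(t.validated_variants))]
            own_clumped = clump(own_recs, inputs.panel,
                                r2_max=cfg.clump_r2, window_kb=cfg.clump_kb)
            own_subs = substitute_proxies(
                own_clumped, inputs.outcome, inputs.panel,
                r2_min=cfg.proxy_r2, palindrome_maf_max=cfg.proxy_maf,
            )
            own_ids = [v for v in own_clumped
                       if v in set(own_subs.loc[own_subs["status"] != "dropped", "SNP"])]
            if not own_ids:
                continue
            ht, _ = _harmonized_for(own_ids, own_subs, inputs, cfg)
            if not ht.empty:
                per_t[t.gene] = ht
        if per_t:
            dec = per_target_decomposition(est, per_t, mode=cfg.ivw_mode,
                                           sd_sbp_mmhg=cfg.sd_sbp_mmhg)
            dec.insert(0, "analysis_mode", mode)
            dec.insert(1, "class_or_target", label)
            per_target_rows.append(dec)
        return est

    if "per_class" in cfg.modes:
        for c in classes:
            members = [targets[g] for g in c.target_genes if targets[g].status in
                       ("analysed", "excluded_no_outcome_data", "validated")]
            if not c.analysable:
                result_rows.append(_skip_row("per_class", c.name, "no target genes"))
                continue
            if not any(t.status == "analysed" for t in members):
                result_rows.append(_skip_row("per_class", c.name, "no analysable target"))
                continue
            run_union("per_class", c.name, members)

    if "all_targets" in cfg.modes:
        members = [t for t in targets.values()
                   if t.status in ("analysed", "excluded_no_outcome_data")]
        if any(t.status == "analysed" for t in members):
            run_union("all_targets", "all targets combined", members)
        else:
            result_rows.append(_skip_row("all_targets", "all targets combined",
                                         "no analysable target"))

    if "all_gw_significant" in cfg.modes:
        ids, subs = build_gw_significant_instrument(
            inputs.exposure, inputs.panel, inputs.outcome,
            p_threshold=cfg.gw_significance_p,
            clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb,
            proxy_r2=cfg.proxy_r2, proxy_maf=cfg.proxy_maf,
        )
        if not subs.empty:
            s = subs.copy()
            s.insert(0, "analysis_mode", "all_gw_significant")
            s.insert(1, "class_or_target", "genome-wide significant SNPs")
            all_subs.append(s)
        if not ids:
            result_rows.append(_skip_row("all_gw_significant", "genome-wide significant SNPs",
                                         "no genome-wide significant SNP usable"))
        else:
            h, drops = _harmonized_for(ids, subs, inputs, cfg)
            if not drops.empty:
                d = drops.copy()
                d.insert(0, "analysis_mode", "all_gw_significant")
                d.insert(1, "class_or_target", "genome-wide significant SNPs")
                all_drops.append(d)
            if h.empty:
                result_rows.append(_skip_row("all_gw_significant",
                                             "genome-wide significant SNPs",
                                             "all variants dropped in harmonization"))
            else:
                result_rows.append(_estimate_block("all_gw_significant",
                                                   "genome-wide significant SNPs",
                                                   h, cfg, verdicts))

    gene_classes = {
        g: "; ".join(c.name for c in classes if g in c.target_genes) for g in genes
    }
    status_rows = [
        {
            "gene": t.gene,
            "classes": gene_classes.get(t.gene, ""),
            "status": t.status,
            "reason": t.exclusion_reason or "",
            "n_candidates": len(t.candidates),
            "n_validated_snps": len(t.validated_variants),
        }
        for t in targets.values()
    ]

    results = pd.DataFrame(result_rows, columns=RESULT_COLUMNS)
    if not any(results["method"] != "none"):
        raise PipelineError("no analysis mode produced an estimate; see notes: "
                            + "; ".join(results["notes"].unique()))
    bundle = ResultsBundle(
        results=results,
        target_status=pd.DataFrame(
            status_rows,
            columns=["gene", "classes", "status", "reason", "n_candidates",
                     "n_validated_snps"],
        ),
        substitutions=(pd.concat(all_subs, ignore_index=True) if all_subs
                       else pd.DataFrame(columns=["analysis_mode", "class_or_target",
                                                  "SNP", "used", "status", "r", "r2"])),
        drops=(pd.concat(all_drops, ignore_index=True) if all_drops
               else pd.DataFrame(columns=["analysis_mode", "class_or_target",
                                          "SNP", "reason"])),
        per_target=(pd.concat(per_target_rows, ignore_index=True) if per_target_rows
                    else pd.DataFrame()),
        counts=stage_counts(list(targets.values())),
        verdicts=verdicts,
    )
    return bundle


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Load inputs from the configured paths, analyse, and write outputs."""
    for p in (cfg.exposure, cfg.outcome, cfg.eqtl, cfg.registry,
              cfg.panel_variants, cfg.panel_matrix):
        if not Path(p).exists():
            raise PipelineError(f"missing input file: {p}")
    exposure, _ = read_summary_stats(cfg.exposure)
    outcome, _ = read_summary_stats(cfg.outcome)
    eqtl, _ = read_eqtl(cfg.eqtl)
    classes = load_drug_class_registry(cfg.registry)
    registry = {c.name: c.target_genes for c in classes}
    panel = LDPanel.load(cfg.panel_variants, cfg.panel_matrix)
    inputs = AnalysisInputs(exposure=exposure, outcome=outcome, eqtl=eqtl,
                            registry=registry, panel=panel)
    bundle = analyse(inputs, cfg)
    write_outputs(bundle, cfg)
    return bundle


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_outputs(bundle: ResultsBundle, cfg: PipelineConfig) -> Path:
    """Write results, status, substitutions, drops, manifest and report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.results, out / "results.tsv")
    _write_tsv(bundle.target_status, out / "target_status.tsv")
    _write_tsv(bundle.substitutions, out / "proxy_substitutions.tsv")
    _write_tsv(bundle.drops, out / "drop_log.tsv")
    if not bundle.per_target.empty:
        _write_tsv(bundle.per_target, out / "per_target_estimates.tsv")
    cfg_dict = asdict(cfg)
    cfg_dict["modes"] = list(cfg.modes)
    manifest = {
        "package": "targetmr",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "counts": bundle.counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report(bundle, cfg))
    return out


def _fmt_or(row) -> str:
    if row["method"] == "none" or pd.isna(row["or_per_10mmhg_lower"]):
        return "-"
    return (f"{row['or_per_10mmhg_lower']:.2f} "
            f"({row['or_ci_low']:.2f} to {row['or_ci_high']:.2f})")


def render_report(bundle: ResultsBundle, cfg: Optional[PipelineConfig] = None) -> str:
    """Human-readable markdown report mirroring the results-table layout."""
    lines = ["# Drug-target MR results", ""]
    modes = sorted(bundle.results["analysis_mode"].unique()) if not bundle.results.empty else []
    skipped = [m for m in ALL_MODES if cfg and m not in cfg.modes]
    if skipped:
        lines.append(f"Modes skipped by configuration: {', '.join(skipped)}.")
        lines.append("")
    lines.append("| analysis | class / target | OR per 10 mmHg lower (95% CI) | p | SNPs | Egger intercept | notes |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, row in bundle.results.iterrows():
        pval = "-" if pd.isna(row["pval"]) else f"{row['pval']:.3g}"
        if pd.isna(row["egger_intercept"]):
            eg = "not computed" if row["method"] != "none" else "-"
        else:
            eg = (f"{row['egger_intercept']:.4f} "
                  f"(p={row['egger_intercept_p']:.3g})")
        lines.append(
            f"| {row['analysis_mode']} | {row['class_or_target']} | {_fmt_or(row)} "
            f"| {pval} | {row['n_snp']} | {eg} | {row['notes']} |"
        )
    c = bundle.counts
    lines += [
        "",
        "## Target filter chain",
        "",
        f"- candidate targets: {c['candidates']}",
        f"- expressed (eQTL best SNP in >=1 tissue): {c['expressed']}",
        f"- validated (evidence of an exposure effect): {c['validated']}",
        f"- excluded (no outcome data or proxy): {c['excluded_no_outcome_data']}",
        f"- analysed: {c['analysed']}",
        "",
    ]
    n_proxy = int((bundle.substitutions["status"] == "proxy").sum()) \
        if not bundle.substitutions.empty else 0
    lines.append("## Proxy substitutions")
    lines.append("")
    if n_proxy:
        sub = bundle.substitutions[bundle.substitutions["status"] == "proxy"]
        for _, s in sub.iterrows():
            lines.append(
                f"- {s['analysis_mode']} / {s['class_or_target']}: {s['SNP']} -> "
                f"{s['used']} (r2 = {s['r2']:.3f})"
            )
    else:
        lines.append("- none")
    lines.append("")
    if bundle.verdicts:
        lines.append("## IVW vs MR-Egger")
        lines.append("")
        for entry in bundle.verdicts:
            v = entry["verdict"]
            flag = "directional pleiotropy flagged" if v.directional_pleiotropy \
                else "no directional pleiotropy"
            cons = "consistent" if v.ivw_point_in_egger_ci else "inconsistent"
            lines.append(
                f"- {entry['analysis_mode']} / {entry['class_or_target']}: "
                f"intercept {v.intercept:.4f} "
                f"({v.intercept_ci_low:.4f} to {v.intercept_ci_high:.4f}), "
                f"{cons}, {flag}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
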