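"""Synthetic two-sample MR studies with a known causal structure.

Generates every input the pipeline consumes — an LD reference panel, an eQTL
best-SNP table, exposure (systolic blood pressure) and outcome (Alzheimer's
disease) GWAS summary statistics, and a drug-class registry — from explicit
generative parameters, so each pipeline stage and estimator can be tested
against ground truth without any external download.

The causal chain is SNP -> gene expression -> exposure -> outcome:

* a gene's lead variant changes expression by ``a`` SD per effect allele
  (the eQTL effect, re-measured with noise in each tissue);
* expression changes the exposure by ``k`` SD per SD (``gene_to_sbp``), so the
  variant's joint exposure effect is ``b = a * k``;
* the exposure changes the outcome log-odds by ``theta`` per SD;
* optional per-SNP horizontal pleiotropy (direct SNP -> outcome effects drawn
  from ``N(pleiotropy_mean, pleiotropy_sd)``);
* an optional competing mechanism: a direct expression -> outcome effect
  ``delta`` per SD expression (``delta_by_gene``), bypassing the exposure.
  A single-SNP Wald ratio then converges to ``theta + delta * a / b``
  (= ``theta + delta / k``), the inflation that makes a drug-target estimate
  unreliable when the target barely moves the exposure.

Marginal GWAS effects are the LD-smeared joint effects (``R @ b_joint`` per
block) and estimation noise is drawn with the block correlation structure, at
standard errors matching the stated sample sizes:
``se_x ~ (2 n maf(1-maf))**-0.5`` for a quantitative trait in SD units and
``se_y ~ (2 maf(1-maf) n_case n_control / (n_case + n_control))**-0.5`` for a
case-control log-odds scale.  Exposure and outcome noise are independent
(two non-overlapping samples).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import write_summary_stats
from .ld import LDPanel

# the 12 antihypertensive drug classes of the British National Formulary
DRUG_CLASSES = [
    "adrenergic neurone blocking drugs",
    "alpha-adrenoceptor blockers",
    "angiotensin-converting enzyme inhibitors",
    "angiotensin-II receptor blockers",
    "beta-adrenoceptor blockers",
    "calcium channel blockers",
    "centrally acting antihypertensive drugs",
    "loop diuretics",
    "potassium-sparing diuretics and aldosterone antagonists",
    "renin inhibitors",
    "thiazides and related diuretics",
    "vasodilator antihypertensives",
]

SCENARIOS = ("null", "causal", "pleiotropic", "competing", "proxy-needed")

# default theta: log-odds of outcome per SD higher exposure such that the
# odds ratio per 10 mmHg LOWER exposure is 1.5 at sd(SBP) = 19.3 mmHg
SD_SBP_MMHG = 19.3
THETA_OR15 = -math.log(1.5) * SD_SBP_MMHG / 10.0

_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"), ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
]


@dataclass
class TruthParams:
    """Generative parameters of a synthetic two-sample MR study.

    ``theta`` is the causal log-odds of outcome per SD higher exposure;
    ``delta_by_gene`` the competing direct expression -> outcome effects;
    ``gene_to_sbp`` the expression -> exposure effects ``k``;
    ``eqtl_effects`` the per-(gene, tissue) SNP -> expression effects ``a``;
    ``gene_variant`` assigns each gene its lead variant in the panel.
    """

    theta: float
    n_exposure: int = 317_754
    n_case: int = 17_008
    n_control: int = 37_154
    n_eqtl: int = 620
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    delta_by_gene: dict = field(default_factory=dict)
    gene_to_sbp: dict = field(default_factory=dict)
    eqtl_effects: dict = field(default_factory=dict)  # (gene, tissue) -> effect
    gene_variant: dict = field(default_factory=dict)  # gene -> variant id
    background_effects: dict = field(default_factory=dict)  # variant id -> joint beta_x
    outcome_missing: list = field(default_factory=list)  # variant ids withheld
    ld_block_spec: list = field(default_factory=list)  # [{"size": int, "r": float}]
    maf_range: tuple = (0.05, 0.45)
    outcome_label_swap_frac: float = 0.3
    outcome_strand_flip_frac: float = 0.1
    registry: dict = field(default_factory=dict)  # class -> [genes]
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_exposure, self.n_case, self.n_control, self.n_eqtl):
            if n <= 0:
                raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_sbp)

    def expression_effect(self, gene: str) -> float:
        """The variant's biological expression effect: mean over tissues."""
        vals = [v for (g, _t), v in self.eqtl_effects.items() if g == gene]
        if not vals:
            raise KeyError(f"no eQTL effects for gene {gene}")
        return float(np.mean(vals))

    def joint_exposure_effect(self, gene: str) -> float:
        """b = a * k, the lead variant's joint effect on the exposure."""
        return self.expression_effect(gene) * self.gene_to_sbp[gene]

    def wald_expectation(self, gene: str) -> float:
        """Large-sample single-SNP estimate: theta + delta * a / b."""
        a = self.expression_effect(gene)
        b = self.joint_exposure_effect(gene)
        delta = self.delta_by_gene.get(gene, 0.0)
        return self.theta + delta * a / b


@dataclass
class StudyData:
    """One complete synthetic study: all pipeline inputs plus the truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    eqtl: pd.DataFrame
    registry: dict
    panel: LDPanel
    truth: TruthParams


def simulate_ld_panel(
    ld_block_spec: Sequence[dict],
    maf_range: tuple = (0.05, 0.45),
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    within_spacing: int = 10_000,
    between_gap: int = 20_000_000,
) -> LDPanel:
    """Block-diagonal LD panel from a block specification.

    Each block is compound-symmetric with the given within-block correlation
    (in [0, 1)); blocks are mutually uncorrelated and separated by
    ``between_gap`` bp so that distinct blocks never share a clumping window
    while variants within a block always do.  MAFs are uniform in
    ``maf_range``; allele pairs are drawn uniformly (so roughly a third of
    variants are palindromic, exercising the frequency-based orientation
    rules).  Variant ids are sequential ``rs000001, ...``.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(b["size"]) for b in ld_block_spec]
    corrs = [float(b["r"]) for b in ld_block_spec]
    if any(s < 1 for s in sizes):
        raise ValueError("block sizes must be >= 1")
    if any(not (0 <= c < 1) for c in corrs):
        raise ValueError("within-block correlations must lie in [0, 1)")
    n = sum(sizes)
    r = np.eye(n)
    rows = []
    pos = start_pos
    i = 0
    for size, corr in zip(sizes, corrs):
        block = np.full((size, size), corr)
        np.fill_diagonal(block, 1.0)
        try:
            np.linalg.cholesky(block)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - corr<1 is PD
            raise ValueError(f"block correlation {corr} not positive definite") from exc
        r[i : i + size, i : i + size] = block
        for j in range(size):
            ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            maf = float(rng.uniform(*maf_range))
            rows.append({
                "SNP": f"rs{i + j + 1:06d}", "CHR": chrom, "POS": pos,
                "A1": ea, "A2": oa, "MAF": maf,
            })
            pos += within_spacing
        pos += between_gap
        i += size
    return LDPanel(variants=pd.DataFrame(rows), r=r)


def _se_quantitative(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _se_case_control(maf: np.ndarray, n_case: int, n_control: int) -> np.ndarray:
    neff = n_case * n_control / (n_case + n_control)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * neff)


def _block_slices(panel: LDPanel) -> list[np.ndarray]:
    """Recover block index groups from the (block-diagonal) correlation matrix."""
    n = len(panel)
    seen = np.zeros(n, dtype=bool)
    blocks = []
    for i in range(n):
        if seen[i]:
            continue
        idx = np.where(np.abs(panel.r[i]) > 1e-12)[0]
        seen[idx] = True
        blocks.append(idx)
    return blocks


def _marginal_and_noise(
    panel: LDPanel, joint: np.ndarray, se: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """LD-smeared marginal effects plus block-correlated estimation noise."""
    beta = np.empty(len(panel))
    for idx in _block_slices(panel):
        rb = panel.r[np.ix_(idx, idx)]
        marginal = rb @ joint[idx]
        chol = np.linalg.cholesky(rb)
        z = chol @ rng.standard_normal(len(idx))
        beta[idx] = marginal + se[idx] * z
    return beta


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta / se)
    p = 2.0 * stats.norm.sf(z)
    return np.maximum(p, np.finfo(float).tiny)  # keep within (0, 1]


def simulate_study(truth: TruthParams, panel: LDPanel) -> StudyData:
    """Simulate exposure GWAS, outcome GWAS, eQTL table and registry.

    Deterministic given ``truth.seed``; exposure and outcome noise are drawn
    from independent streams (the two-sample design has no sample overlap).
    A subset of variants (``truth.outcome_missing``) is withheld from the
    outcome GWAS to exercise proxy substitution.
    """
    rng = np.random.default_rng(truth.seed)
    rng_x = np.random.default_rng(rng.integers(2**31))
    rng_y = np.random.default_rng(rng.integers(2**31))
    rng_e = np.random.default_rng(rng.integers(2**31))
    rng_fmt = np.random.default_rng(rng.integers(2**31))

    v = panel.variants
    n = len(panel)
    maf = v["MAF"].to_numpy(dtype=float)
    idx_of = {s: i for i, s in enumerate(v["SNP"])}

    # joint (causal) per-variant effects
    b_joint = np.zeros(n)
    a_of_variant = np.zeros(n)  # expression effect at the gene lead variant
    delta_at = np.zeros(n)
    for gene in truth.genes:
        vid = truth.gene_variant[gene]
        i = idx_of[vid]
        a = truth.expression_effect(gene)
        b_joint[i] += a * truth.gene_to_sbp[gene]
        a_of_variant[i] = a
        delta_at[i] += truth.delta_by_gene.get(gene, 0.0) * a
    for vid, eff in truth.background_effects.items():
        b_joint[idx_of[vid]] += eff

    # horizontal pleiotropy on every variant carrying a true exposure effect
    pleio = np.zeros(n)
    if truth.pleiotropy_sd > 0 or truth.pleiotropy_mean != 0:
        mask = b_joint != 0
        pleio[mask] = rng_y.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, mask.sum())

    se_x = _se_quantitative(maf, truth.n_exposure)
    beta_x = _marginal_and_noise(panel, b_joint, se_x, rng_x)

    y_joint = truth.theta * b_joint + pleio + delta_at
    se_y = _se_case_control(maf, truth.n_case, truth.n_control)
    beta_y = _marginal_and_noise(panel, y_joint, se_y, rng_y)

    exposure = pd.DataFrame({
        "SNP": v["SNP"], "CHR": v["CHR"], "POS": v["POS"],
        "EA": v["A1"], "OA": v["A2"], "EAF": maf,
        "BETA": beta_x, "SE": se_x, "P": _pvals(beta_x, se_x),
    })

    # outcome records: same strand/labels as the panel, then randomly re-label
    # a fraction (swap effect/other allele, negate beta, complement EAF) and
    # strand-flip another fraction, so harmonization has real work to do
    ea, oa, bet, eaf = v["A1"].to_numpy().copy(), v["A2"].to_numpy().copy(), beta_y.copy(), maf.copy()
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    swap = rng_fmt.uniform(size=n) < truth.outcome_label_swap_frac
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    bet[swap] = -bet[swap]
    eaf[swap] = 1.0 - eaf[swap]
    flip = rng_fmt.uniform(size=n) < truth.outcome_strand_flip_frac
    pal = np.array([comp[a] == b for a, b in zip(v["A1"], v["A2"])])
    flip &= ~pal  # strand flips on palindromic variants are unobservable
    ea[flip] = [comp[a] for a in ea[flip]]
    oa[flip] = [comp[a] for a in oa[flip]]
    outcome = pd.DataFrame({
        "SNP": v["SNP"], "CHR": v["CHR"], "POS": v["POS"],
        "EA": ea, "OA": oa, "EAF": eaf,
        "BETA": bet, "SE": se_y, "P": _pvals(beta_y, se_y),
    })
    if truth.outcome_missing:
        outcome = outcome[~outcome["SNP"].isin(set(truth.outcome_missing))].reset_index(drop=True)

    # eQTL table: per gene and tissue, the whole block is reported with
    # LD-attenuated marginal expression effects, so best-SNP selection is real
    se_e = _se_quantitative(maf, truth.n_eqtl)
    eqtl_rows = []
    tissues_of: dict[str, list[str]] = {}
    for (gene, tissue) in truth.eqtl_effects:
        tissues_of.setdefault(gene, []).append(tissue)
    for gene in truth.genes:
        lead = idx_of[truth.gene_variant[gene]]
        block = next(idx for idx in _block_slices(panel) if lead in idx)
        for tissue in tissues_of.get(gene, []):
            a_gt = truth.eqtl_effects[(gene, tissue)]
            for i in block:
                marg = float(panel.r[i, lead]) * a_gt
                b_hat = marg + rng_e.normal(0.0, se_e[i])
                eqtl_rows.append({
                    "GENE": gene, "TISSUE": tissue, "SNP": v["SNP"].iloc[i],
                    "EA": v["A1"].iloc[i], "OA": v["A2"].iloc[i], "EAF": maf[i],
                    "BETA": b_hat, "SE": se_e[i],
                    "P": float(_pvals(np.array([b_hat]), np.array([se_e[i]]))[0]),
                })
    eqtl = pd.DataFrame(eqtl_rows,
                        columns=["GENE", "TISSUE", "SNP", "EA", "OA", "EAF", "BETA", "SE", "P"])

    registry = truth.registry or {
        cls: [g for j, g in enumerate(truth.genes) if j % len(DRUG_CLASSES) == k]
        for k, cls in enumerate(DRUG_CLASSES)
    }
    return StudyData(exposure=exposure, outcome=outcome, eqtl=eqtl,
                     registry=registry, panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Scenario catalogue
# ---------------------------------------------------------------------------

_TISSUES = ["artery_tibial", "heart_left_ventricle", "adrenal_gland"]


def _gene_truth(rng: np.random.Generator, n_genes: int) -> tuple[dict, dict, dict]:
    """Draw eQTL effects a ~ +/-U(0.3, 0.6) and exposure effects k ~ +/-U(0.05, 0.15)."""
    eqtl_effects, gene_to_sbp = {}, {}
    genes = [f"TGT{i + 1:02d}" for i in range(n_genes)]
    for g in genes:
        a = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
        k = rng.uniform(0.05, 0.15) * rng.choice([-1.0, 1.0])
        gene_to_sbp[g] = float(k)
        for t in _TISSUES:
            eqtl_effects[(g, t)] = float(a)
    return {g: None for g in genes}, eqtl_effects, gene_to_sbp


def make_scenario(name: str, seed: int = 0) -> tuple[TruthParams, LDPanel]:
    """Build the truth parameters and LD panel for a named scenario.

    Catalogue: ``null`` (theta=0, balanced pleiotropy, 30 targets), ``causal``
    (true OR per 10 mmHg lower = 1.5, 20 targets, no pleiotropy),
    ``pleiotropic`` (causal plus directional pleiotropy mean 0.01), ``competing``
    (one target with a weak exposure effect and a direct outcome path) and
    ``proxy-needed`` (causal with instrument variants withheld from the outcome
    GWAS, recoverable through r ~ 0.95 block mates).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    rng = np.random.default_rng(seed + 104729)  # parameter stream, distinct from data stream

    n_genes = {"null": 30, "causal": 20, "pleiotropic": 15,
               "competing": 12, "proxy-needed": 12}[name]
    block_r = 0.95 if name == "proxy-needed" else 0.7
    blocks = [{"size": 3, "r": block_r} for _ in range(n_genes)]
    blocks += [{"size": 2, "r": 0.3} for _ in range(8)]   # background signal blocks
    blocks += [{"size": 2, "r": 0.5} for _ in range(5)]   # null filler
    panel = simulate_ld_panel(blocks, seed=seed)

    genes, eqtl_effects, gene_to_sbp = _gene_truth(rng, n_genes)
    gene_variant = {
        g: panel.variants["SNP"].iloc[3 * i] for i, g in enumerate(genes)
    }
    bg_start = 3 * n_genes
    background = {
        panel.variants["SNP"].iloc[bg_start + 2 * j]: float(
            rng.uniform(0.02, 0.05) * rng.choice([-1.0, 1.0])
        )
        for j in range(8)
    }

    theta = {"null": 0.0}.get(name, THETA_OR15)
    pleio_mean, pleio_sd = 0.0, 0.0
    if name == "null":
        pleio_sd = 0.01
    elif name == "pleiotropic":
        pleio_mean, pleio_sd = 0.01, 0.005

    delta_by_gene: dict[str, float] = {}
    if name == "competing":
        # first target barely moves the exposure but hits the outcome directly
        g0 = next(iter(gene_to_sbp))
        gene_to_sbp[g0] = 0.02
        delta_by_gene[g0] = -0.05

    outcome_missing: list[str] = []
    if name == "competing":
        # the competing check is single-SNP: pin that variant to an
        # unambiguous (non-palindromic) allele pair so it always harmonizes
        g0 = next(iter(gene_to_sbp))
        i0 = panel.idx(gene_variant[g0])
        panel.variants.loc[i0, ["A1", "A2"]] = ["A", "G"]
    if name == "proxy-needed":
        outcome_missing = [gene_variant[g] for g in list(gene_to_sbp)[:2]]
        # the scenario promises a recoverable proxy: make each withheld
        # variant's nearest block mate proxy-eligible by construction
        for vid in outcome_missing:
            mate = panel.idx(vid) + 1
            panel.variants.loc[mate, ["A1", "A2"]] = ["A", "C"]

    truth = TruthParams(
        theta=theta,
        pleiotropy_mean=pleio_mean,
        pleiotropy_sd=pleio_sd,
        delta_by_gene=delta_by_gene,
        gene_to_sbp=gene_to_sbp,
        eqtl_effects=eqtl_effects,
        gene_variant=gene_variant,
        background_effects=background,
        outcome_missing=outcome_missing,
        ld_block_spec=blocks,
        seed=seed,
    )
    return truth, panel


def simulate_scenario(name: str, seed: int = 0) -> StudyData:
    """Convenience: build and simulate a catalogue scenario in one call."""
    truth, panel = make_scenario(name, seed)
    return simulate_study(truth, panel)


def make_fixture(name: str, seed: int, out_dir) -> Path:
    """Write a small deterministic dataset for a catalogue scenario.

    Produces ``exposure.tsv``, ``outcome.tsv``, ``eqtl.tsv``, ``registry.yaml``,
    ``panel_variants.tsv``, ``panel_r.tsv`` and ``truth.json`` under
    ``out_dir``.  Byte-identical for the same name and seed.
    """
    study = simulate_scenario(name, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_summary_stats(study.exposure, out / "exposure.tsv")
    write_summary_stats(study.outcome, out / "outcome.tsv")
    study.eqtl.to_csv(out / "eqtl.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out / "registry.yaml", "w") as fh:
        yaml.safe_dump(
            [{"class": c, "genes": g} for c, g in study.registry.items()],
            fh, sort_keys=False,
        )
    study.panel.save(out / "panel_variants.tsv", out / "panel_r.tsv")
    truth_dict = asdict(study.truth)
    truth_dict["eqtl_effects"] = {f"{g}|{t}": v for (g, t), v in study.truth.eqtl_effects.items()}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Individual-level cross-check generator
# ---------------------------------------------------------------------------

def simulate_outcome_individual(
    truth: TruthParams,
    panel: LDPanel,
    n_individuals: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variant logistic-regression outcome betas from individual-level data.

    A validation path for the summary-level generator: genotypes are drawn at
    the panel MAFs (independent variants), the exposure is built from the joint
    effects plus unit residual noise, and case status follows a logistic model
    with the same theta / pleiotropy / competing paths.  Per-variant log-odds
    are then estimated by single-predictor logistic regression (Newton
    iterations).  Only variants with a nonzero joint effect are returned.
    """
    rng = np.random.default_rng(seed)
    v = panel.variants
    idx_of = {s: i for i, s in enumerate(v["SNP"])}
    maf = v["MAF"].to_numpy(dtype=float)
    n_var = len(panel)
    b_joint = np.zeros(n_var)
    direct = np.zeros(n_var)
    for gene in truth.genes:
        i = idx_of[truth.gene_variant[gene]]
        a = truth.expression_effect(gene)
        b_joint[i] += a * truth.gene_to_sbp[gene]
        direct[i] += truth.delta_by_gene.get(gene, 0.0) * a
    for vid, eff in truth.background_effects.items():
        b_joint[idx_of[vid]] += eff
    active = np.where(b_joint != 0)[0]

    geno = rng.binomial(2, maf[active], size=(n_individuals, len(active))).astype(float)
    std = np.sqrt(2 * maf[active] * (1 - maf[active]))
    geno_std = (geno - 2 * maf[active]) / std
    exposure = geno_std @ b_joint[active] + rng.standard_normal(n_individuals)
    logit = -1.0 + truth.theta * exposure + geno_std @ direct[active]
    case = rng.uniform(size=n_individuals) < 1.0 / (1.0 + np.exp(-logit))

    rows = []
    for j, i in enumerate(active):
        beta, se = _logistic_single(geno_std[:, j], case.astype(float))
        rows.append({"SNP": v["SNP"].iloc[i], "BETA": beta, "SE": se,
                     "true_joint": truth.theta * b_joint[i] + direct[i]})
    return pd.DataFrame(rows)


def _logistic_single(x: np.ndarray, y: np.ndarray, n_iter: int = 25) -> tuple[float, float]:
    """Newton-Raphson logistic regression with intercept, one predictor."""
    beta = np.zeros(2)
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(n_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(hess)
    return float(beta[1]), float(math.sqrt(cov[1, 1]))
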