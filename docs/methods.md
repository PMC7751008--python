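# Methods

## The problem and the model

`targetmr` implements drug-target two-sample Mendelian randomization (MR) for
the question: does lowering systolic blood pressure (SBP) through the protein
targets of antihypertensive drug classes change the risk of Alzheimer's
disease?  Germline variants that alter the expression of a drug-target gene
mimic lifelong pharmacological modulation of that target; their associations
with SBP (from one GWAS sample) and with Alzheimer's disease (from a second,
non-overlapping GWAS sample) identify the causal effect under the standard MR
assumptions (relevance, no confounding of the instrument, no pathway to the
outcome other than the exposure).

Three instrument constructions are run side by side:

1. **per drug class** — the union of validated variants across the class's
   protein-target genes;
2. **all targets combined** — the union over every validated target;
3. **exposure-agnostic** — all genome-wide-significant SBP variants
   (p < 5e-8), ignoring the targets.

For each instrument the per-variant effect pairs (β_X, se_X) from the SBP
GWAS and (β_Y, se_Y) from the Alzheimer's GWAS are harmonized to a shared
effect allele, oriented so every β_X ≥ 0 (an SBP-increasing allele), and
combined:

* **Wald ratio** (1 SNP): β̂ = β_Y / β_X with first-order delta-method
  standard error se_Y / |β_X|.  The first-order SE ignores the uncertainty in
  β_X, the convention for strong instruments in summary-data MR.
* **IVW** (≥ 2 SNPs): weighted least squares of β_Y on β_X through the origin
  with weights 1/se_Y², i.e. β̂ = Σwβ_Xβ_Y / Σwβ_X².  Two standard-error
  flavours: *fixed-effect*, se = (Σwβ_X²)^{-1/2}; and *multiplicative random
  effects* (the default), which multiplies the fixed SE by the residual scale
  √(Σw r²/(n−1)) floored at 1, so heterogeneity widens the interval but
  underdispersion never narrows it.  P-values are normal-based.
* **MR-Egger** (applied at ≥ 10 SNPs in the pipeline; the estimator itself
  needs ≥ 3): the same weighted regression with an intercept.  The slope is
  the pleiotropy-robust causal estimate; the intercept estimates the average
  directional pleiotropic effect across variants.  Inference uses t(n−2).
  Egger requires the exposure-increasing orientation; slope and IVW estimates
  are invariant to it.

Estimates on the log-odds-per-SD-of-SBP scale are re-expressed as the odds
ratio per 10 mmHg *lower* SBP: with c = 10 / sd(SBP), OR = exp(−c·β̂), CI
bounds swapped by the sign flip.  The default sd(SBP) = 19.3 mmHg, a typical
population SD for middle-aged European cohorts; it must be set deliberately
in configuration because the transformed OR scales with it.

## Instrument selection

A drug-class registry maps each of the 12 antihypertensive classes of the
British National Formulary to its protein-target genes.  For each gene, the
candidate instruments are its eQTL "best SNPs": per tissue, the variant with
the smallest nominal p-value for that gene, unioned over tissues and
deduplicated keeping the smallest p (ties break by genomic position, then
variant id).  Each candidate is validated by a Wald-ratio MR of expression on
SBP — the SD change in SBP per SD change in RNA expression — and retained at
two-sided p < 0.05 (configurable).  A target is *validated* when at least one
candidate survives; validated targets none of whose variants are present in
the outcome GWAS (directly or through a proxy) are *excluded*; the rest are
*analysed*.  The counts follow the monotone chain
candidates ≥ expressed ≥ validated ≥ analysed and are reconciled row-by-row
in the run report.

Whether validation should filter per-SNP or per-target is genuinely open; we
filter per-SNP and call the target validated if any SNP survives, which keeps
weak tissues from dragging down a target with one strong instrument.

## LD handling

The LD reference is a desk-scale panel: a variant table plus a dense signed
allelic correlation matrix.  Clumping is greedy and p-ordered: the smallest-p
remaining variant becomes an index SNP and removes everything within the
window (default 10 Mb) with r² above the threshold (default 0.001 — the
convention of widely used summary-data MR tooling; these are configurable
because source publications often leave them unstated).  Proxy search for
instrument variants absent from the outcome GWAS requires r² ≥ 0.8, excludes
palindromic candidates with MAF ≥ 0.3, takes the highest r² (ties: nearest,
then lexicographic id), and re-orients the proxy's outcome beta onto the
original variant via the sign of the panel correlation.

Harmonization follows the frequency-based convention for palindromic (A/T,
C/G) variants: they are kept only when the minor allele frequency is below
0.3 in both datasets and both frequencies are observed, with orientation
inferred from whether the frequencies agree or are complementary.  The 0.3
rule is stated by convention for proxies; we apply the same threshold during
harmonization for consistency (configurable).  A palindromic variant with a
missing frequency is dropped: its orientation is unverifiable.  Every drop
carries a machine-readable reason and input/matched/proxied/dropped counts
reconcile exactly.

## The synthetic-study generator

The generator emulates the full input bundle — LD panel, eQTL best-SNP table,
exposure GWAS, outcome GWAS, drug-class registry — under the explicit causal
chain SNP → expression (a) → SBP (k) → Alzheimer's (θ), with optional
per-SNP horizontal pleiotropy N(μ, σ²) and an optional competing direct
path: an expression → outcome effect δ that bypasses SBP.  Under the
competing path a single-SNP Wald ratio converges to θ + δ·a/b (b = a·k),
the inflation that makes a ratio estimate unreliable exactly when the target
barely moves the exposure.

Defaults mirror the study the pipeline is designed for: exposure GWAS
n = 317,754 (quantitative trait, SD units, se ≈ (2n·maf(1−maf))^{-1/2});
outcome GWAS 17,008 cases / 37,154 controls (log-odds scale,
se ≈ (2·maf(1−maf)·n_eff)^{-1/2} with n_eff the effective case-control size);
eQTL n = 620 donors measured in 3 tissues.  eQTL lead effects are drawn
±U(0.3, 0.6) SD expression per allele and expression→SBP effects
±U(0.05, 0.15) SD per SD — strong instruments (per-variant exposure |z|
mostly ≳ 10), as lead cis-eQTLs for drug-target genes typically are.  MAFs
are uniform on (0.05, 0.45) and allele pairs uniform over ordered pairs, so
about a third of variants are palindromic and the frequency rules are
exercised; outcome records are randomly re-labelled (30% allele swap, 10%
strand flip) so harmonization always has real work to do.

LD is block-diagonal: compound-symmetric blocks (default 3 variants at
r = 0.7 per gene; 0.95 in the proxy scenario so withheld variants have an
eligible proxy) separated by 20 Mb so blocks never share a clumping window.
Marginal GWAS effects are the LD-smeared joint effects (R·b per block) and
estimation noise is drawn with the block correlation at the stated standard
errors; exposure and outcome noise streams are independent (two-sample
design, no overlap).  Outcome betas are generated directly on the log-odds
scale from the linear model; an individual-level logistic generator
(`simulate_outcome_individual`) provides a slower cross-check path used in
the tests.

Scenario catalogue (fixed truth per scenario; replicates vary only the noise
seed): `null` (θ = 0, balanced pleiotropy σ = 0.01, 30 targets), `causal`
(θ = −ln(1.5)·19.3/10 ≈ −0.783, i.e. true OR per 10 mmHg lower = 1.5,
20 targets, no pleiotropy), `pleiotropic` (causal θ with directional
pleiotropy μ = 0.01), `competing` (one target with k = 0.02 and δ = −0.05,
giving a single-SNP expectation θ + δ/k ≈ −3.28), and `proxy-needed`
(causal with two instrument variants withheld from the outcome GWAS).

What the generator deliberately does not emulate: realistic human LD maps
and allele-frequency spectra, ancestry structure, sample overlap, imputation
error, winner's curse in instrument discovery, or selection/survival bias.
Passing tests therefore demonstrate that the statistical machinery is
correct under its stated model, not that any particular real-data estimate
is unbiased.

## Numerical and design choices

* Closed-form WLS (explicit weighted sums) rather than a generic regression
  call; tests verify equality with QR-based least squares and statsmodels WLS
  to 1e-10 relative error.
* Residual scale floored at 1 in both IVW-MRE and Egger, so SEs never fall
  below the fixed-effect value.
* Deterministic tie-breaks everywhere: p-value ties in clumping and best-SNP
  selection resolve by position then variant id; proxy ties by r², distance,
  id; duplicated variant ids keep the smallest p.
* Degenerate inputs: Wald ratio at β_X = 0 raises (a non-instrument); IVW on
  all-zero β_X raises a degenerate-instrument error; Egger below 3 SNPs
  raises; the pipeline converts per-class problems into reported reasons, not
  failures, and only a run with no analysable mode at all exits non-zero.
* Simulation-based checks use the estimator matched to the generating model:
  fixed-effect IVW for coverage under the no-pleiotropy causal scenario
  (the floored random-effects SE is intentionally conservative there),
  the random-effects default wherever pleiotropy creates real overdispersion.
* No multiple-testing correction is applied across classes/targets; the
  report carries the number of analyses so readers can account for it.

## Problem sizes used in checks

Monte-Carlo checks use 500 replicates for recovery and calibration (studies
of ~90 variants, ~20-30 targets), 200 replicates at inflated sample sizes
(n = 5×10⁷ exposure) for the competing-mechanism expectation, 1000 random
instances for estimator-oracle agreement, and 500 random ≤10-variant panels
for clump-vs-brute-force equality.  These sizes keep every Monte-Carlo
standard error small relative to the tolerance it guards.

## Known limitations

* The harmonizer joins on variant id only (both source GWAS conventions are
  rsID-keyed); positional matching, indels and multi-allelic sites are out of
  scope.
* The LD panel is dense and in-memory; it is meant for desk-scale instrument
  sets, not genome-wide panels.
* MR-Egger's intercept sign convention depends on the exposure-increasing
  orientation; the pipeline always applies it, but calling `egger` directly
  on an unoriented table raises rather than silently mis-signing.
* Weighted median/mode estimators, MR-PRESSO, colocalization and
  multivariable MR are not implemented.
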