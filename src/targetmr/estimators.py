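"""Two-sample Mendelian randomization estimators.

Implements the Wald ratio for single-SNP instruments, inverse-variance-weighted
(IVW) meta-analysis for multi-SNP instruments (fixed-effect and multiplicative
random-effects flavours), and MR-Egger regression whose intercept estimates the
average directional pleiotropy across variants.  All estimators operate on a
harmonized table of per-variant effect pairs (``BETA_X``, ``SE_X``, ``BETA_Y``,
``SE_Y``) where X is the exposure (systolic blood pressure, SD units) and Y the
outcome (Alzheimer's disease, log-odds units).

Estimates on the log-odds-per-SD scale can be re-expressed as the odds ratio per
10 mmHg *lower* exposure via :func:`to_or_per_10mmhg_lower`, which makes genetic
estimates comparable to the blood-pressure reduction achieved by a typical
antihypertensive drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959964  # two-sided 95% normal quantile

Method = Literal["wald_ratio", "ivw_fe", "ivw_mre", "egger_slope"]


@dataclass
class MREstimate:
    """A causal-effect estimate with both native and odds-ratio scales.

    ``beta`` is on the scale of log-odds of outcome per SD higher exposure;
    the ``or_*`` fields, when filled, are on the odds-ratio-per-10-mmHg-lower
    scale (so a harmful effect of *high* pressure maps to an OR below 1 for
    *lowering* it).
    """

    method: Method
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_per_10mmhg_lower: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None
    sd_exposure_mmhg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se <= 0 and not math.isnan(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")


@dataclass
class EggerResult:
    """MR-Egger regression: causal slope plus pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_pval: float


@dataclass
class SensitivityVerdict:
    """Comparison of an IVW estimate with its MR-Egger sensitivity analysis."""

    ivw_beta: float
    egger_beta: float
    intercept: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_pval: float
    ivw_point_in_egger_ci: bool
    ivw_ci_in_egger_ci: bool
    directional_pleiotropy: bool
    alpha: float

    @property
    def consistent(self) -> bool:
        return self.ivw_point_in_egger_ci and not self.directional_pleiotropy


class DegenerateInstrumentError(ValueError):
    """Raised when an instrument carries no exposure signal (all beta_X == 0)."""


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(bx: float, se_x: float, by: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate: instrument-outcome / instrument-exposure.

    The standard error is the first-order delta-method approximation
    ``se_y / |bx|``, which ignores the uncertainty in the instrument-exposure
    association (the convention of summary-data MR tools; appropriate when the
    instrument is strong).

    Parameters
    ----------
    bx, se_x : instrument-exposure association and its SE (se_x is accepted for
        interface symmetry; the first-order SE does not use it).
    by, se_y : instrument-outcome association and its SE.

    Raises
    ------
    ValueError
        If ``bx == 0`` — the ratio is undefined and the variant is not an
        instrument for the exposure.
    """
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx=0 (non-instrument)")
    if se_y <= 0:
        raise ValueError("se_y must be positive")
    beta = by / bx
    se = se_y / abs(bx)
    return MREstimate(
        method="wald_ratio",
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pval=_normal_p(beta / se),
        n_snp=1,
    )


def _as_arrays(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = np.asarray(h["BETA_X"], dtype=float)
    by = np.asarray(h["BETA_Y"], dtype=float)
    se_y = np.asarray(h["SE_Y"], dtype=float)
    if np.any(se_y <= 0):
        raise ValueError("all SE_Y must be positive")
    return bx, by, se_y


def ivw(h: pd.DataFrame, mode: Literal["fixed", "mre"] = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate over a harmonized SNP table.

    Weighted least squares of the outcome betas on the exposure betas through
    the origin with weights ``1/SE_Y**2``:

        beta = sum(w * bx * by) / sum(w * bx**2)

    ``mode="fixed"`` uses the analytic SE ``(sum(w * bx**2))**-0.5``;
    ``mode="mre"`` (multiplicative random effects, the default) scales that SE
    by the residual standard deviation, floored at 1 so that underdispersion
    never shrinks the SE below the fixed-effect value.  P-values are
    normal-based.  A single-row table delegates to :func:`wald_ratio`.
    """
    bx, by, se_y = _as_arrays(h)
    n = len(bx)
    if n == 0:
        raise ValueError("empty harmonized set")
    if n == 1:
        return wald_ratio(bx[0], float(h["SE_X"].iloc[0]), by[0], se_y[0])
    w = 1.0 / se_y**2
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0:
        raise DegenerateInstrumentError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    if mode == "fixed":
        se = se_fixed
        method: Method = "ivw_fe"
    elif mode == "mre":
        resid = by - beta * bx
        sigma2 = float(np.sum(w * resid**2)) / (n - 1)
        se = se_fixed * max(1.0, math.sqrt(sigma2))
        method = "ivw_mre"
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown IVW mode {mode!r}")
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pval=_normal_p(beta / se),
        n_snp=n,
    )


def egger(h: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Requires exposure betas already oriented non-negative (the intercept is not
    identifiable otherwise).  Weights are ``1/SE_Y**2``; the residual scale is
    floored at 1 as in :func:`ivw`; p-values use the t distribution with
    ``n - 2`` degrees of freedom.  At least three SNPs are required to leave a
    degree of freedom for the residual scale.
    """
    bx, by, se_y = _as_arrays(h)
    n = len(bx)
    if n < 3:
        raise ValueError(f"MR-Egger requires >= 3 SNPs, got {n}")
    if np.any(bx < 0):
        raise ValueError("MR-Egger requires exposure-increasing orientation (all BETA_X >= 0)")
    w = 1.0 / se_y**2
    # closed-form weighted simple linear regression
    sw = float(np.sum(w))
    mx = float(np.sum(w * bx)) / sw
    my = float(np.sum(w * by)) / sw
    sxx = float(np.sum(w * (bx - mx) ** 2))
    if sxx == 0:
        raise DegenerateInstrumentError("no variation in exposure betas")
    slope = float(np.sum(w * (bx - mx) * (by - my))) / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    scale2 = max(1.0, sigma2)
    se_slope = math.sqrt(scale2 / sxx)
    se_int = math.sqrt(scale2 * (1.0 / sw + mx**2 / sxx))
    tdist = stats.t(df=n - 2)
    t95 = float(tdist.ppf(0.975))
    slope_est = MREstimate(
        method="egger_slope",
        beta=slope,
        se=se_slope,
        ci_low=slope - t95 * se_slope,
        ci_high=slope + t95 * se_slope,
        pval=float(2.0 * tdist.sf(abs(slope / se_slope))),
        n_snp=n,
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_ci_low=intercept - t95 * se_int,
        intercept_ci_high=intercept + t95 * se_int,
        intercept_pval=float(2.0 * tdist.sf(abs(intercept / se_int))),
    )


def to_or_per_10mmhg_lower(est: MREstimate, sd_sbp_mmhg: float = 19.3) -> MREstimate:
    """Fill the odds-ratio-per-10-mmHg-lower fields of an estimate.

    ``est.beta`` must be log-odds of outcome per SD *higher* exposure.  With
    scaling factor ``c = 10 / sd_sbp_mmhg`` the transformed value is
    ``exp(-c * beta)``; the sign flip swaps the CI bounds.  The p-value is scale
    invariant and unchanged.
    """
    if sd_sbp_mmhg <= 0:
        raise ValueError("sd_sbp_mmhg must be positive")
    c = 10.0 / sd_sbp_mmhg
    return replace(
        est,
        or_per_10mmhg_lower=math.exp(-c * est.beta),
        or_ci_low=math.exp(-c * est.ci_high),
        or_ci_high=math.exp(-c * est.ci_low),
        sd_exposure_mmhg=sd_sbp_mmhg,
    )


def from_or_per_10mmhg_lower(or_value: float, sd_sbp_mmhg: float = 19.3) -> float:
    """Inverse of the OR transformation: log-odds per SD higher exposure."""
    if sd_sbp_mmhg <= 0:
        raise ValueError("sd_sbp_mmhg must be positive")
    return -math.log(or_value) * sd_sbp_mmhg / 10.0


def estimate(
    h: pd.DataFrame,
    mode: Literal["fixed", "mre"] = "mre",
    sd_sbp_mmhg: float = 19.3,
) -> MREstimate:
    """Estimate by SNP count (Wald ratio for 1 SNP, IVW otherwise) and transform."""
    return to_or_per_10mmhg_lower(ivw(h, mode=mode), sd_sbp_mmhg=sd_sbp_mmhg)


def compare_ivw_egger(
    ivw_est: MREstimate, egger_res: EggerResult, alpha: float = 0.05
) -> SensitivityVerdict:
    """Summarize agreement between IVW and MR-Egger on the same instrument.

    Reports whether the IVW point estimate (and its whole CI) lies within the
    Egger CI, and flags directional pleiotropy when the Egger intercept differs
    from zero at level ``alpha``.
    """
    e = egger_res.slope
    point_in = e.ci_low <= ivw_est.beta <= e.ci_high
    ci_in = e.ci_low <= ivw_est.ci_low and ivw_est.ci_high <= e.ci_high
    return SensitivityVerdict(
        ivw_beta=ivw_est.beta,
        egger_beta=e.beta,
        intercept=egger_res.intercept,
        intercept_ci_low=egger_res.intercept_ci_low,
        intercept_ci_high=egger_res.intercept_ci_high,
        intercept_pval=egger_res.intercept_pval,
        ivw_point_in_egger_ci=point_in,
        ivw_ci_in_egger_ci=ci_in,
        directional_pleiotropy=egger_res.intercept_pval < alpha,
        alpha=alpha,
    )


def per_target_decomposition(
    class_estimate: MREstimate,
    per_target: dict[str, pd.DataFrame],
    mode: Literal["fixed", "mre"] = "mre",
    sd_sbp_mmhg: float = 19.3,
) -> pd.DataFrame:
    """Estimate each protein target of a drug class separately.

    Returns one row per target with its own estimate (Wald ratio or IVW by SNP
    count), whether the class CI contains the target point estimate, and the
    absolute deviation of the target log-OR from the class log-OR so dominant
    contributors to a heterogeneous class estimate are visible.
    """
    rows = []
    for gene, h in per_target.items():
        est = estimate(h, mode=mode, sd_sbp_mmhg=sd_sbp_mmhg)
        rows.append(
            {
                "gene": gene,
                "method": est.method,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "or_per_10mmhg_lower": est.or_per_10mmhg_lower,
                "or_ci_low": est.or_ci_low,
                "or_ci_high": est.or_ci_high,
                "within_class_ci": bool(
                    class_estimate.ci_low <= est.beta <= class_estimate.ci_high
                ),
                "abs_log_or_deviation": abs(
                    math.log(est.or_per_10mmhg_lower)
                    - math.log(class_estimate.or_per_10mmhg_lower)
                ),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["dominant"] = out["abs_log_or_deviation"] == out["abs_log_or_deviation"].max()
    return out
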