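"""Genetic-parameter algebra and translation of monthly components to days.

With social interactions among ``n`` cage members, the heritable variance
available to selection is that of the total breeding value
TBV_i = A_D,i + (n-1) A_I,i:

    sigma^2_TBV = sigma^2_AD + 2 (n-1) sigma_ADI + (n-1)^2 sigma^2_AI

and T^2 = sigma^2_TBV / sigma^2_P generalises heritability to group-housed
animals.  Because survival time equals the sum of the monthly survival
indicators times c = 30.4 days/month, components of the random-regression
model on time translate exactly to the day scale: a slope effect a
contributes a * t_m to month m, hence c * S * a to survival time with
S = sum of t_m over the recording period, so slope variances map with the
factor (cS)^2 while iid per-month variances (cage-month, monthly
residuals) accumulate as c^2 * sum over months.  Sire-dam slope variances
are first rescaled to the animal scale (x4 under the separate sire + dam
effect convention, x2 under the combined sire-dam couple convention).

The repeated-measures model regressing on x_m = sqrt(p_m (1 - p_m)) and
the logit GLMM have no closed-form day-scale translation and are refused
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popsim import DAYS_PER_MONTH, N_MONTHS


class ScaleError(ValueError):
    pass


@dataclass
class DayScaleParams:
    """Genetic parameters of survival time in days (SDs; T^2, r_A unitless)."""

    sigma_ad: float
    sigma_ai: float
    cov_adi: float
    sigma_tbv: float
    sigma_p: float
    t_squared: float
    r_a: float

    def as_dict(self) -> dict:
        return {
            "sigma_AD": self.sigma_ad,
            "sigma_AI": self.sigma_ai,
            "sigma_ADI": self.cov_adi,
            "sigma_TBV": self.sigma_tbv,
            "sigma_P": self.sigma_p,
            "T2": self.t_squared,
            "r_A": self.r_a,
        }


@dataclass
class TranslationContext:
    """Fixed quantities of the monthly-to-days map."""

    days_per_month: float = DAYS_PER_MONTH
    months: int = N_MONTHS
    # x4: separate sire + dam effects each carrying 1/4 sigma^2_A;
    # x2: one combined effect per sire-dam couple carrying 1/2 sigma^2_A.
    sire_dam_factor: float = 4.0

    @property
    def month_sum(self) -> float:
        """S = sum of t_m for t_m = 1..T (91 for T = 13)."""
        return self.months * (self.months + 1) / 2.0

    @property
    def slope_factor(self) -> float:
        """(c S)^2: slope variance -> day-scale variance."""
        return (self.days_per_month * self.month_sum) ** 2


def tbv_variance(var_ad: float, cov_adi: float, var_ai: float, n: int) -> float:
    """Total-breeding-value variance for groups of size n.

    A negative result is possible when the direct-indirect covariance is
    strongly negative with a non-PSD C; it is returned with a warning since
    the quadratic form is only guaranteed nonnegative for valid C.
    """
    out = var_ad + 2.0 * (n - 1) * cov_adi + (n - 1) ** 2 * var_ai
    if out < 0:
        import logging

        logging.getLogger(__name__).warning(
            "negative total breeding-value variance (%.4g): check that the "
            "genetic covariance matrix is PSD",
            out,
        )
    return out


def phenotypic_variance(
    var_ad: float, var_ai: float, var_cage: float, var_e: float, n: int
) -> float:
    """sigma^2_P = sigma^2_AD + (n-1) sigma^2_AI + sigma^2_cage + sigma^2_e."""
    for v in (var_ad, var_ai, var_cage, var_e):
        if v < 0:
            raise ScaleError("negative variance input")
    return var_ad + (n - 1) * var_ai + var_cage + var_e


def t_squared(var_tbv: float, var_p: float) -> float:
    """T^2 = sigma^2_TBV / sigma^2_P, heritable share of phenotypic variance."""
    if var_p <= 0:
        raise ScaleError("phenotypic variance must be positive")
    return var_tbv / var_p


def genetic_correlation(cov_adi: float, sigma_ad: float, sigma_ai: float) -> float:
    """r_A = sigma_ADI / (sigma_AD sigma_AI)."""
    if sigma_ad <= 0 or sigma_ai <= 0:
        raise ScaleError("genetic standard deviations must be positive")
    return cov_adi / (sigma_ad * sigma_ai)


def day_scale_params(
    var_ad: float,
    var_ai: float,
    cov_adi: float,
    var_cage: float,
    var_e: float,
    n: int = 4,
) -> DayScaleParams:
    """Assemble the full day-scale parameter set from day-scale components."""
    v_tbv = tbv_variance(var_ad, cov_adi, var_ai, n)
    v_p = phenotypic_variance(var_ad, var_ai, var_cage, var_e, n)
    sd_ad, sd_ai = np.sqrt(var_ad), np.sqrt(var_ai)
    if v_p == 0.0:
        return DayScaleParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return DayScaleParams(
        sigma_ad=sd_ad,
        sigma_ai=sd_ai,
        cov_adi=cov_adi,
        sigma_tbv=np.sqrt(max(v_tbv, 0.0)),
        sigma_p=np.sqrt(v_p),
        t_squared=t_squared(v_tbv, v_p),
        r_a=genetic_correlation(cov_adi, sd_ad, sd_ai) if var_ad > 0 and var_ai > 0 else 0.0,
    )


def translate_rmm_to_days(
    components, ctx: TranslationContext, n: int = 4, parameterization: str = "sire-dam"
) -> DayScaleParams:
    """Translate RMM.t monthly components to day-scale genetic parameters.

    ``components`` is a :class:`~cagesurv.mme.VarianceComponents` from an
    RMM.t fit: genetic slope (co)variances (sire-dam scale unless
    ``parameterization="animal"``), ``term_vars`` with ``cage_month``,
    ``cage_slope`` and ``pe``, and per-month residual variances.  Slope
    variances map with (cS)^2; iid per-month variances with c^2 * sum_m.
    The permanent-environment slope and monthly residuals both land in the
    day-scale residual; the two cage terms land in the day-scale cage
    variance.
    """
    spec = getattr(components, "scale", "") or ""
    if "RMM.p" in spec or "logit" in spec:
        raise ScaleError(
            "day-scale translation is only defined for the regression on time"
        )
    f_slope = ctx.slope_factor
    c2 = ctx.days_per_month**2
    resid = np.asarray(components.residual, dtype=float).ravel()
    if resid.size not in (1, ctx.months):
        raise ScaleError(
            f"expected {ctx.months} monthly residual variances, got {resid.size}"
        )
    if resid.size == 1:
        resid = np.full(ctx.months, resid[0])
    g = 1.0 if parameterization == "animal" else ctx.sire_dam_factor
    var_ad = g * components.var_dge * f_slope
    var_ai = g * components.var_ige * f_slope
    cov = g * components.cov_dige * f_slope
    var_cage = (
        components.term_vars.get("cage_slope", 0.0) * f_slope
        + c2 * ctx.months * components.term_vars.get("cage_month", 0.0)
    )
    var_e = components.term_vars.get("pe", 0.0) * f_slope + c2 * float(resid.sum())
    return day_scale_params(var_ad, var_ai, cov, var_cage, var_e, n=n)


def translate_ebv_to_days(
    ebv, ctx: TranslationContext, model_id: str = "RMM.t"
):
    """Map RMM.t slope EBV to the day scale: EBV_days = c S EBV_slope.

    ``ebv`` is the frame produced by :func:`cagesurv.mme.extract_ebv` (for
    the sire-dam parameterization its entries are already the parental-sum
    predictions of the offspring slope).  The map is a positive scalar, so
    rankings are preserved exactly.
    """
    if model_id != "RMM.t":
        raise ScaleError(
            f"day-scale EBV translation is not defined for {model_id}"
        )
    f = ctx.days_per_month * ctx.month_sum
    out = ebv.copy()
    out["ebv_d"] = f * out["ebv_d"]
    out["ebv_i"] = f * out["ebv_i"]
    return out
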