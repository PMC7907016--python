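"""Causal estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure associations (beta_x, se_x)
and outcome associations (beta_y, se_y), each estimator combines the
per-SNP Wald ratios r_j = beta_y_j / beta_x_j into a single causal effect
on the outcome's log-odds scale:

* inverse-variance weighted (IVW) meta-analysis, fixed- or multiplicative
  random-effects, equivalent to zero-intercept weighted regression of
  beta_y on beta_x with weights 1/se_y^2;
* a penalized robust IVW variant (Tukey-biweight robust regression with
  heterogeneity-penalized weights), resistant to outlying instruments;
* full maximum likelihood under the bivariate normal measurement model,
  which unlike IVW accounts for uncertainty in the exposure associations;
* simple and weighted median estimators, consistent when at least half of
  the (weight of the) instruments are valid;
* simple and weighted mode-based estimators, consistent when the largest
  homogeneous cluster of ratios is valid (ZEMPA assumption);
* MR-Egger regression, whose intercept estimates average directional
  pleiotropy and whose slope remains a consistent causal estimate under
  the InSiDE assumption.

Cochran's Q / I^2 heterogeneity statistics are also provided; they drive
the multiplicative random-effects scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core_io import HarmonizedInstrument, MrEstimate

__all__ = [
    "EggerResult",
    "HeterogeneityResult",
    "InsufficientInstrumentsError",
    "ConvergenceError",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "penalized_robust_ivw",
    "maximum_likelihood",
    "median_estimator",
    "mode_estimator",
    "egger",
]

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across the per-SNP Wald ratios.

    ``i2`` = max(0, (Q - df)/Q) is the fraction of ratio variation in
    excess of sampling noise.
    """

    q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal effect) and intercept (average pleiotropy)."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_pval: float


# ---------------------------------------------------------------------------
# Per-SNP ratio
# ---------------------------------------------------------------------------


def wald_ratio(
    inst: HarmonizedInstrument, se_order: Literal["first", "second"] = "first"
) -> tuple[float, float]:
    """Per-SNP causal estimate beta_y/beta_x with a delta-method SE.

    First order (default): se = se_y / |beta_x| — this makes the IVW
    weights reduce to beta_x^2 / se_y^2.  Second order additionally
    propagates the exposure uncertainty:
    se = |ratio| * sqrt(se_y^2/beta_y^2 + se_x^2/beta_x^2).
    """
    if inst.beta_exp == 0:
        raise ZeroDivisionError(f"{inst.snp_id}: Wald ratio undefined for beta_exp = 0")
    ratio = inst.beta_out / inst.beta_exp
    if se_order == "first":
        se = inst.se_out / abs(inst.beta_exp)
    elif se_order == "second":
        se = math.sqrt(
            inst.se_out**2 / inst.beta_exp**2
            + inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
        )
    else:
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return ratio, se


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    if np.any(bx == 0):
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    return bx, sx, by, sy


def _require(instruments, k: int, method: str) -> None:
    if len(instruments) < k:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {k} instruments, got {len(instruments)}"
        )


def _estimate(method: str, beta: float, se: float, n_snps: int) -> MrEstimate:
    z = beta / se if se > 0 else math.inf
    pval = min(1.0, 2.0 * stats.norm.sf(abs(z))) if se > 0 else (1.0 if beta == 0 else 5e-324)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(max(pval, 5e-324)),
        n_snps=n_snps,
    )


# ---------------------------------------------------------------------------
# IVW and heterogeneity
# ---------------------------------------------------------------------------


def _ivw_core(bx, by, sy):
    w = bx**2 / sy**2
    r = by / bx
    theta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - theta) ** 2))
    return theta, se_fixed, q


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    effects_model: Literal["fixed", "random"] = "fixed",
) -> MrEstimate:
    """Inverse-variance weighted meta-analysis of the Wald ratios.

    With weights w_j = beta_x_j^2 / se_y_j^2, the estimate is
    sum(w r)/sum(w) — identical to the slope of the zero-intercept
    weighted least-squares regression of beta_y on beta_x with weights
    1/se_y^2.  ``effects_model="random"`` inflates the fixed-effects SE by
    the multiplicative over-dispersion factor max(1, sqrt(Q/(J-1))), so
    the two models coincide whenever Q <= J - 1.
    """
    _require(instruments, 2, "ivw")
    bx, _, by, sy = _arrays(instruments)
    theta, se, q = _ivw_core(bx, by, sy)
    if effects_model == "random":
        se *= max(1.0, math.sqrt(q / (len(instruments) - 1)))
    elif effects_model != "fixed":
        raise ValueError(f"effects_model must be 'fixed' or 'random', got {effects_model!r}")
    label = f"IVW ({effects_model}-effects)"
    return _estimate(label, theta, se, len(instruments))


def cochran_q(instruments: Sequence[HarmonizedInstrument]) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about the fixed-effects IVW estimate."""
    _require(instruments, 2, "cochran_q")
    bx, _, by, sy = _arrays(instruments)
    _, _, q = _ivw_core(bx, by, sy)
    df = len(instruments) - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        i2=float(max(0.0, (q - df) / q)) if q > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Penalized robust IVW
# ---------------------------------------------------------------------------


def penalized_robust_ivw(
    instruments: Sequence[HarmonizedInstrument],
    penalty_constant: float = 20.0,
    max_iter: int = 200,
) -> MrEstimate:
    """Robust IVW with heterogeneity-penalized weights.

    Each SNP's inverse-variance weight is multiplied by
    min(1, penalty_constant * p_j), where p_j is the upper-tail chi^2_1
    p-value of its contribution to Cochran's Q — so only SNPs that are
    individually inconsistent with the IVW fit (p_j < 1/penalty_constant)
    are down-weighted.  The zero-intercept regression is then fit by
    iteratively reweighted least squares with the Tukey biweight loss
    (c = 4.685, 95% efficiency at the normal).  The reported SE carries a
    multiplicative over-dispersion factor floored at 1.
    """
    _require(instruments, 3, "penalized_robust_ivw")
    bx, _, by, sy = _arrays(instruments)
    theta, _, _ = _ivw_core(bx, by, sy)
    w = bx**2 / sy**2
    r = by / bx
    q_j = w * (r - theta) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    penalty = np.minimum(1.0, penalty_constant * p_j)

    scale = np.sqrt(penalty) / sy  # combined weight sqrt(penalty / se_y^2)
    y = by * scale
    x = (bx * scale)[:, None]
    model = sm.RLM(y, x, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit(maxiter=max_iter)
    n_iter = len(fit.fit_history.get("params", [])) or len(
        fit.fit_history.get("deviance", [])
    )
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"penalized robust IVW did not converge in {max_iter} iterations",
            last_iterate=float(fit.params[0]),
        )
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    sigma = float(fit.scale) ** 0.5 if fit.scale > 0 else 1.0
    if sigma < 1.0:  # floor the over-dispersion at 1
        se = se / sigma
    return _estimate("Penalized robust IVW", beta, se, len(instruments))


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


def maximum_likelihood(
    instruments: Sequence[HarmonizedInstrument], max_iter: int = 200
) -> MrEstimate:
    """Joint-likelihood estimate under the bivariate normal model.

    Model: beta_x_j ~ N(xi_j, se_x_j^2), beta_y_j ~ N(theta xi_j,
    se_y_j^2) with independent errors, maximized over (xi_1..xi_J, theta).
    For fixed theta the nuisance xi_j have the closed form
    xi_j = (beta_x_j/se_x_j^2 + theta beta_y_j/se_y_j^2) /
    (1/se_x_j^2 + theta^2/se_y_j^2), so theta is found by 1-D minimization
    of the profile negative log-likelihood.  The SE is the (theta, theta)
    element of the inverse observed information of the full parameter
    vector at the maximum.
    """
    from scipy.optimize import minimize_scalar

    _require(instruments, 2, "maximum_likelihood")
    bx, sx, by, sy = _arrays(instruments)
    theta0, se0, _ = _ivw_core(bx, by, sy)

    def profile_xi(theta):
        return (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)

    def nll(theta):
        xi = profile_xi(theta)
        return 0.5 * np.sum((bx - xi) ** 2 / sx**2) + 0.5 * np.sum(
            (by - theta * xi) ** 2 / sy**2
        )

    span = 10 * se0 + 1.0
    res = minimize_scalar(
        nll, bracket=(theta0 - span, theta0, theta0 + span), options={"maxiter": max_iter}
    )
    if not res.success:
        raise ConvergenceError("maximum likelihood optimizer did not converge", res.x)
    theta = float(res.x)

    # Observed information of (theta, xi); SE_theta from the inverse.
    xi = profile_xi(theta)
    h_tt = float(np.sum(xi**2 / sy**2))
    h_txi = (2 * theta * xi - by) / sy**2
    h_xixi = 1 / sx**2 + theta**2 / sy**2
    # Block inversion: var(theta) = 1 / (h_tt - sum(h_txi^2 / h_xixi))
    denom = h_tt - float(np.sum(h_txi**2 / h_xixi))
    if denom <= 0:
        raise ConvergenceError("observed information for theta is not positive", theta)
    se = denom**-0.5
    return _estimate("Maximum likelihood", theta, se, len(instruments))


# ---------------------------------------------------------------------------
# Median estimators
# ---------------------------------------------------------------------------


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights[order].sum()
    s = np.cumsum(w) - w / 2  # cumulative midpoints
    return float(np.interp(0.5, s, r))


def median_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighting: Literal["simple", "weighted"] = "simple",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Simple or weighted median of the Wald ratios.

    Ratios are sorted and assigned cumulative weight midpoints
    s_j = sum_{k<=j} u_k - u_j/2 (u equal for "simple",
    proportional to beta_x^2/se_y^2 for "weighted"); the estimate linearly
    interpolates the ratios against s at s = 0.5.  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric-bootstrap
    replicates, each resampling beta_x_j and beta_y_j from normals centred
    at the observed values.
    """
    _require(instruments, 3, "median_estimator")
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"weighting must be 'simple' or 'weighted', got {weighting!r}")
    bx, sx, by, sy = _arrays(instruments)

    def point(bx_, by_):
        r = by_ / bx_
        w = np.ones_like(r) if weighting == "simple" else bx_**2 / sy**2
        return _weighted_median(r, w)

    beta = point(bx, by)
    rng = np.random.default_rng(seed)
    J = len(instruments)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    bx_star[bx_star == 0] = np.finfo(float).tiny
    boots = np.array([point(bx_star[b], by_star[b]) for b in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    label = "Simple median" if weighting == "simple" else "Weighted median"
    return _estimate(label, beta, se, J)


# ---------------------------------------------------------------------------
# Mode-based estimators
# ---------------------------------------------------------------------------

_MODE_GRID_POINTS = 10_000


def _mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    w = weights / weights.sum()
    sd = float(np.std(ratios, ddof=1))
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) * 1.4826
    h = bandwidth_factor * 0.9 * min(sd, mad) * len(ratios) ** (-0.2)
    if h <= 0:
        # MAD (or SD) collapsed: the majority value is the mode.
        return float(np.median(ratios))
    centre, spread = float(np.mean(ratios)), sd
    grid = np.linspace(centre - 5 * spread, centre + 5 * spread, _MODE_GRID_POINTS)
    z = (grid[:, None] - ratios[None, :]) / h
    density = np.exp(-0.5 * z**2) @ w
    return float(grid[int(np.argmax(density))])


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighting: Literal["simple", "weighted"] = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    se_order: Literal["first", "second"] = "second",
) -> MrEstimate:
    """Mode of a Gaussian kernel density over the Wald ratios.

    The kernel bandwidth follows the modified Silverman rule
    h = bandwidth_factor * 0.9 * min(SD, 1.4826 MAD) * J^(-1/5); the
    density is evaluated on a 10,000-point grid spanning the ratio mean
    +/- 5 SD.  Kernel weights are equal ("simple") or proportional to the
    inverse squared delta-method SE of each ratio ("weighted";
    second-order SEs by default, following the original mode-based
    estimator).  Bootstrap SE as in :func:`median_estimator`.

    If all ratios coincide the bandwidth degenerates to zero and the
    common ratio is returned with SE 0 (``pval`` reported as 1 when the
    ratio is 0); such estimates are flagged by ``se == 0``.
    """
    _require(instruments, 3, "mode_estimator")
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"weighting must be 'simple' or 'weighted', got {weighting!r}")
    bx, sx, by, sy = _arrays(instruments)

    def ratio_se(bx_, by_):
        if se_order == "first":
            return sy / np.abs(bx_)
        return np.sqrt(sy**2 / bx_**2 + by_**2 * sx**2 / bx_**4)

    def point(bx_, by_):
        r = by_ / bx_
        w = np.ones_like(r) if weighting == "simple" else ratio_se(bx_, by_) ** -2
        return _mode_point(r, w, bandwidth_factor)

    beta = point(bx, by)
    J = len(instruments)
    ratios = by / bx
    if np.allclose(ratios, ratios[0], rtol=0, atol=0):
        label = "Simple mode" if weighting == "simple" else "Weighted mode"
        return MrEstimate(
            method=label + " (degenerate)",
            beta=float(ratios[0]),
            se=0.0,
            ci_low=float(ratios[0]),
            ci_high=float(ratios[0]),
            pval=1.0 if ratios[0] == 0 else 5e-324,
            n_snps=J,
        )
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    bx_star[bx_star == 0] = np.finfo(float).tiny
    boots = np.array([point(bx_star[b], by_star[b]) for b in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    label = "Simple mode" if weighting == "simple" else "Weighted mode"
    return _estimate(label, beta, se, J)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: weighted regression of beta_y on beta_x with
    an unconstrained intercept.

    Instruments are first oriented so every beta_x is non-negative (both
    betas of a SNP are negated together — the model is invariant to this
    reparametrization, but the intercept is only interpretable in a fixed
    orientation).  Weights are 1/se_y^2; both coefficient SEs carry a
    multiplicative over-dispersion factor floored at 1.  The slope is the
    causal estimate under InSiDE; the intercept estimates the average
    directional pleiotropic effect per SNP.
    """
    _require(instruments, 3, "egger")
    bx, _, by, sy = _arrays(instruments)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1 / sy**2
    design = np.column_stack([np.ones_like(bx), bx])
    xtw = design.T * w
    cov_unscaled = np.linalg.inv(xtw @ design)
    coef = cov_unscaled @ (xtw @ by)
    resid = by - design @ coef
    df = len(instruments) - 2
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else 0.0
    cov = cov_unscaled * max(1.0, sigma2)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    slope_est = _estimate("MR-Egger", slope, se_slope, len(instruments))
    z = intercept / se_int if se_int > 0 else math.inf
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_ci_low=intercept - Z95 * se_int,
        intercept_ci_high=intercept + Z95 * se_int,
        intercept_pval=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
    )
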