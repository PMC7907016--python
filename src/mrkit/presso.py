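"""MR-PRESSO: residual-sum-of-squares global pleiotropy test, per-SNP
outlier test, outlier-corrected estimate, and distortion test.

The global test asks whether the instruments' outcome associations are
jointly consistent with a single causal slope, by comparing the observed
weighted residual sum of squares (each SNP's residual taken about the
leave-one-out IVW slope, so a pleiotropic SNP cannot mask itself) with
its parametric-bootstrap null distribution.  SNPs whose own squared
residual is extreme relative to the simulations are flagged as outliers
(Bonferroni-adjusted); the corrected estimate re-runs IVW without them,
and the distortion test asks whether removing the outliers materially
moved the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import HarmonizedInstrument, MrEstimate
from .estimators import InsufficientInstrumentsError, Z95, _arrays

__all__ = ["PressoResult", "presso_test"]


@dataclass(frozen=True)
class PressoResult:
    """Full output of one MR-PRESSO run.

    ``raw`` is the slope on all instruments; ``corrected`` the slope on
    the non-outliers (identical to ``raw`` when no SNP is flagged).
    ``distortion_pval`` is None when no outliers were detected.
    """

    rss_observed: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outliers: list[str]
    raw: MrEstimate
    corrected: MrEstimate
    distortion_pval: float | None
    n_sim: int
    seed: int | None


def _loo_slopes(bx, by, sy):
    """Leave-one-out zero-intercept WLS slopes, weights 1/se_y^2."""
    w = 1 / sy**2
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _presso_estimate(method: str, bx, by, sy) -> MrEstimate:
    """IVW slope with the original MR-PRESSO reporting conventions.

    SE is the weighted-least-squares SE (fixed-effects SE scaled by the
    residual standard deviation, no floor); the CI uses normal quantiles
    and the p-value a t distribution on J - 1 degrees of freedom.
    """
    w = 1 / sy**2
    sxx = float(np.sum(w * bx * bx))
    theta = float(np.sum(w * bx * by) / sxx)
    df = len(bx) - 1
    resid = by - theta * bx
    sigma2 = float(np.sum(w * resid**2) / df)
    se = math.sqrt(sigma2 / sxx)
    if se == 0:
        pval = 1.0 if theta == 0 else 5e-324
    else:
        pval = float(min(1.0, 2.0 * stats.t.sf(abs(theta / se), df)))
    return MrEstimate(
        method=method,
        beta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=max(pval, 5e-324),
        n_snps=len(bx),
    )


def presso_test(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
) -> PressoResult:
    """Run the full MR-PRESSO procedure.

    Parameters
    ----------
    instruments
        At least 4 harmonized instruments.
    n_sim
        Parametric-bootstrap replicates for the global and per-SNP tests.
        Monte-Carlo p-values use the (1 + exceedances)/(n_sim + 1)
        convention, so they are never zero.
    significance
        Family-wise level for outlier flagging; each per-SNP p-value is
        Bonferroni-adjusted (multiplied by J) before comparison.
    seed
        Seed for the replicate generator; fixing it makes the whole
        result bit-reproducible.
    n_distortion
        Resamples for the distortion test (run only when outliers are
        found).

    Notes
    -----
    Replicates are drawn from the leave-one-out model: for each SNP j,
    beta_x*_j ~ N(beta_x_j, se_x_j) and
    beta_y*_j ~ N(theta_loo_j * beta_x_j, se_y_j), where theta_loo_j is
    the IVW slope computed without SNP j.  The RSS of each replicate is
    computed by the same leave-one-out recipe as the observed RSS.
    """
    if len(instruments) < 4:
        raise InsufficientInstrumentsError(
            f"presso_test needs at least 4 instruments, got {len(instruments)}"
        )
    bx, sx, by, sy = _arrays(instruments)
    ids = [inst.snp_id for inst in instruments]
    J = len(ids)
    w = 1 / sy**2

    theta_loo = _loo_slopes(bx, by, sy)
    d = by - theta_loo * bx
    obs_contrib = d**2 * w
    rss_obs = float(np.sum(obs_contrib))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, J))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, J))

    # Vectorized leave-one-out slopes for every replicate.
    ww = np.broadcast_to(w, (n_sim, J))
    sxy = np.sum(ww * bx_star * by_star, axis=1, keepdims=True)
    sxx = np.sum(ww * bx_star**2, axis=1, keepdims=True)
    loo_star = (sxy - ww * bx_star * by_star) / (sxx - ww * bx_star**2)
    contrib_star = (by_star - loo_star * bx_star) ** 2 * ww
    rss_star = np.sum(contrib_star, axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp = (1 + np.sum(contrib_star >= obs_contrib, axis=0)) / (n_sim + 1)
    per_snp_pvals = dict(zip(ids, per_snp.astype(float)))
    outlier_mask = per_snp * J < significance
    outliers = [snp for snp, flag in zip(ids, outlier_mask) if flag]
    if len(outliers) == J:
        raise RuntimeError("every instrument was flagged as an outlier")

    raw = _presso_estimate("MR-PRESSO (raw)", bx, by, sy)
    keep = ~outlier_mask
    corrected = _presso_estimate(
        "MR-PRESSO (outlier-corrected)", bx[keep], by[keep], sy[keep]
    )

    distortion_pval = None
    if outliers:
        n_out = len(outliers)
        d_obs = abs(raw.beta - corrected.beta)
        exceed = 0
        idx = np.arange(J)
        for _ in range(n_distortion):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(J, dtype=bool)
            mask[drop] = False
            theta_sub = float(
                np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
            )
            if abs(raw.beta - theta_sub) >= d_obs:
                exceed += 1
        distortion_pval = float((1 + exceed) / (n_distortion + 1))

    return PressoResult(
        rss_observed=rss_obs,
        global_pval=global_pval,
        per_snp_pvals=per_snp_pvals,
        outliers=outliers,
        raw=raw,
        corrected=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )
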