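"""Leave-one-out analysis, plot data, and the end-to-end analysis driver.

`run_full_analysis` assembles everything a two-sample MR report needs:
the ten-estimator comparison table, the MR-Egger intercept (directional
pleiotropy) test, Cochran's Q heterogeneity, the leave-one-out influence
scan, MR-PRESSO, and the data behind the standard forest / scatter /
funnel diagnostics.  Rendering is a thin optional layer (matplotlib);
every test and downstream consumer works from the plot *data*.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import HarmonizedInstrument, MrEstimate
from .estimators import (
    EggerResult,
    HeterogeneityResult,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    maximum_likelihood,
    median_estimator,
    mode_estimator,
    penalized_robust_ivw,
    wald_ratio,
    Z95,
)
from .presso import PressoResult, presso_test

__all__ = [
    "AnalysisConfig",
    "LeaveOneOutResult",
    "AnalysisReport",
    "leave_one_out",
    "run_full_analysis",
    "forest_data",
    "scatter_data",
    "funnel_data",
    "report_to_json",
    "report_from_json",
    "table2_rows",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the end-to-end analysis.

    ``seed`` drives every stochastic component (bootstrap SEs, MR-PRESSO
    simulations); reports are bit-reproducible given the same config.
    """

    seed: int = 42
    n_boot: int = 1000
    n_presso_sim: int = 1000
    presso_significance: float = 0.05
    penalty_constant: float = 20.0
    bandwidth_factor: float = 1.0
    run_bootstrap_methods: bool = True
    run_presso: bool = True


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-SNP IVW estimates with each instrument omitted in turn.

    ``influential`` lists SNPs whose omission flips the sign of the
    overall estimate or flips whether the CI covers zero.
    """

    estimates: dict[str, MrEstimate]
    influential: list[str]


def leave_one_out(instruments: Sequence[HarmonizedInstrument]) -> LeaveOneOutResult:
    """Fixed-effects IVW re-estimated with each SNP left out."""
    if len(instruments) < 3:
        raise InsufficientInstrumentsError(
            f"leave_one_out needs at least 3 instruments, got {len(instruments)}"
        )
    overall = ivw(instruments, "fixed")
    overall_covers = overall.ci_low <= 0 <= overall.ci_high
    estimates: dict[str, MrEstimate] = {}
    influential: list[str] = []
    for j, inst in enumerate(instruments):
        rest = list(instruments[:j]) + list(instruments[j + 1 :])
        est = ivw(rest, "fixed")
        estimates[inst.snp_id] = est
        sign_flip = (est.beta > 0) != (overall.beta > 0) and est.beta != 0
        covers = est.ci_low <= 0 <= est.ci_high
        if sign_flip or covers != overall_covers:
            influential.append(inst.snp_id)
    return LeaveOneOutResult(estimates=estimates, influential=influential)


# ---------------------------------------------------------------------------
# Plot data
# ---------------------------------------------------------------------------


def forest_data(instruments: Sequence[HarmonizedInstrument]) -> dict:
    """Per-SNP Wald ratios with 95% CIs plus the overall IVW row."""
    rows = []
    for inst in instruments:
        r, se = wald_ratio(inst)
        rows.append(
            {"snp": inst.snp_id, "ratio": r, "ci_low": r - Z95 * se, "ci_high": r + Z95 * se}
        )
    overall = ivw(instruments, "fixed")
    return {
        "snps": rows,
        "overall": {"ratio": overall.beta, "ci_low": overall.ci_low, "ci_high": overall.ci_high},
    }


def scatter_data(
    instruments: Sequence[HarmonizedInstrument], estimates: Sequence[MrEstimate] = (),
    egger_intercept: float | None = None,
) -> dict:
    """Exposure vs outcome betas with SE bars and fitted lines per method."""
    points = [
        {
            "snp": i.snp_id,
            "beta_exp": i.beta_exp,
            "se_exp": i.se_exp,
            "beta_out": i.beta_out,
            "se_out": i.se_out,
        }
        for i in instruments
    ]
    lines = []
    for est in estimates:
        intercept = egger_intercept if est.method.startswith("MR-Egger") else 0.0
        if intercept is None:
            intercept = 0.0
        lines.append({"method": est.method, "slope": est.beta, "intercept": intercept})
    return {"points": points, "lines": lines}


def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> dict:
    """Wald ratio vs instrument precision (1/SE) with the IVW reference line."""
    rows = []
    for inst in instruments:
        r, se = wald_ratio(inst)
        rows.append({"snp": inst.snp_id, "ratio": r, "precision": 1.0 / se})
    return {"snps": rows, "overall": ivw(instruments, "fixed").beta}


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Everything the ten-method comparison produces, JSON-serializable."""

    estimates: list[MrEstimate]
    failures: dict[str, str]
    egger_intercept: dict
    heterogeneity: HeterogeneityResult | None
    leave_one_out: LeaveOneOutResult
    presso: PressoResult | None
    plot_data: dict
    config: AnalysisConfig
    n_snps: int


def run_full_analysis(
    instruments: Sequence[HarmonizedInstrument],
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Run the complete estimator suite and diagnostics on one instrument set.

    Estimators are reported in a fixed order (fixed IVW, random IVW,
    penalized robust IVW, maximum likelihood, simple/weighted median,
    simple/weighted mode, MR-Egger, MR-PRESSO).  A method that raises is
    recorded in ``failures`` instead of aborting the report.  The whole
    report is deterministic given ``config.seed``.
    """
    estimates: list[MrEstimate] = []
    failures: dict[str, str] = {}

    def run(label, fn):
        try:
            estimates.append(fn())
        except Exception as exc:  # noqa: BLE001 - reported per-method
            failures[label] = f"{type(exc).__name__}: {exc}"

    run("IVW (fixed-effects)", lambda: ivw(instruments, "fixed"))
    run("IVW (random-effects)", lambda: ivw(instruments, "random"))
    run(
        "Penalized robust IVW",
        lambda: penalized_robust_ivw(instruments, config.penalty_constant),
    )
    run("Maximum likelihood", lambda: maximum_likelihood(instruments))
    if config.run_bootstrap_methods:
        run(
            "Simple median",
            lambda: median_estimator(instruments, "simple", config.n_boot, config.seed),
        )
        run(
            "Weighted median",
            lambda: median_estimator(instruments, "weighted", config.n_boot, config.seed),
        )
        run(
            "Simple mode",
            lambda: mode_estimator(
                instruments, "simple", config.bandwidth_factor, config.n_boot, config.seed
            ),
        )
        run(
            "Weighted mode",
            lambda: mode_estimator(
                instruments, "weighted", config.bandwidth_factor, config.n_boot, config.seed
            ),
        )
    else:
        for label in ("Simple median", "Weighted median", "Simple mode", "Weighted mode"):
            failures[label] = "skipped: bootstrap methods disabled"

    egger_block: dict = {}
    try:
        egger_result = egger(instruments)
        estimates.append(egger_result.slope)
        egger_block = {
            "intercept": egger_result.intercept,
            "se": egger_result.intercept_se,
            "ci_low": egger_result.intercept_ci_low,
            "ci_high": egger_result.intercept_ci_high,
            "pval": egger_result.intercept_pval,
        }
    except Exception as exc:  # noqa: BLE001
        failures["MR-Egger"] = f"{type(exc).__name__}: {exc}"

    presso_result = None
    if config.run_presso:
        try:
            presso_result = presso_test(
                instruments,
                n_sim=config.n_presso_sim,
                significance=config.presso_significance,
                seed=config.seed,
            )
            estimates.append(presso_result.raw)
        except Exception as exc:  # noqa: BLE001
            failures["MR-PRESSO"] = f"{type(exc).__name__}: {exc}"
    else:
        failures["MR-PRESSO"] = "skipped: disabled in config"

    try:
        heterogeneity = cochran_q(instruments)
    except Exception as exc:  # noqa: BLE001
        failures["Cochran Q"] = f"{type(exc).__name__}: {exc}"
        heterogeneity = None
    try:
        loo = leave_one_out(instruments)
    except Exception as exc:  # noqa: BLE001
        failures["Leave-one-out"] = f"{type(exc).__name__}: {exc}"
        loo = LeaveOneOutResult(estimates={}, influential=[])
    plot_data = {
        "forest": forest_data(instruments),
        "scatter": scatter_data(
            instruments, estimates, egger_block.get("intercept")
        ),
        "funnel": funnel_data(instruments),
        "leave_one_out": {
            snp: {"beta": e.beta, "ci_low": e.ci_low, "ci_high": e.ci_high}
            for snp, e in loo.estimates.items()
        },
    }
    return AnalysisReport(
        estimates=estimates,
        failures=failures,
        egger_intercept=egger_block,
        heterogeneity=heterogeneity,
        leave_one_out=loo,
        presso=presso_result,
        plot_data=plot_data,
        config=config,
        n_snps=len(instruments),
    )


# ---------------------------------------------------------------------------
# Serialization and display
# ---------------------------------------------------------------------------


def _estimate_to_dict(est: MrEstimate) -> dict:
    return est.to_dict()


def _estimate_from_dict(d: dict) -> MrEstimate:
    return MrEstimate(
        method=d["method"],
        beta=d["beta"],
        se=d["se"],
        ci_low=d["ci_low"],
        ci_high=d["ci_high"],
        pval=d["pval"],
        n_snps=d["n_snps"],
    )


def report_to_json(report: AnalysisReport) -> str:
    """Serialize a report losslessly (floats survive a round-trip exactly)."""
    presso = None
    if report.presso is not None:
        presso = {
            "rss_observed": report.presso.rss_observed,
            "global_pval": report.presso.global_pval,
            "per_snp_pvals": report.presso.per_snp_pvals,
            "outliers": report.presso.outliers,
            "raw": _estimate_to_dict(report.presso.raw),
            "corrected": _estimate_to_dict(report.presso.corrected),
            "distortion_pval": report.presso.distortion_pval,
            "n_sim": report.presso.n_sim,
            "seed": report.presso.seed,
        }
    payload = {
        "n_snps": report.n_snps,
        "config": dataclasses.asdict(report.config),
        "estimates": [_estimate_to_dict(e) for e in report.estimates],
        "failures": report.failures,
        "egger_intercept": report.egger_intercept,
        "heterogeneity": (
            None
            if report.heterogeneity is None
            else dataclasses.asdict(report.heterogeneity)
        ),
        "leave_one_out": {
            "estimates": {
                snp: _estimate_to_dict(e) for snp, e in report.leave_one_out.estimates.items()
            },
            "influential": report.leave_one_out.influential,
        },
        "presso": presso,
        "plot_data": report.plot_data,
    }
    return json.dumps(payload, indent=2)


def report_from_json(text: str) -> AnalysisReport:
    """Inverse of :func:`report_to_json`."""
    d = json.loads(text)
    presso = None
    if d["presso"] is not None:
        p = d["presso"]
        presso = PressoResult(
            rss_observed=p["rss_observed"],
            global_pval=p["global_pval"],
            per_snp_pvals=p["per_snp_pvals"],
            outliers=p["outliers"],
            raw=_estimate_from_dict(p["raw"]),
            corrected=_estimate_from_dict(p["corrected"]),
            distortion_pval=p["distortion_pval"],
            n_sim=p["n_sim"],
            seed=p["seed"],
        )
    return AnalysisReport(
        estimates=[_estimate_from_dict(e) for e in d["estimates"]],
        failures=d["failures"],
        egger_intercept=d["egger_intercept"],
        heterogeneity=(
            None if d["heterogeneity"] is None else HeterogeneityResult(**d["heterogeneity"])
        ),
        leave_one_out=LeaveOneOutResult(
            estimates={
                snp: _estimate_from_dict(e)
                for snp, e in d["leave_one_out"]["estimates"].items()
            },
            influential=d["leave_one_out"]["influential"],
        ),
        presso=presso,
        plot_data=d["plot_data"],
        config=AnalysisConfig(**d["config"]),
        n_snps=d["n_snps"],
    )


def table2_rows(report: AnalysisReport) -> list[dict]:
    """Display rows: method, OR (95% CI) and p, rounded to two decimals."""
    rows = []
    for est in report.estimates:
        rows.append(
            {
                "method": est.method,
                "or": f"{est.or_:.2f}",
                "ci": f"{est.or_ci_low:.2f}-{est.or_ci_high:.2f}",
                "p": f"{est.pval:.2f}",
            }
        )
    return rows


def render_plots(report: AnalysisReport, prefix: str) -> list[str]:
    """Minimal matplotlib rendering of the four diagnostics (optional).

    Requires matplotlib; returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pd_ = report.plot_data

    fig, ax = plt.subplots()
    snps = pd_["forest"]["snps"]
    ys = range(len(snps))
    ax.errorbar(
        [s["ratio"] for s in snps],
        list(ys),
        xerr=[
            [s["ratio"] - s["ci_low"] for s in snps],
            [s["ci_high"] - s["ratio"] for s in snps],
        ],
        fmt="o",
    )
    ax.axvline(pd_["forest"]["overall"]["ratio"], linestyle="--")
    ax.set_yticks(list(ys), [s["snp"] for s in snps])
    ax.set_xlabel("per-SNP causal estimate (log OR)")
    path = f"{prefix}_forest.png"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots()
    pts = pd_["scatter"]["points"]
    ax.errorbar(
        [p["beta_exp"] for p in pts],
        [p["beta_out"] for p in pts],
        xerr=[p["se_exp"] for p in pts],
        yerr=[p["se_out"] for p in pts],
        fmt="ko",
    )
    xs = np.array([0, max(p["beta_exp"] for p in pts) * 1.1])
    for line in pd_["scatter"]["lines"]:
        ax.plot(xs, line["intercept"] + line["slope"] * xs, label=line["method"])
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    ax.legend(fontsize=6)
    path = f"{prefix}_scatter.png"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots()
    fd = pd_["funnel"]
    ax.plot([s["ratio"] for s in fd["snps"]], [s["precision"] for s in fd["snps"]], "ko")
    ax.axvline(fd["overall"], linestyle="--")
    ax.set_xlabel("per-SNP causal estimate (log OR)")
    ax.set_ylabel("precision (1/SE)")
    path = f"{prefix}_funnel.png"
    fig.savefig(path)
    plt.close(fig)
    written.append(path)

    return written
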