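"""Generator of two-sample GWAS summary statistics with known ground truth.

The generative model is the standard linear instrumental-variable setup
for summary data.  For each instrument j:

* allele frequency  p_j ~ Uniform(maf_range);
* true exposure effect  gamma_j from a configurable distribution
  (normal(mean, sd) or a fixed list), exposure in SD units;
* direct (pleiotropic) outcome effect alpha_j — zero under
  ``pleiotropy_mode="none"``, normal(0, alpha_sd) under ``"balanced"``,
  normal(alpha_mean, alpha_sd) under ``"directional"``.  alpha is drawn
  independently of gamma, so the InSiDE condition holds by construction;
* true outcome effect  Gamma_j = theta * gamma_j + alpha_j on the
  log-odds scale;
* sampling noise matching the asymptotic SEs of GWAS regression
  coefficients: se_x_j = (2 n_exp p_j (1-p_j))^(-1/2) for a standardized
  quantitative exposure and
  se_y_j = (2 n_out p_j (1-p_j) cf (1-cf))^(-1/2) for a binary outcome
  with case fraction cf (normal approximation to the logistic score);
* observed betas drawn from normals centred on the truth.

The returned instruments carry no ground truth; the true
(gamma_j, alpha_j, theta) travel in a separate sidecar so estimator code
can never read them accidentally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import FIXTURE_N_EXPOSURE, HarmonizedInstrument, load_paper_fixture

__all__ = [
    "SimulationScenario",
    "ScenarioValidationError",
    "simulate_summary_stats",
    "scenario_from_fixture",
    "FIXTURE_N_OUTCOME",
    "FIXTURE_CASES",
]

#: Outcome-study shape of the bundled fixture: 3,968 CAD cases and
#: 11,696 controls among individuals with diabetes.
FIXTURE_CASES = 3968
FIXTURE_N_OUTCOME = 3968 + 11696  # = 15664


class ScenarioValidationError(ValueError):
    """A scenario violates its invariants."""


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic two-sample dataset."""

    n_snps: int = 50
    theta: float = 0.0
    gamma_mean: float = 0.06
    gamma_sd: float = 0.03
    gamma_fixed: tuple[float, ...] | None = None
    pleiotropy_mode: str = "none"  # none | balanced | directional
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 44147
    n_outcome: int = 15664
    case_fraction: float = FIXTURE_CASES / FIXTURE_N_OUTCOME
    seed: int | None = None

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ScenarioValidationError("n_snps must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ScenarioValidationError(
                f"unknown pleiotropy_mode {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_mode == "none" and (self.alpha_mean != 0 or self.alpha_sd != 0):
            raise ScenarioValidationError("pleiotropy_mode='none' requires alpha_mean = alpha_sd = 0")
        if self.pleiotropy_mode == "balanced" and self.alpha_mean != 0:
            raise ScenarioValidationError("balanced pleiotropy requires alpha_mean = 0")
        if self.alpha_sd < 0 or self.gamma_sd < 0:
            raise ScenarioValidationError("standard deviations must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ScenarioValidationError("maf_range must lie within (0, 0.5]")
        if not (0 < self.case_fraction < 1):
            raise ScenarioValidationError("case_fraction must be in (0, 1)")
        if self.gamma_fixed is not None and len(self.gamma_fixed) != self.n_snps:
            raise ScenarioValidationError("gamma_fixed length must equal n_snps")


def simulate_summary_stats(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[list[HarmonizedInstrument], pd.DataFrame]:
    """Draw one synthetic dataset.

    Returns ``(instruments, truth)`` where ``truth`` is a sidecar frame
    with columns snp, gamma, alpha, theta, maf.  ``seed`` overrides
    ``scenario.seed`` when given; a fixed seed reproduces the dataset
    bit-for-bit.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    J = scenario.n_snps

    maf = rng.uniform(*scenario.maf_range, size=J)
    if scenario.gamma_fixed is not None:
        gamma = np.asarray(scenario.gamma_fixed, dtype=float)
    else:
        gamma = rng.normal(scenario.gamma_mean, scenario.gamma_sd, size=J)
    if scenario.pleiotropy_mode == "none":
        alpha = np.zeros(J)
    else:
        alpha = rng.normal(scenario.alpha_mean, scenario.alpha_sd, size=J)
    big_gamma = scenario.theta * gamma + alpha

    het = 2 * maf * (1 - maf)
    se_x = (scenario.n_exposure * het) ** -0.5
    cf = scenario.case_fraction
    se_y = (scenario.n_outcome * het * cf * (1 - cf)) ** -0.5
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)

    instruments = [
        HarmonizedInstrument(
            snp_id=f"sim{j}",
            effect_allele="A",
            other_allele="G",
            beta_exp=float(beta_x[j]),
            se_exp=float(se_x[j]),
            beta_out=float(beta_y[j]),
            se_out=float(se_y[j]),
            eaf_exp=float(maf[j]),
            wald_ratio=float(beta_y[j] / beta_x[j]) if beta_x[j] != 0 else None,
            wald_se=float(se_y[j] / abs(beta_x[j])) if beta_x[j] != 0 else None,
        )
        for j in range(J)
    ]
    truth = pd.DataFrame(
        {
            "snp": [f"sim{j}" for j in range(J)],
            "gamma": gamma,
            "alpha": alpha,
            "theta": scenario.theta,
            "maf": maf,
        }
    )
    return instruments, truth


def scenario_from_fixture(theta: float = 0.0, seed: int | None = None) -> SimulationScenario:
    """A scenario mimicking the bundled homocysteine -> CAD study shape.

    Nine instruments; exposure sample size 44,147; outcome 15,664
    individuals with case fraction 3968/15664; true exposure effects
    matched to the spread of the fixture's exposure betas.
    """
    fixture = load_paper_fixture()
    bx = np.array([inst.beta_exp for inst in fixture])
    return SimulationScenario(
        n_snps=len(fixture),
        theta=theta,
        gamma_mean=float(np.mean(bx)),
        gamma_sd=float(np.std(bx, ddof=1)),
        maf_range=(0.07, 0.5),
        n_exposure=FIXTURE_N_EXPOSURE,
        n_outcome=FIXTURE_N_OUTCOME,
        case_fraction=FIXTURE_CASES / FIXTURE_N_OUTCOME,
        seed=seed,
    )
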