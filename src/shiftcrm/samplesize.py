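"""CRM sample-size calculation.

The sample size of a CRM trial is characterized by four quantities: the
desired average probability of correct selection (PCS), the target DLT rate
theta, the number of test doses K, and an effect size psi defined as the
odds ratio of the DLT rates of neighbouring doses. The calculator returns
the smallest N at which the average PCS of a single-agent two-stage
likelihood CRM — the same design class used for trial conduct in this
package — reaches the goal, averaged over the K calibrated scenarios in
which dose k is the MTD (p_k = theta) and the remaining doses sit at
logit(theta) plus integer multiples of log(psi).

The average PCS curve is estimated by simulating full CRM trajectories once
with a fixed internal seed, so the calculator is a deterministic function
of its specification. A CRM trial of size n is the truncation of the same
adaptive trajectory after n patients, which makes the entire PCS-versus-n
curve available from a single set of simulations and gives common random
numbers across candidate sample sizes.

The simulated design: empiric model p = q^{exp(a)} with the skeleton
calibrated by the indifference-interval recursion (prior MTD at the middle
dose, halfwidth a quarter of the psi-induced probability gap around theta);
initial escalation from the lowest dose in cohorts of one until the data
contain both a DLT and a non-DLT; then maximum-likelihood estimation and
allocation to the dose with estimated DLT rate closest to theta, ties low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from ._mle import mle_power
from .core import SkeletonSpec, lee_cheung_skeleton
from .errors import OutOfDomainError

#: fixed internal seed: the calculator is a deterministic function of its spec
_CALC_SEED = 271828


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the CRM sample-size calculation."""

    pcs_goal: float
    target: float
    n_levels: int
    effect_size: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pcs_goal < 1.0:
            raise OutOfDomainError("pcs_goal must lie in (0, 1)")
        if not 0.0 < self.target < 1.0:
            raise OutOfDomainError("target must lie in (0, 1)")
        if self.n_levels < 2:
            raise OutOfDomainError("n_levels must be >= 2")
        if not 1.0 < self.effect_size <= 4.0:
            raise OutOfDomainError("effect_size (adjacent-dose odds ratio) must lie in (1, 4]")
        if self.pcs_goal <= 1.0 / self.n_levels:
            raise OutOfDomainError("pcs_goal must exceed the random-guessing rate 1/n_levels")


def calibrated_scenarios(spec: SampleSizeSpec) -> np.ndarray:
    """K scenarios (rows) with the MTD at dose k and logit spacing log(psi)."""
    K = spec.n_levels
    offsets = np.arange(K)[None, :] - np.arange(K)[:, None]  # j - k
    return expit(logit(spec.target) + offsets * math.log(spec.effect_size))


def _calculator_skeleton(spec: SampleSizeSpec) -> np.ndarray:
    p_hi = float(expit(logit(spec.target) + math.log(spec.effect_size)))
    p_lo = float(expit(logit(spec.target) - math.log(spec.effect_size)))
    halfwidth = (p_hi - p_lo) / 4.0
    nu = (spec.n_levels + 1) // 2
    return lee_cheung_skeleton(
        SkeletonSpec(
            target=spec.target, halfwidth=halfwidth, prior_mtd=nu, length=spec.n_levels
        )
    )


def average_pcs_curve(
    spec: SampleSizeSpec,
    n_cap: int = 80,
    n_sim: int = 400,
    seed: int = _CALC_SEED,
) -> np.ndarray:
    """Average PCS after n = 1..n_cap patients, from simulated trajectories.

    Element n-1 is the probability, averaged over the K calibrated
    scenarios, that the CRM recommendation after n patients is that
    scenario's MTD. While the data are still homogeneous (no DLT yet, or
    nothing but DLTs) the recommendation is the current escalation dose.
    """
    K = spec.n_levels
    theta = spec.target
    logq = np.log(_calculator_skeleton(spec))
    scenarios = calibrated_scenarios(spec)
    rng = np.random.default_rng(seed)
    correct = np.zeros((K, n_cap))
    for k in range(K):
        p_true = scenarios[k]
        for _ in range(n_sim):
            u = rng.random(n_cap)
            n_vec = np.zeros(K)
            x_vec = np.zeros(K)
            n_dlt = n_tot = 0
            cur = 0
            for t in range(n_cap + 1):
                if 0 < n_dlt < n_tot:
                    mask = n_vec > 0
                    a_hat, _ = mle_power(
                        logq[mask], n_vec[mask], x_vec[mask], -10.0, 10.0, 1e-8
                    )
                    phat = np.exp(math.exp(a_hat) * logq)
                    rec = int(np.argmin(np.round(np.abs(phat - theta), 10)))
                else:
                    # initial stage: escalate one level per non-DLT patient
                    if n_tot == 0:
                        rec = 0
                    elif n_dlt == 0:
                        rec = min(cur + 1, K - 1)
                    else:  # all DLT so far: stay at the lowest tried dose
                        rec = cur
                if t > 0:
                    correct[k, t - 1] += rec == k
                if t == n_cap:
                    break
                y = u[t] < p_true[rec]
                n_vec[rec] += 1
                x_vec[rec] += y
                n_dlt += y
                n_tot += 1
                cur = rec
    return correct.mean(axis=0) / n_sim


def crm_sample_size(
    spec: SampleSizeSpec,
    n_cap: int = 80,
    n_sim: int = 400,
    seed: int = _CALC_SEED,
) -> int:
    """Smallest N whose average PCS meets ``spec.pcs_goal``.

    Monotone nonincreasing in the effect size and nondecreasing in the PCS
    goal; raises OutOfDomainError when the goal is not reached by ``n_cap``
    patients.
    """
    curve = average_pcs_curve(spec, n_cap=n_cap, n_sim=n_sim, seed=seed)
    reached = np.maximum.accumulate(curve) >= spec.pcs_goal
    if not reached.any():
        raise OutOfDomainError(
            f"average PCS does not reach {spec.pcs_goal:g} within {n_cap} patients"
        )
    return int(np.argmax(reached)) + 1
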