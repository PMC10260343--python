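"""The CRM shift-model design: estimation, allocation, conduct and selection.

Conduct is two-stage. Likelihood estimation of the power parameter has no
solution until the data contain both a DLT and a non-DLT, so the trial opens
with a prespecified path: start at the lowest combination and escalate along
row 1 in cohorts of one; if row 1 is exhausted without a DLT, continue from
the lowest level of row 2. Once the data are heterogeneous the modeling
stage begins: every working model (one per hypothesized MTD shift) is fitted
by maximum likelihood, the model with the largest likelihood is selected
(exact ties broken uniformly at random), the selected fit recommends the
level closest to the target rate in each row, and the next patient is
randomized between the two row recommendations with equal probability.

Because every working model constrains the row-2 MTD to sit at or below the
row-1 MTD, the final recommended pair can never be a reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._mle import mle_power
from .core import (
    Combination,
    DoseGrid,
    SkeletonSpec,
    WorkingModel,
    build_shift_working_models,
    closest_level,
    lee_cheung_skeleton,
)
from .errors import HeterogeneityRequiredError, WrongStageError

STAGE_INITIAL = "initial"
STAGE_MODELING = "modeling"

#: bounds for the log-power parameter a (the power is exp(a) in [4.5e-5, 2.2e4])
A_BOUNDS = (-10.0, 10.0)
#: golden-section convergence tolerance on a
A_TOL = 1e-9
#: two fits whose (weighted) log-likelihoods differ by less than this are tied
TIE_TOL = 1e-9


@dataclass(frozen=True)
class TrialRecord:
    patient: int
    combination: Combination
    dlt: int


@dataclass
class TrialState:
    """Accumulated per-patient records plus the derived conduct stage."""

    grid: DoseGrid = field(default_factory=DoseGrid)
    records: list[TrialRecord] = field(default_factory=list)

    def add(self, combination: Combination, dlt: int) -> None:
        if not self.grid.contains(combination):
            raise ValueError(f"{combination} outside the {self.grid.n_rows}x{self.grid.n_levels} grid")
        if dlt not in (0, 1):
            raise ValueError("dlt must be 0 or 1")
        self.records.append(TrialRecord(len(self.records) + 1, combination, int(dlt)))

    @property
    def n_patients(self) -> int:
        return len(self.records)

    @property
    def n_dlt(self) -> int:
        return sum(r.dlt for r in self.records)

    @property
    def is_heterogeneous(self) -> bool:
        n1 = self.n_dlt
        return 0 < n1 < self.n_patients

    @property
    def stage(self) -> str:
        return STAGE_MODELING if self.is_heterogeneous else STAGE_INITIAL

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (n treated, x DLT) matrices, shape (n_rows, n_levels)."""
        n = np.zeros((self.grid.n_rows, self.grid.n_levels), dtype=np.int64)
        x = np.zeros_like(n)
        for r in self.records:
            n[r.combination.row - 1, r.combination.level - 1] += 1
            x[r.combination.row - 1, r.combination.level - 1] += r.dlt
        return n, x

    def counts_at(self, combination: Combination) -> tuple[int, int]:
        n = x = 0
        for r in self.records:
            if r.combination == combination:
                n += 1
                x += r.dlt
        return n, x


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit of one working model."""

    model: WorkingModel
    a_hat: float
    loglik: float
    dlt_estimates: np.ndarray


@dataclass(frozen=True)
class ShiftCrmConfig:
    """Design configuration for the shift-model CRM.

    Defaults are the trial's own settings: target DLT rate 30%, N = 39,
    shifts {0, -1}, skeleton calibrated with halfwidth 0.05 and prior MTD at
    level 4 from a base vector of length n_levels + max|shift|. The safety
    rule stops the trial when, with at least ``safety_min_exposure`` patients
    at the lowest combination, the one-sided lower ``safety_confidence``
    Clopper-Pearson bound on its DLT rate exceeds the target.
    """

    target: float = 0.30
    n_max: int = 39
    shifts: tuple[int, ...] = (0, -1)
    halfwidth: float = 0.05
    prior_mtd: int = 4
    n_rows: int = 2
    n_levels: int = 7
    safety_confidence: float = 0.90
    safety_min_exposure: int = 3
    model_weights: Optional[tuple[float, ...]] = None
    max_step: Optional[int] = None  # optional per-row escalation cap in the modeling stage

    def __post_init__(self) -> None:
        if not 0 < self.target < 1:
            raise ValueError("target must lie in (0, 1)")
        if self.n_max < self.n_rows:
            raise ValueError("n_max must be at least the number of rows")
        if self.model_weights is not None and len(self.model_weights) != len(self.shifts):
            raise ValueError("model_weights must match the number of shifts")

    def skeleton_spec(self) -> SkeletonSpec:
        length = self.n_levels + max(-s for s in self.shifts)
        return SkeletonSpec(
            target=self.target,
            halfwidth=self.halfwidth,
            prior_mtd=self.prior_mtd,
            length=length,
        )

    def build_models(self) -> list[WorkingModel]:
        base = lee_cheung_skeleton(self.skeleton_spec())
        return build_shift_working_models(base, self.shifts, self.n_levels)

    def grid(self) -> DoseGrid:
        return DoseGrid(n_rows=self.n_rows, n_levels=self.n_levels)


def power_model_loglik(model: WorkingModel, state: TrialState, a: float) -> float:
    """Binomial log-likelihood of the data under skeleton^exp(a)."""
    if state.n_patients == 0:
        raise ValueError("state is empty")
    lam = math.exp(a)
    ll = 0.0
    for rec in state.records:
        q = model.skeleton[rec.combination.row - 1, rec.combination.level - 1]
        s = lam * math.log(q)
        ll += rec.dlt * s + (1 - rec.dlt) * math.log1p(-math.exp(s))
    return ll


def fit_working_model(model: WorkingModel, state: TrialState) -> ModelFit:
    """MLE of the power parameter for one working model.

    Raises HeterogeneityRequiredError on homogeneous data (all DLT or all
    non-DLT), for which the likelihood has no interior maximum.
    """
    if not state.is_heterogeneous:
        raise HeterogeneityRequiredError(
            "maximum likelihood estimation requires at least one DLT and one non-DLT"
        )
    n, x = state.counts()
    mask = n.ravel() > 0
    logq = np.log(model.skeleton.ravel()[mask])
    a_hat, ll = mle_power(
        logq,
        n.ravel()[mask].astype(np.float64),
        x.ravel()[mask].astype(np.float64),
        A_BOUNDS[0],
        A_BOUNDS[1],
        A_TOL,
    )
    estimates = model.skeleton ** math.exp(a_hat)
    return ModelFit(model=model, a_hat=a_hat, loglik=ll, dlt_estimates=estimates)


def select_working_model(
    fits: Sequence[ModelFit],
    rng: np.random.Generator,
    weights: Optional[Sequence[float]] = None,
) -> int:
    """Index of the fit with the largest (optionally weighted) likelihood.

    With equal prior model weights (the default) this is pure maximum
    likelihood. Exact ties are resolved by a uniform draw among the tied set.
    """
    if len(fits) == 0:
        raise ValueError("no fits to select from")
    scores = np.array([f.loglik for f in fits], dtype=float)
    if weights is not None:
        scores = scores + np.log(np.asarray(weights, dtype=float))
    best = scores.max()
    tied = np.flatnonzero(scores >= best - TIE_TOL * max(1.0, abs(best)))
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[rng.integers(len(tied))])


def row_recommendations(fit: ModelFit, target: float) -> tuple[int, ...]:
    """Per-row level with fitted DLT rate closest to the target, ties low.

    By construction of the shift models the recommended levels satisfy
    level[row 2] - level[row 1] = the model's shift.
    """
    return tuple(
        closest_level(fit.dlt_estimates[r], target) for r in range(fit.dlt_estimates.shape[0])
    )


def initial_escalation_next(state: TrialState) -> Combination:
    """Next assignment on the prespecified initial path.

    Empty trial: the lowest combination (row 1, level 1). Otherwise escalate
    one level at a time along row 1, then continue from level 1 of row 2.
    If the grid is exhausted without heterogeneity, or the data contain DLTs
    but no non-DLT (no lower dose exists to retreat to), the last
    combination is repeated.
    """
    if state.stage != STAGE_INITIAL:
        raise WrongStageError("initial escalation requested but the modeling stage has begun")
    if not state.records:
        return Combination(1, 1)
    last = state.records[-1].combination
    if state.n_dlt > 0:  # all-DLT data: no lower dose, repeat until a non-DLT occurs
        return last
    if last.level < state.grid.n_levels:
        return Combination(last.row, last.level + 1)
    if last.row < state.grid.n_rows:
        return Combination(last.row + 1, 1)
    return last  # whole grid tried without a DLT: stay at the top combination


def _capped_level(state: TrialState, row: int, level: int, max_step: Optional[int]) -> int:
    if max_step is None:
        return level
    tried = [r.combination.level for r in state.records if r.combination.row == row]
    ceiling = (max(tried) if tried else 0) + max_step
    return min(level, max(1, ceiling))


def next_assignment(
    state: TrialState,
    config: ShiftCrmConfig,
    models: Sequence[WorkingModel],
    rng: np.random.Generator,
) -> Optional[Combination]:
    """Assignment for the next patient, or None when the trial is complete.

    In the modeling stage the next patient is randomized with probability
    1/2 to the recommended level of row 1 or row 2 under the selected model.
    """
    if state.n_patients >= config.n_max:
        return None
    if state.stage == STAGE_INITIAL:
        return initial_escalation_next(state)
    fits = [fit_working_model(m, state) for m in models]
    idx = select_working_model(fits, rng, config.model_weights)
    levels = row_recommendations(fits[idx], config.target)
    row = int(rng.integers(state.grid.n_rows)) + 1
    level = _capped_level(state, row, levels[row - 1], config.max_step)
    return Combination(row, level)


def safety_stop(state: TrialState, config: ShiftCrmConfig) -> bool:
    """True when the lowest combination is demonstrably too toxic.

    Requires at least ``safety_min_exposure`` patients at (row 1, level 1)
    and an exact one-sided lower Clopper-Pearson confidence bound on the DLT
    rate there exceeding the target.
    """
    n, x = state.counts_at(Combination(1, 1))
    if n < config.safety_min_exposure or x == 0:
        return False
    lower = float(stats.beta.ppf(1.0 - config.safety_confidence, x, n - x + 1))
    return lower > config.target


def final_selection(
    state: TrialState,
    config: ShiftCrmConfig,
    models: Sequence[WorkingModel],
    rng: np.random.Generator,
    stopped_for_safety: bool = False,
) -> tuple[Optional[int], ...]:
    """Final MTD level per row, or (None, ...) after a safety stop.

    The returned pair always satisfies level[row 2] <= level[row 1]: every
    working model's shift is <= 0, so a reversal is structurally impossible.
    """
    if stopped_for_safety:
        return (None,) * config.n_rows
    if not state.is_heterogeneous:
        # The likelihood has no solution on homogeneous data. A trial that
        # ends with zero DLTs recommends the highest tried level per row
        # (nothing looked toxic); an all-DLT trial recommends nothing (in
        # practice the safety rule stops such trials first).
        if state.n_dlt > 0:
            return (None,) * config.n_rows
        levels = []
        for r in range(1, config.n_rows + 1):
            tried = [rec.combination.level for rec in state.records if rec.combination.row == r]
            levels.append(max(tried) if tried else None)
        return tuple(levels)
    fits = [fit_working_model(m, state) for m in models]
    idx = select_working_model(fits, rng, config.model_weights)
    return row_recommendations(fits[idx], config.target)


class ShiftCrmDesign:
    """Bundles a configuration with its prebuilt working models.

    ``simulate_trial`` runs one complete trial against a true scenario:
    patient outcomes are Bernoulli draws at the assigned combination's true
    DLT probability, the safety rule is checked before every enrolment, and
    the final pair is selected on the complete data.
    """

    name = "shift-crm"

    def __init__(self, config: ShiftCrmConfig | None = None):
        self.config = config or ShiftCrmConfig()
        self.models = self.config.build_models()

    def simulate_trial(self, scenario, rng: np.random.Generator):
        from .simulate import TrialResult  # deferred: simulate imports this module

        cfg = self.config
        state = TrialState(grid=cfg.grid())
        stopped = False
        while state.n_patients < cfg.n_max:
            if safety_stop(state, cfg):
                stopped = True
                break
            combo = next_assignment(state, cfg, self.models, rng)
            dlt = int(rng.random() < scenario.prob(combo))
            state.add(combo, dlt)
        mtd = final_selection(state, cfg, self.models, rng, stopped_for_safety=stopped)
        return TrialResult(
            design=self.name,
            allocations=tuple(r.combination for r in state.records),
            dlts=tuple(r.dlt for r in state.records),
            final_mtd=mtd,
            stopped_early=stopped,
            row_stopped=(stopped,) * cfg.n_rows,
            n_enrolled=state.n_patients,
        )
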