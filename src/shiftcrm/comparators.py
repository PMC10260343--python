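"""Parallel per-row comparator designs: 3+3 rules and the BOIN interval design.

Both comparators treat the two rows of the grid as independent single-agent
trials, which is exactly what makes a *reversal* possible: nothing stops the
combination row from settling on a higher MTD than the monotherapy row.

BOIN compares the observed DLT rate at the current dose with two fixed
boundaries (lambda_e, lambda_d) derived from the target rate phi and the
indifference bounds (phi1, phi2); decisions depend on the current level's
counts only. Overly toxic levels are eliminated when the Beta(1 + x,
1 + n - x) posterior puts more than ``threshold`` mass above phi (minimum
exposure 3), and the MTD is chosen by isotonically adjusted posterior means.

The 3+3 is the classic rule table: 0/3 escalate, 1/3 expand to six,
<=1/6 escalate, >=2 stop with the next-lower level as MTD (no MTD when
stopping occurs at the lowest level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import log
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.isotonic import isotonic_regression

ESCALATE = "escalate"
DEESCALATE = "de-escalate"
STAY = "stay"
EXPAND = "expand"
STOP = "stop"


@dataclass(frozen=True)
class BoinBoundaries:
    phi: float
    phi1: float
    phi2: float
    lambda_e: float
    lambda_d: float


@dataclass
class RowTrialState:
    """Per-level counts and conduct state of one row's independent trial."""

    n_levels: int
    n_max: int = 20
    n: np.ndarray = field(default=None)  # patients treated per level
    x: np.ndarray = field(default=None)  # DLTs per level
    current: int = 1
    eliminated: int = 0  # levels >= this 1-based index are eliminated; 0 = none
    stopped_for_safety: bool = False
    finished: bool = False

    def __post_init__(self) -> None:
        if self.n is None:
            self.n = np.zeros(self.n_levels, dtype=np.int64)
        if self.x is None:
            self.x = np.zeros(self.n_levels, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def is_eliminated(self, level: int) -> bool:
        return self.eliminated > 0 and level >= self.eliminated

    def treat(self, level: int, dlt: int) -> None:
        self.n[level - 1] += 1
        self.x[level - 1] += int(dlt)


def boin_boundaries(phi: float, phi1: float = None, phi2: float = None) -> BoinBoundaries:
    """Escalation/de-escalation boundaries of the BOIN design.

    Defaults phi1 = 0.6*phi and phi2 = 1.4*phi are the method's recommended
    settings. The closed forms guarantee lambda_e < phi < lambda_d.
    """
    if phi1 is None:
        phi1 = 0.6 * phi
    if phi2 is None:
        phi2 = 1.4 * phi
    if not 0 < phi1 < phi < phi2 < 1:
        raise ValueError(f"need 0 < phi1 < phi < phi2 < 1, got {(phi1, phi, phi2)}")
    lambda_e = log((1 - phi1) / (1 - phi)) / log(phi * (1 - phi1) / (phi1 * (1 - phi)))
    lambda_d = log((1 - phi) / (1 - phi2)) / log(phi2 * (1 - phi) / (phi * (1 - phi2)))
    return BoinBoundaries(phi=phi, phi1=phi1, phi2=phi2, lambda_e=lambda_e, lambda_d=lambda_d)


def boin_next(row_state: RowTrialState, b: BoinBoundaries) -> str:
    """Escalate / de-escalate / stay, from the current level's counts only.

    The move never lands on an eliminated level: elimination is upward-closed,
    so a blocked escalation becomes "stay".
    """
    j = row_state.current
    n = row_state.n[j - 1]
    if n < 1:
        raise ValueError("current level has no treated patients yet")
    phat = row_state.x[j - 1] / n
    if phat <= b.lambda_e:
        if j < row_state.n_levels and not row_state.is_eliminated(j + 1):
            return ESCALATE
        return STAY
    if phat >= b.lambda_d:
        return DEESCALATE if j > 1 else STAY
    return STAY


@lru_cache(maxsize=None)
def _eliminate_decision(n: int, x: int, phi: float, threshold: float) -> bool:
    if n < 3:
        return False
    return float(stats.beta.sf(phi, 1 + x, 1 + n - x)) > threshold


def boin_eliminate(row_state: RowTrialState, phi: float, threshold: float = 0.95) -> RowTrialState:
    """Eliminate overly toxic levels (and everything above them) in place.

    A level with at least 3 patients is eliminated when the Beta(1 + x,
    1 + n - x) posterior probability of exceeding phi passes ``threshold``.
    Eliminating level 1 stops the row for safety.
    """
    for j in range(1, row_state.n_levels + 1):
        if row_state.is_eliminated(j):
            break
        if _eliminate_decision(int(row_state.n[j - 1]), int(row_state.x[j - 1]), phi, threshold):
            row_state.eliminated = j
            if j == 1:
                row_state.stopped_for_safety = True
                row_state.finished = True
            break
    return row_state


def pava_isotonic(values, weights=None) -> np.ndarray:
    """Weighted least-squares monotone (nondecreasing) fit via pool-adjacent-violators."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return isotonic_regression(values, sample_weight=weights)


def boin_select_mtd(row_state: RowTrialState, phi: float) -> Optional[int]:
    """MTD for a finished row, or None after a safety stop.

    Posterior means under the near-vague Beta(0.05, 0.05) prior (the
    interval method's own selection default, so sparsely tried levels are
    estimated by essentially their observed rate) at the tried,
    non-eliminated levels are isotonically adjusted (weights = inverse
    posterior variance) and the level with adjusted estimate closest to phi
    is selected, ties low.
    """
    if row_state.stopped_for_safety:
        return None
    tried = [
        j
        for j in range(1, row_state.n_levels + 1)
        if row_state.n[j - 1] > 0 and not row_state.is_eliminated(j)
    ]
    if not tried:
        return None
    n = row_state.n[np.array(tried) - 1]
    x = row_state.x[np.array(tried) - 1]
    post_mean = (x + 0.05) / (n + 0.10)
    post_var = post_mean * (1 - post_mean) / (n + 0.10 + 1)
    adjusted = pava_isotonic(post_mean, 1.0 / post_var)
    d = np.round(np.abs(adjusted - phi), 10)
    return tried[int(np.argmin(d))]


def three_plus_three_next(row_state: RowTrialState) -> str:
    """Decision after a complete cohort at the current level of a 3+3 trial.

    0/3 DLT -> escalate; 1/3 -> expand to six; <=1/6 -> escalate;
    >=2 (of 3 or 6) -> stop.
    """
    j = row_state.current
    n = int(row_state.n[j - 1])
    x = int(row_state.x[j - 1])
    if n not in (3, 6):
        raise ValueError("3+3 decisions apply after complete cohorts of 3 or 6")
    if x >= 2:
        return STOP
    if n == 3 and x == 1:
        return EXPAND
    return ESCALATE  # 0/3, 0-1/6


def three_plus_three_mtd(row_state: RowTrialState) -> Optional[int]:
    """MTD after a finished 3+3 row: the highest level cleared with <=1/6.

    Stopping at the lowest level yields no MTD (the row stopped for safety);
    escalating past the top level caps the MTD at the top level.
    """
    if not row_state.finished:
        raise ValueError("row trial not finished")
    if row_state.stopped_for_safety:
        return None
    j = row_state.current
    x = int(row_state.x[j - 1])
    n = int(row_state.n[j - 1])
    if n in (3, 6) and x >= 2:
        return j - 1 if j > 1 else None
    return j  # cleared the top level


def reversal(mtd_row1: Optional[int], mtd_row2: Optional[int]) -> bool:
    """True iff both rows selected an MTD and row 2's exceeds row 1's."""
    return mtd_row1 is not None and mtd_row2 is not None and mtd_row2 > mtd_row1


@dataclass(frozen=True)
class ParallelRowConfig:
    """Settings shared by the parallel (per-row) comparator designs."""

    target: float = 0.30
    n_levels: int = 7
    n_rows: int = 2
    n_max_per_row: int = 20  # BOIN only; the 3+3 sample size is rule-determined
    phi1: Optional[float] = None
    phi2: Optional[float] = None
    elimination_threshold: float = 0.95


class ParallelBoinDesign:
    """Independent BOIN trials in each row, cohorts of size one."""

    name = "parallel-boin"

    def __init__(self, config: ParallelRowConfig | None = None):
        self.config = config or ParallelRowConfig()
        self.boundaries = boin_boundaries(self.config.target, self.config.phi1, self.config.phi2)

    def _run_row(self, probs: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        st = RowTrialState(n_levels=cfg.n_levels, n_max=cfg.n_max_per_row)
        allocations = []
        dlts = []
        while st.total < st.n_max and not st.finished:
            level = st.current
            dlt = int(rng.random() < probs[level - 1])
            st.treat(level, dlt)
            allocations.append(level)
            dlts.append(dlt)
            boin_eliminate(st, cfg.target, cfg.elimination_threshold)
            if st.finished:
                break
            action = boin_next(st, self.boundaries)
            if action == ESCALATE:
                st.current += 1
            elif action == DEESCALATE:
                st.current -= 1
        st.finished = True
        return st, allocations, dlts, boin_select_mtd(st, cfg.target)

    def simulate_trial(self, scenario, rng: np.random.Generator):
        from .simulate import TrialResult
        from .core import Combination

        allocations, dlts, mtds, stops = [], [], [], []
        for r in range(self.config.n_rows):
            st, alloc, d, mtd = self._run_row(scenario.probs[r], rng)
            allocations.extend(Combination(r + 1, lv) for lv in alloc)
            dlts.extend(d)
            mtds.append(mtd)
            stops.append(st.stopped_for_safety)
        return TrialResult(
            design=self.name,
            allocations=tuple(allocations),
            dlts=tuple(dlts),
            final_mtd=tuple(mtds),
            stopped_early=any(stops),
            row_stopped=tuple(stops),
            n_enrolled=len(allocations),
        )


class ParallelThreePlusThreeDesign:
    """Independent classic 3+3 trials in each row."""

    name = "parallel-3p3"

    def __init__(self, config: ParallelRowConfig | None = None):
        self.config = config or ParallelRowConfig()

    def _run_row(self, probs: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        st = RowTrialState(n_levels=cfg.n_levels, n_max=6 * cfg.n_levels)
        allocations = []
        dlts = []
        while not st.finished:
            level = st.current
            for _ in range(3):
                dlt = int(rng.random() < probs[level - 1])
                st.treat(level, dlt)
                allocations.append(level)
                dlts.append(dlt)
            action = three_plus_three_next(st)
            if action == EXPAND:
                for _ in range(3):
                    dlt = int(rng.random() < probs[level - 1])
                    st.treat(level, dlt)
                    allocations.append(level)
                    dlts.append(dlt)
                action = three_plus_three_next(st)
            if action == STOP:
                st.finished = True
                if level == 1:
                    st.stopped_for_safety = True
            else:  # escalate
                if level == cfg.n_levels:
                    st.finished = True
                else:
                    st.current += 1
        return st, allocations, dlts, three_plus_three_mtd(st)

    def simulate_trial(self, scenario, rng: np.random.Generator):
        from .simulate import TrialResult
        from .core import Combination

        allocations, dlts, mtds, stops = [], [], [], []
        for r in range(self.config.n_rows):
            st, alloc, d, mtd = self._run_row(scenario.probs[r], rng)
            allocations.extend(Combination(r + 1, lv) for lv in alloc)
            dlts.extend(d)
            mtds.append(mtd)
            stops.append(st.stopped_for_safety)
        return TrialResult(
            design=self.name,
            allocations=tuple(allocations),
            dlts=tuple(dlts),
            final_mtd=tuple(mtds),
            stopped_early=any(stops),
            row_stopped=tuple(stops),
            n_enrolled=len(allocations),
        )
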