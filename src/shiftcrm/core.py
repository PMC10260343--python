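"""Core dose-grid types, skeleton calibration, and shift-structured working models.

The trial operates on a 2 x L grid of combinations: row 1 is the less-toxic
strategy (Agent A alone), row 2 adds the second agent at the same Agent A
dose. The maximum tolerated dose (MTD) in each row is the level whose DLT
probability is closest to a prespecified target rate theta (0.30 by default),
ties broken to the lower (safer) level.

Skeletons — the prior DLT probability guesses raised to a power by the CRM —
are calibrated with the indifference-interval recursion of Lee and Cheung for
the empiric (power) model: starting from q[nu] = theta, the next level up
solves q[k+1]^{a*} = theta + delta where a* solves q[k]^{a*} = theta - delta,
and symmetrically downward. A shift-structured family of working models is
then built from a single calibrated base vector: for shift s <= 0, row 1
reads positions 1..L of the base and row 2 reads positions 1-s..L-s, so the
hypothesized row-2 MTD sits s levels below the row-1 MTD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    ColumnOrderingError,
    InvalidHalfwidthError,
    RowMonotonicityError,
    ScenarioValidationError,
    ShiftConstraintError,
    SkeletonCalibrationError,
)

#: decimal places used when comparing |p - theta| distances, so that exact
#: arithmetic ties (e.g. 0.25 vs 0.35 around 0.30) are broken to the lower
#: level instead of by floating-point noise.
_TIE_DECIMALS = 10


@dataclass(frozen=True)
class DoseGrid:
    """A 2 x L (or more generally R x L) grid of drug combinations.

    Row index 1 is the least-toxic strategy; level index 1 the lowest dose.
    All indices in the public interface are 1-based, matching trial tables.
    """

    n_rows: int = 2
    n_levels: int = 7
    row_labels: tuple[str, ...] = ()
    dose_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("grid needs at least 2 rows")
        if self.n_levels < 2:
            raise ValueError("grid needs at least 2 dose levels per row")
        if self.row_labels and len(self.row_labels) != self.n_rows:
            raise ValueError("row_labels length must equal n_rows")
        if self.dose_labels and len(self.dose_labels) != self.n_levels:
            raise ValueError("dose_labels length must equal n_levels")

    def contains(self, combo: "Combination") -> bool:
        return 1 <= combo.row <= self.n_rows and 1 <= combo.level <= self.n_levels


@dataclass(frozen=True, order=True)
class Combination:
    """One cell of the dose grid: (row, level), both 1-based."""

    row: int
    level: int

    def __post_init__(self) -> None:
        if self.row < 1 or self.level < 1:
            raise ValueError("row and level are 1-based and must be >= 1")


@dataclass(frozen=True)
class SkeletonSpec:
    """Parameters of the Lee-Cheung indifference-interval calibration.

    target     -- theta, the target DLT rate anchoring the skeleton.
    halfwidth  -- delta, half the indifference interval; 0 gives a flat skeleton.
    prior_mtd  -- nu, the 1-based position at which the skeleton equals theta.
    length     -- number of skeleton values to generate.
    """

    target: float
    halfwidth: float
    prior_mtd: int
    length: int

    def __post_init__(self) -> None:
        if not 0.0 < self.target < 1.0:
            raise ValueError("target must lie in (0, 1)")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 1 <= self.prior_mtd <= self.length:
            raise ValueError("prior_mtd must lie in 1..length")
        if self.halfwidth < 0 or self.halfwidth >= min(self.target, 1 - self.target):
            raise InvalidHalfwidthError(
                f"halfwidth must lie in [0, {min(self.target, 1 - self.target):g}) "
                f"for target {self.target:g}; got {self.halfwidth:g}"
            )


@dataclass(frozen=True)
class WorkingModel:
    """One hypothesized MTD shift and its skeleton matrix.

    ``shift`` is the row-2 MTD level minus the row-1 MTD level (0 or -1 in
    this trial). ``skeleton`` has shape (n_rows, n_levels) with probabilities
    in (0, 1), nondecreasing along each row and, column-wise, row 2 >= row 1.
    """

    shift: int
    skeleton: np.ndarray

    def __post_init__(self) -> None:
        skel = np.asarray(self.skeleton, dtype=float)
        object.__setattr__(self, "skeleton", skel)
        if skel.ndim != 2:
            raise ValueError("skeleton must be a 2-D matrix")
        if np.any(skel <= 0) or np.any(skel >= 1):
            raise ValueError("skeleton values must lie strictly in (0, 1)")
        if np.any(np.diff(skel, axis=1) < 0):
            raise ValueError("skeleton must be nondecreasing along each row")
        if np.any(np.diff(skel, axis=0) < 0):
            raise ValueError("skeleton row 2 must dominate row 1 at every level")

    @property
    def n_rows(self) -> int:
        return self.skeleton.shape[0]

    @property
    def n_levels(self) -> int:
        return self.skeleton.shape[1]


@dataclass(frozen=True)
class ToxScenario:
    """A true dose-toxicity scenario: DLT probabilities plus derived MTDs.

    ``true_mtd`` (one 1-based level per row) is filled by
    :func:`validate_scenario`; construct scenarios through that function.
    """

    probs: np.ndarray
    target: float = 0.30
    true_mtd: Optional[tuple[int, ...]] = None
    name: str = ""

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.probs, dtype=float))
        object.__setattr__(self, "probs", p)

    @property
    def n_rows(self) -> int:
        return self.probs.shape[0]

    @property
    def n_levels(self) -> int:
        return self.probs.shape[1]

    def prob(self, combo: Combination) -> float:
        return float(self.probs[combo.row - 1, combo.level - 1])


def closest_level(probs: Sequence[float], target: float) -> int:
    """1-based level whose probability is closest to ``target``, ties low.

    Distances are rounded to 10 decimals before comparison so that ties that
    are exact in decimal arithmetic (e.g. 0.25/0.35 around 0.30) resolve to
    the lower level rather than by floating-point representation noise.
    """
    d = np.round(np.abs(np.asarray(probs, dtype=float) - target), _TIE_DECIMALS)
    return int(np.argmin(d)) + 1


def lee_cheung_skeleton(spec: SkeletonSpec) -> np.ndarray:
    """Calibrate a CRM skeleton by the Lee-Cheung indifference-interval recursion.

    For the empiric model p = q^a: moving up from position nu (where
    q[nu] = theta), q[k+1] solves q[k+1]^{a*} = theta + delta with a* the
    power at which q[k]^{a*} = theta - delta; moving down exchanges
    theta + delta and theta - delta. With delta = 0 the recursion is the
    identity and all values equal theta.

    Returns a vector in (0, 1), strictly increasing when delta > 0, with
    value exactly theta at position nu.
    """
    theta, delta, nu, length = spec.target, spec.halfwidth, spec.prior_mtd, spec.length
    q = np.empty(length, dtype=float)
    q[nu - 1] = theta
    log_hi = math.log(theta + delta)
    log_lo = math.log(theta - delta)
    for k in range(nu - 1, length - 1):
        # a* = log(theta - delta) / log(q[k]); q[k+1] = (theta + delta)^(1/a*)
        q[k + 1] = math.exp(log_hi * math.log(q[k]) / log_lo)
    for k in range(nu - 1, 0, -1):
        q[k - 1] = math.exp(log_lo * math.log(q[k]) / log_hi)
    if np.any(q <= 0) or np.any(q >= 1):
        raise SkeletonCalibrationError("recursion produced a value outside (0, 1)")
    if delta > 0 and np.any(np.diff(q) <= 0):
        raise SkeletonCalibrationError("recursion failed to produce a strictly increasing skeleton")
    return q


def build_shift_working_models(
    base: Sequence[float],
    shifts: Iterable[int],
    n_levels: int,
) -> list[WorkingModel]:
    """Construct one 2-row working model per hypothesized MTD shift.

    ``base`` is a strictly increasing probability vector of length at least
    ``n_levels + max(|shift|)``. For shift s (s <= 0), row 1 takes base
    positions 1..n_levels and row 2 takes positions 1-s..n_levels-s, i.e.
    row 2 is offset upward in toxicity by |s| positions, placing its
    hypothesized MTD s levels below row 1's.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim != 1:
        raise ValueError("base must be a 1-D probability vector")
    if np.any(np.diff(base) <= 0):
        raise ValueError("base skeleton must be strictly increasing")
    shifts = sorted(set(int(s) for s in shifts), reverse=True)
    if not shifts:
        raise ValueError("at least one shift is required")
    if any(s > 0 for s in shifts):
        raise ValueError("shifts must be <= 0 (row 2 is at least as toxic as row 1)")
    max_offset = max(-s for s in shifts)
    if len(base) < n_levels + max_offset:
        raise ValueError(
            f"base of length {len(base)} too short for {n_levels} levels "
            f"with maximum shift {-max_offset}"
        )
    models = []
    for s in shifts:
        off = -s
        skeleton = np.vstack([base[:n_levels], base[off : off + n_levels]])
        models.append(WorkingModel(shift=s, skeleton=skeleton))
    return models


def validate_scenario(scenario: ToxScenario, max_shift: int = 1) -> ToxScenario:
    """Validate a scenario's ordering constraints and fill its true MTDs.

    Checks, raising a distinct error for each violation:

    * probabilities in (0, 1) and nondecreasing along each row;
    * column ordering: each row dominates the previous (adding the second
      agent can only increase DLT risk);
    * the derived true MTDs of adjacent rows differ by at most ``max_shift``.

    Returns a copy of the scenario with ``true_mtd`` filled by the
    closest-to-target rule (ties to the lower level).
    """
    p = scenario.probs
    if np.any(p <= 0) or np.any(p >= 1):
        raise ScenarioValidationError("DLT probabilities must lie strictly in (0, 1)")
    if np.any(np.diff(p, axis=1) < 0):
        raise RowMonotonicityError("DLT probabilities must be nondecreasing in dose level")
    if np.any(np.diff(p, axis=0) < 0):
        raise ColumnOrderingError(
            "row 2 must be at least as toxic as row 1 at every dose level"
        )
    mtd = tuple(closest_level(p[r], scenario.target) for r in range(p.shape[0]))
    for r in range(len(mtd) - 1):
        if abs(mtd[r] - mtd[r + 1]) > max_shift:
            raise ShiftConstraintError(
                f"true MTDs {mtd} differ by more than {max_shift} level(s) between rows"
            )
    return replace(scenario, true_mtd=mtd)
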