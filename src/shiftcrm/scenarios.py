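"""Fixed and randomly generated dose-toxicity scenarios.

``illustration_scenario`` is the 2 x 7 truth used throughout the worked
example: row-1 probabilities {0.01, 0.12, 0.18, 0.21, 0.22, 0.31, 0.60}
(true MTD at level 6) and row-2 probabilities {0.09, 0.14, 0.22, 0.25,
0.32, 0.40, 0.64} (true MTD at level 5).

``random_scenario`` emulates a constrained random-curve generator: it draws
an intended row-1 MTD location uniformly over the levels and an intended
shift uniformly over the allowed set (clipped so the row-2 MTD stays on the
grid), anchors each row's probability near the target at its intended MTD,
and fills the remaining levels with random increments — moderate near the
MTD, heavier-tailed elsewhere, so the ensemble contains both steep and flat
curves. Candidate matrices are rejected until all scenario invariants hold
and the closest-to-target level in each row equals the intended MTD; the
intended (location, shift) pair is held fixed across rejections so its
sampling law is exactly the one stated above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ToxScenario, closest_level, validate_scenario
from .errors import ScenarioGenerationError

ILLUSTRATION_ROW1 = (0.01, 0.12, 0.18, 0.21, 0.22, 0.31, 0.60)
ILLUSTRATION_ROW2 = (0.09, 0.14, 0.22, 0.25, 0.32, 0.40, 0.64)


@dataclass(frozen=True)
class CurveEnsembleSpec:
    """Specification of an ensemble of constrained random dose-toxicity curves."""

    n_curves: int = 50
    n_levels: int = 7
    target: float = 0.30
    shifts: tuple[int, ...] = (0, -1)
    mtd_prob_halfwidth: float = 0.04  # MTD-level probability drawn in target +/- this
    near_gap_shape: float = 2.0  # Gamma shape of increments adjacent to the MTD
    near_gap_scale: float = 0.04  # mean near-MTD increment = shape * scale = 0.08
    far_gap_shape: float = 1.2  # heavier-tailed increments away from the MTD
    far_gap_scale: float = 0.10
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if any(s > 0 for s in self.shifts):
            raise ValueError("allowed shifts must be <= 0")


def illustration_scenario(target: float = 0.30) -> ToxScenario:
    """The worked-example truth with MTDs at levels (6, 5)."""
    scenario = ToxScenario(
        probs=np.array([ILLUSTRATION_ROW1, ILLUSTRATION_ROW2]),
        target=target,
        name="illustration",
    )
    return validate_scenario(scenario, max_shift=1)


def true_mtd_row(probs, theta: float) -> int:
    """1-based level with DLT probability closest to theta, ties to the lower level."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("probs must be a non-empty vector")
    return closest_level(p, theta)


def _row_curve(spec: CurveEnsembleSpec, mtd: int, rng: np.random.Generator) -> np.ndarray:
    """One monotone row with its anchor probability near the target at ``mtd``."""
    L = spec.n_levels
    theta = spec.target
    p = np.empty(L)
    p[mtd - 1] = theta + rng.uniform(-spec.mtd_prob_halfwidth, spec.mtd_prob_halfwidth)
    for j in range(mtd - 1, L - 1):  # upward
        near = j == mtd - 1
        gap = rng.gamma(
            spec.near_gap_shape if near else spec.far_gap_shape,
            spec.near_gap_scale if near else spec.far_gap_scale,
        )
        p[j + 1] = p[j] + gap * (1.0 - p[j])  # damped toward 1, keeps p < 1
    for j in range(mtd - 1, 0, -1):  # downward
        near = j == mtd - 1
        gap = rng.gamma(
            spec.near_gap_shape if near else spec.far_gap_shape,
            spec.near_gap_scale if near else spec.far_gap_scale,
        )
        cand = p[j] - gap
        # steep drops are allowed; fall back to a multiplicative shrink near 0
        p[j - 1] = cand if cand > 0.002 else p[j] * rng.uniform(0.1, 0.6)
    return p


def random_scenario(spec: CurveEnsembleSpec, rng: np.random.Generator) -> ToxScenario:
    """One constrained random 2-row scenario (see module docstring)."""
    L = spec.n_levels
    m1 = int(rng.integers(1, L + 1))
    allowed = [s for s in spec.shifts if m1 + s >= 1]
    s = int(allowed[rng.integers(len(allowed))])
    m2 = m1 + s
    for _ in range(spec.max_attempts):
        row1 = _row_curve(spec, m1, rng)
        row2 = _row_curve(spec, m2, rng)
        if np.any(row2 < row1):
            continue
        if np.any(np.diff(row1) <= 0) or np.any(np.diff(row2) <= 0):
            continue
        if np.any(row1 <= 0) or np.any(row2 >= 1):
            continue
        if closest_level(row1, spec.target) != m1 or closest_level(row2, spec.target) != m2:
            continue
        scenario = ToxScenario(probs=np.vstack([row1, row2]), target=spec.target)
        return validate_scenario(scenario, max_shift=max(-sh for sh in spec.shifts))
    raise ScenarioGenerationError(
        f"could not generate a valid curve with MTDs ({m1}, {m2}) "
        f"within {spec.max_attempts} attempts"
    )


def random_ensemble(spec: CurveEnsembleSpec, rng: np.random.Generator) -> list[ToxScenario]:
    """A list of ``spec.n_curves`` independent constrained random scenarios."""
    curves = []
    for i in range(spec.n_curves):
        scenario = random_scenario(spec, rng)
        curves.append(
            ToxScenario(
                probs=scenario.probs,
                target=scenario.target,
                true_mtd=scenario.true_mtd,
                name=f"curve-{i + 1:03d}",
            )
        )
    return curves
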