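"""Trial simulation engine and operating-characteristics computation.

Every design object exposes ``simulate_trial(scenario, rng)``; this module
drives those over many seeded trials and aggregates the field-standard
operating characteristics:

* PCR (percentage of correct recommendation) per row: share of trials whose
  final selection in that row equals the row's true MTD. Trials with no
  selection in a row (safety stop) count as incorrect.
* PCA (proportion of correct allocation) per row: mean share of a trial's
  enrolled patients treated at that row's true MTD combination, so the
  overall PCA is the sum over rows.
* mean sample size, early-stop percentages (per trial and per row),
  reversal percentage, and the zero / at-least-one / both-correct split.

Reproducibility: trial t of stream s under base seed B uses the generator
seeded by SeedSequence(entropy=B, spawn_key=(s, t)), so any single trial can
be re-run in isolation and streams never share state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .comparators import reversal
from .core import Combination, ToxScenario


@dataclass(frozen=True)
class TrialResult:
    """Complete record of one simulated trial."""

    design: str
    allocations: tuple[Combination, ...]
    dlts: tuple[int, ...]
    final_mtd: tuple[Optional[int], ...]
    stopped_early: bool
    row_stopped: tuple[bool, ...]
    n_enrolled: int

    def __post_init__(self) -> None:
        if self.n_enrolled != len(self.allocations):
            raise ValueError("n_enrolled must equal the number of allocations")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-design summary over simulated trials under one scenario.

    Percentages are on the 0-100 scale; PCA values are proportions in [0, 1].
    """

    design: str
    scenario: str
    n_trials: int
    pcr_by_row: tuple[float, ...]
    avg_pcr: float
    pca_by_row: tuple[float, ...]
    overall_pca: float
    mean_sample_size: float
    early_stop_pct: float
    early_stop_by_row: tuple[float, ...]
    reversal_pct: float
    pct_zero_correct: float
    pct_one_correct: float
    pct_both_correct: float
    pct_at_least_one_correct: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for r, (pcr, pca, stop) in enumerate(
            zip(self.pcr_by_row, self.pca_by_row, self.early_stop_by_row), start=1
        ):
            d[f"pcr_row{r}"] = pcr
            d[f"pca_row{r}"] = pca
            d[f"early_stop_row{r}"] = stop
        for k in ("pcr_by_row", "pca_by_row", "early_stop_by_row"):
            del d[k]
        return d


def trial_rng(base_seed: int, trial: int, stream: int = 0) -> np.random.Generator:
    """The documented per-trial substream of a base seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=base_seed, spawn_key=(stream, trial)))


def run_trial(design, scenario: ToxScenario, seed) -> TrialResult:
    """One fully reproducible simulated trial.

    ``seed`` may be an integer seed or a ready numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return design.simulate_trial(scenario, rng)


def compute_ocs(
    results: Sequence[TrialResult], scenario: ToxScenario, design: str = ""
) -> OperatingCharacteristics:
    """Aggregate operating characteristics from finished trial results."""
    if not results:
        raise ValueError("no trial results to aggregate")
    if scenario.true_mtd is None:
        raise ValueError("scenario must be validated (true_mtd filled)")
    n_rows = scenario.n_rows
    m = len(results)
    correct = np.zeros((m, n_rows), dtype=bool)
    pca = np.zeros((m, n_rows))
    sizes = np.zeros(m)
    stopped = np.zeros(m, dtype=bool)
    row_stopped = np.zeros((m, n_rows), dtype=bool)
    reversals = np.zeros(m, dtype=bool)
    for i, res in enumerate(results):
        sizes[i] = res.n_enrolled
        stopped[i] = res.stopped_early
        row_stopped[i] = res.row_stopped
        reversals[i] = reversal(res.final_mtd[0], res.final_mtd[-1])
        for r in range(n_rows):
            correct[i, r] = res.final_mtd[r] == scenario.true_mtd[r]
            at_mtd = sum(
                1
                for c in res.allocations
                if c.row == r + 1 and c.level == scenario.true_mtd[r]
            )
            pca[i, r] = at_mtd / res.n_enrolled if res.n_enrolled else 0.0
    n_correct = correct.sum(axis=1)
    pcr_by_row = tuple(100.0 * correct[:, r].mean() for r in range(n_rows))
    pca_by_row = tuple(float(pca[:, r].mean()) for r in range(n_rows))
    return OperatingCharacteristics(
        design=design or results[0].design,
        scenario=scenario.name or "scenario",
        n_trials=m,
        pcr_by_row=pcr_by_row,
        avg_pcr=float(np.mean(pcr_by_row)),
        pca_by_row=pca_by_row,
        overall_pca=float(np.sum(pca_by_row)),
        mean_sample_size=float(sizes.mean()),
        early_stop_pct=100.0 * float(stopped.mean()),
        early_stop_by_row=tuple(100.0 * row_stopped[:, r].mean() for r in range(n_rows)),
        reversal_pct=100.0 * float(reversals.mean()),
        pct_zero_correct=100.0 * float((n_correct == 0).mean()),
        pct_one_correct=100.0 * float((n_correct == 1).mean()),
        pct_both_correct=100.0 * float((n_correct == n_rows).mean()),
        pct_at_least_one_correct=100.0 * float((n_correct >= 1).mean()),
    )


def simulate_ocs(
    design,
    scenario: ToxScenario,
    n_trials: int,
    base_seed: int,
    stream: int = 0,
) -> OperatingCharacteristics:
    """Run ``n_trials`` independent trials and aggregate their OCs."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results = [
        design.simulate_trial(scenario, trial_rng(base_seed, t, stream)) for t in range(n_trials)
    ]
    return compute_ocs(results, scenario, design.name)


def aggregate_over_curves(
    designs: Mapping[str, object],
    curves: Sequence[ToxScenario],
    n_trials: int,
    base_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Operating characteristics of each design over an ensemble of curves.

    Returns ``(per_curve, summary)``: one row per (design, curve) with all OC
    fields, and per-design means of the ensemble metrics (zero / at-least-one
    / both correct, reversal, sample size).
    """
    if not curves:
        raise ValueError("at least one curve is required")
    rows = []
    for d_idx, (name, design) in enumerate(designs.items()):
        for c_idx, curve in enumerate(curves):
            oc = simulate_ocs(
                design, curve, n_trials, base_seed, stream=d_idx * len(curves) + c_idx
            )
            rec = oc.to_dict()
            rec["design"] = name
            rec["scenario"] = curve.name or f"curve-{c_idx + 1:03d}"
            rows.append(rec)
    per_curve = pd.DataFrame(rows)
    summary = (
        per_curve.groupby("design", sort=False)
        .agg(
            mean_pct_zero_correct=("pct_zero_correct", "mean"),
            mean_pct_at_least_one_correct=("pct_at_least_one_correct", "mean"),
            mean_pct_both_correct=("pct_both_correct", "mean"),
            mean_reversal_pct=("reversal_pct", "mean"),
            mean_sample_size=("mean_sample_size", "mean"),
            mean_early_stop_pct=("early_stop_pct", "mean"),
        )
        .reset_index()
    )
    return per_curve, summary


def compare_report(
    results: Sequence[OperatingCharacteristics],
    csv_path=None,
    summary_path=None,
) -> pd.DataFrame:
    """Tidy (design, scenario, metric, value) table, optionally written to disk.

    ``summary_path`` additionally receives a human-readable block per design
    and scenario mirroring the usual operating-characteristics table layout.
    """
    if not results:
        raise ValueError("no results to report")
    records = []
    for oc in results:
        for metric, value in oc.to_dict().items():
            if metric in ("design", "scenario"):
                continue
            records.append(
                {"design": oc.design, "scenario": oc.scenario, "metric": metric, "value": value}
            )
    tidy = pd.DataFrame(records)
    if csv_path is not None:
        tidy.to_csv(csv_path, index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write(format_report(results))
    return tidy


def format_report(results: Sequence[OperatingCharacteristics]) -> str:
    lines = []
    for oc in results:
        lines.append(f"design: {oc.design}   scenario: {oc.scenario}   trials: {oc.n_trials}")
        pcr = " / ".join(f"{v:.1f}%" for v in oc.pcr_by_row)
        pca = " / ".join(f"{v:.3f}" for v in oc.pca_by_row)
        stops = " / ".join(f"{v:.1f}%" for v in oc.early_stop_by_row)
        lines.append(f"  PCR by row: {pcr}   average PCR: {oc.avg_pcr:.2f}%")
        lines.append(f"  PCA by row: {pca}   overall PCA: {oc.overall_pca:.3f}")
        lines.append(
            f"  mean sample size: {oc.mean_sample_size:.1f}   "
            f"early stop: {oc.early_stop_pct:.1f}% (by row: {stops})   "
            f"reversals: {oc.reversal_pct:.1f}%"
        )
        lines.append(
            f"  correct MTDs: zero {oc.pct_zero_correct:.1f}%, "
            f"one {oc.pct_one_correct:.1f}%, both {oc.pct_both_correct:.1f}%, "
            f"at least one {oc.pct_at_least_one_correct:.1f}%"
        )
        lines.append("")
    return "\n".join(lines)
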