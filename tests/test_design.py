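"""Likelihood, model selection, allocation, conduct and safety of the shift CRM."""

import math

import numpy as np
import pytest

from shiftcrm import (
    Combination,
    ModelFit,
    ShiftCrmConfig,
    WorkingModel,
    final_selection,
    fit_working_model,
    initial_escalation_next,
    next_assignment,
    power_model_loglik,
    row_recommendations,
    safety_stop,
    select_working_model,
)
from shiftcrm.design import STAGE_INITIAL, STAGE_MODELING
from shiftcrm.errors import HeterogeneityRequiredError, WrongStageError

from conftest import make_state


def reference_loglik(model, state, a):
    """Deliberately naive per-patient re-summation of the likelihood."""
    lam = math.exp(a)
    total = 0.0
    for rec in state.records:
        p = model.skeleton[rec.combination.row - 1, rec.combination.level - 1] ** lam
        total += math.log(p) if rec.dlt else math.log(1.0 - p)
    return total


class TestLikelihood:
    def test_identity_power_single_patient(self):
        model = WorkingModel(0, np.array([[0.5, 0.6], [0.5, 0.6]]))
        for dlt in (0, 1):
            state = make_state([(1, 1, dlt)])
            assert power_model_loglik(model, state, 0.0) == pytest.approx(math.log(0.5))

    def test_matches_reference_summation_on_interim_data(self, interim_state, models):
        for model in models:
            for a in np.linspace(-3, 3, 25):
                assert power_model_loglik(model, interim_state, a) == pytest.approx(
                    reference_loglik(model, interim_state, a), abs=1e-12
                )

    def test_fit_requires_heterogeneous_data(self, models):
        all_clear = make_state([(1, 1, 0), (1, 2, 0)])
        with pytest.raises(HeterogeneityRequiredError):
            fit_working_model(models[0], all_clear)

    def test_mle_matches_brute_force_grid(self):
        # One DLT at skeleton 0.30, one non-DLT at skeleton 0.10.
        from shiftcrm import DoseGrid, TrialState

        model = WorkingModel(0, np.array([[0.10, 0.30], [0.10, 0.30]]))
        state = TrialState(grid=DoseGrid(2, 2))
        state.add(Combination(1, 2), 1)
        state.add(Combination(1, 1), 0)
        fit = fit_working_model(model, state)
        lam_grid = np.logspace(-4, 4, 1_000_000)
        ll = lam_grid * np.log(0.30) + np.log1p(-0.10**lam_grid)
        lam_best = lam_grid[np.argmax(ll)]
        assert np.allclose(
            fit.dlt_estimates, model.skeleton**lam_best, atol=1e-4
        )

    def test_mle_dominates_random_alternatives(self, interim_state, models):
        rng = np.random.default_rng(3)
        fit = fit_working_model(models[1], interim_state)
        for a in rng.uniform(-10, 10, 100):
            assert fit.loglik >= power_model_loglik(models[1], interim_state, a) - 1e-9

    def test_fitted_probabilities_follow_power_form(self, interim_state, models):
        fit = fit_working_model(models[0], interim_state)
        assert np.allclose(
            fit.dlt_estimates, fit.model.skeleton ** math.exp(fit.a_hat)
        )


class TestModelSelection:
    def test_largest_likelihood_wins(self):
        fits = [
            ModelFit(None, 0.0, -3.0, None),
            ModelFit(None, 0.0, -2.5, None),
        ]
        assert select_working_model(fits, np.random.default_rng(0)) == 1

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            select_working_model([], np.random.default_rng(0))

    def test_exact_tie_resolved_uniformly(self):
        fits = [ModelFit(None, 0.0, -4.2, None), ModelFit(None, 0.0, -4.2, None)]
        rng = np.random.default_rng(7)
        picks = np.array([select_working_model(fits, rng) for _ in range(10_000)])
        assert abs(picks.mean() - 0.5) < 0.02

    def test_row_one_only_data_ties_the_shift_models(self, interim_state, models):
        # Both models share the row-1 skeleton, so data confined to row 1
        # cannot distinguish them; the tie-break rule decides.
        fits = [fit_working_model(m, interim_state) for m in models]
        assert fits[0].loglik == pytest.approx(fits[1].loglik, abs=1e-9)

    def test_interim_recommendations_under_the_shifted_model(self, interim_state, models):
        # With the first DLT at row-1 level 5, the shift -1 model recommends
        # row-1 level 5 and row-2 level 4 (one level lower).
        shifted = next(m for m in models if m.shift == -1)
        fit = fit_working_model(shifted, interim_state)
        assert row_recommendations(fit, 0.30) == (5, 4)

    def test_borrowing_updates_untried_row(self, interim_state, models):
        # Row 2 has no patients yet, but its fitted probabilities move away
        # from the prior skeleton because the power parameter is shared.
        fit = fit_working_model(models[1], interim_state)
        assert not np.allclose(fit.dlt_estimates[1], fit.model.skeleton[1])

    def test_recommended_levels_differ_by_model_shift(self, interim_state, models):
        for model in models:
            fit = fit_working_model(model, interim_state)
            rec = row_recommendations(fit, 0.30)
            assert rec[1] - rec[0] == model.shift


class TestRowRecommendations:
    def test_closest_and_tie_rules(self):
        fit = ModelFit(None, 0.0, 0.0, np.array([[0.10, 0.28, 0.50]]))
        assert row_recommendations(fit, 0.30) == (2,)
        fit = ModelFit(None, 0.0, 0.0, np.array([[0.25, 0.35, 0.60]]))
        assert row_recommendations(fit, 0.30) == (1,)


class TestInitialEscalation:
    def test_path_walks_row_one_then_row_two(self, config):
        assert initial_escalation_next(make_state([], config)) == Combination(1, 1)
        three_clear = make_state([(1, j, 0) for j in range(1, 4)], config)
        assert initial_escalation_next(three_clear) == Combination(1, 4)
        row1_done = make_state([(1, j, 0) for j in range(1, 8)], config)
        assert initial_escalation_next(row1_done) == Combination(2, 1)
        all_done = make_state(
            [(1, j, 0) for j in range(1, 8)] + [(2, j, 0) for j in range(1, 8)], config
        )
        assert initial_escalation_next(all_done) == Combination(2, 7)

    def test_all_dlt_data_repeat_the_lowest_dose(self, config):
        state = make_state([(1, 1, 1)], config)
        assert state.stage == STAGE_INITIAL
        assert initial_escalation_next(state) == Combination(1, 1)

    def test_wrong_stage_rejected(self, interim_state):
        with pytest.raises(WrongStageError):
            initial_escalation_next(interim_state)

    def test_stage_flips_exactly_at_first_heterogeneity(self, config):
        outcomes = [0, 0, 1, 1, 0]
        state = make_state([], config)
        seen_both = False
        for j, y in enumerate(outcomes, start=1):
            state.add(Combination(1, min(j, 7)), y)
            seen_both = seen_both or (0 < state.n_dlt < state.n_patients)
            assert state.stage == (STAGE_MODELING if seen_both else STAGE_INITIAL)


class TestNextAssignment:
    def test_complete_trial_returns_none(self, config, models):
        state = make_state([(1, 1, 0)] * 20 + [(1, 2, 1)] * 19, config)
        assert state.n_patients == config.n_max
        assert next_assignment(state, config, models, np.random.default_rng(0)) is None

    def test_modeling_stage_randomizes_rows_equally(self, interim_state, config, models):
        fits = [fit_working_model(m, interim_state) for m in models]
        possible = {
            Combination(r + 1, row_recommendations(f, config.target)[r])
            for f in fits
            for r in range(2)
        }
        rng = np.random.default_rng(11)
        rows = np.empty(10_000)
        for i in range(10_000):
            combo = next_assignment(interim_state, config, models, rng)
            assert combo in possible
            rows[i] = combo.row
        assert abs((rows == 1).mean() - 0.5) < 0.02


class TestSafetyStop:
    def test_no_patients_at_lowest_dose(self, config):
        assert not safety_stop(make_state([], config), config)
        assert not safety_stop(make_state([(1, 2, 1)] * 5, config), config)

    def test_three_of_three_dlts_stop(self, config):
        state = make_state([(1, 1, 1)] * 3, config)
        assert safety_stop(state, config)
        # closed-form Clopper-Pearson lower bound for x = n: alpha^(1/n)
        assert 0.1 ** (1 / 3) == pytest.approx(0.464, abs=5e-4)

    def test_one_of_six_does_not_stop(self, config):
        state = make_state([(1, 1, 1)] + [(1, 1, 0)] * 5, config)
        assert not safety_stop(state, config)


class TestFinalSelection:
    def test_safety_stopped_trial_selects_nothing(self, config, models):
        state = make_state([(1, 1, 1)] * 3, config)
        pair = final_selection(state, config, models, np.random.default_rng(0), True)
        assert pair == (None, None)

    def test_dlt_free_trial_recommends_highest_tried_levels(self, config, models):
        state = make_state(
            [(1, j, 0) for j in range(1, 8)] + [(2, j, 0) for j in range(1, 6)], config
        )
        pair = final_selection(state, config, models, np.random.default_rng(0))
        assert pair == (7, 5)

    def test_selected_pair_never_reverses(self, design, illustration):
        for t in range(200):
            res = design.simulate_trial(
                illustration, np.random.default_rng((7, t))
            )
            m1, m2 = res.final_mtd
            if m1 is not None and m2 is not None:
                assert m2 <= m1


def test_mle_agrees_with_dense_grid_on_random_datasets(models):
    # Spot check of likelihood unimodality: interior optimum vs grid refine.
    rng = np.random.default_rng(99)
    model = models[1]
    for _ in range(100):
        n_pat = int(rng.integers(2, 30))
        recs = []
        for _ in range(n_pat):
            recs.append((int(rng.integers(1, 3)), int(rng.integers(1, 8)), int(rng.integers(2))))
        if not (0 < sum(r[2] for r in recs) < n_pat):
            continue
        state = make_state(recs)
        fit = fit_working_model(model, state)
        n, x = state.counts()
        mask = n.ravel() > 0
        logq = np.log(model.skeleton.ravel()[mask])
        nv, xv = n.ravel()[mask], x.ravel()[mask]

        def grid_ll(a_values):
            s = np.exp(a_values)[:, None] * logq[None, :]
            return (xv * s + (nv - xv) * np.log1p(-np.exp(s))).sum(axis=1)

        a_grid = np.linspace(-10, 10, 4001)
        a0 = a_grid[int(np.argmax(grid_ll(a_grid)))]
        fine = np.linspace(a0 - 0.01, a0 + 0.01, 2001)
        a_best = fine[int(np.argmax(grid_ll(fine)))]
        assert math.exp(fit.a_hat) == pytest.approx(math.exp(a_best), abs=1e-3)
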