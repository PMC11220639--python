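"""Correction formula, step finder, state peaks and pattern calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligbend.fret import (
    CorrectionParams,
    EfficiencyTrace,
    StateModel,
    StepFit,
    StepFitConfig,
    classify_trace,
    correct_trace,
    fit_steps,
    locate_state_peaks,
    pattern_percentages,
)
from ligbend.simulate import FluorescenceTrace, TraceGenParams, simulate_trace


def make_eff_trace(values) -> EfficiencyTrace:
    return EfficiencyTrace(efficiency=np.asarray(values, dtype=float))


class TestCorrection:
    def test_neutral_calibration_is_the_plain_ratio(self):
        tr = FluorescenceTrace(donor=[70.0], acceptor=[30.0])
        eff = correct_trace(tr, CorrectionParams())
        assert eff.efficiency[0] == pytest.approx(0.3)

    def test_gamma_rescales_the_donor_term(self):
        tr = FluorescenceTrace(donor=[70.0], acceptor=[30.0])
        eff = correct_trace(tr, CorrectionParams(gamma=2.0))
        assert eff.efficiency[0] == pytest.approx(30 / 170)  # 0.17647...

    def test_background_and_crosstalk_are_subtracted(self):
        # D' = 100, A' = 60 - 0.1*100 = 50 -> E = 1/3
        tr = FluorescenceTrace(donor=[110.0], acceptor=[80.0])
        cal = CorrectionParams(
            background_donor=10.0, background_acceptor=20.0, crosstalk_alpha=0.1
        )
        assert correct_trace(tr, cal).efficiency[0] == pytest.approx(1 / 3)

    def test_matched_roundtrip_is_exact_for_pattern_one(self):
        p = TraceGenParams(noise_sd=0.0, seed=0)
        tr = simulate_trace(p, "I")
        eff = correct_trace(tr, CorrectionParams.from_generation(p))
        assert np.all(eff.efficiency == 0.27)

    def test_dead_frames_are_flagged_not_fatal(self):
        tr = FluorescenceTrace(donor=[70, 0.0, 70], acceptor=[30, 0.0, 30])
        eff = correct_trace(tr, CorrectionParams())
        assert list(eff.flagged) == [False, True, False]

    def test_all_dead_trace_raises(self):
        tr = FluorescenceTrace(donor=[0.0, 0.0], acceptor=[0.0, 0.0])
        with pytest.raises(ValueError, match="usable signal"):
            correct_trace(tr, CorrectionParams())


class TestStepFinder:
    def test_single_noiseless_step_recovered_exactly(self):
        y = np.concatenate([np.full(100, 0.27), np.full(100, 0.67)])
        fit = fit_steps(make_eff_trace(y))
        assert [(s, e) for s, e, _ in fit.plateaus] == [(0, 100), (100, 200)]
        assert fit.means == pytest.approx([0.27, 0.67])

    def test_constant_trace_yields_one_plateau(self):
        fit = fit_steps(make_eff_trace(np.full(150, 0.42)))
        assert len(fit.plateaus) == 1
        assert fit.plateaus[0] == (0, 150, pytest.approx(0.42))

    def test_multistep_noiseless_staircase_recovered_exactly(self):
        levels = [0.27, 0.67, 0.27, 0.88, 0.27]
        y = np.concatenate([np.full(40, v) for v in levels])
        fit = fit_steps(make_eff_trace(y))
        assert [(s, e) for s, e, _ in fit.plateaus] == [
            (i * 40, (i + 1) * 40) for i in range(5)
        ]
        assert fit.means == pytest.approx(levels)

    def test_plateaus_always_tile_the_frame_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(0.5, 0.1, rng.integers(20, 200))
            fit = fit_steps(make_eff_trace(y))
            edges = [s for s, _, _ in fit.plateaus] + [fit.plateaus[-1][1]]
            assert edges[0] == 0 and edges[-1] == y.size
            assert all(a < b for a, b in zip(edges, edges[1:]))

    def test_noisy_change_points_recovered_within_two_frames(self):
        # two-state trace, gap 0.4, noise sd 0.1, 50-frame plateaus
        rng = np.random.default_rng(1)
        hits = total = 0
        for _ in range(200):
            y = np.concatenate([np.full(50, 0.3), np.full(50, 0.7)])
            y = y + rng.normal(0, 0.1, 100)
            fit = fit_steps(make_eff_trace(y))
            total += 1
            boundaries = [s for s, _, _ in fit.plateaus[1:]]
            hits += any(abs(b - 50) <= 2 for b in boundaries)
        assert hits / total >= 0.95

    def test_pure_noise_is_called_step_free(self):
        rng = np.random.default_rng(2)
        step_free = sum(
            len(fit_steps(make_eff_trace(rng.normal(0.27, 0.08, 200))).plateaus) == 1
            for _ in range(50)
        )
        assert step_free >= 45  # quality threshold suppresses spurious steps

    def test_merge_tolerance_joins_near_equal_plateaus(self):
        y = np.concatenate([np.full(50, 0.27), np.full(50, 0.30), np.full(50, 0.7)])
        fit = fit_steps(make_eff_trace(y), StepFitConfig(merge_tolerance=0.08))
        assert len(fit.plateaus) == 2

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_steps(make_eff_trace([0.1, 0.2, 0.3]), StepFitConfig())


class TestStatePeaks:
    def test_tight_single_cluster_selects_one_component(self):
        rng = np.random.default_rng(3)
        model = locate_state_peaks(rng.normal(0.27, 0.01, 200), k_max=4)
        assert model.k == 1
        assert model.centers[0] == pytest.approx(0.27, abs=0.01)

    def test_four_separated_clusters_recovered(self):
        rng = np.random.default_rng(4)
        truth = [0.27, 0.42, 0.67, 0.88]
        means = np.concatenate(
            [rng.normal(c, 0.02, 150) for c in truth]
        )
        model = locate_state_peaks(means, k_max=4)
        assert model.k == 4
        assert model.centers == pytest.approx(truth, abs=0.01)

    def test_peak_location_is_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        means = np.concatenate([rng.normal(c, 0.03, 80) for c in (0.3, 0.7)])
        a = locate_state_peaks(means, seed=7)
        b = locate_state_peaks(means, seed=7)
        assert np.array_equal(a.centers, b.centers)

    def test_too_few_plateaus_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            locate_state_peaks([0.3, 0.4, 0.5], k_max=4)


def _fit(plateaus, n):
    return StepFit(plateaus=plateaus, n_frames=n, rss=0.0)


@pytest.fixture()
def four_state_model():
    return StateModel(
        centers=np.array([0.27, 0.42, 0.67, 0.88]), assignment_halfwidth=0.06
    )


class TestClassification:
    def test_low_only_trace_is_pattern_one(self, four_state_model):
        fit = _fit([(0, 100, 0.27)], 100)
        assert classify_trace(fit, four_state_model).pattern == "I"

    def test_recurring_single_high_state_is_its_pattern(self, four_state_model):
        fit = _fit(
            [(0, 50, 0.27), (50, 80, 0.67), (80, 120, 0.27), (120, 150, 0.67)],
            150,
        )
        a = classify_trace(fit, four_state_model)
        assert a.pattern == "III"
        assert a.n_excursions == 2

    def test_two_distinct_high_states_make_mixed(self, four_state_model):
        fit = _fit(
            [(0, 50, 0.27), (50, 80, 0.42), (80, 110, 0.67), (110, 150, 0.27)],
            150,
        )
        assert classify_trace(fit, four_state_model).pattern == "mixed"

    def test_long_out_of_window_plateau_unassigns_trace(self, four_state_model):
        fit = _fit([(0, 50, 0.27), (50, 100, 0.55)], 100)
        assert classify_trace(fit, four_state_model).pattern == "unassigned"

    def test_short_transition_artifacts_are_ignored(self, four_state_model):
        fit = _fit(
            [(0, 50, 0.27), (50, 54, 0.55), (54, 100, 0.88)], 100
        )
        a = classify_trace(fit, four_state_model)
        assert a.pattern == "IV"

    def test_classification_is_stable_under_trace_order(self, four_state_model):
        fits = [
            _fit([(0, 100, 0.27)], 100),
            _fit([(0, 40, 0.27), (40, 100, 0.42)], 100),
            _fit([(0, 40, 0.27), (40, 100, 0.88)], 100),
        ]
        forward = [classify_trace(f, four_state_model).pattern for f in fits]
        backward = [
            classify_trace(f, four_state_model).pattern for f in reversed(fits)
        ]
        assert forward == backward[::-1]


class TestPatternPercentages:
    def test_uniform_assignments_give_degenerate_distribution(self, four_state_model):
        fits = [_fit([(0, 100, 0.27)], 100) for _ in range(10)]
        assigns = [classify_trace(f, four_state_model) for f in fits]
        df = pattern_percentages(assigns, n_bootstrap=100, seed=0)
        row = df[df["pattern"] == "I"].iloc[0]
        assert row["fraction"] == 1.0
        assert row["ci_low"] == row["ci_high"] == 1.0

    def test_bootstrap_is_deterministic_under_seed(self, four_state_model):
        rng = np.random.default_rng(6)
        fits = [
            _fit([(0, 100, rng.choice([0.27, 0.42]))], 100) for _ in range(50)
        ]
        assigns = [classify_trace(f, four_state_model) for f in fits]
        a = pattern_percentages(assigns, n_bootstrap=200, seed=3)
        b = pattern_percentages(assigns, n_bootstrap=200, seed=3)
        assert a.equals(b)

    def test_no_assigned_traces_rejected(self, four_state_model):
        fit = _fit([(0, 100, 0.55)], 100)
        assigns = [classify_trace(fit, four_state_model)]
        with pytest.raises(ValueError, match="no assigned"):
            pattern_percentages(assigns)


class TestEnsembleRecovery:
    def test_pattern_fractions_recover_generator_proportions(self, reference_results):
        """2000-trace end-to-end recovery within 3-sigma binomial bounds."""
        df = reference_results.percentages
        n = df.attrs["n_assigned"]
        for pattern, p_true in zip(("I", "II", "III", "IV"), (0.55, 0.25, 0.12, 0.08)):
            frac = float(df[df["pattern"] == pattern]["fraction"].iloc[0])
            assert abs(frac - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n), pattern

    def test_state_centers_recover_generator_efficiencies(self, reference_results):
        centers = reference_results.states.centers
        assert centers == pytest.approx([0.27, 0.42, 0.67, 0.88], abs=0.03)
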