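"""Bow-construct mechanics: chord geometry, FJC statistics, bend angles.

The bend-angle distribution is checked against an independent oracle: the
exact radial density of a discrete freely jointed chain (the classical
alternating-sum formula, evaluated in exact rational arithmetic to dodge
catastrophic cancellation) pushed through the same hinge-reweighting by
quadrature on a fine grid.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ligbend import defaults
from ligbend.mechanics import (
    BowConstruct,
    ConformerGeometry,
    SsDNAParams,
    bend_angle_distribution,
    calibrate_forster_radius,
    chord_length,
    classify_complex,
    fjc_end_to_end_samples,
    fjc_radial_density,
    fret_vs_angle,
    gaussian_radial_density,
    measure_bend_angle,
    min_bend_angle,
)


def exact_fjc_radial_density(r: float, n_seg: int, b: float) -> float:
    """Closed-form radial density of an N-segment FJC (unit steps scaled by b).

    f_N(x) = x / (2^(N-1) (N-2)!) * sum_k (-1)^k C(N,k) (N - x - 2k)^(N-2)
    for x = r/b in [0, N]; evaluated with Fractions for numerical exactness.
    """
    x = Fraction(r / b).limit_denominator(10**12)
    if x < 0 or x > n_seg:
        return 0.0
    total = Fraction(0)
    k_max = int((n_seg - x) / 2)
    for k in range(k_max + 1):
        term = Fraction(math.comb(n_seg, k)) * (n_seg - x - 2 * k) ** (n_seg - 2)
        total += -term if k % 2 else term
    dens = x * total / (2 ** (n_seg - 1) * Fraction(math.factorial(n_seg - 2)))
    return float(dens) / b  # per nm


class TestChordGeometry:
    def test_straight_duplex_spans_two_arm_lengths(self):
        c = BowConstruct(linker_nt=10)
        assert chord_length(0.0, c) == pytest.approx(17.0)

    def test_fully_folded_duplex_has_zero_chord(self):
        assert chord_length(180.0, BowConstruct()) == pytest.approx(0.0, abs=1e-12)

    def test_sixty_degree_chord_matches_closed_form(self):
        assert chord_length(60.0, BowConstruct()) == pytest.approx(14.722431864, abs=1e-6)

    def test_chord_is_strictly_decreasing_in_bend_angle(self):
        thetas = np.linspace(0, 180, 200)
        d = chord_length(thetas, BowConstruct())
        assert np.all(np.diff(d) < 0)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            chord_length(181.0, BowConstruct())


class TestFJC:
    def test_radial_density_normalizes_to_one(self):
        ss = SsDNAParams()
        n_seg = ss.n_segments(30)
        r = np.linspace(0, n_seg * ss.kuhn_length, 2000)
        dens = fjc_radial_density(r, 30, ss, n_samples=100_000, seed=0)
        assert np.trapezoid(dens, r) == pytest.approx(1.0, abs=1e-6)

    def test_density_vanishes_beyond_contour_length(self):
        ss = SsDNAParams()
        l_max = ss.n_segments(20) * ss.kuhn_length
        assert fjc_radial_density(l_max * 1.01, 20, ss) == 0.0

    def test_mean_square_extension_matches_ideal_chain(self):
        ss = SsDNAParams()
        n_seg = ss.n_segments(80)
        r = fjc_end_to_end_samples(80, ss, n_samples=100_000, seed=1)
        expected = n_seg * ss.kuhn_length**2
        se = np.std(r**2, ddof=1) / np.sqrt(r.size)
        assert abs(np.mean(r**2) - expected) < 3 * se

    def test_monte_carlo_density_matches_exact_formula(self):
        ss = SsDNAParams()
        for linker in (10, 30):
            n_seg = ss.n_segments(linker)
            grid = np.linspace(0.1, n_seg * ss.kuhn_length * 0.95, 40)
            mc = fjc_radial_density(grid, linker, ss, n_samples=400_000, seed=2)
            exact = np.array(
                [exact_fjc_radial_density(r, n_seg, ss.kuhn_length) for r in grid]
            )
            assert np.max(np.abs(mc - exact)) < 0.02  # density units: per nm

    def test_gaussian_limit_agrees_for_long_chains(self):
        ss = SsDNAParams()
        grid = np.linspace(1, 25, 30)
        mc = fjc_radial_density(grid, 80, ss, n_samples=400_000, seed=3)
        gauss = gaussian_radial_density(grid, 80, ss)
        assert np.max(np.abs(mc - gauss)) < 0.01

    def test_zero_length_linker_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fjc_radial_density(0.5, 0)


class TestBendAngleDistribution:
    def test_distribution_normalizes(self):
        dist = bend_angle_distribution(BowConstruct(linker_nt=30), seed=0)
        assert np.sum(dist.weights) == pytest.approx(1.0)

    @pytest.mark.parametrize("linker", [10, 30, 80])
    def test_matches_exact_density_quadrature_within_tv(self, linker):
        """Monte-Carlo sampler vs closed-form quadrature of the same model."""
        construct = BowConstruct(linker_nt=linker)
        dist = bend_angle_distribution(construct, n_samples=400_000, seed=4)
        grid = np.arange(0.0, 180.5, 1.0)
        impl = dist.density_on_grid(grid)
        # oracle: P(theta) ~ sin(theta) rho(d) |dd/dtheta| with exact rho
        ss = construct.ssdna
        n_seg = ss.n_segments(linker)
        centers = 0.5 * (grid[:-1] + grid[1:])
        a = construct.arm_length_nm
        d = 2 * a * np.cos(np.radians(centers) / 2)
        jac = a * np.sin(np.radians(centers) / 2) * np.pi / 180.0
        rho = np.array(
            [exact_fjc_radial_density(x, n_seg, ss.kuhn_length) for x in d]
        )
        oracle = np.sin(np.radians(centers)) * rho * jac
        oracle /= oracle.sum()
        tv = 0.5 * np.sum(np.abs(impl - oracle))
        assert tv < 0.05

    def test_zero_length_linker_concentrates_at_full_fold(self):
        dist = bend_angle_distribution(BowConstruct(linker_nt=0))
        assert dist.degenerate
        assert dist.quantile(0.5) == pytest.approx(180.0, abs=1e-6)

    def test_unconstrained_construct_follows_the_free_hinge_law(self):
        dist = bend_angle_distribution(BowConstruct(linker_nt=None))
        grid = np.arange(0.0, 180.5, 1.0)
        dens = dist.density_on_grid(grid)
        centers = 0.5 * (grid[:-1] + grid[1:])
        expected = np.sin(np.radians(centers))
        expected /= expected.sum()
        assert 0.5 * np.sum(np.abs(dens - expected)) < 0.01


class TestMinBendAngle:
    def test_grid_endpoints_match_the_calibrated_range(self):
        # 10 nt -> ~130 deg, 80 nt -> ~10 deg at the default quantile
        assert min_bend_angle(BowConstruct(linker_nt=10), seed=0) == pytest.approx(
            130.0, abs=15.0
        )
        assert min_bend_angle(BowConstruct(linker_nt=80), seed=0) == pytest.approx(
            10.0, abs=8.0
        )

    def test_monotone_non_increasing_in_linker_length(self):
        angles = [
            min_bend_angle(BowConstruct(linker_nt=L), seed=0)
            for L in defaults.LINKER_GRID_NT
        ]
        assert all(a >= b for a, b in zip(angles, angles[1:]))

    def test_monotone_non_decreasing_in_quantile(self):
        c = BowConstruct(linker_nt=40)
        dist_qs = [
            min_bend_angle(c, quantile=q, seed=0) for q in (0.001, 0.01, 0.1, 0.5)
        ]
        assert all(a <= b for a, b in zip(dist_qs, dist_qs[1:]))

    def test_quantile_level_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            min_bend_angle(BowConstruct(linker_nt=40), quantile=0.9)


class TestFretVsAngle:
    def test_straight_dna_reads_the_unbound_efficiency(self):
        assert fret_vs_angle(0.0) == pytest.approx(0.27, abs=0.01)

    def test_calibration_inverts_the_forster_equation(self):
        r0 = calibrate_forster_radius(0.27)
        assert r0 == pytest.approx(defaults.DEFAULT_FORSTER_RADIUS_NM, abs=1e-3)

    def test_hundred_degree_bend_matches_hand_evaluation(self):
        # r = 7.14 cos(50 deg) = 4.58950 nm; E = 1/(1+(r/6.0493)^6)
        assert fret_vs_angle(100.0) == pytest.approx(0.8398381, abs=1e-6)

    def test_efficiency_is_strictly_increasing_in_bend(self):
        thetas = np.linspace(0, 179.9, 300)
        eff = fret_vs_angle(thetas)
        assert np.all(np.diff(eff) > 0)

    def test_conformer_angles_map_to_ordered_efficiencies(self):
        eff = [fret_vs_angle(t) for t in defaults.CONFORMER_ANGLES_DEG]
        assert all(a < b for a, b in zip(eff, eff[1:]))


def _two_arm_cloud(bend_deg: float, n: int = 60, noise: float = 0.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    inter = math.radians(180.0 - bend_deg)
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([math.cos(inter), math.sin(inter), 0.0])
    pts, labels = [], []
    for u, name in ((u1, "arm1"), (u2, "arm2")):
        t = np.linspace(0.1, 8.5, n)
        arm = t[:, None] * u[None, :]
        if noise:
            arm = arm + rng.normal(0, noise, arm.shape)
        pts.append(arm)
        labels += [name] * n
    return np.vstack(pts), np.array(labels)


class TestMeasureBendAngle:
    def test_collinear_arms_measure_zero(self):
        pts, labels = _two_arm_cloud(0.0)
        assert measure_bend_angle(pts, labels) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_arms_measure_ninety(self):
        pts, labels = _two_arm_cloud(90.0)
        assert measure_bend_angle(pts, labels) == pytest.approx(90.0, abs=1e-9)

    def test_noisy_measurement_is_unbiased_at_sixty_degrees(self):
        measured = [
            measure_bend_angle(*_two_arm_cloud(60.0, n=200, noise=0.3, seed=s))
            for s in range(100)
        ]
        assert np.mean(measured) == pytest.approx(60.0, abs=2.0)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_rigid_motions(self, seed):
        rng = np.random.default_rng(seed)
        bend = float(rng.uniform(5, 170))
        pts, labels = _two_arm_cloud(bend, seed=seed)
        base = measure_bend_angle(pts, labels)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        shift = rng.normal(0, 50, 3)
        moved = pts @ rot.T + shift
        assert measure_bend_angle(moved, labels) == pytest.approx(base, abs=1e-9)

    def test_degenerate_arm_rejected(self):
        pts = np.vstack([np.zeros((5, 3)), np.eye(3)])
        labels = np.array(["arm1"] * 5 + ["arm2"] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            measure_bend_angle(pts, labels)


class TestClassifyComplex:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (0.0, "I"),
            (100.0, "IV"),
            (9.9, "I"),
            (10.1, "II"),
            (10.0, "I"),  # midpoint tie goes to the smaller class
            (39.9, "II"),
            (40.1, "III"),
            (79.9, "III"),
            (80.1, "IV"),
            (179.0, "IV"),
        ],
    )
    def test_nearest_angle_rule_with_ties_down(self, angle, expected):
        assert classify_complex(angle) == expected

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            classify_complex(180.0)
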