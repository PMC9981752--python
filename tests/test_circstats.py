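"""Circular statistics: resultant vectors, tests, correlations, phase rules."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chorodiurnal.circstats import (
    AngleSample,
    PhaseRelationKind,
    circular_deviation,
    fisher_lee_correlation,
    mann_whitney_u,
    mean_resultant,
    phase_relation,
    rayleigh_p,
    rayleigh_test,
    spearman_rho,
    watson_u2_statistic,
    watson_u2_two_sample,
)

TWO_PI = 2 * math.pi


class TestMeanResultant:
    def test_identical_angles_r_is_one(self):
        r, mean = mean_resultant(AngleSample((1.3,) * 10))
        assert r == pytest.approx(1.0)
        assert mean == pytest.approx(1.3)

    def test_antipodal_pair_cancels(self):
        r, mean = mean_resultant(AngleSample((0.0, math.pi)))
        assert r == pytest.approx(0.0, abs=1e-12)
        assert mean is None

    def test_quarter_turn_pair(self):
        r, _ = mean_resultant(AngleSample((0.0, math.pi / 2)))
        assert r == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    @given(rot=st.floats(0.0, TWO_PI))
    def test_r_invariant_under_rotation(self, rot):
        angles = (0.1, 0.5, 2.0, 4.4, 5.1)
        r0, _ = mean_resultant(AngleSample(angles))
        r1, _ = mean_resultant(AngleSample(tuple(a + rot for a in angles)))
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestRayleigh:
    def test_reported_r_gives_significant_p(self):
        assert rayleigh_p(44, 0.44) < 0.001

    def test_uniform_grid_not_clustered(self):
        angles = tuple(np.linspace(0, TWO_PI, 44, endpoint=False))
        res = rayleigh_test(AngleSample(angles))
        assert res.r == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.99

    def test_agrees_with_independent_implementation(self, rng):
        import pingouin as pg

        for _ in range(5):
            angles = rng.uniform(0, TWO_PI, 30)
            ours = rayleigh_test(AngleSample(tuple(angles)))
            z, p_ref = pg.circ_rayleigh(angles)
            assert ours.p == pytest.approx(p_ref, rel=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(AngleSample((0.0, 1.0, 2.0)))

    def test_null_pvalues_are_uniform(self):
        from chorodiurnal.experiments import rayleigh_null_pvalues

        p = np.sort(rayleigh_null_pvalues(n=44, reps=10000, seed=5))
        ecdf = np.arange(1, p.size + 1) / p.size
        ks = np.max(np.abs(ecdf - p))
        assert ks < 0.02


class TestCircularDeviation:
    def test_identical_angles_zero(self):
        assert circular_deviation(AngleSample((2.0,) * 5)) == pytest.approx(0.0)

    def test_angular_deviation_formula_at_r_044(self):
        # construct a 2-point sample with known r, then check hours conversion
        # r = cos(delta/2) for {-delta/2, +delta/2}; pick delta for r = 0.44
        delta = 2 * math.acos(0.44)
        sample = AngleSample((-delta / 2, delta / 2))
        r, _ = mean_resultant(sample)
        assert r == pytest.approx(0.44, abs=1e-12)
        expected_h = math.sqrt(2 * (1 - 0.44)) * 24 / TWO_PI
        assert circular_deviation(sample) == pytest.approx(expected_h, abs=1e-9)
        assert expected_h == pytest.approx(4.04, abs=5e-3)

    @given(rot=st.floats(0.0, TWO_PI))
    def test_invariant_under_rotation(self, rot):
        angles = (0.2, 1.1, 3.0, 5.9)
        cd0 = circular_deviation(AngleSample(angles))
        cd1 = circular_deviation(AngleSample(tuple(a + rot for a in angles)))
        assert cd1 == pytest.approx(cd0, abs=1e-9)

    def test_alternative_convention(self):
        sample = AngleSample((0.1, 0.2, 0.4, 6.0))
        assert circular_deviation(sample, method="circular_sd") > circular_deviation(
            sample, method="angular"
        )


class TestWatsonU2:
    def test_identical_samples_not_separated(self):
        angles = tuple(np.linspace(0, TWO_PI, 20, endpoint=False))
        res = watson_u2_two_sample(AngleSample(angles), AngleSample(angles), n_perm=999)
        assert res.p >= 0.5

    def test_twelve_hour_offset_detected(self, rng):
        a = AngleSample(tuple(rng.normal(0.0, 0.3, 20) % TWO_PI))
        b = AngleSample(tuple((rng.normal(0.0, 0.3, 20) + math.pi) % TWO_PI))
        res = watson_u2_two_sample(a, b, n_perm=9999, seed=1)
        assert res.p <= 0.001

    def test_degenerate_pooled_sample(self):
        a = AngleSample((1.0,) * 5)
        res = watson_u2_two_sample(a, a, n_perm=99)
        assert res.p == 1.0

    def test_statistic_invariant_under_rotation(self, rng):
        a = rng.uniform(0, TWO_PI, 12)
        b = rng.uniform(0, TWO_PI, 15)
        u0 = watson_u2_statistic(a, b)
        # rotation moves angles across the 0/2pi cut; U2 must not change
        u1 = watson_u2_statistic((a + 1.234) % TWO_PI, (b + 1.234) % TWO_PI)
        assert u1 == pytest.approx(u0, abs=1e-9)

    def test_permutation_p_reproducible(self, rng):
        a = AngleSample(tuple(rng.uniform(0, TWO_PI, 10)))
        b = AngleSample(tuple(rng.uniform(0, TWO_PI, 10)))
        r1 = watson_u2_two_sample(a, b, n_perm=499, seed=7)
        r2 = watson_u2_two_sample(a, b, n_perm=499, seed=7)
        assert r1.p == r2.p


class TestFisherLee:
    def test_equal_samples_perfect_correlation(self, rng):
        x = AngleSample(tuple(rng.uniform(0, TWO_PI, 10)))
        r, _ = fisher_lee_correlation(x, x, n_perm=99)
        assert r == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        angles = rng.uniform(0, TWO_PI, 10)
        x = AngleSample(tuple(angles))
        y = AngleSample(tuple((angles + 1.0) % TWO_PI))
        r, _ = fisher_lee_correlation(x, y, n_perm=99)
        assert r == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self, rng):
        angles = rng.uniform(0, TWO_PI, 10)
        x = AngleSample(tuple(angles))
        y = AngleSample(tuple((-angles) % TWO_PI))
        r, _ = fisher_lee_correlation(x, y, n_perm=99)
        assert r == pytest.approx(-1.0)

    def test_degenerate_sample_rejected(self, rng):
        x = AngleSample((1.0,) * 8)
        y = AngleSample(tuple(rng.uniform(0, TWO_PI, 8)))
        with pytest.raises(ValueError):
            fisher_lee_correlation(x, y, n_perm=99)


class TestPhaseRelation:
    @pytest.mark.parametrize(
        "a,b,kind",
        [
            (3.0, 4.5, PhaseRelationKind.IN_PHASE),
            (3.0, 15.5, PhaseRelationKind.ANTIPHASE),
            (3.0, 9.0, PhaseRelationKind.NEITHER),
            (23.5, 0.5, PhaseRelationKind.IN_PHASE),  # wraps midnight
        ],
    )
    def test_classification(self, a, b, kind):
        assert phase_relation(a, b).kind == kind

    @given(
        a=st.floats(0.0, 23.999),
        b=st.floats(0.0, 23.999),
    )
    def test_symmetric_in_arguments(self, a, b):
        assert phase_relation(a, b).kind == phase_relation(b, a).kind
        assert phase_relation(a, b).separation_h == pytest.approx(
            phase_relation(b, a).separation_h
        )


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.10, abs=1e-9)

    def test_identical_multisets(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.02)

    def test_all_tied_gives_p_one(self):
        _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @given(
        a=st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=6),
        b=st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=6),
    )
    def test_u_statistics_sum_to_product(self, a, b):
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [10, 20, 25, 70, 90])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        rho, p = spearman_rho([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_independent_uniforms_centered_at_zero(self, rng):
        rhos = []
        for _ in range(1000):
            x = rng.uniform(size=44)
            y = rng.uniform(size=44)
            rho, _ = spearman_rho(x, y)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.02
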