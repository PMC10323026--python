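"""Thermodynamic integration: windows, statistics, quadrature, totals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halosynergy.ti import (EmptyWindowError, LambdaWindow,
                            ThermodynamicIntegration, block_statistics,
                            discard_equilibration, integrate_leg,
                            integration_weights, mutation_free_energy,
                            replicate_statistics, window_statistics)


def make_window(times, dvdl, lam=0.5, leg="decharge"):
    return LambdaWindow(lambda_value=lam, times=np.asarray(times, float),
                        dvdl=np.asarray(dvdl, float), leg=leg)


class TestLambdaWindow:
    def test_validation(self):
        with pytest.raises(ValueError, match="outside"):
            make_window([1], [1], lam=1.5)
        with pytest.raises(ValueError, match="leg"):
            make_window([1], [1], leg="bogus")
        with pytest.raises(ValueError, match="increasing"):
            make_window([1, 1], [1, 2])
        with pytest.raises(EmptyWindowError):
            make_window([], [])


class TestDiscardEquilibration:
    def test_default_1ns_discard(self):
        w = make_window(np.arange(0.0, 5001.0), np.zeros(5001))
        out = discard_equilibration(w, 1000.0)
        assert out.times[0] == 1001.0 and out.times[-1] == 5000.0
        assert out.leg == w.leg and out.lambda_value == w.lambda_value

    def test_zero_is_identity(self):
        w = make_window([1, 2, 3], [4, 5, 6])
        out = discard_equilibration(w, 0.0)
        np.testing.assert_array_equal(out.times, w.times)
        np.testing.assert_array_equal(out.dvdl, w.dvdl)

    def test_100ps_spacing(self):
        w = make_window(100.0 * np.arange(10), np.arange(10))
        assert len(discard_equilibration(w, 450.0)) == 5

    def test_all_discarded_raises_naming_window(self):
        w = make_window([1, 2], [0, 0], lam=0.25, leg="vdw")
        with pytest.raises(EmptyWindowError, match="vdw.*0.25"):
            discard_equilibration(w, 10.0)

    def test_composition_invariance(self):
        rng = np.random.default_rng(1)
        times = np.arange(1.0, 2001.0)
        dvdl = rng.normal(size=2000)
        w = make_window(times, dvdl)
        pre = make_window(times[times > 500.0], dvdl[times > 500.0])
        a = block_statistics(discard_equilibration(w, 500.0), 5)
        b = block_statistics(pre, 5)
        assert a == b


class TestWindowStatistics:
    def test_constant_series(self):
        w = make_window(np.arange(10.0), np.full(10, 4.2))
        mean, sem = block_statistics(w, 5)
        assert mean == pytest.approx(4.2) and sem == 0.0

    def test_replicate_means(self):
        reps = [make_window(np.arange(3.0), np.full(3, v)) for v in (1, 2, 3, 4, 5)]
        mean, sem = replicate_statistics(reps)
        assert mean == pytest.approx(3.0)
        assert sem == pytest.approx(np.sqrt(2.5) / np.sqrt(5))

    def test_alternating_series_symmetry(self):
        w = make_window(np.arange(8.0), [1, -1] * 4)
        mean, _ = block_statistics(w, 2)
        assert mean == 0.0

    def test_single_block_flagged_not_zero(self):
        w = make_window(np.arange(4.0), [1, 2, 3, 4])
        with pytest.warns(UserWarning, match="SEM undefined"):
            _, sem = block_statistics(w, 1)
        assert np.isnan(sem)

    def test_dispatcher_modes(self):
        w = make_window(np.arange(10.0), np.arange(10.0))
        assert window_statistics(w, n_blocks=5) == block_statistics(w, 5)
        reps = [w, make_window(np.arange(10.0), np.arange(10.0) + 1, lam=0.5)]
        assert window_statistics(replicates=reps) == replicate_statistics(reps)
        with pytest.raises(ValueError):
            window_statistics(w, n_blocks=2, replicates=reps)


class TestIntegrateLeg:
    @pytest.mark.parametrize("method", ["spline", "trapezoid"])
    def test_linear_integrand_exact(self, method):
        grid = np.array([0, 0.25, 0.5, 0.75, 1.0])
        est = integrate_leg(grid, 2 + 3 * grid, method=method)
        assert est.delta_g == pytest.approx(3.5, abs=1e-12)

    def test_spline_matches_analytic_sine(self):
        grid = np.linspace(0, 1, 101)
        est = integrate_leg(grid, np.sin(np.pi * grid), method="spline")
        assert est.delta_g == pytest.approx(2 / np.pi, abs=1e-6)

    def test_zero_sems_propagate_to_zero(self):
        grid = np.linspace(0, 1, 5)
        est = integrate_leg(grid, grid, np.zeros(5))
        assert est.delta_g_sem == 0.0

    def test_missing_endpoint_is_hard_error(self):
        with pytest.raises(ValueError, match="endpoint"):
            integrate_leg([0.1, 0.5, 1.0], [1, 1, 1])

    def test_duplicate_lambda_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            integrate_leg([0.0, 0.5, 0.5, 1.0], [1, 1, 1, 1])

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            integrate_leg([0.0, 0.5, 1.0], [1, np.nan, 1])

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8,
                    unique=True),
           st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_methods_agree_on_linear(self, interior, a, b):
        grid = np.sort(np.array([0.0, 1.0] + interior))
        means = a + b * grid
        spl = integrate_leg(grid, means, method="spline").delta_g
        trap = integrate_leg(grid, means, method="trapezoid").delta_g
        assert spl == pytest.approx(trap, abs=1e-10)
        assert trap == pytest.approx(a + b / 2, abs=1e-10)

    def test_spline_error_decreases_on_nested_grids(self):
        errors = []
        for n in (5, 9, 17, 33, 65):
            grid = np.linspace(0, 1, n)
            est = integrate_leg(grid, np.sin(np.pi * grid), method="spline")
            errors.append(abs(est.delta_g - 2 / np.pi))
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))

    def test_sem_uses_quadrature_weights(self):
        grid = np.linspace(0, 1, 5)
        w = integration_weights(grid, "trapezoid")
        sems = np.array([0.1, 0.2, 0.3, 0.2, 0.1])
        est = integrate_leg(grid, np.ones(5), sems, method="trapezoid")
        assert est.delta_g_sem == pytest.approx(np.sqrt(np.sum((w * sems) ** 2)))


def leg_estimate(leg, dg, sem=0.0):
    return integrate_leg([0.0, 1.0], [dg, dg], [sem, sem], method="trapezoid",
                         leg=leg)


class TestMutationFreeEnergy:
    def test_total_is_leg_sum(self):
        mfe = mutation_free_energy(leg_estimate("decharge", 1.0),
                                   leg_estimate("vdw", 0.2),
                                   leg_estimate("charge", -3.0))
        assert mfe.total == pytest.approx(-1.8, abs=1e-12)

    def test_sem_quadrature_3_4_5(self):
        # per-λ sems are constant, so the trapezoid weights sum them to the
        # target per-leg sems 0.3, 0.0, 0.4 exactly
        mfe = mutation_free_energy(
            leg_estimate("decharge", 1.0, 0.3 / np.sqrt(0.5)),
            leg_estimate("vdw", 0.2, 0.0),
            leg_estimate("charge", -3.0, 0.4 / np.sqrt(0.5)))
        assert mfe.total_sem == pytest.approx(0.5, abs=1e-12)

    def test_wrong_leg_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            mutation_free_energy(leg_estimate("vdw", 1.0),
                                 leg_estimate("vdw", 0.2),
                                 leg_estimate("charge", -3.0))


class TestModel:
    def test_replicates_drive_sem(self):
        rng = np.random.default_rng(0)
        windows = []
        for lam in (0.0, 0.5, 1.0):
            for rep in range(5):
                dvdl = np.full(100, 2 + 3 * lam) + rng.normal(0, 0.1, 100)
                windows.append(LambdaWindow(lam, np.arange(1.0, 101.0), dvdl,
                                            "decharge"))
        res = ThermodynamicIntegration(windows, t_eq=0).fit("trapezoid")
        est = res.legs["decharge"]
        assert est.delta_g == pytest.approx(3.5, abs=0.05)
        assert est.delta_g_sem > 0

    def test_recovery_within_two_sem(self):
        """Estimated ΔG lies within 2×SEM of truth in ≥90 % of seeded runs."""
        from halosynergy.synth import DvdlProfile, gen_dvdl

        hits = 0
        for seed in range(100):
            profile = DvdlProfile(coefficients=(2.0, 3.0, -4.0), seed=seed)
            windows, truth = gen_dvdl(profile)
            res = ThermodynamicIntegration(windows, t_eq=0).fit("spline")
            est = res.legs["decharge"]
            hits += abs(est.delta_g - truth["exact_integral"]) <= 2 * est.delta_g_sem
        assert hits >= 90

    def test_summary_mentions_total(self):
        windows = [LambdaWindow(lam, np.arange(1.0, 51.0), np.full(50, 1.0), leg)
                   for leg in ("decharge", "vdw", "charge")
                   for lam in (0.0, 0.5, 1.0)]
        res = ThermodynamicIntegration(windows, t_eq=0).fit()
        assert "total" in res.summary()
        assert res.mutation_free_energy().total == pytest.approx(3.0)
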