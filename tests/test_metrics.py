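"""Subpopulation gating, E10/F90 extraction and Hill-curve fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from galmod import (
    HillCurveModel,
    InductionModel,
    compute_E10,
    compute_F90,
    compute_metrics,
    fit_hill_coefficient,
    induction_table,
    simulate_population,
    simulate_profile,
    simulate_reference,
    split_subpopulations,
)
from galmod.simulate import Condition, InductionProfile, PopulationSample


class TestSplit:
    def test_false_positive_rate_matches_gate_quantile(self, balanced_model):
        ref = simulate_reference(balanced_model, "uninduced", seed=1)
        other = simulate_reference(balanced_model, "uninduced", n_cells=50_000, seed=2)
        sp = split_subpopulations(other, ref)
        # binomial error around 1 - gate_quantile
        se = math.sqrt(0.01 * 0.99 / other.n_cells)
        assert sp.induced_fraction == pytest.approx(0.01, abs=4 * se)

    def test_fully_induced_sample(self, balanced_model):
        ref = simulate_reference(balanced_model, "uninduced", seed=3)
        rng = np.random.default_rng(4)
        s = PopulationSample(rng.normal(-0.5, 0.1, 20_000), Condition(glucose=0.0))
        sp = split_subpopulations(s, ref)
        assert sp.induced_fraction == pytest.approx(1.0, abs=1e-3)
        assert sp.induced_mean_log_level == pytest.approx(-0.5, abs=0.01)

    def test_known_mixture_fraction_recovered(self, balanced_model):
        ref = simulate_reference(balanced_model, "uninduced", seed=5)
        rng = np.random.default_rng(6)
        x = np.concatenate(
            [rng.normal(-3.0, 0.0875, 14_000), rng.normal(-0.6, 0.1, 6_000)]
        )
        sp = split_subpopulations(PopulationSample(x, Condition(glucose=0.1)), ref)
        assert sp.induced_fraction == pytest.approx(0.30, abs=0.02)

    def test_empty_reference_rejected(self, balanced_model):
        s = simulate_reference(balanced_model, "uninduced", n_cells=100, seed=7)
        with pytest.raises(ValueError):
            split_subpopulations(s, None)


class TestThresholdMetrics:
    def test_round_trip_recovery(self):
        """Metrics measured from a simulated profile recover the inputs."""
        m = InductionModel(E10=0.125, F90=0.0625)
        ms = compute_metrics(simulate_profile(m, seed=8))
        assert ms.E10.flag == "ok"
        assert ms.F90.flag == "ok"
        assert ms.E10.value == pytest.approx(0.125, rel=0.25)
        assert ms.F90.value == pytest.approx(0.0625, rel=0.25)
        assert ms.max_level_log == pytest.approx(-0.5, abs=0.02)

    def test_noise_free_interpolation(self):
        """Crossings read off the exact model curves land near truth.

        Samples are two-point distributions at the exact per-condition gated
        statistics, so the only error is log-linear interpolation on the
        twofold grid.
        """
        m = InductionModel(E10=0.0625, F90=0.0625)
        grid = [1 * 0.5**i for i in range(9)]
        samples = []
        n = 10_000
        for g in grid:
            f = float(m.induced_fraction(g))
            lev = float(m.mean_induced_log_level(g))
            k = round(f * n)
            x = np.concatenate([np.full(k, lev), np.full(n - k, -5.0)])
            samples.append(PopulationSample(x, Condition(glucose=g)))
        ref_un = PopulationSample(np.full(n, -5.0), Condition(glucose=2.0, galactose=0))
        ref_max = PopulationSample(np.full(n, -0.5), Condition(glucose=0, galactose=2.0))
        prof = InductionProfile(samples, uninduced_ref=ref_un, max_induction_ref=ref_max)
        e10 = compute_E10(prof)
        f90 = compute_F90(prof)
        assert e10.value == pytest.approx(0.0625, rel=0.10)
        assert f90.value == pytest.approx(0.0625, rel=0.10)

    def test_f90_lower_bound_when_always_induced(self):
        m = InductionModel(E10=0.5, F90=20.0)  # fraction stays >= 0.9 on the grid
        ms = compute_metrics(simulate_profile(m, seed=9))
        assert ms.F90.flag == "lower_bound"
        assert ms.F90.value == pytest.approx(1.0)

    def test_f90_not_reached_when_never_induced(self, balanced_model):
        ref_un = simulate_reference(balanced_model, "uninduced", seed=10)
        ref_max = simulate_reference(balanced_model, "max_induction", seed=11)
        rng = np.random.default_rng(12)
        samples = [
            PopulationSample(rng.normal(-3, 0.0875, 5_000), Condition(glucose=g))
            for g in [0.1, 0.05, 0.025, 0.0125]
        ][::-1]
        prof = InductionProfile(samples, uninduced_ref=ref_un, max_induction_ref=ref_max)
        assert compute_F90(prof).flag == "not_reached"
        assert compute_E10(prof).flag == "not_reached"

    def test_unimodal_strain_f90_flagged_lower_bound(self):
        m = InductionModel(E10=0.0078, F90=0.125)
        ms = compute_metrics(simulate_profile(m, seed=13), is_bimodal=False)
        assert ms.F90.flag == "lower_bound"

    def test_e10_invariant_to_common_rescaling(self):
        """Scaling every expression value by one factor leaves E10 unchanged."""
        m = InductionModel(E10=0.125, F90=0.0625)
        prof = simulate_profile(m, seed=14)
        e10_before = compute_E10(prof).value
        shift = math.log10(37.0)  # x37 on the linear scale
        for s in prof.samples + [prof.uninduced_ref, prof.max_induction_ref]:
            s.log_expression = s.log_expression + shift
        assert compute_E10(prof).value == pytest.approx(e10_before, rel=1e-9)

    def test_induction_table_sorted_ascending(self, bimodal_profile):
        tab = induction_table(bimodal_profile)
        assert tab["glucose"].is_monotonic_increasing
        assert len(tab) == 9


class TestHillFit:
    @pytest.mark.parametrize("n_true", [1.15, 2.95])
    def test_noise_free_fraction_round_trip(self, n_true):
        m = InductionModel(E10=0.1, F90=0.05, n_frac=n_true)
        g = np.array([1 * 0.5**i for i in range(9)])
        res = fit_hill_coefficient(g, m.induced_fraction(g), kind="fraction")
        assert res.converged
        assert res.n == pytest.approx(n_true, abs=1e-3)
        assert res.threshold == pytest.approx(0.05, rel=1e-3)

    @pytest.mark.parametrize("n_true", [0.84, 1.15, 1.50])
    def test_noise_free_level_round_trip(self, n_true):
        m = InductionModel(E10=0.2, F90=0.05, n_level=n_true)
        g = np.array([1 * 0.5**i for i in range(9)])
        res = fit_hill_coefficient(g, m.mean_induced_log_level(g), kind="level")
        assert res.n == pytest.approx(n_true, abs=1e-3)
        assert res.threshold == pytest.approx(0.2, rel=1e-3)

    def test_two_point_curve_rejected(self):
        with pytest.raises(ValueError):
            HillCurveModel([0.1, 0.2], [0.9, 0.5], kind="fraction")

    def test_from_dataframe_and_summary(self):
        m = InductionModel(E10=0.1, F90=0.05)
        g = np.array([1 * 0.5**i for i in range(9)])
        df = pd.DataFrame({"glucose": g, "induced_fraction": m.induced_fraction(g)})
        res = HillCurveModel.from_dataframe(df, kind="fraction").fit()
        assert "F90" in res.summary()
        assert res.threshold == pytest.approx(0.05, rel=1e-3)

    def test_metrics_with_hill_fit(self):
        m = InductionModel(E10=0.125, F90=0.0625)
        ms = compute_metrics(simulate_profile(m, seed=15), fit_hill=True)
        assert ms.fitted_n_frac == pytest.approx(m.n_frac, rel=0.35)
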