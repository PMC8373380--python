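"""Gaussian curve fitting and the unimodal/bimodal decision rule."""

import dataclasses

import numpy as np
import pytest

from galmod import (
    InductionModel,
    ModalityThresholds,
    aggregate_modality,
    classify_condition,
    classify_profile,
    fit_gaussians,
    simulate_profile,
)
from galmod.modality import FitError, HistogramGaussianModel
from galmod.simulate import Condition, PopulationSample

from conftest import make_two_component_sample


def gaussian_sample(mean, sd, n=20_000, seed=0):
    rng = np.random.default_rng(seed)
    return PopulationSample(rng.normal(mean, sd, n), Condition(glucose=0.1))


class TestFitGaussians:
    def test_single_gaussian_is_well_fit_by_one_component(self):
        fit = fit_gaussians(gaussian_sample(-1.5, 0.3, seed=1), k=1)
        assert fit.converged
        assert fit.adj_r2 >= 0.99
        assert fit.means[0] == pytest.approx(-1.5, abs=0.02)

    def test_balanced_mixture_rejects_one_component(self):
        s = make_two_component_sample(12.5, 0.5, seed=2)  # means -3 / -0.5, sd 0.2
        assert fit_gaussians(s, k=1).adj_r2 < 0.99

    def test_two_component_parameter_recovery(self):
        s = make_two_component_sample(12.5, 0.5, seed=2)
        fit = fit_gaussians(s, k=2)
        means = np.sort(fit.means)
        assert means == pytest.approx([-3.0, -0.5], abs=0.1)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.05)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_mixture_recovery(self):
        """Minor mode far from the percentile split still recovered."""
        s = make_two_component_sample(12.5, 0.2, seed=3)
        fit = fit_gaussians(s, k=2)
        assert fit.minor_fraction == pytest.approx(0.2, abs=0.03)

    def test_recovery_agrees_with_em_mixture_oracle(self):
        """Independent route: likelihood-based EM on the raw cells."""
        from sklearn.mixture import GaussianMixture

        s = make_two_component_sample(10.0, 0.3, seed=4)
        fit = fit_gaussians(s, k=2)
        gm = GaussianMixture(2, random_state=0).fit(s.log_expression[:, None])
        em_means = np.sort(gm.means_.ravel())
        em_weights = gm.weights_[np.argsort(gm.means_.ravel())]
        assert np.sort(fit.means) == pytest.approx(em_means, abs=0.05)
        assert fit.weights[np.argsort(fit.means)] == pytest.approx(em_weights, abs=0.03)

    def test_zero_variance_sample_raises(self):
        x = np.full(500, -2.0)
        with pytest.raises(FitError):
            HistogramGaussianModel(x, 1)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussians(np.zeros(50), k=1)

    def test_summary_mentions_fit_quality(self):
        fit = fit_gaussians(gaussian_sample(-1.0, 0.2, seed=5), k=1)
        assert "adj R2" in fit.summary()


class TestClassifyCondition:
    def test_clear_bimodal(self):
        call = classify_condition(make_two_component_sample(4.0, 0.5, seed=6))
        assert call.is_bimodal is True
        assert call.separation_over_maxsd > 2.0
        assert call.minor_fraction > 0.15

    def test_well_separated_but_minor_below_threshold(self):
        call = classify_condition(make_two_component_sample(8.0, 0.10, seed=7))
        assert call.is_bimodal is False
        assert call.minor_fraction < 0.15

    def test_insufficient_separation(self):
        call = classify_condition(make_two_component_sample(1.5, 0.5, seed=8))
        assert call.is_bimodal is False

    def test_component_relabeling_symmetry(self):
        """The decision depends on (separation, minor weight), not ordering."""
        call = classify_condition(make_two_component_sample(4.0, 0.3, seed=9))
        fit = call.fit2
        swapped = dataclasses.replace(
            fit,
            amplitudes=fit.amplitudes[::-1].copy(),
            means=fit.means[::-1].copy(),
            sds=fit.sds[::-1].copy(),
            weights=fit.weights[::-1].copy(),
        )
        assert swapped.separation_over_maxsd == pytest.approx(fit.separation_over_maxsd)
        assert swapped.minor_fraction == pytest.approx(fit.minor_fraction)

    def test_threshold_monotonicity(self):
        """Raising either decision threshold never creates new bimodal calls."""
        samples = [
            make_two_component_sample(s, w, seed=100 + i)
            for i, (s, w) in enumerate([(2.5, 0.3), (3.0, 0.2), (4.0, 0.5), (2.2, 0.18)])
        ]
        for sep_mult, min_frac in [(2.0, 0.15), (2.5, 0.15), (2.0, 0.25), (3.0, 0.35)]:
            base = [classify_condition(s).is_bimodal for s in samples]
            strict = [
                classify_condition(
                    s,
                    ModalityThresholds(
                        separation_multiplier=sep_mult, min_fraction=min_frac
                    ),
                ).is_bimodal
                for s in samples
            ]
            for b, st_ in zip(base, strict):
                if st_:
                    assert b  # bimodal under stricter thresholds => bimodal under defaults


class TestProfileAndAggregate:
    def test_profile_bimodal_iff_any_condition(self, bimodal_profile):
        call = classify_profile(bimodal_profile)
        assert call.status == "ok"
        per = [c.is_bimodal for c in call.per_condition]
        assert call.profile_is_bimodal == any(per)
        assert call.profile_is_bimodal is True

    def test_unimodal_profile(self):
        m = InductionModel(E10=0.0039, F90=0.5)  # level shut off in the transition
        call = classify_profile(simulate_profile(m, seed=13))
        assert call.profile_is_bimodal is False

    def test_aggregate_requires_all_replicates_bimodal(self, bimodal_profile):
        bi = classify_profile(bimodal_profile)
        uni = classify_profile(
            simulate_profile(InductionModel(E10=0.0039, F90=0.5), seed=14)
        )
        assert aggregate_modality([bi, bi]) is True
        assert aggregate_modality([bi, uni]) is False
        assert aggregate_modality([uni]) is False

    def test_aggregate_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_modality([])

    def test_unclassifiable_never_silent(self):
        # constant-expression condition: fit error -> explicit status
        const = PopulationSample(np.full(500, -2.0), Condition(glucose=0.1))
        call = classify_condition(const)
        assert call.status == "unclassifiable"
        assert call.is_bimodal is None
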