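"""Multi-contrast co-refinement: objective, optimizer, uncertainty, comparison."""

import copy

import numpy as np
import pytest

from slbnr.fitting import (
    FitResult,
    chi_square,
    co_refine,
    compare_models,
    estimate_uncertainty,
)
from slbnr.models import OneLayerVesicleBilayer, ParamSpec
from slbnr.reflectivity import ReflectivityCurve
from slbnr.scattering import ContrastSpec
from slbnr.simulate import InstrumentSpec, ground_truth_presets, simulate_contrast_series

SEED = 20151211


@pytest.fixture(scope="module")
def hecoli():
    return ground_truth_presets()["hEcoli_50C"]


@pytest.fixture(scope="module")
def hecoli_nobg(hecoli):
    """Background-free copy: the generator and the fit model must agree
    exactly for the noiseless identities below."""
    model = copy.deepcopy(hecoli.model)
    model.background = 0.0
    return hecoli, model


@pytest.fixture(scope="module")
def decoli():
    return ground_truth_presets()["dEcoli_50C"]


@pytest.fixture(scope="module")
def coarse():
    return InstrumentSpec(q_min=0.005, q_max=0.3, points_per_decade=25)


@pytest.fixture(scope="module")
def noiseless(coarse):
    return InstrumentSpec(
        q_min=0.005, q_max=0.3, points_per_decade=25, noise_rel=0.0, background=0.0
    )


@pytest.fixture(scope="module")
def hecoli_noisy_data(hecoli, coarse):
    return simulate_contrast_series(hecoli.model, hecoli.contrasts, coarse, seed=SEED)


class TestChiSquare:
    def test_exact_model_gives_zero(self, hecoli_nobg, noiseless):
        gt, model = hecoli_nobg
        data = simulate_contrast_series(model, gt.contrasts, noiseless, 0)
        values = model.init_values()
        assert chi_square(model, values, data) == pytest.approx(0.0, abs=1e-12)

    def test_two_sigma_residual_counts_four(self, hecoli_nobg, noiseless):
        gt, model = hecoli_nobg
        data = simulate_contrast_series(model, gt.contrasts[:1], noiseless, 0)
        curve, contrast = data[0]
        dr = 0.05 * curve.r
        shifted = ReflectivityCurve(
            curve.q[:1], curve.r[:1] + 2 * dr[:1], dr[:1]
        )
        values = model.init_values()
        assert chi_square(model, values, [(shifted, contrast)]) == pytest.approx(
            4.0, rel=1e-9
        )

    def test_truth_is_local_minimum(self, hecoli, hecoli_noisy_data):
        values = hecoli.model.init_values()
        chi0 = chi_square(hecoli.model, values, hecoli_noisy_data)
        for name, delta in [("d_head", 0.8), ("d_tail", 1.5), ("phi_tail", 0.05)]:
            for sign in (+1, -1):
                perturbed = dict(values)
                perturbed[name] += sign * delta
                assert (
                    chi_square(hecoli.model, perturbed, hecoli_noisy_data) > chi0
                )

    def test_ordering_invariance(self, hecoli, hecoli_noisy_data):
        values = hecoli.model.init_values()
        a = chi_square(hecoli.model, values, hecoli_noisy_data)
        b = chi_square(hecoli.model, values, list(reversed(hecoli_noisy_data)))
        assert a == b

    def test_unweighted_dataset_uses_relative_weights(self, hecoli, noiseless):
        data = simulate_contrast_series(hecoli.model, hecoli.contrasts, noiseless, 0)
        assert all(curve.dr is None for curve, _ in data)
        values = dict(hecoli.model.init_values())
        values["d_tail"] += 1.0
        assert np.isfinite(chi_square(hecoli.model, values, data))


class TestCoRefine:
    def test_noiseless_round_trip_within_2_percent(self, hecoli_nobg, noiseless):
        gt, model = hecoli_nobg
        data = simulate_contrast_series(model, gt.contrasts, noiseless, 0)
        fit = co_refine(model, data, n_starts=4, seed=SEED)
        truth = gt.truth_values()
        for name in ("d_head", "d_tail", "phi_tail"):
            assert fit.params[name] == pytest.approx(truth[name], rel=0.02)

    def test_start_at_truth_returns_truth(self, hecoli_nobg, noiseless):
        gt, model = hecoli_nobg
        data = simulate_contrast_series(model, gt.contrasts, noiseless, 0)
        fit = co_refine(model, data, n_starts=1, seed=0, jitter=0.0)
        assert fit.chisq == pytest.approx(0.0, abs=1e-6)
        truth = gt.truth_values()
        for name, v in fit.params.items():
            assert v == pytest.approx(truth[name], abs=1e-4)

    def test_deterministic_for_seed(self, hecoli, hecoli_noisy_data):
        fit1 = co_refine(hecoli.model, hecoli_noisy_data, n_starts=3, seed=SEED)
        fit2 = co_refine(hecoli.model, hecoli_noisy_data, n_starts=3, seed=SEED)
        assert fit1.params == fit2.params
        assert fit1.chisq == fit2.chisq
        assert fit1.start_costs == fit2.start_costs

    def test_bounds_respected(self, hecoli, hecoli_noisy_data):
        fit = co_refine(hecoli.model, hecoli_noisy_data, n_starts=3, seed=SEED)
        for name in hecoli.model.free_names():
            spec = hecoli.model.params[name]
            assert spec.lo <= fit.params[name] <= spec.hi

    def test_global_chisq_is_sum_of_contrasts(self, hecoli, hecoli_noisy_data):
        fit = co_refine(hecoli.model, hecoli_noisy_data, n_starts=2, seed=SEED)
        assert fit.chisq == pytest.approx(sum(fit.chisq_per_contrast), rel=1e-12)
        assert fit.n_points == sum(len(c) for c, _ in hecoli_noisy_data)

    def test_single_contrast_fit_disperses_more(self, hecoli, coarse):
        """Contrast variation pins the tail hydration; a D2O-only fit leaves it
        poorly determined, visible as a wider spread across multistart results."""
        data = simulate_contrast_series(hecoli.model, hecoli.contrasts, coarse, SEED)
        fit_all = co_refine(hecoli.model, data, n_starts=6, seed=SEED)
        fit_d2o = co_refine(hecoli.model, data[-1:], n_starts=6, seed=SEED)

        def spread(fit):
            vals = [p["phi_tail"] for p in fit.start_params]
            return max(vals) - min(vals)

        assert spread(fit_d2o) > spread(fit_all)

    def test_requires_data(self, hecoli):
        with pytest.raises(ValueError):
            co_refine(hecoli.model, [], seed=0)

    def test_no_free_parameters_returns_forward_model(self, decoli, coarse):
        model = copy.deepcopy(decoli.model)
        for spec in model.params.values():
            spec.vary = False
        data = simulate_contrast_series(model, decoli.contrasts, coarse, seed=3)
        fit = co_refine(model, data, seed=0)
        assert fit.n_varied == 0
        assert fit.params == model.init_values()
        assert np.isfinite(fit.chisq)


class TestUncertainty:
    def test_zero_noise_intervals_collapse(self, hecoli_nobg, noiseless):
        gt, model = hecoli_nobg
        data = simulate_contrast_series(model, gt.contrasts, noiseless, 0)
        # give the noiseless curves an explicit tiny dR so residuals are defined
        data = [
            (ReflectivityCurve(c.q, c.r, np.maximum(1e-4 * c.r, 1e-12), c.dq), ct)
            for c, ct in data
        ]
        fit = co_refine(model, data, n_starts=1, seed=0, jitter=0.0)
        iv = estimate_uncertainty(fit, model, data, n_boot=5, seed=1)
        lo, hi = iv["d_tail"]
        assert hi - lo < 0.05

    def test_interval_width_grows_with_noise(self, hecoli, coarse):
        widths = {}
        for noise in (0.01, 0.05):
            inst = InstrumentSpec(
                q_min=0.005, q_max=0.3, points_per_decade=25, noise_rel=noise
            )
            data = simulate_contrast_series(hecoli.model, hecoli.contrasts, inst, 5)
            fit = co_refine(hecoli.model, data, n_starts=1, seed=0, jitter=0.0)
            iv = estimate_uncertainty(fit, hecoli.model, data, n_boot=8, seed=2)
            widths[noise] = {k: hi - lo for k, (lo, hi) in iv.items()}
        grew = [widths[0.05][k] >= widths[0.01][k] for k in widths[0.01]]
        assert np.median([widths[0.05][k] / max(widths[0.01][k], 1e-12) for k in widths[0.01]]) > 1.0
        assert sum(grew) >= len(grew) - 1  # allow one bootstrap fluctuation

    def test_tail_interval_of_order_one_angstrom(self, hecoli, hecoli_noisy_data):
        fit = co_refine(hecoli.model, hecoli_noisy_data, n_starts=2, seed=SEED)
        iv = estimate_uncertainty(
            fit, hecoli.model, hecoli_noisy_data, n_boot=20, seed=3
        )
        half = (iv["d_tail"][1] - iv["d_tail"][0]) / 2
        assert 0.05 < half < 3.0

    def test_requires_convergence(self, hecoli, hecoli_noisy_data):
        fit = co_refine(hecoli.model, hecoli_noisy_data, n_starts=1, seed=SEED)
        fit.success = False
        with pytest.raises(ValueError):
            estimate_uncertainty(fit, hecoli.model, hecoli_noisy_data, n_boot=2)

    def test_profile_method_brackets_best(self, hecoli, hecoli_noisy_data):
        fit = co_refine(hecoli.model, hecoli_noisy_data, n_starts=1, seed=SEED)
        iv = estimate_uncertainty(
            fit, hecoli.model, hecoli_noisy_data, method="profile"
        )
        lo, hi = iv["d_tail"]
        assert lo <= fit.params["d_tail"] <= hi


class TestCompareModels:
    def test_identical_fits_tie(self, decoli, coarse):
        data = simulate_contrast_series(decoli.model, decoli.contrasts, coarse, 7)
        fit = co_refine(decoli.model, data, n_starts=1, seed=0, jitter=0.0)
        cmp = compare_models(fit, fit, data)
        assert cmp.preferred == "tie"
        assert cmp.delta_per_point == 0.0
        assert not cmp.necessary

    def test_mismatched_datasets_rejected(self, decoli, coarse):
        data = simulate_contrast_series(decoli.model, decoli.contrasts, coarse, 7)
        fit = co_refine(decoli.model, data, n_starts=1, seed=0, jitter=0.0)
        with pytest.raises(ValueError):
            compare_models(fit, fit, data[:-1])
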