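"""Distance binning, exponential decay fitting, lambda_eff."""

import numpy as np
import pandas as pd
import pytest

from synpid.spatial import (
    DistanceBinnedCurve,
    bin_by_distance,
    effective_length,
    fit_exponential_decay,
    normalized_curve,
    pairwise_pearson,
)


def model_curve(c0, c_inf, lam, d):
    return c_inf + (c0 - c_inf) * np.exp(-d / lam)


def synth_curve(c0=0.1, c_inf=0.01, lam=500.0, n_bins=20, noise_sd=0.0,
                seed=0):
    edges = np.geomspace(20, 2500, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    rng = np.random.default_rng(seed)
    means = model_curve(c0, c_inf, lam, centers) + rng.normal(0, noise_sd,
                                                             n_bins)
    return DistanceBinnedCurve(
        bin_edges=edges, bin_centers=centers, mean_value=means,
        pair_count=np.full(n_bins, 100), min_pairs_per_bin=1,
    )


class TestPairwisePearson:
    def test_duplicate_and_inverted_columns(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 200)
        raster = np.column_stack([x, x, 1 - x])
        df = pairwise_pearson(raster)
        lookup = {(r.i, r.j): r.value for r in df.itertuples()}
        assert lookup[(0, 1)] == pytest.approx(1.0)
        assert lookup[(0, 2)] == pytest.approx(-1.0)

    def test_constant_columns_excluded(self):
        rng = np.random.default_rng(1)
        raster = np.column_stack([
            rng.integers(0, 2, 100), np.zeros(100), rng.integers(0, 2, 100)
        ])
        df = pairwise_pearson(raster)
        assert set(zip(df.i, df.j)) == {(0, 2)}

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        raster = rng.integers(0, 2, (50_000, 6))
        assert np.abs(pairwise_pearson(raster)["value"]).max() < 0.02


class TestBinByDistance:
    def test_hand_binning_three_pairs(self):
        pairs = pd.DataFrame({
            "i": [0, 0, 0], "j": [1, 2, 3],
            "distance_um": [110.0, 450.0, 1400.0],
            "value": [0.3, 0.2, 0.1],
        })
        curve = bin_by_distance(pairs, n_bins=3, d_min=100, d_max_bin=1500,
                                min_pairs_per_bin=1)
        np.testing.assert_allclose(curve.mean_value, [0.3, 0.2, 0.1])
        np.testing.assert_array_equal(curve.pair_count, [1, 1, 1])

    def test_equidistant_pairs_single_bin(self):
        pairs = pd.DataFrame({
            "i": [0, 1, 2], "j": [3, 4, 5],
            "distance_um": [500.0] * 3, "value": [0.1, 0.2, 0.6],
        })
        curve = bin_by_distance(pairs, n_bins=5, d_min=10, d_max_bin=1000,
                                min_pairs_per_bin=1)
        occupied = curve.occupied
        assert occupied.sum() == 1
        assert curve.mean_value[occupied][0] == pytest.approx(0.3)

    def test_log_spaced_edges(self):
        pairs = pd.DataFrame({
            "i": [0], "j": [1], "distance_um": [100.0], "value": [0.5]
        })
        curve = bin_by_distance(pairs, n_bins=10, d_min=10, d_max_bin=1000,
                                min_pairs_per_bin=1)
        ratios = curve.bin_edges[1:] / curve.bin_edges[:-1]
        np.testing.assert_allclose(ratios, ratios[0])
        assert (np.diff(curve.bin_edges) > 0).all()
        assert ((curve.bin_centers > curve.bin_edges[:-1])
                & (curve.bin_centers < curve.bin_edges[1:])).all()

    def test_distances_from_positions(self):
        positions = pd.DataFrame({
            "neuron_id": [0, 1, 2],
            "x_um": [0.0, 300.0, 0.0], "y_um": [0.0, 0.0, 400.0],
        })
        pairs = pd.DataFrame({"i": [0, 0], "j": [1, 2], "value": [0.2, 0.4]})
        curve = bin_by_distance(pairs, positions, n_bins=2, d_min=100,
                                d_max_bin=500, min_pairs_per_bin=1)
        assert curve.pair_count.sum() == 2

    def test_sparse_bins_masked(self):
        rng = np.random.default_rng(3)
        pairs = pd.DataFrame({
            "i": np.zeros(100, int), "j": np.arange(100),
            "distance_um": rng.uniform(100, 200, 100), "value": rng.random(100),
        })
        curve = bin_by_distance(pairs, n_bins=5, d_min=10, d_max_bin=3000,
                                min_pairs_per_bin=50)
        assert np.isnan(curve.mean_value[curve.pair_count < 50]).all()


class TestFitExponentialDecay:
    def test_noiseless_recovery_to_1e6_relative(self):
        fit = fit_exponential_decay(synth_curve())
        assert fit.converged
        assert fit.c0 == pytest.approx(0.1, rel=1e-6)
        assert fit.c_inf == pytest.approx(0.01, rel=1e-6)
        assert fit.lam == pytest.approx(500.0, rel=1e-6)

    def test_model_limits(self):
        fit = fit_exponential_decay(synth_curve())
        assert fit.predict(0.0) == pytest.approx(fit.c0, rel=1e-9)
        assert fit.predict(1e9) == pytest.approx(fit.c_inf, rel=1e-6)

    def test_noisy_recovery_within_5_percent_median(self):
        lams = []
        for seed in range(100):
            fit = fit_exponential_decay(synth_curve(noise_sd=0.005, seed=seed))
            lams.append(fit.lam)
        assert abs(np.median(lams) - 500) / 500 < 0.05

    def test_too_few_bins_rejected(self):
        curve = synth_curve(n_bins=3)
        with pytest.raises(ValueError, match="occupied bins"):
            fit_exponential_decay(curve)

    def test_flat_curve_unidentifiable(self):
        curve = synth_curve(c0=0.05, c_inf=0.05, lam=500)
        fit = fit_exponential_decay(curve)
        assert fit.unidentifiable
        assert np.isnan(fit.lam)


class TestNormalizedCurve:
    def test_plug_in_identity(self):
        curve = synth_curve()
        fit = fit_exponential_decay(curve)
        norm = normalized_curve(curve, fit)
        np.testing.assert_allclose(
            norm.mean_value, np.exp(-curve.bin_centers / fit.lam), atol=1e-6
        )

    def test_endpoint_values(self):
        curve = synth_curve()
        fit = fit_exponential_decay(curve)
        norm = normalized_curve(curve, fit)
        # value equal to c0 maps to 1, value equal to c_inf maps to 0
        assert (0.1 - fit.c_inf) / (fit.c0 - fit.c_inf) == pytest.approx(1.0,
                                                                         rel=1e-6)
        assert norm.mean_value[0] == pytest.approx(
            np.exp(-curve.bin_centers[0] / fit.lam), rel=1e-5)

    def test_degenerate_fit_rejected(self):
        curve = synth_curve()
        fit = fit_exponential_decay(curve)
        flat = type(fit)(c0=0.05, c_inf=0.05, lam=fit.lam,
                         covariance=fit.covariance, rss=0.0, converged=True)
        with pytest.raises(ValueError, match="unidentifiable"):
            normalized_curve(curve, flat)


class TestEffectiveLength:
    def closed_form(self, c0, c_inf, lam, d0, dmax):
        return (c_inf * (dmax - d0)
                + (c0 - c_inf) * lam * (np.exp(-d0 / lam) - np.exp(-dmax / lam))
                ) / c0

    def test_quadrature_equals_closed_form(self):
        fit = fit_exponential_decay(synth_curve())
        eff = effective_length(fit, 100, 1500)
        assert eff.lambda_eff == pytest.approx(
            self.closed_form(fit.c0, fit.c_inf, fit.lam, 100, 1500), abs=1e-9
        )

    def test_limit_recovers_lambda(self):
        """c_inf = 0, d0 -> 0, dmax -> inf: lambda_eff -> lambda."""
        from synpid.spatial import DecayFit

        fit = DecayFit(c0=0.1, c_inf=0.0, lam=500.0,
                       covariance=np.zeros((3, 3)), rss=0.0, converged=True)
        eff = effective_length(fit, 1e-9, 1e6)
        assert eff.lambda_eff == pytest.approx(500.0, rel=1e-6)

    def test_flat_curve_gives_window_width(self):
        from synpid.spatial import DecayFit

        fit = DecayFit(c0=0.07, c_inf=0.07, lam=500.0,
                       covariance=np.zeros((3, 3)), rss=0.0, converged=True)
        eff = effective_length(fit, 100, 1500)
        assert eff.lambda_eff == pytest.approx(1400.0, abs=1e-9)

    def test_monotone_in_lambda(self):
        from synpid.spatial import DecayFit

        effs = []
        for lam in np.linspace(100, 3000, 12):
            fit = DecayFit(c0=0.1, c_inf=0.01, lam=lam,
                           covariance=np.zeros((3, 3)), rss=0.0,
                           converged=True)
            effs.append(effective_length(fit, 100, 1500).lambda_eff)
        assert (np.diff(effs) > 0).all()

    def test_nonpositive_c0_flagged(self):
        from synpid.spatial import DecayFit

        fit = DecayFit(c0=-0.01, c_inf=0.0, lam=300.0,
                       covariance=np.zeros((3, 3)), rss=0.0, converged=True)
        assert effective_length(fit).undefined

    def test_invalid_window_rejected(self):
        fit = fit_exponential_decay(synth_curve())
        with pytest.raises(ValueError):
            effective_length(fit, 1500, 100)


class TestEffectiveLengthTrapezoid:
    def test_flat_curve_gives_window_width(self):
        from synpid.spatial import effective_length_trapezoid

        curve = synth_curve(c0=0.07, c_inf=0.07, lam=500)
        eff = effective_length_trapezoid(curve, 100, 1500)
        assert eff.lambda_eff == pytest.approx(1400.0, rel=1e-9)

    def test_matches_analytic_area_on_decaying_curve(self):
        """Model-free estimate approaches (1/C(d0)) * integral of C(d).

        Unlike the fit-based variant, normalisation is at the window's
        left edge (no model to extrapolate to d = 0).
        """
        from synpid.spatial import effective_length_trapezoid

        curve = synth_curve(n_bins=60)
        c0, c_inf, lam, d0, dmax = 0.1, 0.01, 500.0, 100.0, 1500.0
        area = (c_inf * (dmax - d0)
                + (c0 - c_inf) * lam * (np.exp(-d0 / lam) - np.exp(-dmax / lam)))
        expected = area / model_curve(c0, c_inf, lam, d0)
        trapz = effective_length_trapezoid(curve, d0, dmax).lambda_eff
        assert trapz == pytest.approx(expected, rel=0.02)

    def test_nonpositive_left_edge_flagged(self):
        from synpid.spatial import effective_length_trapezoid

        curve = synth_curve(c0=-0.2, c_inf=-0.05, lam=400)
        assert effective_length_trapezoid(curve, 100, 1500).undefined

    def test_too_few_occupied_bins_rejected(self):
        from synpid.spatial import effective_length_trapezoid

        curve = synth_curve(n_bins=2)
        with pytest.raises(ValueError):
            effective_length_trapezoid(
                type(curve)(bin_edges=curve.bin_edges,
                            bin_centers=curve.bin_centers,
                            mean_value=np.array([0.1, np.nan]),
                            pair_count=curve.pair_count,
                            min_pairs_per_bin=1),
                100, 1500,
            )
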