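"""Feature assembly, z-scoring, noise injection, synthetic test-retest data."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesbi import (
    MiddleEarParams,
    NoiseModel,
    assemble_features,
    estimate_noise_std,
    feature_mask,
    generate_test_retest,
    inject_noise,
    simulate_spectra,
)
from mesbi.features import (
    BLOCK_NAMES,
    FeatureScaler,
    FeatureVector,
    decode_features,
    default_base_sigma,
    fit_scaler,
)
from mesbi.features import TestRetestDataset as ReplicateDataset
from mesbi.simulator import FrequencyGrid, SpectrumSet


@pytest.fixture(scope="module")
def spectra(midpoint_params):
    return simulate_spectra(midpoint_params)


class TestAssembly:
    def test_vector_has_250_elements_on_default_grid(self, spectra):
        assert assemble_features(spectra).values.shape == (250,)

    def test_layout_is_a_bijection(self, spectra):
        fv = assemble_features(spectra)
        vst, zec, ab = decode_features(fv)
        assert np.allclose(vst, spectra.vst_over_pec, rtol=1e-12)
        assert np.allclose(zec, spectra.z_ec, rtol=1e-12)
        assert np.allclose(ab, spectra.abs_ec, rtol=1e-12)

    def test_doubling_velocity_shifts_only_its_magnitude_block(self, spectra):
        doubled = SpectrumSet(
            grid=spectra.grid,
            vst_over_pec=2 * spectra.vst_over_pec,
            z_ec=spectra.z_ec,
            abs_ec=spectra.abs_ec,
        )
        a, b = assemble_features(spectra), assemble_features(doubled)
        assert np.allclose(
            b.block("vst_mag_db") - a.block("vst_mag_db"), 20 * np.log10(2), atol=1e-12
        )
        for name in BLOCK_NAMES[1:]:
            assert np.array_equal(a.block(name), b.block(name))

    def test_constant_phase_survives_unwrapping(self, spectra):
        ph = -0.4  # cycles, within the principal branch
        z = np.abs(spectra.vst_over_pec) * np.exp(2j * np.pi * ph)
        s = SpectrumSet(grid=spectra.grid, vst_over_pec=z, z_ec=spectra.z_ec,
                        abs_ec=spectra.abs_ec)
        assert np.allclose(assemble_features(s).block("vst_phase_cycles"), ph, atol=1e-12)

    def test_zero_magnitude_rejected(self, spectra):
        z = spectra.vst_over_pec.copy()
        z[10] = 0
        s = SpectrumSet(grid=spectra.grid, vst_over_pec=z, z_ec=spectra.z_ec,
                        abs_ec=spectra.abs_ec)
        with pytest.raises(ValueError):
            assemble_features(s)

    @pytest.mark.parametrize(
        "blocks,expected_dim",
        [("abs", 50), ("vst", 100), ("zec", 100), ("all", 250),
         (["vst_mag_db"], 50), (["vst", "abs"], 150)],
    )
    def test_feature_mask_arithmetic(self, blocks, expected_dim):
        assert feature_mask(blocks).sum() == expected_dim

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            feature_mask("pressure")


class TestScaler:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 17)) * rng.uniform(0.1, 50, 17)
        sc = fit_scaler(X)
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X, rtol=1e-12)

    def test_zero_mean_unit_spread_on_fitting_set(self):
        X = np.random.default_rng(1).normal(size=(200, 5))
        Z = fit_scaler(X).transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_two_point_hand_example(self):
        # values {0, 2}: center 1, sample STD sqrt(2), transformed +-1/sqrt(2)
        sc = fit_scaler(np.array([[0.0], [2.0]]))
        assert sc.center_[0] == pytest.approx(1.0)
        assert sc.spread_[0] == pytest.approx(np.sqrt(2))
        assert sc.transform(np.array([[0.0], [2.0]]))[:, 0] == pytest.approx(
            [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_degenerate_column_floored(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        sc = fit_scaler(X)
        assert sc.spread_[0] == sc.eps
        assert np.allclose(sc.transform(X)[:, 0], 0)

    def test_fitting_needs_two_rows(self):
        with pytest.raises(ValueError):
            fit_scaler(np.ones((1, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, seed):
        X = np.random.default_rng(seed).normal(size=(5, 4)) * 100
        sc = fit_scaler(X)
        Y = np.random.default_rng(seed + 1).normal(size=(3, 4)) * 100
        assert np.allclose(sc.inverse_transform(sc.transform(Y)), Y, rtol=1e-12)


class TestNoise:
    def test_zero_scale_leaves_vector_unchanged(self, spectra):
        fv = assemble_features(spectra)
        noise = NoiseModel(sigma=default_base_sigma(), scale=0.0)
        assert np.array_equal(inject_noise(fv, noise, 0).values, fv.values)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sigma=np.ones(250), scale=-1.0)

    def test_seeded_reproducibility(self, spectra):
        fv = assemble_features(spectra)
        noise = NoiseModel(sigma=default_base_sigma(), scale=1.0)
        a = inject_noise(fv, noise, 123).values
        b = inject_noise(fv, noise, 123).values
        assert np.array_equal(a, b)
        assert not np.array_equal(a, inject_noise(fv, noise, 124).values)

    def test_monte_carlo_std_matches_noise_law(self, spectra):
        fv = assemble_features(spectra)
        sigma = default_base_sigma()
        noise = NoiseModel(sigma=sigma, scale=2.0)
        draws = inject_noise(np.tile(fv.values, (10_000, 1)), noise, 7)
        sample_std = (draws - fv.values).std(axis=0, ddof=1)
        assert np.all(np.abs(sample_std - 2.0 * sigma) < 0.05 * 2.0 * sigma)

    def test_noise_is_unbiased(self, spectra):
        # law of large numbers: mean of many noisy copies approaches clean
        fv = assemble_features(spectra)
        sigma = default_base_sigma()
        n = 10_000
        draws = inject_noise(np.tile(fv.values, (n, 1)), NoiseModel(sigma, 1.0), 8)
        err = draws.mean(axis=0) - fv.values
        assert np.all(np.abs(err) <= 3 * sigma / np.sqrt(n) + 1e-12)


class TestTestRetest:
    def test_generated_dataset_summary_consistency(self, prior):
        theta = prior.sample(1, seed=3)[0]
        ds = generate_test_retest(theta, n_replicates=17, seed=4)
        assert ds.replicates.shape == (17, 250)
        assert np.array_equal(ds.mean, ds.replicates.mean(axis=0))
        assert np.array_equal(estimate_noise_std(ds), ds.std)
        # chi^2 bound: (K-1) s^2 / sigma^2 ~ chi^2_{16}; check the central
        # 1 - 1e-5 interval elementwise (expected failures over 250: ~0.003)
        from scipy.stats import chi2

        base = default_base_sigma()
        ratio = ds.std / base
        lo = np.sqrt(chi2.ppf(5e-6, 16) / 16)
        hi = np.sqrt(chi2.ppf(1 - 5e-6, 16) / 16)
        assert np.all((ratio > lo) & (ratio < hi))
        assert abs(np.median(ratio) - 1) < 0.2

    def test_zero_noise_gives_identical_replicates(self, prior):
        theta = prior.sample(1, seed=5)[0]
        ds = generate_test_retest(theta, n_replicates=5, base_sigma=np.zeros(250), seed=6)
        assert np.all(ds.replicates == ds.replicates[0])
        # identical replicates: STD vanishes (up to pairwise-mean rounding)
        assert np.all(ds.std <= 1e-12 * np.abs(ds.mean).max())

    def test_hand_computed_std(self):
        grid = FrequencyGrid()
        reps = np.zeros((2, 250))
        reps[1, 37] = 2.0
        ds = ReplicateDataset(replicates=reps, grid=grid)
        expected = np.zeros(250)
        expected[37] = np.sqrt(2)  # ddof=1 convention
        assert np.allclose(estimate_noise_std(ds), expected)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            ReplicateDataset(replicates=np.zeros((1, 250)), grid=FrequencyGrid())

    def test_equal_seeds_give_identical_datasets(self, prior):
        theta = prior.sample(1, seed=9)[0]
        a = generate_test_retest(theta, n_replicates=4, seed=11)
        b = generate_test_retest(theta, n_replicates=4, seed=11)
        assert np.array_equal(a.replicates, b.replicates)
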