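import numpy as np
import pytest

import zebratk as z
from zebratk.calibration import LOG_BCF_GUARD
from zebratk.data_io import DEFAULT_TRUTH_PAIR


class TestSourceSinkModel:
    def test_noise_free_recovery_lands_on_degeneracy_curve(
        self, noisefree_dataset, small_pso
    ):
        res = z.SourceSinkModel(noisefree_dataset).fit(
            small_pso.replace(score_cutoff=1 - 1e-9, max_iterations=400), seed=11
        )
        assert res.rmse < 1e-3
        # the recovered pair need not equal the truth: any point on the
        # source/sink degeneracy curve reproduces the data
        truth_rmse = z.SourceSinkModel(noisefree_dataset).rmse(*DEFAULT_TRUTH_PAIR)
        assert truth_rmse < 1e-12

    def test_seeded_determinism(self, noisefree_dataset, small_pso):
        m = z.SourceSinkModel(noisefree_dataset)
        a = m.fit(small_pso, seed=5)
        b = m.fit(small_pso, seed=5)
        assert (a.f_gill, a.k_m, a.rmse) == (b.f_gill, b.k_m, b.rmse)

    def test_basin_consistency_across_seeds(self, analog_dataset, small_pso):
        m = z.SourceSinkModel(analog_dataset)
        rmses = [m.fit(small_pso, seed=s).rmse for s in range(8)]
        best = min(rmses)
        assert all(r <= 1.05 * best for r in rmses)

    def test_from_dataframe_roundtrip(self, noisefree_dataset):
        df = noisefree_dataset.to_dataframe()
        m = z.SourceSinkModel.from_dataframe(df)
        assert m.nobs == len(noisefree_dataset)
        assert m.rmse() == pytest.approx(
            z.SourceSinkModel(noisefree_dataset).rmse()
        )

    def test_summary_contains_estimates(self, noisefree_dataset, small_pso):
        res = z.SourceSinkModel(noisefree_dataset).fit(small_pso, seed=1)
        text = res.summary()
        assert "F_gill" in text and "k_m" in text and "RMSE" in text
        assert f"{res.nobs}" in text

    def test_functional_wrapper_agrees(self, noisefree_dataset, small_pso):
        pair = z.calibrate_source_sink(
            noisefree_dataset, pso_config=small_pso, seed=5
        )
        res = z.SourceSinkModel(noisefree_dataset).fit(small_pso, seed=5)
        assert pair.f_gill == res.f_gill and pair.k_m == res.k_m


class TestAllParameterModel:
    def test_collapsed_bounds_return_literature_score(self, analog_dataset, phys7c):
        from zebratk.physiology import BODY_PARAMETERS, get_parameter

        bounds = [
            (get_parameter(phys7c, n), get_parameter(phys7c, n))
            for n in BODY_PARAMETERS
        ]
        model = z.AllParameterModel(analog_dataset, phys7c, bounds=bounds)
        cfg = z.PSOConfig(bounds=bounds, n_particles=5, max_iterations=2, seed=0)
        res = model.fit(cfg)
        assert res.r_squared == pytest.approx(model.score_literature(), rel=1e-12)
        assert res.rmse == pytest.approx(
            z.SourceSinkModel(analog_dataset, phys7c).rmse(), rel=1e-12
        )

    def test_improves_on_literature(self, analog_dataset):
        model = z.AllParameterModel(analog_dataset)
        cfg = z.PSOConfig(bounds=((1, 2),), n_particles=40, max_iterations=60, seed=2)
        res = model.fit(cfg)
        assert res.r_squared >= model.score_literature()
        assert "optimized" in res.summary()

    def test_free_subset_configurable(self, analog_dataset):
        model = z.AllParameterModel(analog_dataset, free_params=("f_car", "m_tot"))
        assert model.free_params == ("f_car", "m_tot")
        with pytest.raises(z.InvalidInputError):
            z.AllParameterModel(analog_dataset, free_params=("F_gill",))


class TestPerChemicalCalibration:
    def test_self_consistency_on_synthetic_truth(self, noisefree_dataset):
        record = max(noisefree_dataset, key=lambda r: r.log10_bcf_observed)
        pair = z.calibrate_per_chemical(record, seed=3)
        assert pair.score < 1e-3
        pred = np.log10(
            z.bcf_7c_batch(
                z.default_physiology_7c(),
                [record.chemical.log10_kow],
                pair.f_gill,
                pair.k_m,
            )
        )[0]
        rel = abs(record.log10_bcf_observed - pred) / abs(record.log10_bcf_observed)
        assert rel < 1e-3

    def test_near_zero_observation_refused(self, phys7c):
        record = z.BCFRecord(z.Chemical("flat", 1.0), log10_bcf_observed=0.01)
        with pytest.raises(z.InvalidInputError, match="ill-defined"):
            z.calibrate_per_chemical(record, phys7c)
        ok = z.BCFRecord(z.Chemical("edge", 1.0), log10_bcf_observed=LOG_BCF_GUARD)
        z.calibrate_per_chemical(ok, phys7c, seed=0)

    def test_pooled_optima_follow_saturating_median(self, noisefree_dataset):
        # small ensemble: medians of F_gill rise monotonically with k_m
        records = [
            r for r in noisefree_dataset if abs(r.log10_bcf_observed) > 0.5
        ][:12]
        pairs = []
        for i, r in enumerate(records):
            for s in range(3):
                pairs.append(z.calibrate_per_chemical(r, seed=100 * i + s))
        curve = z.median_curve(pairs, n_bins=8)
        assert curve.shape[0] >= 2
        # increasing overall (rank correlation tolerates boundary wiggles at
        # this reduced ensemble size)
        from scipy.stats import spearmanr

        rho = spearmanr(np.log10(curve[:, 0]), curve[:, 1]).statistic
        assert rho > 0.6


class TestMedianCurve:
    def test_identical_pairs_single_bin(self):
        pairs = [z.SourceSinkPair(1.0, 1e-3, 0.0)] * 5
        curve = z.median_curve(pairs)
        assert curve.shape == (1, 2)
        assert curve[0, 1] == 1.0

    def test_noiseless_eq4_points_lie_on_curve(self):
        fit = z.Eq4Fit(f_max=0.327, k_half=0.00161, r_squared=1.0)
        km = np.logspace(-5, -1, 300)
        pairs = [
            z.SourceSinkPair(z.eq4_predict(fit, k), k, 0.0) for k in km
        ]
        curve = z.median_curve(pairs, n_bins=30)
        expected = z.eq4_predict(fit, curve[:, 0])
        assert np.allclose(curve[:, 1], expected, rtol=0.2)

    def test_too_few_bins_is_error(self):
        pairs = [
            z.SourceSinkPair(1.0, 1e-3, 0.0),
            z.SourceSinkPair(1.0, 1.0001e-3, 0.0),
        ]
        with pytest.raises(z.InvalidInputError, match="bins"):
            z.median_curve(pairs, n_bins=1)
        with pytest.raises(z.InvalidInputError):
            z.median_curve([])


class TestEq4:
    def test_noiseless_exact_recovery(self):
        km = np.logspace(-5, -1, 40)
        f = 0.327 * km / (0.00161 + km)
        fit = z.fit_eq4(np.column_stack([km, f]))
        assert fit.f_max == pytest.approx(0.327, rel=1e-6)
        assert fit.k_half == pytest.approx(0.00161, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_half_saturation_point(self):
        fit = z.Eq4Fit(f_max=0.4, k_half=2e-3, r_squared=1.0)
        assert z.eq4_predict(fit, 2e-3) == pytest.approx(0.2)
        assert z.eq4_predict(fit, 0.0) == 0.0
        assert z.eq4_predict(fit, 1e6) == pytest.approx(0.4, rel=1e-3)

    def test_inverse_and_range_error(self):
        fit = z.Eq4Fit(f_max=0.4, k_half=2e-3, r_squared=1.0)
        km = 5e-3
        assert z.eq4_inverse(fit, z.eq4_predict(fit, km)) == pytest.approx(km)
        with pytest.raises(z.InvalidInputError):
            z.eq4_inverse(fit, 0.4)

    def test_noisy_recovery_within_ten_percent(self):
        errs_f, errs_k = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            km = np.exp(rng.uniform(np.log(1e-5), np.log(1e-1), 76))
            f = 0.327 * km / (0.00161 + km) * np.exp(rng.normal(0, 0.1, 76))
            fit = z.fit_eq4(np.column_stack([km, f]))
            errs_f.append(abs(fit.f_max - 0.327) / 0.327)
            errs_k.append(abs(fit.k_half - 0.00161) / 0.00161)
        assert np.mean(errs_f) < 0.10
        assert np.mean(errs_k) < 0.10

    def test_too_few_points(self):
        with pytest.raises(z.InvalidInputError):
            z.fit_eq4([(1e-3, 0.1), (2e-3, 0.2)])


class TestGridScan:
    def test_cells_match_direct_evaluation(self, noisefree_dataset, phys7c):
        km_grid = np.logspace(-6, -2, 6)
        fg_grid = np.logspace(-4, 1, 5)
        gs = z.grid_scan(noisefree_dataset, phys7c, km_grid, fg_grid)
        model = z.SourceSinkModel(noisefree_dataset, phys7c)
        for i in (0, 3, 5):
            for j in (0, 2, 4):
                direct = model.rmse(fg_grid[j], km_grid[i])
                assert gs.rmse[i, j] == pytest.approx(direct, rel=1e-12)

    def test_minimum_not_above_literature_point(self, noisefree_dataset, phys7c):
        km_grid = np.logspace(-6, -1, 20)
        fg_grid = np.sort(np.append(np.logspace(-5, 1, 19), phys7c.F_gill))
        gs = z.grid_scan(noisefree_dataset, phys7c, km_grid, fg_grid)
        j = int(np.argmin(np.abs(gs.fgill_grid - phys7c.F_gill)))
        i = int(np.argmin(np.abs(gs.km_grid - phys7c.k_m)))
        assert gs.min_rmse <= gs.rmse[i, j]

    def test_degeneracy_region_is_a_curve(self, noisefree_dataset):
        # noise-free data: the near-zero-RMSE set is thin (1-D), not a blob
        gs = z.grid_scan(
            noisefree_dataset,
            km_grid=np.logspace(-6, -1, 40),
            fgill_grid=np.logspace(-7, 1, 40),
        )
        tight = gs.region_mask(0.05)
        assert tight.any()
        # every k_m row crosses the curve in a narrow F_gill band
        rows = tight.sum(axis=1)
        assert np.median(rows[rows > 0]) <= 6

    def test_grid_validation(self):
        with pytest.raises(z.InvalidInputError):
            z.GridScan(
                km_grid=[1e-3, 1e-4], fgill_grid=[0.1, 1.0],
                rmse=np.zeros((2, 2)),
            )
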