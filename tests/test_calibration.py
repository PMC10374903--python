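"""LOESS + isotonic calibration: PSM selection, fitting, recovery, deltas."""

import numpy as np
import pytest

from psmfeat.calibration import (
    CalibrationError,
    CalibrationModel,
    delta_im,
    delta_rt_loess,
    delta_rt_loess_normalized,
    fit_calibration,
    fit_im_models,
    select_calibration_psms,
)
from psmfeat.pin import PsmRecord


def make_psm(i, evalue, label=1, rank=1, charge=2):
    return PsmRecord(
        spec_id=f"id{i}",
        label=label,
        scan_nr=i,
        rank=rank,
        peptide="PEPTIDEK",
        charge=charge,
        evalue=evalue,
        feature_values={},
    )


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSelection:
    def test_caps_at_max_n_by_ascending_evalue(self):
        psms = [make_psm(i, 10 ** (-8 + i * 0.0005)) for i in range(6000)]
        chosen, flag = select_calibration_psms(psms)
        assert flag == "loess"
        assert len(chosen) == 5000
        assert max(p.evalue for p in chosen) <= min(
            p.evalue for p in psms if p not in chosen
        )

    def test_few_psms_fall_back_to_linear(self):
        psms = [make_psm(i, 1e-5) for i in range(30)]
        chosen, flag = select_calibration_psms(psms)
        assert (len(chosen), flag) == (30, "linear")

    def test_decoys_higher_ranks_and_weak_psms_excluded(self):
        psms = (
            [make_psm(i, 1e-6) for i in range(60)]
            + [make_psm(100 + i, 1e-6, label=-1) for i in range(20)]
            + [make_psm(200 + i, 1e-6, rank=2) for i in range(20)]
            + [make_psm(300 + i, 1e-2) for i in range(20)]
        )
        chosen, flag = select_calibration_psms(psms)
        assert len(chosen) == 60
        assert all(p.is_target and p.rank == 1 and p.evalue < 10**-3.5 for p in chosen)

    def test_threshold_is_ten_to_minus_3_5(self):
        at = make_psm(0, 10.0**-3.5)
        below = make_psm(1, 10.0**-3.6)
        chosen, _ = select_calibration_psms([at, below] + [make_psm(i, 1e-9) for i in range(2, 5)])
        assert below in chosen and at not in chosen

    def test_no_qualifying_psms_raises(self):
        with pytest.raises(CalibrationError):
            select_calibration_psms([make_psm(0, 0.5)])


class TestFitting:
    def test_identity_line_recovered(self):
        x = np.linspace(0, 100, 200)
        model = fit_calibration(list(zip(x, x)), "loess", 0.05)
        grid = np.linspace(0, 100, 500)
        np.testing.assert_allclose(model.predict(grid), grid, atol=1e-6)

    def test_linear_flag_recovers_slope_intercept(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 * x + 5.0
        model = fit_calibration(list(zip(x, y)), "linear")
        assert model.slope == pytest.approx(2.0, abs=1e-9)
        assert model.intercept == pytest.approx(5.0, abs=1e-9)
        assert model(3.0) == pytest.approx(11.0, abs=1e-9)

    def test_sigmoid_with_noise_recovered_and_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-6, 6, size=1000)
        y = sigmoid(x) + rng.normal(0, 0.02, size=1000)
        model = fit_calibration(list(zip(x, y)), "loess", 0.05)
        grid = np.linspace(np.quantile(x, 0.05), np.quantile(x, 0.95), 2000)
        assert np.max(np.abs(model.predict(grid) - sigmoid(grid))) < 0.05
        dense = model.predict(np.linspace(-6, 6, 10000))
        assert np.all(np.diff(dense) >= 0)

    def test_out_of_domain_clamps(self):
        x = np.linspace(0, 10, 100)
        model = fit_calibration(list(zip(x, 2 * x)), "loess", 0.3)
        assert model(-5.0) == model(0.0)
        assert model(50.0) == model(10.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(1.0, 2.0)], "loess")
        with pytest.raises(CalibrationError):
            fit_calibration([(1.0, 2.0), (1.0, 3.0)], "loess")

    def test_rmse_improves_with_more_psms(self):
        """Calibration quality increases from n=100 to n=1000 (median over seeds)."""
        def rmse(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-6, 6, size=n)
            y = sigmoid(x) + rng.normal(0, 0.05, size=n)
            model = fit_calibration(list(zip(x, y)), "loess", 0.05)
            grid = np.linspace(-5, 5, 500)
            return float(np.sqrt(np.mean((model.predict(grid) - sigmoid(grid)) ** 2)))

        small = np.median([rmse(100, s) for s in range(10)])
        large = np.median([rmse(1000, s) for s in range(10)])
        assert large < small

    def test_dump_load_round_trip(self, tmp_path):
        x = np.linspace(0, 10, 50)
        model = fit_calibration(list(zip(x, x**1.5)), "loess", 0.2)
        model.dump(tmp_path / "model.json")
        back = CalibrationModel.load(tmp_path / "model.json")
        grid = np.linspace(0, 10, 100)
        np.testing.assert_allclose(back.predict(grid), model.predict(grid))
        assert back.residual_iqr == pytest.approx(model.residual_iqr)


class TestImModels:
    def _items(self, charge, n, slope, intercept, seed):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            xe = float(rng.uniform(0.7, 1.3))
            yp = slope * xe + intercept + float(rng.normal(0, 0.005))
            out.append((make_psm(1000 * charge + i, 1e-6, charge=charge), xe, yp))
        return out

    def test_one_model_per_charge_with_distinct_maps(self):
        items = self._items(2, 500, 1.02, 0.01, 0) + self._items(3, 500, 0.98, -0.02, 1)
        models = fit_im_models(items)
        assert set(models) == {2, 3}
        for charge, (slope, intercept) in ((2, (1.02, 0.01)), (3, (0.98, -0.02))):
            grid = np.linspace(0.75, 1.25, 50)
            np.testing.assert_allclose(
                models[charge].predict(grid), slope * grid + intercept, atol=0.01
            )

    def test_sparse_charge_uses_pooled_fallback(self):
        items = self._items(2, 500, 1.0, 0.0, 0) + self._items(4, 10, 1.0, 0.0, 1)
        models = fit_im_models(items)
        assert 2 in models and 4 not in models and "all" in models

    def test_single_charge_data_yields_one_model(self):
        models = fit_im_models(self._items(2, 200, 1.0, 0.0, 0))
        assert set(models) == {2}

    def test_no_confident_psms_raises(self):
        with pytest.raises(CalibrationError):
            fit_im_models([(make_psm(0, 0.5), 1.0, 1.0)])


class TestDeltas:
    def identity_model(self):
        x = np.linspace(0, 100, 100)
        return fit_calibration(list(zip(x, x)), "linear")

    def test_delta_is_absolute_difference_on_predicted_scale(self):
        model = self.identity_model()
        assert delta_rt_loess(model, 50.0, 50.0) == pytest.approx(0.0, abs=1e-9)
        assert delta_rt_loess(model, 50.0, 53.5) == pytest.approx(3.5, abs=1e-9)
        assert delta_im(model, 50.0, 53.5) == pytest.approx(3.5, abs=1e-9)

    def test_normalized_divides_by_residual_iqr(self):
        model = self.identity_model()
        got = delta_rt_loess_normalized(model, 50.0, 53.0, residual_scale=2.0)
        assert got == pytest.approx(1.5)

    def test_zero_iqr_falls_back_to_raw_delta(self):
        model = self.identity_model()
        assert model.residual_iqr == pytest.approx(0.0, abs=1e-9)
        with pytest.warns(UserWarning, match="IQR"):
            got = delta_rt_loess_normalized(model, 50.0, 53.0)
        assert got == pytest.approx(3.0, abs=1e-6)

    def test_scale_equivariance_doubling_residuals_halves_normalized(self):
        model = self.identity_model()
        a = delta_rt_loess_normalized(model, 10.0, 20.0, residual_scale=1.0)
        b = delta_rt_loess_normalized(model, 10.0, 20.0, residual_scale=2.0)
        assert a == pytest.approx(2.0 * b)

    def test_delta_invariant_to_affine_rescaling_of_experimental_axis(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 100, 400))
        y = sigmoid((x - 50) / 10) * 80 + rng.normal(0, 0.5, 400)
        m1 = fit_calibration(list(zip(x, y)), "loess", 0.1)
        m2 = fit_calibration(list(zip(3.0 * x + 7.0, y)), "loess", 0.1)
        for xq, yq in ((20.0, 30.0), (60.0, 10.0)):
            d1 = delta_rt_loess(m1, xq, yq)
            d2 = delta_rt_loess(m2, 3.0 * xq + 7.0, yq)
            assert d1 == pytest.approx(d2, abs=1e-6)
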