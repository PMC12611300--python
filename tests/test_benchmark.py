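"""Label-efficiency metrics: AUPC, gain, data savings, sweeps."""

import numpy as np
import pytest

from exprssl import (
    AccuracyCurve,
    BenchmarkData,
    EncoderConfig,
    aupc,
    data_savings,
    default_proportion_grid,
    default_size_grid,
    gain,
    run_curve,
)
from exprssl.finetune import FineTuneConfig
from exprssl.pretraining import ScarfConfig
from exprssl.benchmark import make_pretrainer, pretrain_size_sweep


def const_curve(value, method="m", grid=None):
    grid = default_proportion_grid(0.02) if grid is None else grid
    return AccuracyCurve(grid, np.full(grid.shape, value),
                         np.zeros(grid.shape), 1, method)


class TestAupc:
    def test_constant_curve_rectangle(self):
        assert aupc(const_curve(0.7)) == pytest.approx(0.7 * 0.28, abs=1e-12)

    def test_linear_curve_exact_integral(self):
        grid = np.round(np.arange(0.02, 1.001, 0.01), 6)
        curve = AccuracyCurve(grid, grid, np.zeros(grid.shape), 1, "lin")
        assert aupc(curve) == pytest.approx((0.3 ** 2 - 0.02 ** 2) / 2,
                                            abs=1e-12)
        assert aupc(curve) == pytest.approx(0.0448, abs=1e-12)

    def test_matches_midpoint_riemann_oracle(self):
        rng = np.random.default_rng(0)
        grid = np.round(np.arange(0.02, 1.001, 0.01), 6)
        vals = np.clip(0.5 + np.cumsum(rng.normal(0, 0.01, grid.shape)), 0, 1)
        curve = AccuracyCurve(grid, vals, np.zeros(grid.shape), 1, "r")
        fine = np.arange(0.02, 0.3, 0.001)
        mid = fine + 0.0005
        oracle = np.sum(np.interp(mid, grid, vals) * 0.001)
        assert aupc(curve) == pytest.approx(oracle, abs=1e-3)

    def test_monotone_in_pointwise_dominance(self):
        rng = np.random.default_rng(1)
        grid = default_proportion_grid(0.02)
        for _ in range(20):
            lo = np.clip(rng.uniform(0, 0.8, grid.shape), 0, 1)
            hi = np.clip(lo + rng.uniform(0, 0.2, grid.shape), 0, 1)
            c_lo = AccuracyCurve(grid, lo, np.zeros(grid.shape), 1, "lo")
            c_hi = AccuracyCurve(grid, hi, np.zeros(grid.shape), 1, "hi")
            assert aupc(c_hi) >= aupc(c_lo)

    def test_too_few_points_rejected(self):
        grid = np.array([0.5, 1.0])
        with pytest.raises(ValueError):
            aupc(AccuracyCurve(grid, grid * 0 + 0.5, grid * 0, 1, "m"))


class TestGain:
    def test_self_gain_zero_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        grid = default_proportion_grid(0.02)
        m1 = AccuracyCurve(grid, rng.uniform(0.2, 0.9, grid.shape),
                           np.zeros(grid.shape), 1, "m1")
        m2 = AccuracyCurve(grid, rng.uniform(0.2, 0.9, grid.shape),
                           np.zeros(grid.shape), 1, "m2")
        assert gain(m1, m1).g == pytest.approx(0.0, abs=1e-15)
        assert gain(m1, m2).g == pytest.approx(-gain(m2, m1).g, abs=1e-15)

    def test_constant_curves_closed_form(self):
        g = gain(const_curve(0.8, "a"), const_curve(0.5, "b"))
        assert g.g == pytest.approx(0.3 * 0.28, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        grid = default_proportion_grid(0.02)
        vals = rng.uniform(0.3, 0.6, grid.shape)
        m1 = AccuracyCurve(grid, vals, np.zeros(grid.shape), 1, "m1")
        m1_up = AccuracyCurve(grid, vals + 0.1, np.zeros(grid.shape), 1, "up")
        m2 = const_curve(0.5, "m2")
        delta = gain(m1_up, m2).g - gain(m1, m2).g
        assert delta == pytest.approx(0.1 * 0.28, abs=1e-12)

    def test_mismatched_grids_interpolated(self):
        g1 = np.round(np.arange(0.02, 1.001, 0.02), 6)
        g2 = np.round(np.arange(0.02, 1.001, 0.07), 6)
        m1 = const_curve(0.9, "m1", g1)
        m2 = const_curve(0.4, "m2", g2)
        assert gain(m1, m2).g == pytest.approx(0.5 * 0.28, abs=1e-12)

    def test_uncovered_range_rejected(self):
        grid = np.array([0.5, 0.6, 1.0])
        m = AccuracyCurve(grid, np.full(3, 0.5), np.zeros(3), 1, "m")
        with pytest.raises(ValueError):
            gain(m, m)


class TestDataSavings:
    def test_definitional_values(self):
        pre = const_curve(0.9, "pre")
        base = const_curve(0.8, "base")
        s = data_savings(pre, base)
        assert s.reached and s.p_star == 0.02
        assert s.savings == pytest.approx(0.98)

    def test_identical_curves_max_at_one(self):
        grid = default_proportion_grid(0.02)
        vals = np.linspace(0.2, 0.9, grid.shape[0])
        m = AccuracyCurve(grid, vals, np.zeros(grid.shape), 1, "m")
        s = data_savings(m, m)
        assert s.reached and s.p_star == 1.0 and s.savings == 0.0

    def test_never_reached(self):
        s = data_savings(const_curve(0.5, "pre"), const_curve(0.8, "base"))
        assert not s.reached and s.savings == 0.0


class TestRunCurve:
    def _data(self, small_dataset, small_split):
        _, X, y = small_dataset
        s = small_split
        return BenchmarkData(X.values[s.finetune_idx], y[s.finetune_idx],
                             X.values[s.finetune_val_idx], y[s.finetune_val_idx],
                             X.values[s.test_idx], y[s.test_idx], 4)

    def test_grid_and_repeat_contract(self, small_dataset, small_split,
                                      tiny_encoder_config):
        data = self._data(small_dataset, small_split)
        ft = FineTuneConfig(max_epochs=3, patience=3)
        curve = run_curve("baseline", data, encoder_config=tiny_encoder_config,
                          grid=np.array([0.1, 0.5, 1.0]), n_repeats=2,
                          finetune_config=ft)
        assert curve.proportions.shape == (3,)
        assert np.all(curve.sd_accuracy >= 0)
        single = run_curve("baseline", data,
                           encoder_config=tiny_encoder_config,
                           grid=np.array([0.5, 1.0]), n_repeats=1,
                           finetune_config=ft)
        assert np.all(single.sd_accuracy == 0)

    def test_default_grid_has_99_points(self):
        assert default_proportion_grid().shape[0] == 99

    def test_missing_encoder_raises_named_error(self, small_dataset,
                                                small_split):
        data = self._data(small_dataset, small_split)
        with pytest.raises(ValueError, match="scarf"):
            run_curve("scarf", data)

    def test_pretrained_curve_runs(self, small_dataset, small_split,
                                   tiny_encoder_config):
        _, X, y = small_dataset
        data = self._data(small_dataset, small_split)
        pre = make_pretrainer("scarf", X.values[small_split.pretrain_idx],
                              tiny_encoder_config,
                              ScarfConfig(epochs=2, batch_size=32))
        res = pre.fit()
        rows = []
        curve = run_curve("scarf", data, encoder=res.encoder,
                          grid=np.array([0.2, 1.0]), n_repeats=2,
                          finetune_config=FineTuneConfig(max_epochs=3,
                                                         patience=3),
                          collect_rows=rows)
        assert curve.method == "scarf"
        assert len(rows) == 4
        assert {r["method"] for r in rows} == {"scarf"}


class TestSizeSweep:
    def test_default_size_grid_enumeration(self):
        grid = default_size_grid()
        assert grid.shape[0] == 24  # 0.01..0.05 step 0.01 plus 0.05..1 step 0.05
        assert grid[0] == 0.01 and grid[-1] == 1.0
        assert np.all(np.diff(grid) > 0)

    def test_sweep_table_contract(self, small_dataset, small_split,
                                  tiny_encoder_config):
        _, X, y = small_dataset
        s = small_split
        data = TestRunCurve()._data(small_dataset, small_split)
        table = pretrain_size_sweep(
            "scarf", X.values[s.pretrain_idx], y[s.pretrain_idx], data,
            tiny_encoder_config, ScarfConfig(epochs=1, batch_size=32),
            q_grid=np.array([0.5, 1.0]), p=0.5, n_repeats=1,
            finetune_config=FineTuneConfig(max_epochs=2, patience=2))
        assert len(table) == 3  # baseline row + two q rows
        assert table.iloc[0]["method"] == "baseline"
        assert table.iloc[0]["q"] == 0.0
        assert set(table["method"][1:]) == {"scarf"}

    def test_too_small_q_rejected(self, small_dataset, small_split,
                                  tiny_encoder_config):
        _, X, y = small_dataset
        s = small_split
        data = TestRunCurve()._data(small_dataset, small_split)
        with pytest.raises(ValueError, match="too few"):
            pretrain_size_sweep(
                "scarf", X.values[s.pretrain_idx][:40], y[s.pretrain_idx][:40],
                data, tiny_encoder_config, ScarfConfig(epochs=1),
                q_grid=np.array([0.02]), n_repeats=1)


class TestAccuracyCurveIO:
    def test_tsv_roundtrip(self, tmp_path):
        curve = const_curve(0.6, "demo")
        path = tmp_path / "curve.tsv"
        curve.to_tsv(path)
        back = AccuracyCurve.from_tsv(path)
        assert np.allclose(back.proportions, curve.proportions)
        assert np.allclose(back.mean_accuracy, curve.mean_accuracy)
        assert back.method == "demo"

    def test_invalid_curves_rejected(self):
        grid = np.array([0.1, 0.1, 0.2])
        with pytest.raises(ValueError):
            AccuracyCurve(grid, np.full(3, 0.5), np.zeros(3), 1, "m")
        with pytest.raises(ValueError):
            AccuracyCurve(np.array([0.1, 0.2]), np.array([0.5, 1.5]),
                          np.zeros(2), 1, "m")
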