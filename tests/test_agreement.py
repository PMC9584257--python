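"""Agreement statistics: alignment, ICC (vs ANOVA oracles), Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest

from fidtrack.agreement import (ICC_FORMS, align_series, anova_mean_squares,
                                cohen_kappa, icc, load_coder_csv,
                                table1_analysis)
from fidtrack.analytics import series_from_values
from fidtrack.scenes import expected_kappa, simulate_coder


def icc21_oracle(a, b):
    """Independent ICC(2,1) from raw ANOVA sums of squares, written from the
    textbook definition rather than the package's mean-square helper."""
    y = np.column_stack([a, b]).astype(float)
    n, k = y.shape
    grand = y.mean()
    msr = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = (((y - y.mean(axis=1)[:, None] - y.mean(axis=0)[None, :] + grand) ** 2)
           .sum())
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAlign:
    def test_identical_series(self):
        a = series_from_values([1, 0, 1, 1], resolution="second")
        va, vb, start = align_series(a, a)
        assert np.array_equal(va, vb)

    def test_frame_vs_second_downsampled(self):
        frame_vals = np.zeros(90, np.uint8)
        frame_vals[40:50] = 1  # presence in second 1
        f = series_from_values(frame_vals, resolution="frame")
        s = series_from_values([0, 1, 0], resolution="second")
        va, vb, start = align_series(f, s, resolution="second")
        assert np.array_equal(va, vb)

    def test_disjoint_intervals_error(self):
        a = series_from_values([1, 1], resolution="second", start=0)
        b = series_from_values([1, 1], resolution="second", start=10)
        with pytest.raises(ValueError, match="overlap"):
            align_series(a, b)

    def test_offset_trimming(self):
        a = series_from_values([1, 1, 0, 0], resolution="second", start=0)
        b = series_from_values([1, 0, 1], resolution="second", start=2)
        va, vb, start = align_series(a, b)
        assert start == 2 and len(va) == len(vb) == 2


class TestICC:
    def test_perfect_agreement(self):
        a = np.array([1, 0, 1, 0, 1, 1, 0])
        r = icc(a, a.copy(), form="2,1")
        assert r.estimate == pytest.approx(1.0)

    def test_worked_pairs_match_anova_oracle(self):
        a = np.array([1, 0, 1, 0, 1, 0])
        b = np.array([1, 0, 0, 0, 1, 1])
        r = icc(a, b, form="2,1")
        assert r.estimate == pytest.approx(icc21_oracle(a, b), abs=1e-10)

    @pytest.mark.parametrize("form", ICC_FORMS)
    def test_all_forms_match_pingouin(self, form):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 60)
        b = (a ^ (rng.random(60) < 0.25)).astype(int)
        r = icc(a, b, form=form)
        df = pd.DataFrame({"t": np.repeat(np.arange(60), 2),
                           "r": np.tile(["x", "y"], 60),
                           "s": np.column_stack([a, b]).ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
        row = ref.iloc[ICC_FORMS.index(form)]
        assert r.estimate == pytest.approx(row["ICC"], abs=1e-9)
        assert r.p_value == pytest.approx(row["pval"], abs=1e-9)
        lo, hi = row["CI95"]
        assert r.ci_low == pytest.approx(lo, abs=0.01)
        assert r.ci_high == pytest.approx(hi, abs=0.01)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        r = icc(a, b, form="2,1")
        assert abs(r.estimate) < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert icc(a, b).estimate == pytest.approx(icc(b, a).estimate, abs=1e-12)

    def test_degenerate_flagged(self):
        r = icc(np.zeros(10), np.zeros(10))
        assert not r.defined and np.isnan(r.estimate)

    def test_too_few_targets(self):
        with pytest.raises(ValueError):
            icc(np.array([1]), np.array([1]))


class TestKappa:
    def test_perfect_agreement(self):
        a = np.array([1, 0, 1, 1, 0])
        assert cohen_kappa(a, a.copy()).estimate == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        """a=40, b=10, c=10, d=40 -> p_o = 0.8, p_e = 0.5, kappa = 0.6."""
        x = np.array([1] * 40 + [1] * 10 + [0] * 10 + [0] * 40)
        y = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        r = cohen_kappa(x, y)
        assert r.estimate == pytest.approx(0.6, abs=1e-12)
        assert r.p_value < 0.001

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 200)
        b = (a ^ (rng.random(200) < 0.3)).astype(int)
        assert cohen_kappa(a, b).estimate == pytest.approx(
            sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohen_kappa(a, b).estimate) <= 0.05

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 300)
        b = (a ^ (rng.random(300) < 0.2)).astype(int)
        k1 = cohen_kappa(a, b).estimate
        assert cohen_kappa(b, a).estimate == pytest.approx(k1, abs=1e-12)
        assert cohen_kappa(1 - a, 1 - b).estimate == pytest.approx(k1, abs=1e-12)

    def test_degenerate_table_flagged(self):
        r = cohen_kappa(np.ones(5), np.ones(5))
        assert not r.defined

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.array([]), np.array([]))

    def test_simulated_coder_matches_closed_form(self):
        """Parameter recovery: kappa vs truth converges to its analytic
        expectation under the miss/false-alarm coder model."""
        n, prev, miss, fa = 10_000, 0.2, 0.1, 0.01
        rng = np.random.default_rng(21)
        truth = (rng.random(n) < prev).astype(np.uint8)
        coded = simulate_coder(truth, miss_rate=miss, false_alarm_rate=fa,
                               seed=22)
        r = cohen_kappa(truth, coded)
        expect = expected_kappa(prev, miss, fa)
        se = np.sqrt(r.estimate * (1 - r.estimate) / n) + 3 / np.sqrt(n)
        assert abs(r.estimate - expect) < 3 * se


class TestStudyTable:
    def _inputs(self, n=600, err=0.0, seed=0):
        rng = np.random.default_rng(seed)
        eat = np.zeros(n, np.uint8)
        eat[50:200] = 1
        eat[400:500] = 1
        drink = np.zeros(n, np.uint8)
        drink[250:320] = 1
        rows = []
        for f in range(n):
            if eat[f]:
                rows.append({"frame": f, "timestamp": f / 30, "id": 0,
                             "x": 50.0, "y": 50.0, "rois": "1"})
            if drink[f]:
                rows.append({"frame": f, "timestamp": f / 30, "id": 0,
                             "x": 200.0, "y": 50.0, "rois": "2"})
        log = pd.DataFrame(rows, columns=["frame", "timestamp", "id",
                                          "x", "y", "rois"])
        code_eat = simulate_coder(eat, miss_rate=err, false_alarm_rate=err / 4,
                                  seed=seed + 1)
        code_drink = simulate_coder(drink, miss_rate=err,
                                    false_alarm_rate=err / 4, seed=seed + 2)
        coding = pd.DataFrame({"unit": np.arange(n), "eating": code_eat,
                               "drinking": code_drink, "food_roi": code_eat,
                               "water_roi": code_drink})
        return log, coding

    def test_zero_error_coder_all_ones(self):
        log, coding = self._inputs(err=0.0)
        table = table1_analysis(log, coding, "post_event")
        assert len(table) == 4
        assert np.allclose(table["kappa"], 1.0)
        assert np.allclose(table["icc"], 1.0)

    def test_noisy_coder_degrades_agreement(self):
        log, c0 = self._inputs(err=0.0)
        _, c1 = self._inputs(err=0.15)
        t0 = table1_analysis(log, c0, "post_event")
        t1 = table1_analysis(log, c1, "post_event")
        assert (t1["kappa"] < t0["kappa"]).all()

    def test_corrected_arm_restricts_water_interval(self):
        log, coding = self._inputs(err=0.0)
        # corrupt the drinking coding only outside the corrected interval
        coding.loc[500:, "drinking"] = 1
        full = table1_analysis(log, coding, "post_event")
        corr = table1_analysis(log, coding, "post_event_corrected",
                               corrected_interval=(0, 500))
        k_full = full.set_index("comparison").loc[
            "drinking_vs_water_detection", "kappa"]
        k_corr = corr.set_index("comparison").loc[
            "drinking_vs_water_detection", "kappa"]
        assert k_corr > k_full
        assert k_corr == pytest.approx(1.0)

    def test_real_time_arm_uses_seconds(self):
        log, coding = self._inputs(err=0.0)
        sec = coding.groupby(coding["unit"] // 30).max().reset_index(drop=True)
        table = table1_analysis(log, sec[["eating", "drinking"]].assign(
            unit=np.arange(len(sec))), "real_time")
        assert set(table["comparison"]) == {"eating_vs_food_detection",
                                            "drinking_vs_water_detection"}
        assert np.allclose(table["kappa"], 1.0)

    def test_missing_label_raises(self):
        log, coding = self._inputs()
        with pytest.raises(ValueError, match="eating"):
            table1_analysis(log, coding.drop(columns=["eating"]), "post_event")


def test_coder_csv_schema_tolerance(tmp_path):
    p = tmp_path / "coding.csv"
    pd.DataFrame({"Frame": [0, 1, 2], "Eat": [1, 0, 1],
                  "Drink": [0, 0, 1], "Food": [1, 0, 1]}).to_csv(p, index=False)
    df = load_coder_csv(p)
    assert set(df.columns) >= {"unit", "eating", "drinking", "food_roi"}
    assert df["eating"].tolist() == [1, 0, 1]
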