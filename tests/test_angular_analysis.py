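import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mavi.angular_analysis import (
    amplitude_vs_nadir,
    correlation_by_angle,
    dr_statistic,
    oneway_f,
    pearson_r,
    r_profile_summary,
    significance_stars,
    stability_report,
)
from mavi.errors import DataError, UndefinedStatisticError
from mavi.reference import PUBLISHED_R_BY_ANGLE
from mavi.spectral_core import SampleRecord


class TestAmplitude:
    def test_zero_when_equal(self):
        assert amplitude_vs_nadir(0.42, 0.42) == pytest.approx(0.0)

    def test_hand_value(self):
        assert amplitude_vs_nadir(0.508, 0.500) == pytest.approx(1.60)

    def test_halving(self):
        assert amplitude_vs_nadir(0.250, 0.500) == pytest.approx(-50.0)

    def test_zero_nadir_raises(self):
        with pytest.raises(UndefinedStatisticError):
            amplitude_vs_nadir(0.3, 0.0)


def brute_force_f(groups):
    """Independent oracle: explicit sums of squares."""
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
    k, n = len(groups), len(allv)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestOnewayF:
    def test_identical_groups_zero(self):
        f, dfb, dfw, p = oneway_f([[1.0, 2.0, 3.0]] * 3)
        assert f == 0.0
        assert (dfb, dfw) == (2, 6)

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 10)
        f, *_ = oneway_f([a, b])
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1, 5) for _ in range(3)]
            f, dfb, dfw, p = oneway_f(groups)
            assert f == pytest.approx(brute_force_f(groups), abs=1e-10)
            f_scipy, p_scipy = stats.f_oneway(*groups)
            assert f == pytest.approx(f_scipy, rel=1e-10)
            assert p == pytest.approx(p_scipy, rel=1e-8)

    def test_shift_invariance(self, rng):
        groups = [rng.normal(0, 1, 6) for _ in range(4)]
        f1, *_ = oneway_f(groups)
        f2, *_ = oneway_f([g + 100.0 for g in groups])
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            oneway_f([[1.0], [2.0, 3.0]])

    def test_one_group_rejected(self):
        with pytest.raises(DataError):
            oneway_f([[1.0, 2.0]])

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == ""


class TestPearson:
    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805060619659, abs=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestDr:
    def test_all_equal_zero(self):
        assert dr_statistic([0.8] * 9) == 0.0

    def test_two_values(self):
        assert dr_statistic([0.0, 1.0]) == pytest.approx(2.0)

    def test_published_profile(self):
        # nine values, hand-evaluated: (0.82 - 0.74)/0.782222... = 0.102273
        row = PUBLISHED_R_BY_ANGLE["bolting"]["OPIVI"]
        assert dr_statistic(row) == pytest.approx(0.08 / (7.04 / 9), abs=1e-12)
        assert dr_statistic(row) == pytest.approx(0.10227, abs=5e-6)

    def test_zero_mean_raises(self):
        with pytest.raises(UndefinedStatisticError):
            dr_statistic([-0.5, 0.5])

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        values = np.array([0.2, 0.5, 0.9, 0.4])
        assert dr_statistic(c * values) == pytest.approx(dr_statistic(values), rel=1e-9)

    def test_nonnegative_for_positive_profiles(self, rng):
        for _ in range(25):
            values = rng.uniform(0.05, 1.0, 9)
            assert dr_statistic(values) >= 0.0


class TestCorrelationByAngle:
    @staticmethod
    def _table(slope=2.0):
        rng = np.random.default_rng(5)
        lai = rng.uniform(1, 4, 10)
        rows = []
        meta = {}
        for i, l in enumerate(lai):
            sid = f"S{i}"
            meta[sid] = SampleRecord(sid, "budding", "N2", "NM", float(l))
            for vza in (-15.0, 0.0, 15.0):
                rows.append((sid, vza, "VI", slope * l + 1.0))
        return pd.DataFrame(rows, columns=["sample_id", "vza_deg", "index", "value"]), meta

    def test_linear_gives_one(self):
        vt, meta = self._table()
        r = correlation_by_angle(vt, meta, "VI")
        np.testing.assert_allclose(r.values, 1.0, atol=1e-12)

    def test_negation_flips_sign(self):
        vt, meta = self._table()
        vt["value"] *= -1
        r = correlation_by_angle(vt, meta, "VI")
        np.testing.assert_allclose(r.values, -1.0, atol=1e-12)

    def test_subset_filter(self, vitable90, sim90):
        r_all = correlation_by_angle(vitable90, sim90.metadata, "OPIVI")
        r_budding = correlation_by_angle(
            vitable90, sim90.metadata, "OPIVI", lambda rec: rec.stage == "budding"
        )
        assert len(r_all) == len(r_budding) == 9
        assert not np.allclose(r_all.values, r_budding.values)


class TestStabilityReport:
    def test_published_rows_rank_opivi_first(self):
        # DR on every published sub-dataset row: OPIVI strictly smallest
        for sub, rows in PUBLISHED_R_BY_ANGLE.items():
            drs = {vi: dr_statistic(r) for vi, r in rows.items()}
            assert drs["OPIVI"] < drs["EVI-1"], sub
            assert drs["OPIVI"] < drs["REP"], sub

    def test_published_bolting_values(self):
        drs = {vi: dr_statistic(r) for vi, r in PUBLISHED_R_BY_ANGLE["bolting"].items()}
        assert drs["OPIVI"] == pytest.approx(0.1023, abs=5e-5)
        assert drs["EVI-1"] == pytest.approx(0.2133, abs=5e-5)
        assert drs["REP"] == pytest.approx(0.1741, abs=5e-5)

    def test_angle_flat_index(self):
        rng = np.random.default_rng(11)
        lai = rng.uniform(1, 4, 12)
        rows, meta = [], {}
        for i, l in enumerate(lai):
            sid = f"S{i}"
            stage = "budding" if i % 2 else "flowering"
            nitrogen = f"N{i % 5}"
            coverage = ("SM", "FM", "NM")[i % 3]
            meta[sid] = SampleRecord(sid, stage, nitrogen, coverage, float(l))
            value = 3.0 * l + rng.normal(0, 0.1)
            for vza in (-60.0, 0.0, 60.0):
                rows.append((sid, vza, "FLAT", value))  # identical at every angle
        vt = pd.DataFrame(rows, columns=["sample_id", "vza_deg", "index", "value"])
        report = stability_report(
            vt, meta, sub_datasets={"all": lambda rec: True}
        )
        amp = report.amplitudes.iloc[0]
        assert amp["amplitude_minus60_pct"] == pytest.approx(0.0, abs=1e-9)
        assert amp["amplitude_plus60_pct"] == pytest.approx(0.0, abs=1e-9)
        full = report.anova[report.anova["design"] == "full"].iloc[0]
        assert full["f_value"] == pytest.approx(0.0, abs=1e-18)
        assert report.dr["dr"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_nadir_rejected(self, vitable90, sim90):
        no_nadir = vitable90[vitable90["vza_deg"] != 0.0]
        with pytest.raises(DataError, match="nadir"):
            stability_report(no_nadir, sim90.metadata)

    def test_permutation_invariance(self, vitable90, sim90):
        shuffled = vitable90.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = stability_report(vitable90, sim90.metadata)
        b = stability_report(shuffled, sim90.metadata)
        pd.testing.assert_frame_equal(a.dr, b.dr)
        pd.testing.assert_frame_equal(a.amplitudes, b.amplitudes)

    def test_report_shapes(self, vitable90, sim90):
        report = stability_report(vitable90, sim90.metadata)
        assert set(report.anova["design"]) == {"full", "forward"}
        assert len(report.amplitudes) == 16
        # dfs reflect the actual data: 90 samples x 9 VZAs
        full = report.anova[report.anova["design"] == "full"]
        assert (full["df_between"] == 8).all()
        assert (full["df_within"] == 90 * 9 - 9).all()
        ranked = report.ranking("budding")
        assert list(ranked.columns)[:2] == ["index", "sub_dataset"]

    def test_r_profile_summary_keys(self):
        s = r_profile_summary([0.5, 0.7, 0.6])
        assert s["r_max"] == 0.7 and s["r_min"] == 0.5
        assert s["dr"] == pytest.approx(0.2 / 0.6)
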