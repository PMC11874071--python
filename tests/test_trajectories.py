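"""Age windows, GESD screening, group statistics, and differential curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from braintraj.entropy import profiles_to_frame
from braintraj.errors import ParameterError
from braintraj.io import SubjectRecord
from braintraj.trajectories import (WHOLE_BRAIN, assign_to_windows, bonferroni_alpha,
                                    build_age_windows, differential_curves,
                                    gesd_outliers, group_tests, group_trajectory,
                                    ks_normality, window_ttest)
from _oracles import gesd_bruteforce, student_ttest_bruteforce


class TestWindows:
    def test_default_protocol_has_21_labeled_windows(self):
        windows = build_age_windows(6, 26, 5, 1)
        assert len(windows) == 21
        assert windows[0].label == "6 to 10"
        assert windows[-1].label == "26 to 30"
        # consecutive windows overlap by width - 1 = 4 years
        assert all(b.lo - a.lo == 1 for a, b in zip(windows, windows[1:]))

    def test_single_window(self):
        assert len(build_age_windows(6, 6, 5, 1)) == 1

    def test_step_two(self):
        windows = build_age_windows(6, 10, 5, 2)
        assert [w.lo for w in windows] == [6, 8, 10]

    @given(min_lo=st.integers(0, 40), span=st.integers(0, 40), step=st.integers(1, 7))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_formula(self, min_lo, span, step):
        windows = build_age_windows(min_lo, min_lo + span, 5, step)
        assert len(windows) == span // step + 1

    @pytest.mark.parametrize("kwargs", [
        dict(min_lo=10, max_lo=6), dict(width=0), dict(step=0), dict(min_lo=-1),
        dict(min_lo=6.5)])
    def test_invalid_parameters(self, kwargs):
        full = dict(min_lo=6, max_lo=26, width=5, step=1)
        full.update(kwargs)
        with pytest.raises(ParameterError):
            build_age_windows(**full)


class TestAssignment:
    def _subject(self, age, sid="s"):
        return SubjectRecord(subject_id=sid, group="case", age=age, sex="male")

    def test_interior_age_membership(self):
        windows = build_age_windows(6, 26, 5, 1)
        membership, unassigned = assign_to_windows([self._subject(8.3)], windows)
        hit = [w.lo for w in windows if "s" in membership[w.index]]
        # the rule lo <= 8.3 < lo+5 admits lo in {4..8}; available windows start at 6
        assert hit == [6, 7, 8]
        assert unassigned == []

    def test_oldest_subject_only_in_last_window(self):
        windows = build_age_windows(6, 26, 5, 1)
        membership, _ = assign_to_windows([self._subject(30.78)], windows)
        hit = [w.lo for w in windows if "s" in membership[w.index]]
        assert hit == [26]

    def test_below_range_is_reported_unassigned(self):
        windows = build_age_windows(6, 26, 5, 1)
        membership, unassigned = assign_to_windows([self._subject(5.0)], windows)
        assert unassigned == ["s"]
        assert all(not ids for ids in membership.values())

    @given(age=st.floats(3.0, 35.0, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_never_in_two_disjoint_windows(self, age):
        windows = build_age_windows(6, 26, 5, 1)
        membership, _ = assign_to_windows([self._subject(age)], windows)
        hits = [w for w in windows if "s" in membership[w.index]]
        for a in hits:
            for b in hits:
                assert a.lo < b.lo + b.width and b.lo < a.lo + a.width


class TestKSNormality:
    def test_normal_data_rarely_rejected(self):
        rng = np.random.default_rng(5)
        ps = [ks_normality(rng.standard_normal(500))[1] for _ in range(100)]
        assert np.mean(np.array(ps) > 0.05) >= 0.90

    def test_uniform_data_has_larger_statistic_on_average(self):
        rng = np.random.default_rng(6)
        stat_n, stat_u = [], []
        for _ in range(60):
            stat_n.append(ks_normality(rng.standard_normal(500))[0])
            u = rng.uniform(0, 1, 500)
            stat_u.append(ks_normality((u - 0.5) / u.std(ddof=1))[0])
        assert np.mean(stat_u) > np.mean(stat_n)

    def test_small_sample_skipped(self):
        assert ks_normality([1.0, 2.0, 3.0]) is None


class TestGESD:
    def test_benign_sample_has_no_outliers(self):
        assert gesd_outliers(list(range(1, 11)), max_k=3, alpha=0.05) == []

    def test_gross_outlier_is_flagged(self):
        assert gesd_outliers([1, 2, 3, 4, 5, 100], max_k=2, alpha=0.05) == [5]

    def test_constant_sample_yields_empty_set(self):
        assert gesd_outliers([4.0] * 10, max_k=2, alpha=0.05) == []

    def test_matches_bruteforce_oracle_on_200_samples(self):
        """Identical index sets on random samples with injected contamination."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(8, 51))
            x = rng.standard_normal(n)
            n_bad = int(rng.integers(0, 4))
            for pos in rng.choice(n, size=min(n_bad, n), replace=False):
                x[pos] += rng.choice([-1, 1]) * rng.uniform(4, 12)
            max_k = int(rng.integers(1, max(2, n // 4)))
            if n < max_k + 3:
                max_k = n - 3
            assert gesd_outliers(x, max_k, 0.05) == gesd_bruteforce(x, max_k, 0.05)

    def test_screening_never_increases_sd(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.standard_normal(30)
            x[0] += 8.0
            out = gesd_outliers(x, max_k=3, alpha=0.05)
            if out:
                assert np.delete(x, out).std(ddof=1) <= x.std(ddof=1)


def _profiles_and_records(case_vals, control_vals, age=8.0):
    """One window's worth of subjects with a single target column."""
    records, rows = [], []
    for g, vals in (("case", case_vals), ("control", control_vals)):
        for i, v in enumerate(vals):
            sid = f"{g}{i}"
            records.append(SubjectRecord(subject_id=sid, group=g, age=age, sex="male"))
            rows.append({"subject_id": sid, "R1": v, WHOLE_BRAIN: v})
    return pd.DataFrame(rows).set_index("subject_id"), records


class TestGroupTrajectory:
    def test_identical_constant_groups_give_zero_differential(self):
        profiles, records = _profiles_and_records([1.3] * 6, [1.3] * 6)
        windows = build_age_windows(6, 8, 5, 1)
        traj = group_trajectory(profiles, records, windows)
        assert (traj["sd"].dropna() == 0).all()
        curves = differential_curves(traj)
        assert np.allclose(curves.to_numpy(float), 0.0)

    def test_cell_means_match_oracle_screened_recomputation(self, rng):
        """Cell means equal a direct recomputation excluding oracle-flagged outliers."""
        case = list(rng.normal(1.30, 0.05, 25)) + [2.5]
        ctrl = list(rng.normal(1.32, 0.05, 25))
        profiles, records = _profiles_and_records(case, ctrl)
        windows = build_age_windows(6, 6, 5, 1)
        traj = group_trajectory(profiles, records, windows).set_index(["group", "target"])
        for g, vals in (("case", case), ("control", ctrl)):
            x = np.asarray(vals)
            out = gesd_bruteforce(x, max_k=int(np.ceil(0.1 * len(x))), alpha=0.05)
            survivors = np.delete(x, out)
            cell = traj.loc[(g, "R1")]
            assert cell["mean"] == pytest.approx(survivors.mean(), abs=1e-12)
            assert cell["n"] == len(survivors)
            assert cell["n_outliers_removed"] == len(out)
            assert cell["sem"] == pytest.approx(
                survivors.std(ddof=1) / np.sqrt(len(survivors)), abs=1e-12)

    def test_single_subject_cell_conventions(self):
        profiles, records = _profiles_and_records([1.3], [1.31, 1.32])
        windows = build_age_windows(6, 6, 5, 1)
        traj = group_trajectory(profiles, records, windows).set_index(["group", "target"])
        cell = traj.loc[("case", "R1")]
        assert cell["n"] == 1
        assert cell["sd"] == 0.0
        assert np.isnan(cell["sem"])


class TestWindowTTest:
    def test_identical_samples(self):
        assert window_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        t, p = window_ttest(a, b)
        t0, p0 = student_ttest_bruteforce(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_single_subject_group_is_skipped(self):
        assert window_ttest([1.0], [1.0, 2.0, 3.0]) is None


class TestBonferroni:
    @pytest.mark.parametrize("base,n,expected", [
        (0.05, 5, 0.01),          # five overlapping repeats of each 5-year span
        (0.05, 1, 0.05),
        (0.05, 450, 0.05 / 450),  # 5 repeats x 90 regions: 1.11e-4 exactly
    ])
    def test_quotient(self, base, n, expected):
        assert bonferroni_alpha(base, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_count(self):
        with pytest.raises(ParameterError):
            bonferroni_alpha(0.05, 0)


class TestDifferentialCurves:
    def _cohort(self, rng, deficit_by_age):
        records, rows = [], []
        i = 0
        for age in np.linspace(6.5, 29.5, 80):
            for g in ("case", "control"):
                sid = f"s{i}"
                i += 1
                base = 1.30 + rng.normal(0, 0.002)
                v = base + (deficit_by_age(age) if g == "case" else 0.0)
                records.append(SubjectRecord(subject_id=sid, group=g, age=float(age), sex="male"))
                rows.append({"subject_id": sid, "R1": v, WHOLE_BRAIN: v})
        return pd.DataFrame(rows).set_index("subject_id"), records

    def test_planted_childhood_deficit_recovers_sign(self, rng):
        profiles, records = self._cohort(rng, lambda a: -0.02 if a < 12 else 0.0)
        windows = build_age_windows(6, 26, 5, 1)
        traj = group_trajectory(profiles, records, windows)
        curves = differential_curves(traj)
        row = curves.loc["R1"]
        assert (row[[1, 2]] < 0).all()            # childhood windows negative
        assert row[21] == pytest.approx(0.0, abs=0.005)

    def test_reconstruction_identity(self, rng):
        profiles, records = self._cohort(rng, lambda a: 0.01 * np.sin(a))
        windows = build_age_windows(6, 26, 5, 1)
        traj = group_trajectory(profiles, records, windows)
        curves = differential_curves(traj, include_whole_brain=True)
        means = traj.set_index(["target", "window_index", "group"])["mean"].unstack("group")
        for target in curves.index:
            for w in curves.columns:
                case_m = means.loc[(target, w), "case"]
                ctrl_m = means.loc[(target, w), "control"]
                if np.isfinite(case_m) and np.isfinite(ctrl_m):
                    assert curves.loc[target, w] + ctrl_m == pytest.approx(case_m, abs=1e-12)

    def test_missing_control_cell_is_missing_not_zero(self):
        profiles, records = _profiles_and_records([1.3, 1.31], [])
        windows = build_age_windows(6, 6, 5, 1)
        traj = group_trajectory(profiles, records, windows)
        curves = differential_curves(traj)
        assert np.isnan(curves.loc["R1", 1])


class TestGroupTests:
    def test_bonferroni_flagging(self, rng):
        profiles, records = _profiles_and_records(
            list(rng.normal(1.0, 0.02, 20)), list(rng.normal(1.3, 0.02, 20)))
        windows = build_age_windows(6, 6, 5, 1)
        traj = group_trajectory(profiles, records, windows, keep_values=True)
        tests = group_tests(traj, base_alpha=0.05)
        assert (tests["corrected_alpha"] == 0.05 / len(tests)).all()
        assert tests["significant"].all()
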