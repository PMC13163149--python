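"""Group comparison: GAM adjustment, screening, bootstrap, U test, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from respvar import compare as cmp
from respvar.errors import ParameterError


def _subjects_frame(n, seed=0, group_split=None):
    rng = np.random.default_rng(seed)
    groups = (
        ["patient"] * (n // 2) + ["control"] * (n - n // 2)
        if group_split is None
        else group_split
    )
    return pd.DataFrame(
        {
            "group": groups,
            "age": rng.uniform(20, 75, n),
            "sex": rng.integers(0, 2, n),
            "temperature": rng.normal(36.5, 0.3, n),
            "heart_rate": rng.normal(78, 12, n),
            "pulse_pressure": rng.normal(46, 10, n),
        },
        index=[f"S{i:03d}" for i in range(n)],
    ).rename_axis("subject_id")


class TestGamAdjust:
    def test_age_confounder_removed(self):
        subjects = _subjects_frame(80, seed=1)
        rng = np.random.default_rng(2)
        metric = 0.5 * subjects["age"] + rng.normal(0, 0.1, 80)
        feats = pd.DataFrame({"m": metric})
        adj = cmp.gam_adjust(feats, subjects)
        r = np.corrcoef(adj["m"], subjects["age"])[0, 1]
        assert abs(r) < 0.1

    def test_null_confounder_passthrough(self):
        subjects = _subjects_frame(80, seed=3)
        rng = np.random.default_rng(4)
        feats = pd.DataFrame({"m": rng.normal(5, 1, 80)}, index=subjects.index)
        adj = cmp.gam_adjust(feats, subjects)
        r = np.corrcoef(adj["m"], feats["m"])[0, 1]
        assert r > 0.95

    def test_constant_metric_passthrough(self):
        subjects = _subjects_frame(40, seed=5)
        feats = pd.DataFrame({"m": np.full(40, 2.0)}, index=subjects.index)
        adj = cmp.gam_adjust(feats, subjects)
        assert np.allclose(adj["m"], 2.0)

    def test_missing_covariates_dropped(self):
        subjects = _subjects_frame(40, seed=6)
        subjects.loc["S000", "age"] = np.nan
        feats = pd.DataFrame(
            {"m": np.random.default_rng(0).normal(size=40)}, index=subjects.index
        )
        adj = cmp.gam_adjust(feats, subjects)
        assert len(adj) == 39 and "S000" not in adj.index

    def test_nonlinear_age_effect_removed(self):
        """The s(age) smooth must absorb a curved age dependence, not just linear."""
        subjects = _subjects_frame(100, seed=7)
        rng = np.random.default_rng(8)
        age = subjects["age"]
        metric = 0.002 * (age - 47) ** 2 + rng.normal(0, 0.08, 100)
        adj = cmp.gam_adjust(pd.DataFrame({"m": metric}), subjects)
        r = np.corrcoef(adj["m"], (age - 47) ** 2)[0, 1]
        assert abs(r) < 0.25


class TestShapiro:
    def test_lognormal_rejected(self):
        subjects = _subjects_frame(100, seed=9)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = np.concatenate(
                [rng.lognormal(0, 1.0, 50), rng.lognormal(0, 1.0, 50)]
            )
            feats = pd.DataFrame({"m": vals}, index=subjects.index)
            p = cmp.shapiro_screen(feats, subjects["group"])
            hits += (p.loc["m"] < 0.05).all()
        assert hits >= 0.9 * n_seeds

    def test_gaussian_type_i_calibrated(self):
        subjects = _subjects_frame(100, seed=10)
        rejections = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            feats = pd.DataFrame(
                {"m": rng.standard_normal(100)}, index=subjects.index
            )
            p = cmp.shapiro_screen(feats, subjects["group"])
            rejections.append(float(p.loc["m", "shapiro_p_patient"] < 0.05))
        assert abs(np.mean(rejections) - 0.05) < 0.04

    def test_constant_sample_not_applicable(self):
        subjects = _subjects_frame(20, seed=11)
        feats = pd.DataFrame({"m": np.full(20, 1.0)}, index=subjects.index)
        p = cmp.shapiro_screen(feats, subjects["group"])
        assert p.loc["m"].isna().all()


class TestMannWhitney:
    def test_disjoint_small_samples_vs_enumeration_oracle(self):
        """[1,2,3] vs [4,5,6]: enumerate all C(6,3) rank assignments."""
        subjects = _subjects_frame(
            6, group_split=["patient"] * 3 + ["control"] * 3
        )
        feats = pd.DataFrame({"m": [1, 2, 3, 4, 5, 6]}, index=subjects.index)
        res = cmp.mann_whitney(feats, subjects["group"])
        # oracle: exact null distribution of U by enumeration
        pooled = [1, 2, 3, 4, 5, 6]
        u_obs = 0.0
        for x in [1, 2, 3]:
            for y in [4, 5, 6]:
                u_obs += (x > y) + 0.5 * (x == y)
        null_u = []
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            null_u.append(sum((x > y) + 0.5 * (x == y) for x in xs for y in ys))
        null_u = np.array(null_u)
        # two-sided: as or more extreme in either tail
        d = abs(u_obs - 4.5)
        p_exact = np.mean(np.abs(null_u - 4.5) >= d - 1e-12)
        assert res.loc["m", "U"] == 0.0
        assert p_exact == pytest.approx(0.1)
        assert res.loc["m", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_identical_samples_p_one(self):
        subjects = _subjects_frame(12)
        feats = pd.DataFrame(
            {"m": list(range(6)) + list(range(6))}, index=subjects.index
        )
        res = cmp.mann_whitney(feats, subjects["group"])
        assert res.loc["m", "p"] == pytest.approx(1.0, abs=0.01)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=20)
        subjects = _subjects_frame(20, seed=13)
        feats = pd.DataFrame({"m": vals}, index=subjects.index)
        res1 = cmp.mann_whitney(feats, subjects["group"])
        swapped = subjects["group"].map({"patient": "control", "control": "patient"})
        res2 = cmp.mann_whitney(feats, swapped)
        assert res1.loc["m", "U"] + res2.loc["m", "U"] == pytest.approx(100)  # n1*n2
        assert res1.loc["m", "p"] == pytest.approx(res2.loc["m", "p"])


class TestBootstrap:
    def _frame(self, x, y):
        subjects = _subjects_frame(
            len(x) + len(y),
            group_split=["patient"] * len(x) + ["control"] * len(y),
        )
        feats = pd.DataFrame({"m": list(x) + list(y)}, index=subjects.index)
        return feats, subjects

    def test_shifted_groups_ci_excludes_zero(self):
        feats, subjects = self._frame(range(1, 21), range(11, 31))
        res = cmp.bootstrap_compare(feats, subjects["group"], B=5000, seed=0)
        assert res.loc["m", "ci_hi"] < 0

    def test_single_resample_degenerate_ci(self):
        feats, subjects = self._frame(range(1, 21), range(11, 31))
        res = cmp.bootstrap_compare(feats, subjects["group"], B=1, seed=0)
        assert res.loc["m", "ci_lo"] == res.loc["m", "ci_hi"]

    def test_null_coverage_about_95(self):
        """Identical groups: the 95% CI should contain 0 ~95% of the time."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            feats, subjects = self._frame(rng.normal(size=20), rng.normal(size=20))
            res = cmp.bootstrap_compare(feats, subjects["group"], B=400, seed=seed)
            hits += res.loc["m", "ci_lo"] <= 0 <= res.loc["m", "ci_hi"]
        assert 0.88 <= hits / n_rep <= 1.0

    def test_deterministic_given_seed(self):
        feats, subjects = self._frame(range(10), range(10))
        a = cmp.bootstrap_compare(feats, subjects["group"], B=200, seed=3)
        b = cmp.bootstrap_compare(feats, subjects["group"], B=200, seed=3)
        assert a.equals(b)


class TestFdr:
    def test_hand_applied_bh(self):
        q = cmp.fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert cmp.fdr_correct([0.123])[0] == pytest.approx(0.123)

    def test_all_ones(self):
        assert np.allclose(cmp.fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            cmp.fdr_correct([0.5, 1.5])

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(size=30))
        q = cmp.fdr_correct(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestCompareGroups:
    def test_full_stage_structure(self, cohort_tables):
        feats, subjects = cohort_tables
        result = cmp.compare_groups(feats, subjects, B=200, seed=1)
        t = result.table
        assert len(t) == 35
        for col in (
            "median_patient", "median_control", "diff", "ci_lo", "ci_hi",
            "U", "p", "q", "significant", "shapiro_p_patient", "shapiro_p_control",
        ):
            assert col in t.columns
        assert (t["ci_lo"] <= t["ci_hi"]).all()
        # BH: the largest p keeps q >= p
        worst = t["p"].idxmax()
        assert t.loc[worst, "q"] >= t.loc[worst, "p"] - 1e-12
        assert (t["significant"] == (t["q"] < 0.05)).all()

    def test_deterministic(self, cohort_tables):
        feats, subjects = cohort_tables
        a = cmp.compare_groups(feats, subjects, B=100, seed=2).table
        b = cmp.compare_groups(feats, subjects, B=100, seed=2).table
        pd.testing.assert_frame_equal(a, b)
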