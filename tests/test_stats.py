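"""Classification rules, adjusted contrasts, FDR, regressions, item-wise tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from cofluct.io import CohortTable, RunConfig, ValidationError
from cofluct.stats import (adjusted_contrast, agitation_regression,
                           classify_subjects, fdr_adjust, itemwise_comparison,
                           regroup, run_full_contrast_suite)

CFG = RunConfig()


def _cohort(rows):
    return CohortTable(pd.DataFrame(rows))


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


class TestClassify:
    def _row(self, sid, total, item9, cohort="MDD"):
        return {"subject_id": sid, "cohort": cohort,
                "hamd_total": total, "hamd_09": item9}

    def test_item9_rule(self):
        tab = classify_subjects(_cohort([
            self._row("a", 30, 2), self._row("b", 30, 1),
            self._row("c", 30, 4)]), CFG)
        assert list(tab.df.group_label) == ["A-MDD", "NA-MDD", "A-MDD"]

    def test_inclusion_minimum(self):
        tab = classify_subjects(_cohort([self._row("low", 16, 3)]), CFG)
        assert not tab.df.qc_pass.iloc[0]
        assert "below inclusion" in tab.df.exclusion_reason.iloc[0]

    def test_missing_item9_excluded_with_reason(self):
        tab = classify_subjects(_cohort([
            {"subject_id": "m", "cohort": "MDD", "hamd_total": 25}]), CFG)
        assert not tab.df.qc_pass.iloc[0]
        assert "item 9" in tab.df.exclusion_reason.iloc[0]

    def test_hc_untouched(self):
        tab = classify_subjects(_cohort([
            {"subject_id": "h", "cohort": "HC", "hamd_total": 2,
             "hamd_09": 0}]), CFG)
        assert tab.df.group_label.iloc[0] == "HC" and tab.df.qc_pass.iloc[0]


class TestRegroup:
    def test_cutoff_semantics(self):
        tab = _cohort([
            {"subject_id": "a", "cohort": "MDD", "hama_total": 25,
             "hamd_total": 23},
            {"subject_id": "b", "cohort": "MDD", "hama_total": 24,
             "hamd_total": 30},
            {"subject_id": "c", "cohort": "MDD", "hama_total": 10,
             "hamd_total": 18}])
        hama = regroup(tab, "HAMA")
        assert list(hama) == ["severe", "severe", "moderate"]
        hamd = regroup(tab, "HAMD")
        assert list(hamd) == ["moderate", "severe", "moderate"]

    def test_missing_totals_dropped(self):
        tab = _cohort([{"subject_id": "a", "cohort": "MDD"}])
        assert regroup(tab, "HAMA").isna().all()


class TestAdjustedContrast:
    def test_equals_pooled_t_without_covariates(self, rng):
        y = pd.Series(np.r_[rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)])
        labels = pd.Series(["g1"] * 20 + ["g2"] * 25)
        res = adjusted_contrast(y, labels, "g1", "g2")
        t_ref, p_ref = sstats.ttest_ind(y[:20], y[20:], equal_var=True)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df == 43 and res.n_a == 20 and res.n_b == 25

    def test_label_swap_flips_t(self, rng):
        y = pd.Series(rng.standard_normal(40))
        labels = pd.Series(["a"] * 20 + ["b"] * 20)
        cov = pd.DataFrame({"age": rng.normal(30, 5, 40)})
        r1 = adjusted_contrast(y, labels, "a", "b", cov)
        r2 = adjusted_contrast(y, labels, "b", "a", cov)
        assert r1.t == pytest.approx(-r2.t, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_shifted_group_detected_with_power(self, rng):
        hits = 0
        for _ in range(100):
            y = pd.Series(np.r_[rng.normal(1.0, 1, 40), rng.normal(0, 1, 40)])
            labels = pd.Series(["a"] * 40 + ["b"] * 40)
            res = adjusted_contrast(y, labels, "a", "b")
            hits += (res.t > 0) and (res.p < 0.05)
        assert hits > 90

    def test_listwise_deletion_reported(self, rng):
        y = pd.Series(rng.standard_normal(30))
        labels = pd.Series(["a"] * 15 + ["b"] * 15)
        cov = pd.DataFrame({"age": [np.nan] * 3 + list(rng.normal(30, 5, 27))})
        res = adjusted_contrast(y, labels, "a", "b", cov)
        assert res.n_a == 12 and res.n_b == 15

    def test_small_group_errors(self, rng):
        y = pd.Series(rng.standard_normal(5))
        labels = pd.Series(["a", "a", "b", "b", "b"])
        with pytest.raises(ValidationError, match="n >= 3"):
            adjusted_contrast(y, labels, "a", "b")

    def test_categorical_covariate_encoded(self, rng):
        y = pd.Series(rng.standard_normal(30))
        labels = pd.Series(["a"] * 15 + ["b"] * 15)
        cov = pd.DataFrame({"gender": ["female", "male"] * 15})
        res = adjusted_contrast(y, labels, "a", "b", cov)
        assert any("gender" in c for c in res.covariates)


class TestFDR:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_empty_list(self):
        assert len(fdr_adjust([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_stepup_oracle_exactly(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), bh_oracle(pvals),
                                   atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        adj = fdr_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _mdd_frame(rng, n=119, beta=0.0):
    pred = rng.standard_normal(n)
    agitation = beta * pred + np.sqrt(max(1 - beta ** 2, 0.1)) * \
        rng.standard_normal(n)
    return pd.DataFrame({
        "hamd_09": agitation, "metric": pred,
        "age": rng.normal(34, 10, n),
        "gender": rng.choice(["female", "male"], n),
        "education": rng.integers(0, 6, n),
        "hama_total": rng.normal(22, 6, n)})


class TestAgitationRegression:
    def test_translation_invariance(self, rng):
        df = _mdd_frame(rng, beta=-0.3)
        r1 = agitation_regression(df, "metric")
        df2 = df.assign(metric=df.metric + 100.0)
        r2 = agitation_regression(df2, "metric")
        assert r1.beta_raw == pytest.approx(r2.beta_raw, abs=1e-9)
        assert r1.t == pytest.approx(r2.t, abs=1e-9)

    def test_null_predictor_unbiased(self, rng):
        betas = [agitation_regression(_mdd_frame(rng), "metric").beta_std
                 for _ in range(500)]
        assert abs(np.mean(betas)) < 0.02

    def test_recovers_negative_slope(self, rng):
        errs = []
        for _ in range(200):
            df = _mdd_frame(rng, beta=-0.3)
            r = agitation_regression(df, "metric")
            errs.append(r.beta_std - (-0.3))
        assert abs(np.median(errs)) < 0.08

    def test_sign_consistency(self, rng):
        r = agitation_regression(_mdd_frame(rng, beta=-0.4), "metric")
        assert np.sign(r.beta_raw) == np.sign(r.beta_std) == np.sign(r.t)

    def test_zero_variance_predictor_errors(self, rng):
        df = _mdd_frame(rng)
        df["metric"] = 1.0
        with pytest.raises(ValidationError, match="zero variance"):
            agitation_regression(df, "metric")


class TestItemwise:
    def _items_frame(self, rng, n_a=44, n_b=75, shift_item=None):
        rows = []
        for g, n in (("A-MDD", n_a), ("NA-MDD", n_b)):
            for _ in range(n):
                row = {"group": g}
                for i in range(1, 18):
                    cap = 4 if i in (1, 2, 3, 7, 8, 9, 10, 11, 15) else 2
                    v = rng.integers(0, cap + 1)
                    if g == "A-MDD" and i == shift_item:
                        v = min(v + 1, cap)
                    row[f"hamd_{i:02d}"] = v
                rows.append(row)
        return pd.DataFrame(rows)

    def test_f_equals_t_squared(self, rng):
        df = self._items_frame(rng)
        out = itemwise_comparison(df, df["group"])
        np.testing.assert_allclose(out["F"], out["t"] ** 2, atol=1e-9)

    def test_family_size_is_17(self, rng):
        df = self._items_frame(rng)
        out = itemwise_comparison(df, df["group"])
        assert len(out) == 17
        np.testing.assert_allclose(out["p_fdr"], bh_oracle(out["p"]),
                                   atol=1e-12)

    def test_shifted_item_has_minimal_p(self, rng):
        df = self._items_frame(rng, shift_item=12)
        out = itemwise_comparison(df, df["group"])
        assert out.loc[out.p.idxmin(), "item"] == 12

    def test_constant_item_flagged(self, rng):
        df = self._items_frame(rng)
        df["hamd_17"] = 1
        out = itemwise_comparison(df, df["group"])
        row = out[out.item == 17].iloc[0]
        assert row.p == 1.0 and row.flag == "constant"

    def test_null_items_mostly_nonsignificant(self, rng):
        meds = []
        for _ in range(10):
            df = self._items_frame(rng)
            out = itemwise_comparison(df, df["group"])
            meds.append(np.median(out["p_fdr"]))
        assert np.median(meds) > 0.5


class TestFullSuite:
    def _data(self, rng, n=15):
        rows = []
        for g in ("A-MDD", "NA-MDD", "HC"):
            for k in range(n):
                row = {"subject_id": f"{g}{k}", "group_label": g,
                       "cohort": "HC" if g == "HC" else "MDD",
                       "age": rng.normal(34, 10),
                       "gender": rng.choice(["female", "male"]),
                       "education": int(rng.integers(0, 6)),
                       "hama_total": rng.normal(20, 6),
                       "hamd_total": 0,
                       "mean_trough_duration": rng.normal(5, 1),
                       "mean_peak_height": rng.normal(20, 2),
                       "td_smn": rng.normal(0, 0.4),
                       "fc_static": rng.normal(0.3, 0.1),
                       "fc_high": rng.normal(0.4, 0.1),
                       "fc_low": rng.normal(0.1, 0.1)}
                for i in range(1, 18):
                    row[f"hamd_{i:02d}"] = int(rng.integers(0, 3))
                row["hamd_total"] = sum(row[f"hamd_{i:02d}"]
                                        for i in range(1, 18))
                rows.append(row)
        return pd.DataFrame(rows)

    def test_three_contrasts_per_family_with_fdr(self, rng):
        out = run_full_contrast_suite(self._data(rng), CFG,
                                      include_controls=False)
        c = out["contrasts"]
        assert set(c.family.unique()) == {
            "mean_trough_duration", "mean_peak_height", "td_smn",
            "fc_static", "fc_high", "fc_low"}
        assert (c.groupby("family").size() == 3).all()
        for _, fam in c.groupby("family"):
            np.testing.assert_allclose(fam.p_fdr, bh_oracle(fam.p), atol=1e-12)

    def test_subgroup_contrast_uses_extra_covariates(self, rng):
        out = run_full_contrast_suite(self._data(rng), CFG,
                                      include_controls=False)
        c = out["contrasts"]
        sub = c[c.contrast == "A-MDD vs NA-MDD"].iloc[0]
        hc = c[c.contrast == "A-MDD vs HC"].iloc[0]
        assert "hama_total" in sub.covariates and "dep_subdim" in sub.covariates
        assert "hama_total" not in hc.covariates

    def test_missing_group_names_contrast(self, rng):
        data = self._data(rng)
        data = data[data.group_label != "HC"]
        with pytest.raises(ValidationError, match="HC"):
            run_full_contrast_suite(data, CFG)

    def test_controls_table_present(self, rng):
        data = self._data(rng, n=20)
        data.loc[data.cohort == "MDD", "hamd_total"] = \
            np.asarray(rng.integers(17, 35, (data.cohort == "MDD").sum()))
        data.loc[data.cohort == "MDD", "hama_total"] = \
            np.asarray(rng.integers(10, 40, (data.cohort == "MDD").sum()))
        out = run_full_contrast_suite(data, CFG, include_itemwise=False)
        ctrl = out["controls"]
        assert set(ctrl.regrouping.unique()) <= {"HAMA-24", "HAMD-24"}
        assert len(ctrl) > 0
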