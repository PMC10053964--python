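"""Contingency statistics for the surgical-group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mpclock as mp
from mpclock.cohort_stats import ClassContingency, round_ratio

# published class counts per group (blood and cardiac cohorts)
BLOOD_COUNTS = pd.DataFrame(
    [[22, 42, 10], [79, 87, 73]],
    index=["AVR", "CABG"],
    columns=["decelerated", "normal", "accelerated"],
)
CARDIAC_COUNTS = pd.DataFrame(
    [[27, 25, 16], [55, 108, 61]],
    index=["AVR", "CABG"],
    columns=["decelerated", "normal", "accelerated"],
)


def chi2_loop_oracle(counts: np.ndarray) -> float:
    """Independent Pearson statistic: explicit O/E double loop."""
    total = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def random_table(rng, rows=2, cols=3, low=5, high=80) -> ClassContingency:
    counts = rng.integers(low, high, size=(rows, cols))
    return ClassContingency(
        pd.DataFrame(
            counts,
            index=[f"G{i}" for i in range(rows)],
            columns=[f"C{j}" for j in range(cols)],
        )
    )


class TestBuildContingency:
    @staticmethod
    def _cohort_and_delta(counts: pd.DataFrame):
        rows = []
        for grp in counts.index:
            for cls in counts.columns:
                rows += [(grp, cls)] * int(counts.loc[grp, cls])
        ids = [f"S{i:03d}" for i in range(len(rows))]
        cohort = mp.CohortTable(
            pd.DataFrame(
                {
                    "tissue": "blood",
                    "chronological_age": 66.0,
                    "group": [g for g, _ in rows],
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        delta = pd.DataFrame({"class": [c for _, c in rows]}, index=ids)
        return cohort, delta

    def test_blood_cohort_shares_match_published_percentages(self):
        cohort, delta = self._cohort_and_delta(BLOOD_COUNTS)
        tab = mp.build_contingency(delta, cohort)
        pct = tab.row_percentages(1)
        assert pct.loc["AVR", "normal"] == 56.8     # 42/74
        assert pct.loc["CABG", "accelerated"] == 30.5  # 73/239
        assert pct.loc["AVR", "accelerated"] == 13.5

    def test_cardiac_cohort_decelerated_share(self):
        cohort, delta = self._cohort_and_delta(CARDIAC_COUNTS)
        tab = mp.build_contingency(delta, cohort)
        assert tab.row_percentages(1).loc["AVR", "decelerated"] == 39.7  # 27/68

    def test_single_sample_group_is_all_one_class(self):
        counts = pd.DataFrame(
            [[0, 1, 0], [5, 5, 5]],
            index=["AVR", "CABG"],
            columns=["decelerated", "normal", "accelerated"],
        )
        cohort, delta = self._cohort_and_delta(counts)
        tab = mp.build_contingency(delta, cohort)
        assert tab.row_percentages().loc["AVR", "normal"] == 100.0

    def test_stratified_tables_partition_samples(self, rng):
        cohort, delta = self._cohort_and_delta(BLOOD_COUNTS)
        smoker = rng.random(len(delta)) < 0.4
        cohort.data["smoker"] = smoker
        strata = mp.build_contingency(delta, cohort, stratify_by="smoker")
        assert sum(t.counts.to_numpy().sum() for t in strata.values()) == len(delta)


class TestPearsonChi2:
    def test_perfect_independence_is_zero(self):
        tab = ClassContingency(
            pd.DataFrame([[10, 10], [10, 10]], index=["a", "b"], columns=["x", "y"])
        )
        res = mp.pearson_chi2(tab)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_matches_loop_oracle_on_random_tables(self, rng):
        for _ in range(30):
            tab = random_table(rng)
            res = mp.pearson_chi2(tab)
            assert res.statistic == pytest.approx(
                chi2_loop_oracle(tab.counts.to_numpy(float)), abs=1e-10
            )
            assert res.df == 2

    def test_doubling_counts_doubles_statistic(self, rng):
        tab = random_table(rng)
        doubled = ClassContingency(tab.counts * 2)
        assert mp.pearson_chi2(doubled).statistic == pytest.approx(
            2 * mp.pearson_chi2(tab).statistic, rel=1e-12
        )

    def test_zero_margin_rejected(self):
        tab = ClassContingency(
            pd.DataFrame([[5, 0], [7, 0]], index=["a", "b"], columns=["x", "y"])
        )
        with pytest.raises(ValueError, match="margin"):
            mp.pearson_chi2(tab)


class TestPosthocBH:
    def test_bh_adjustment_hand_computed(self):
        from statsmodels.stats.multitest import multipletests

        raw = [0.01, 0.02, 0.03]
        adj = multipletests(raw, method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_identical_distributions_all_p_one(self):
        tab = ClassContingency(
            pd.DataFrame(
                [[10, 20, 30], [10, 20, 30]],
                index=["AVR", "CABG"],
                columns=["decelerated", "normal", "accelerated"],
            )
        )
        for res in mp.posthoc_bh(tab).values():
            assert res.p_adjusted == pytest.approx(1.0)
            assert res.effects["ratio"] == pytest.approx(1.0)

    def test_adjusted_monotone_and_at_least_raw(self, rng):
        for _ in range(20):
            tab = random_table(rng)
            out = mp.posthoc_bh(tab)
            raws = [r.p_raw for r in out.values()]
            adjs = [r.p_adjusted for r in out.values()]
            assert all(a >= p - 1e-15 for a, p in zip(adjs, raws))
            order = np.argsort(raws)
            assert all(
                adjs[order[i]] <= adjs[order[i + 1]] + 1e-15
                for i in range(len(order) - 1)
            )

    def test_blood_published_posthoc_direction(self):
        out = mp.posthoc_bh(ClassContingency(BLOOD_COUNTS))
        # normal and accelerated classes differ between groups
        assert out["normal"].p_adjusted < 0.05
        assert out["accelerated"].p_adjusted < 0.05


class TestCMH:
    def test_single_stratum_identity_with_pearson(self, rng):
        for _ in range(20):
            tab = random_table(rng)
            n = tab.counts.to_numpy().sum()
            cmh = mp.cmh_test([tab])
            pearson = mp.pearson_chi2(tab)
            assert cmh.statistic == pytest.approx(
                (n - 1) / n * pearson.statistic, abs=1e-8
            )
            assert cmh.df == 2

    def test_independent_strata_give_large_p(self, rng):
        tabs = [
            ClassContingency(
                pd.DataFrame(
                    [[20, 40, 20], [40, 80, 40]],
                    index=["AVR", "CABG"],
                    columns=["d", "n", "a"],
                )
            )
            for _ in range(2)
        ]
        assert mp.cmh_test(tabs).p_raw > 0.99

    def test_replicating_a_stratum_reinforces_association(self, rng):
        tab = ClassContingency(
            pd.DataFrame(
                [[30, 10, 5], [10, 30, 25]],
                index=["AVR", "CABG"],
                columns=["d", "n", "a"],
            )
        )
        one = mp.cmh_test([tab]).statistic
        two = mp.cmh_test([tab, tab]).statistic
        assert two > one

    def test_permutation_null_calibration(self, rng):
        """Under label permutation the CMH p-value is approximately uniform."""
        n = 120
        classes = rng.choice(["d", "n", "a"], size=n)
        strata_labels = rng.choice([0, 1], size=n)
        rejections = 0
        reps = 200
        for _ in range(reps):
            groups = rng.permutation(["AVR"] * 50 + ["CABG"] * 70)
            tabs = []
            for s in (0, 1):
                mask = strata_labels == s
                ct = pd.crosstab(
                    pd.Series(groups[mask]), pd.Series(classes[mask])
                ).reindex(index=["AVR", "CABG"], columns=["d", "n", "a"], fill_value=0)
                tabs.append(ClassContingency(ct))
            if mp.cmh_test(tabs).p_raw < 0.05:
                rejections += 1
        assert rejections / reps < 0.12  # nominal 0.05 plus Monte-Carlo slack

    def test_degenerate_stratum_rejected(self):
        bad = ClassContingency(
            pd.DataFrame(
                [[0, 0, 0], [5, 5, 5]], index=["AVR", "CABG"], columns=["d", "n", "a"]
            )
        )
        with pytest.raises(ValueError, match="degenerate"):
            mp.cmh_test([bad])


class TestMultinomialOR:
    def test_published_cardiac_decelerated_or(self):
        out = mp.multinomial_group_or(
            ClassContingency(CARDIAC_COUNTS),
            reference_class="normal",
            reference_group="AVR",
        )
        or_dec = out["decelerated"].effects["odds_ratio"]
        assert or_dec == pytest.approx((55 * 25) / (108 * 27), rel=1e-4)
        assert round(or_dec, 2) == 0.47
        assert out["decelerated"].p_raw < 0.05

    def test_identical_rows_give_unit_ors(self):
        tab = ClassContingency(
            pd.DataFrame(
                [[10, 20, 30], [10, 20, 30]],
                index=["AVR", "CABG"],
                columns=["decelerated", "normal", "accelerated"],
            )
        )
        for res in mp.multinomial_group_or(tab).values():
            assert res.effects["odds_ratio"] == pytest.approx(1.0, abs=1e-4)

    def test_mle_matches_cross_ratio_oracle(self, rng):
        for _ in range(10):
            tab = random_table(rng, low=10, high=90)
            out = mp.multinomial_group_or(
                tab, reference_class="C0", reference_group="G0"
            )
            c = tab.counts
            for cls in ("C1", "C2"):
                expected = (c.loc["G1", cls] * c.loc["G0", "C0"]) / (
                    c.loc["G1", "C0"] * c.loc["G0", cls]
                )
                assert out[cls].effects["odds_ratio"] == pytest.approx(
                    expected, rel=1e-4
                )

    def test_zero_cell_reported_non_estimable(self):
        tab = ClassContingency(
            pd.DataFrame(
                [[0, 20, 30], [10, 20, 30]],
                index=["AVR", "CABG"],
                columns=["decelerated", "normal", "accelerated"],
            )
        )
        out = mp.multinomial_group_or(tab)
        assert not out["decelerated"].effects["estimable"]
        assert np.isnan(out["decelerated"].effects["odds_ratio"])


class TestStratifiedRatioTable:
    @staticmethod
    def _make(counts_by_level):
        rows = []
        for level, counts in counts_by_level.items():
            for grp in counts.index:
                for cls in counts.columns:
                    rows += [(grp, cls, level)] * int(counts.loc[grp, cls])
        ids = [f"S{i:04d}" for i in range(len(rows))]
        cohort = mp.CohortTable(
            pd.DataFrame(
                {
                    "tissue": "blood",
                    "chronological_age": 66.0,
                    "group": [g for g, _, _ in rows],
                    "smoker": [lv for _, _, lv in rows],
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        delta = pd.DataFrame({"class": [c for _, c, _ in rows]}, index=ids)
        return cohort, delta

    def test_published_smoker_stratum_ratios(self):
        # smoker stratum percentages: AVR 29.2/62.5/8.3, CABG 34.8/31.8/33.3
        smoker = pd.DataFrame(
            [[7, 15, 2], [46, 42, 44]],
            index=["AVR", "CABG"],
            columns=["decelerated", "normal", "accelerated"],
        )
        cohort, delta = self._make({True: smoker})
        out = mp.stratified_ratio_table(delta, cohort, "smoker")
        acc = out[(out["class"] == "accelerated")].iloc[0]
        assert acc["pct_AVR"] == 8.3 and acc["pct_CABG"] == 33.3
        assert round_ratio(acc["ratio"]) == 0.25
        norm = out[(out["class"] == "normal")].iloc[0]
        assert round_ratio(norm["ratio"]) == 2.0

    def test_equal_percentages_give_unit_ratios(self):
        counts = pd.DataFrame(
            [[10, 20, 10], [20, 40, 20]],
            index=["AVR", "CABG"],
            columns=["decelerated", "normal", "accelerated"],
        )
        cohort, delta = self._make({True: counts, False: counts * 2})
        out = mp.stratified_ratio_table(delta, cohort, "smoker")
        assert np.allclose(out["ratio"], 1.0)


class TestCompareContinuous:
    @staticmethod
    def _cells(values_by_cell):
        rows, ids = [], []
        i = 0
        for (grp, cls), values in values_by_cell.items():
            for v in values:
                rows.append((grp, cls, v))
                ids.append(f"S{i:03d}")
                i += 1
        cohort = mp.CohortTable(
            pd.DataFrame(
                {
                    "tissue": "heart",
                    "chronological_age": 66.0,
                    "group": [g for g, _, _ in rows],
                    "SV": [v for _, _, v in rows],
                },
                index=pd.Index(ids, name="sample_id"),
            )
        )
        delta = pd.DataFrame({"class": [c for _, c, _ in rows]}, index=ids)
        return cohort, delta

    def test_identical_cells_give_p_one_zero_difference(self):
        vals = [60.0, 61.0, 62.0, 63.0]
        cohort, delta = self._cells(
            {("AVR", "accelerated"): vals, ("CABG", "accelerated"): vals}
        )
        out = mp.compare_continuous(cohort, "SV", delta)
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["mean_a"].iloc[0] == out["mean_b"].iloc[0]

    def test_welch_statistic_matches_closed_form(self):
        a = [10.0, 12.0, 14.0, 16.0]
        b = [20.0, 21.0, 22.0]
        cohort, delta = self._cells(
            {("AVR", "accelerated"): a, ("AVR", "decelerated"): b}
        )
        out = mp.compare_continuous(cohort, "SV", delta)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        expected_t = (ma - mb) / np.sqrt(va + vb)
        assert abs(out["statistic"].iloc[0]) == pytest.approx(abs(expected_t), rel=1e-12)

    def test_type_i_error_calibrated(self, rng):
        """Two cells from the same distribution reject at ~ the 5% level."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            cohort, delta = self._cells(
                {
                    ("AVR", "accelerated"): rng.normal(60, 10, 20),
                    ("CABG", "accelerated"): rng.normal(60, 10, 20),
                }
            )
            if mp.compare_continuous(cohort, "SV", delta)["p_raw"].iloc[0] < 0.05:
                rejections += 1
        assert 0.02 < rejections / reps < 0.09

    def test_tiny_cell_rejected(self):
        cohort, delta = self._cells(
            {("AVR", "accelerated"): [1.0], ("CABG", "accelerated"): [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            mp.compare_continuous(cohort, "SV", delta)
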