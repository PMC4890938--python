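"""Adjusted prevalence, Wald intervals, combination and concentration tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

import anonprev as ap
from anonprev.classify import Status
from anonprev.prevalence import UndefinedEstimateError


def make_status_frame(rows):
    """rows: list of (sample_no, substance, status)."""
    return pd.DataFrame(
        [
            {"site_id": "hut", "cassette_id": "c1", "slot": i,
             "substance": sub, "status": status}
            for i, sub, status in rows
        ]
    )


class TestWaldCI:
    def test_published_overall_interval(self):
        low, high = ap.wald_ci(154, 430, 0.95)
        assert (round(low, 1), round(high, 1)) == (31.3, 40.3)

    def test_degenerate_proportion_clips_to_zero(self):
        assert ap.wald_ci(0, 100, 0.95) == (0.0, 0.0)

    def test_contaminated_share_lower_bound(self):
        low, _ = ap.wald_ci(66, 430, 0.95)
        assert round(low, 1) == 11.9

    @given(
        st.integers(min_value=1, max_value=500).flatmap(
            lambda n: st.tuples(st.just(n), st.integers(0, n))
        ),
        st.sampled_from([0.9, 0.95, 0.99]),
    )
    def test_matches_statsmodels_normal_interval(self, nk, level):
        n, k = nk
        low, high = ap.wald_ci(k, n, level)
        sm_low, sm_high = proportion_confint(k, n, alpha=1 - level,
                                             method="normal")
        assert low == pytest.approx(max(0.0, sm_low * 100), abs=1e-9)
        assert high == pytest.approx(min(100.0, sm_high * 100), abs=1e-9)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedEstimateError):
            ap.wald_ci(0, 0)


class TestSubstancePrevalence:
    def test_formula_direct(self):
        rows = []
        statuses = (["positive"] * 2 + ["contaminated"] * 2 + ["negative"] * 6)
        for i, s in enumerate(statuses, start=1):
            rows.append((i, "drugX", s))
        est = ap.substance_prevalence(make_status_frame(rows), "drugX")
        assert est.prevalence_pct == pytest.approx(25.0)
        assert est.n_effective == 8
        assert est.ci_low_pct <= est.prevalence_pct <= est.ci_high_pct

    def test_unknown_substance(self):
        frame = make_status_frame([(1, "drugX", "negative")])
        with pytest.raises(KeyError, match="unknown substance"):
            ap.substance_prevalence(frame, "drugY")

    @given(st.lists(st.sampled_from([s.value for s in Status]),
                    min_size=1, max_size=60))
    def test_matches_brute_force_recount(self, statuses):
        frame = make_status_frame(
            [(i, "drugX", s) for i, s in enumerate(statuses, start=1)]
        )
        n_pos = statuses.count("positive")
        n_con = statuses.count("contaminated")
        if len(statuses) == n_con:
            with pytest.raises(UndefinedEstimateError):
                ap.substance_prevalence(frame, "drugX")
            return
        est = ap.substance_prevalence(frame, "drugX")
        assert est.n_positive == n_pos
        assert est.n_contaminated == n_con
        assert est.prevalence_pct == pytest.approx(
            100 * n_pos / (len(statuses) - n_con)
        )

    def test_all_contaminated_is_undefined(self):
        frame = make_status_frame([(1, "drugX", "contaminated")])
        with pytest.raises(UndefinedEstimateError):
            ap.substance_prevalence(frame, "drugX")

    def test_contaminated_sample_cannot_decrease_prevalence(self):
        base = [(i, "drugX", s) for i, s in
                enumerate(["positive"] * 3 + ["negative"] * 7, start=1)]
        with_con = base + [(11, "drugX", "contaminated")]
        p0 = ap.substance_prevalence(make_status_frame(base), "drugX")
        p1 = ap.substance_prevalence(make_status_frame(with_con), "drugX")
        assert p1.n_positive == p0.n_positive
        assert p1.prevalence_pct >= p0.prevalence_pct


class TestSampleLevelRates:
    def _frame(self, n_pos, n_neg, n_con):
        statuses = (["positive"] * n_pos + ["negative"] * n_neg
                    + ["contaminated"] * n_con)
        return pd.DataFrame(
            {"site_id": "hut", "cassette_id": "c1",
             "slot": range(1, len(statuses) + 1), "status": statuses}
        )

    def test_published_shares(self):
        rates = ap.sample_level_rates(self._frame(154, 210, 66))
        assert round(rates["positive"].prevalence_pct, 1) == 35.8
        assert round(rates["negative"].prevalence_pct, 1) == 48.8
        assert round(rates["contaminated"].prevalence_pct, 1) == 15.3
        assert round(rates["negative"].ci_low_pct, 1) == 44.1
        assert round(rates["contaminated"].ci_low_pct, 1) == 11.9

    def test_all_negative(self):
        rates = ap.sample_level_rates(self._frame(0, 25, 0))
        shares = [rates[s].prevalence_pct for s in
                  ("positive", "negative", "contaminated")]
        assert shares == [0.0, 100.0, 0.0]

    def test_shares_partition(self, study_statuses):
        _, sample_status = study_statuses
        rates = ap.sample_level_rates(sample_status)
        total = sum(r.prevalence_pct for r in rates.values())
        assert total == pytest.approx(100.0)

    def test_empty_dataset(self):
        with pytest.raises(UndefinedEstimateError):
            ap.sample_level_rates(self._frame(0, 0, 0))


class TestClassPrevalence:
    @pytest.fixture
    def panel(self):
        return ap.SubstancePanel(
            substances=(
                ap.SubstanceSpec(name="acetazolamide", drug_class="diuretics"),
                ap.SubstanceSpec(name="hydrochlorothiazide",
                                 drug_class="diuretics"),
                ap.SubstanceSpec(name="zolpidem", drug_class="hypnotics"),
            )
        )

    def test_single_member_class_reduces_to_substance(self, panel):
        rows = []
        for i, s in enumerate(["positive", "negative", "contaminated",
                               "negative"], start=1):
            rows += [(i, "acetazolamide", "negative"),
                     (i, "hydrochlorothiazide", "negative"),
                     (i, "zolpidem", s)]
        frame = make_status_frame(rows)
        by_class = ap.class_prevalence(frame, "hypnotics", panel)
        by_substance = ap.substance_prevalence(frame, "zolpidem")
        assert by_class.prevalence_pct == by_substance.prevalence_pct
        assert (by_class.ci_low_pct, by_class.ci_high_pct) == (
            by_substance.ci_low_pct, by_substance.ci_high_pct)

    def test_positive_overrides_contaminated_member(self, panel):
        rows = [(1, "acetazolamide", "positive"),
                (1, "hydrochlorothiazide", "contaminated"),
                (1, "zolpidem", "negative"),
                (2, "acetazolamide", "negative"),
                (2, "hydrochlorothiazide", "negative"),
                (2, "zolpidem", "negative")]
        est = ap.class_prevalence(make_status_frame(rows), "diuretics", panel)
        assert est.n_positive == 1
        assert est.n_contaminated == 0

    @given(st.lists(
        st.tuples(st.sampled_from([s.value for s in Status]),
                  st.sampled_from([s.value for s in Status])),
        min_size=1, max_size=40,
    ))
    def test_matches_set_logic_recount(self, pairs):
        panel = ap.SubstancePanel(
            substances=(
                ap.SubstanceSpec(name="a", drug_class="d"),
                ap.SubstanceSpec(name="b", drug_class="d"),
            )
        )
        rows = []
        for i, (sa, sb) in enumerate(pairs, start=1):
            rows += [(i, "a", sa), (i, "b", sb)]
        n_pos = sum(1 for sa, sb in pairs if "positive" in (sa, sb))
        n_con = sum(1 for sa, sb in pairs
                    if "positive" not in (sa, sb)
                    and "contaminated" in (sa, sb))
        if n_con == len(pairs):
            return  # estimate undefined; covered elsewhere
        est = ap.class_prevalence(make_status_frame(rows), "d", panel)
        assert (est.n_positive, est.n_contaminated) == (n_pos, n_con)

    def test_empty_class_rejected(self, panel):
        with pytest.raises(ap.ConfigurationError):
            ap.class_prevalence(
                make_status_frame([(1, "zolpidem", "negative")]),
                "steroids", panel)


class TestCombinationTable:
    def test_published_fixture_totals(self):
        fix = ap.fixtures.table2_fixture()
        table = ap.combination_table(fix, n_total=ap.fixtures.STUDY_N_TOTAL)
        assert table.attrs["grand_total"] == 32
        assert int(table["gouter"].sum()) == 20
        assert int(table["cosmiques"].sum()) == 12

    def test_published_class_shares(self):
        fix = ap.fixtures.table2_fixture()
        table = ap.combination_table(fix, n_total=430)
        hypnotics = ap.fixtures.class_members_from_table1("hypnotics")
        gluco = ap.fixtures.class_members_from_table1("glucocorticoids")
        assert ap.combination_class_share(table, "acetazolamide",
                                          hypnotics, 430) == 2.1
        assert ap.combination_class_share(table, "acetazolamide",
                                          gluco, 430) == 1.9
        assert ap.combination_class_share(
            table, "acetazolamide", ["hydrochlorothiazide"], 430) == 0.9

    def test_no_multi_positive_samples_gives_empty_table(self):
        frame = make_status_frame(
            [(1, "a", "positive"), (1, "b", "negative"),
             (2, "a", "negative"), (2, "b", "positive")]
        )
        table = ap.combination_table(frame)
        assert table.attrs["grand_total"] == 0
        assert table.empty

    def test_grand_total_counts_multi_substance_samples(self, study_dataset,
                                                        study_statuses):
        config, _, _ = study_dataset
        substance_status, _ = study_statuses
        collapsed = ap.collapse_metabolites_frame(substance_status,
                                                  config.panel)
        table = ap.combination_table(collapsed)
        key = ["site_id", "cassette_id", "slot"]
        pos = collapsed[collapsed["status"] == "positive"]
        expected = int((pos.groupby(key).size() >= 2).sum())
        assert table.attrs["grand_total"] == expected
        assert int(table["pooled"].sum()) == expected


class TestConcentrationSummary:
    def _data(self, concs):
        dataset = pd.DataFrame(
            {"site_id": "hut", "cassette_id": "c1",
             "slot": range(1, len(concs) + 1), "substance": "drugX",
             "concentration_ng_ml": concs,
             "below_lod": [int(c == 0) for c in concs]}
        )
        status = make_status_frame(
            [(i, "drugX", "positive" if c > 0 else "negative")
             for i, c in enumerate(concs, start=1)]
        )
        return dataset, status

    def test_single_positive_has_no_sd(self):
        dataset, status = self._data([23.0, 0.0])
        out = ap.concentration_summary(dataset, status, "drugX")
        assert out == {"substance": "drugX", "n": 1, "mean": 23.0,
                       "sd": None, "min": 23.0, "max": 23.0}

    def test_constant_positives(self):
        dataset, status = self._data([10.0, 10.0, 10.0])
        out = ap.concentration_summary(dataset, status, "drugX")
        assert out["sd"] == 0.0 and out["mean"] == 10.0

    def test_zero_positives_signal_not_exception(self):
        dataset, status = self._data([0.0, 0.0])
        out = ap.concentration_summary(dataset, status, "drugX")
        assert out["n"] == 0 and out["mean"] is None

    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=2,
                    max_size=30))
    def test_matches_two_pass_moments(self, concs):
        dataset, status = self._data(concs)
        out = ap.concentration_summary(dataset, status, "drugX")
        arr = np.asarray(concs)
        mean = arr.sum() / len(arr)
        sd = np.sqrt(((arr - mean) ** 2).sum() / (len(arr) - 1))
        assert out["mean"] == pytest.approx(mean)
        assert out["sd"] == pytest.approx(sd)
        assert out["min"] == min(concs) and out["max"] == max(concs)

    def test_contaminated_excluded(self):
        dataset, status = self._data([100.0, 50.0])
        status.loc[status["slot"] == 2, "status"] = "contaminated"
        out = ap.concentration_summary(dataset, status, "drugX")
        assert out["n"] == 1 and out["mean"] == 100.0
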