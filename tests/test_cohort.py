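"""Eligibility filtering, stratification and transition-pair extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metsyn.classify import classify_table
from metsyn.cohort import (EligibilityError, EmptyCohortError, Stratum,
                           add_strata, apply_eligibility, assign_stratum,
                           extract_pairs, fine_age_band, model_age_band)

from conftest import make_table, make_visit


def two_visits(sid, years=(2010, 2011), **kw):
    return [make_visit(sid, y, **kw) for y in years]


class TestEligibility:
    def test_empty_input_raises(self):
        with pytest.raises(EmptyCohortError):
            apply_eligibility(pd.DataFrame())

    def test_gap_only_subject_excluded(self):
        df = make_table(two_visits("ok") + two_visits("gap", (2010, 2012)))
        kept, report = apply_eligibility(df)
        assert set(kept["subject_id"]) == {"ok"}
        assert report.counts == {"no_consecutive_visits": 1}

    @pytest.mark.parametrize("flag", ["has_chd", "has_t1dm",
                                      "has_familial_hyperlipidemia"])
    def test_disease_history_excluded(self, flag):
        df = make_table(two_visits("ok") + two_visits("sick", **{flag: True}))
        kept, report = apply_eligibility(df)
        assert set(kept["subject_id"]) == {"ok"}
        assert report.counts == {"disease_history": 1}

    def test_invalid_physiology_counts_as_missing_information(self):
        # sbp <= dbp is treated as lacking the necessary information
        rows = two_visits("ok") + two_visits("bad")
        rows[2]["sbp"], rows[2]["dbp"] = 80, 95
        kept, report = apply_eligibility(make_table(rows))
        assert set(kept["subject_id"]) == {"ok"}
        assert report.counts == {"missing_or_invalid_fields": 1}

    def test_priority_order_first_reason_wins(self):
        # age violation outranks a disease flag for the same subject
        df = make_table(two_visits("ok")
                        + two_visits("both", age=95, has_t1dm=True))
        _, report = apply_eligibility(df)
        assert report.counts == {"age_out_of_range": 1}

    def test_planted_violations_are_counted_by_reason(self, rng):
        """100 subjects, 13 planted violations -> 87 retained, 13 reported."""
        rows = []
        for i in range(87):
            rows += two_visits(f"good{i}", age=int(rng.integers(18, 80)))
        planted = {"age_out_of_range": 4, "disease_history": 5,
                   "missing_or_invalid_fields": 2, "no_consecutive_visits": 2}
        k = 0
        for _ in range(planted["age_out_of_range"]):
            rows += two_visits(f"bad{k}", age=17); k += 1
        for _ in range(planted["disease_history"]):
            rows += two_visits(f"bad{k}", has_chd=True); k += 1
        for _ in range(planted["missing_or_invalid_fields"]):
            rows += two_visits(f"bad{k}", hdl=np.nan); k += 1
        for _ in range(planted["no_consecutive_visits"]):
            rows += two_visits(f"bad{k}", years=(2010, 2013)); k += 1
        kept, report = apply_eligibility(make_table(rows))
        assert kept["subject_id"].nunique() == 87
        assert report.counts == planted
        assert report.n_excluded == 13
        # reasons partition the excluded set
        all_ids = [s for ids in report.subjects.values() for s in ids]
        assert len(all_ids) == len(set(all_ids)) == 13

    def test_exclusion_report_json_round_trips(self, tmp_path):
        import json
        df = make_table(two_visits("ok") + two_visits("sick", has_chd=True))
        _, report = apply_eligibility(df)
        path = tmp_path / "report.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["counts"] == {"disease_history": 1}


class TestStrata:
    @pytest.mark.parametrize("age,band", [(49, "18-49"), (50, "50+"),
                                          (18, "18-49"), (88, "50+")])
    def test_model_band_boundaries(self, age, band):
        assert model_age_band(age) == band

    @pytest.mark.parametrize("age,band", [(39, "18-39"), (40, "40-49"),
                                          (59, "50-59"), (60, "60+")])
    def test_fine_band_boundaries(self, age, band):
        assert fine_age_band(age) == band

    def test_assign_stratum_examples(self):
        assert assign_stratum("male", 49).key == "men_18_49"
        assert assign_stratum("female", 50).key == "women_50plus"

    def test_out_of_range_age_raises(self):
        with pytest.raises(EligibilityError):
            assign_stratum("male", 17)

    def test_stratum_key_round_trip(self):
        for s in [Stratum("male", "18-49"), Stratum("female", "50+")]:
            assert Stratum.from_key(s.key) == s

    def test_stratum_fixed_at_baseline_even_when_crossing_50(self):
        rows = [make_visit("s", 2010 + k, age=48 + k) for k in range(4)]
        cohort = add_strata(classify_table(make_table(rows)))
        assert (cohort["age_band"] == "18-49").all()

    def test_stratum_invariant_under_row_reordering(self, rng):
        rows = [make_visit(f"s{i}", 2010 + j, age=30 + i)
                for i in range(10) for j in range(3)]
        df = classify_table(make_table(rows))
        a = add_strata(df)
        b = add_strata(df.sample(frac=1, random_state=3))
        a = a.set_index(["subject_id", "visit_year"]).sort_index()
        b = b.set_index(["subject_id", "visit_year"]).sort_index()
        pd.testing.assert_series_equal(a["age_band"], b["age_band"])


def brute_force_pairs(years):
    ys = sorted(years)
    return sum(1 for a, b in zip(ys, ys[1:]) if b - a == 1)


class TestPairs:
    def _cohort(self, visit_years, sid="s"):
        rows = [make_visit(sid, y) for y in visit_years]
        return add_strata(classify_table(make_table(rows)))

    def test_three_consecutive_years_give_two_pairs(self):
        pairs = extract_pairs(self._cohort([2010, 2011, 2012]))
        assert list(pairs["cycle"]) == [1, 2]

    def test_gap_contributes_nothing(self):
        pairs = extract_pairs(self._cohort([2010, 2011, 2013, 2014]))
        assert list(pairs["cycle"]) == [1, 4]

    def test_single_visit_no_pairs(self):
        assert len(extract_pairs(self._cohort([2012]))) == 0

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sets(st.integers(2010, 2015), min_size=1, max_size=6),
                    min_size=1, max_size=8))
    def test_pair_count_matches_brute_force(self, year_sets):
        rows = []
        for i, ys in enumerate(year_sets):
            rows += [make_visit(f"s{i}", y) for y in sorted(ys)]
        cohort = add_strata(classify_table(make_table(rows)))
        pairs = extract_pairs(cohort)
        assert len(pairs) == sum(brute_force_pairs(ys) for ys in year_sets)

    def test_pair_states_follow_the_classified_states(self):
        rows = [make_visit("s", 2010, state_flags=(0, 0, 0, 0)),
                make_visit("s", 2011, state_flags=(1, 1, 1, 0))]
        pairs = extract_pairs(add_strata(classify_table(make_table(rows))))
        assert pairs.loc[0, "from_state"] == "NONE"
        assert pairs.loc[0, "to_state"] == "MS"
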