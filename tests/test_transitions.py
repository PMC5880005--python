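"""Cycle tallies, cycle averaging, and the published reference matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metsyn.transitions as tr
from metsyn.states import STATE_ORDER, InputError, MetabolicState
from metsyn.transitions import (FixtureIntegrityError, TransitionMatrix,
                                cycle_matrix, estimate_matrices,
                                load_printed_matrix, mean_matrix)

LABELS = [s.value for s in STATE_ORDER]


def pair_frame(triples):
    """triples: (cycle, from_label, to_label)."""
    cols = ["subject_id", "sex", "age_band", "cycle", "from_state", "to_state"]
    return pd.DataFrame(
        [(f"s{i}", "male", "18-49", c, f, t)
         for i, (c, f, t) in enumerate(triples)], columns=cols)


class TestCycleMatrix:
    def test_single_pair_row_is_one_hot_others_undefined(self):
        props, denom = cycle_matrix(pair_frame([(1, "NONE", "MS")]), 1)
        assert denom[0] == 1
        assert props[0, 11] == 1.0 and props[0, :11].sum() == 0
        assert np.isnan(props[1:]).all()

    def test_no_pairs_all_rows_undefined(self):
        props, denom = cycle_matrix(pair_frame([]), 3)
        assert np.isnan(props).all() and denom.sum() == 0

    @pytest.mark.parametrize("cycle", [0, 6, -1])
    def test_cycle_out_of_range(self, cycle):
        with pytest.raises(InputError):
            cycle_matrix(pair_frame([]), cycle)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 5), st.sampled_from(LABELS),
                              st.sampled_from(LABELS)),
                    min_size=1, max_size=80),
           st.integers(1, 5))
    def test_matches_brute_force_tally(self, triples, cycle):
        props, denom = cycle_matrix(pair_frame(triples), cycle)
        # independent tally by dict counting
        from collections import Counter
        counts = Counter((f, t) for c, f, t in triples if c == cycle)
        from_totals = Counter(f for c, f, _ in triples if c == cycle)
        for i, fi in enumerate(LABELS):
            if from_totals[fi] == 0:
                assert np.isnan(props[i]).all()
                continue
            assert denom[i] == from_totals[fi]
            for j, tj in enumerate(LABELS):
                expected = counts[(fi, tj)] / from_totals[fi]
                assert props[i, j] == pytest.approx(expected, abs=1e-12)


class TestMeanMatrix:
    def test_identical_cycles_average_to_themselves(self, printed):
        P = printed["men_18_49"].probs
        denom = np.full(12, 100)
        m = mean_matrix([(P.copy(), denom)] * 5, stratum="x")
        np.testing.assert_allclose(m.probs, P, atol=1e-12)

    def test_partial_rows_average_over_defined_cycles_only(self):
        a = np.full((12, 12), np.nan)
        b = np.full((12, 12), np.nan)
        a[0] = 0.0; a[0, 0], a[0, 1] = 0.4, 0.6
        b[0] = 0.0; b[0, 0], b[0, 1] = 0.6, 0.4
        m = mean_matrix([(a, np.eye(12)[0] * 10), (b, np.eye(12)[0] * 10)])
        assert m.probs[0, 0] == pytest.approx(0.5)
        assert m.probs[0, 1] == pytest.approx(0.5)

    def test_never_observed_rows_become_identity_and_flagged(self):
        a = np.full((12, 12), np.nan)
        a[0] = 0.0; a[0, 0] = 1.0
        m = mean_matrix([(a, np.eye(12)[0] * 5)])
        assert set(m.filled_rows) == set(STATE_ORDER[1:])
        np.testing.assert_allclose(m.probs[1:], np.eye(12)[1:])

    def test_invariant_to_cycle_ordering(self, rng):
        cycles = []
        for _ in range(4):
            raw = rng.random((12, 12))
            raw /= raw.sum(1, keepdims=True)
            cycles.append((raw, np.full(12, 50)))
        a = mean_matrix(cycles)
        b = mean_matrix(cycles[::-1])
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_rows_are_stochastic_after_averaging(self, rng):
        cycles = []
        for _ in range(5):
            raw = rng.random((12, 12))
            raw /= raw.sum(1, keepdims=True)
            raw[rng.random(12) < 0.3] = np.nan
            cycles.append((raw, np.full(12, 30)))
        m = mean_matrix(cycles)
        np.testing.assert_allclose(m.probs.sum(1), 1.0, atol=1e-9)


class TestPrintedMatrices:
    def test_all_four_load_row_stochastic(self, printed):
        for m in printed.values():
            np.testing.assert_allclose(m.probs.sum(1), 1.0, atol=1e-9)
            assert ((m.probs >= 0) & (m.probs <= 1)).all()

    def test_men_18_49_none_row_leading_entry(self, printed):
        # the NONE row sums to exactly 100.00 in percent, so no
        # renormalisation distortion: self-retention is exactly 0.6644
        assert printed["men_18_49"].probs[0, 0] == pytest.approx(0.6644, abs=1e-12)

    def test_selected_published_entries(self, printed):
        ms = MetabolicState.MS.index
        assert printed["men_18_49"].to_frame().loc["MS", "MS"] == \
            pytest.approx(0.7525, abs=2e-4)
        assert printed["women_50plus"].probs[
            MetabolicState.HTN_HYP.index, ms] == pytest.approx(0.2499, abs=2e-4)

    def test_alternate_corrupt_cell_placement(self, printed):
        alt = load_printed_matrix("men_18_49", alternate_corrupt_cell=True)
        i = MetabolicState.HYP.index
        default = printed["men_18_49"]
        assert alt.probs[i, MetabolicState.OW_DYS.index] == pytest.approx(
            default.probs[i, MetabolicState.OW_HYP.index])
        assert alt.probs[i, MetabolicState.OW_HYP.index] == 0.0
        with pytest.raises(InputError):
            load_printed_matrix("women_18_49", alternate_corrupt_cell=True)

    def test_unknown_fixture_name(self):
        with pytest.raises(InputError):
            load_printed_matrix("men_90plus")

    def test_tampered_row_sum_raises_naming_the_row(self, monkeypatch):
        payload = tr._load_fixture_payload("men_18_49")
        payload["percent"][3][0] += 1.0  # break the DYS row
        monkeypatch.setattr(tr, "_load_fixture_payload", lambda name: payload)
        with pytest.raises(FixtureIntegrityError, match="DYS"):
            load_printed_matrix("men_18_49")


class TestEstimateMatrices:
    def test_groups_by_stratum(self):
        pairs = pd.concat([
            pair_frame([(1, "NONE", "NONE"), (2, "NONE", "OW")]),
            pair_frame([(1, "MS", "MS")]).assign(sex="female", age_band="50+"),
        ], ignore_index=True)
        mats = estimate_matrices(pairs)
        assert set(mats) == {"men_18_49", "women_50plus"}
        assert mats["men_18_49"].probs[0, 0] == pytest.approx(0.5)
        assert mats["women_50plus"].probs[11, 11] == 1.0

    def test_matrix_validation_rejects_bad_rows(self):
        bad = np.eye(12); bad[0, 0] = 0.9
        with pytest.raises(InputError):
            TransitionMatrix(stratum="x", probs=bad)
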