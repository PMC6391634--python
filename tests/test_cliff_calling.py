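import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acmine.chem_io import Compound, Status, TargetSet
from acmine.cliff_calling import (
    CLIFF_ISD,
    CLIFF_SD,
    Cliff,
    QualificationCriterion,
    call_isd_cliffs,
    call_original_cliffs,
    call_sd_cliffs,
    compute_set_threshold,
    determine_acrp_compounds,
    qualify_target_set,
)
from acmine.errors import EmptyDistributionError
from acmine.fragmentation import MMP, RMMP, MatchedPair, find_matched_pairs, tsr_pairs

from conftest import active, inactive


def _pairs_from_deltas(deltas, base=5.0):
    """One synthetic MatchedPair per delta plus the pki map realizing it."""
    pairs, pki = [], {}
    for i, d in enumerate(deltas):
        a, b = f"A{i}", f"B{i}"
        pki[a], pki[b] = base, base + d
        pairs.append(MatchedPair(a, b, "*C", "*N", "*O", MMP, 12, 1, 1))
    return pairs, pki


class TestQualifyTargetSet:
    def _set(self, pkis):
        return TargetSet(
            "T1",
            actives=[active(f"C{i}", "CCO", p) for i, p in enumerate(pkis)],
        )

    def test_flat_set_rejected(self):
        assert not qualify_target_set(self._set([7.0] * 100))

    def test_uniform_spread_accepted(self):
        # sample sd of linspace(5, 9, 100) ~ 1.17 >= 1.0
        assert qualify_target_set(self._set(np.linspace(5, 9, 100)))

    def test_too_few_compounds(self):
        assert not qualify_target_set(self._set(np.linspace(5, 9, 10)))

    def test_custom_predicate(self):
        crit = QualificationCriterion(predicate=lambda ts: True)
        assert qualify_target_set(self._set([7.0]), crit)

    def test_monotone_in_criteria(self):
        pkis = np.linspace(5, 9, 60)
        loose = QualificationCriterion(min_compounds=50, min_sigma=1.0)
        tight = QualificationCriterion(min_compounds=70, min_sigma=1.5)
        ts = self._set(pkis)
        assert qualify_target_set(ts, loose)
        assert not qualify_target_set(ts, tight)


class TestComputeSetThreshold:
    def test_constant_deltas(self):
        pairs, pki = _pairs_from_deltas([1.0, 1.0, 1.0])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        assert th.mean_delta == pytest.approx(1.0)
        assert th.sigma_delta == pytest.approx(0.0)
        assert th.threshold == pytest.approx(1.0)

    def test_two_deltas_hand_value(self):
        pairs, pki = _pairs_from_deltas([0.5, 1.5])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        # 1.0 + 2 * stdev({0.5, 1.5}) = 1 + 2/sqrt(2)
        assert th.threshold == pytest.approx(2.414213562373095, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(EmptyDistributionError):
            compute_set_threshold([], {}, "T1", MMP)

    @given(
        st.lists(st.floats(0.0, 6.0, allow_nan=False), min_size=2, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_statistics_oracle(self, deltas):
        pairs, pki = _pairs_from_deltas(deltas)
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        expected = statistics.fmean(deltas) + 2 * statistics.stdev(deltas)
        assert th.threshold == pytest.approx(expected, abs=1e-9)

    def test_threshold_at_least_mean(self):
        pairs, pki = _pairs_from_deltas([0.1, 2.2, 0.9, 3.3])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        assert th.threshold >= th.mean_delta >= 0


class TestCallSdCliffs:
    def test_outlier_called_iff_above_hand_threshold(self):
        deltas = [0.2] * 20 + [3.0]
        pairs, pki = _pairs_from_deltas(deltas)
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        hand = statistics.fmean(deltas) + 2 * statistics.stdev(deltas)
        cliffs = call_sd_cliffs(pairs, pki, th)
        expected_ids = {p.ids for p, d in zip(pairs, deltas) if d >= hand}
        assert {c.ids for c in cliffs} == expected_ids
        assert expected_ids == {pairs[-1].ids}  # the 3.0 outlier qualifies

    def test_all_equal_deltas_all_cliffs(self):
        pairs, pki = _pairs_from_deltas([1.5, 1.5, 1.5])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        assert len(call_sd_cliffs(pairs, pki, th)) == 3  # inclusive boundary

    def test_empty_pairs(self):
        pairs, pki = _pairs_from_deltas([1.0])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        assert call_sd_cliffs([], pki, th) == []

    def test_potent_partner_is_higher(self):
        pairs, pki = _pairs_from_deltas([2.0])
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        (cliff,) = call_sd_cliffs(pairs, pki, th)
        assert pki[cliff.potent_partner] > pki[cliff.other_partner]


class TestCallOriginalCliffs:
    def test_boundary_inclusive(self):
        pairs, pki = _pairs_from_deltas([2.0, 1.99])
        cliffs = call_original_cliffs(pairs, pki, MMP)
        assert len(cliffs) == 1
        assert cliffs[0].delta_pki == pytest.approx(2.0)

    def test_threshold_ordering_implies_inclusion(self):
        deltas = [0.5, 1.0, 2.1, 2.5, 3.5]
        pairs, pki = _pairs_from_deltas(deltas)
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        sd = {c.ids for c in call_sd_cliffs(pairs, pki, th)}
        orig = {c.ids for c in call_original_cliffs(pairs, pki, MMP)}
        if th.threshold < 2.0:
            assert orig <= sd
        else:
            assert sd <= orig


class TestDetermineAcrp:
    def _set_and_cliffs(self):
        cpds = [
            active("X", "CCO", 8.0),
            active("Y", "CCN", 9.0),
            active("L1", "CCC", 5.0),
            active("L2", "CC=O", 6.2),
            active("Z", "CCF", 8.7),  # no cliff but above median
        ]
        ts = TargetSet("T1", actives=cpds)
        pki = ts.pki_map
        # hand-built sd cliffs (X appears twice as the potent partner)
        cliffs = [
            Cliff(
                MatchedPair(lo, hi, "*C", "*N", "*O", MMP, 12, 1, 1),
                CLIFF_SD, MMP, hi, lo, pki[hi] - pki[lo],
            )
            for lo, hi in (("L1", "X"), ("L2", "Y"), ("L2", "X"))
        ]
        return ts, cliffs

    def test_median_and_membership(self):
        ts, cliffs = self._set_and_cliffs()
        # potent partners: X (twice) and Y -> unique {8.0, 9.0}, median 8.5
        assert {c.potent_partner for c in cliffs} == {"X", "Y"}
        acrp = determine_acrp_compounds(cliffs, ts)
        assert acrp.acrp_threshold == pytest.approx(8.5)
        assert acrp.acrp_compound_ids == {"Y", "Z"}  # Z joins without a cliff

    def test_inclusive_at_threshold(self):
        ts = TargetSet(
            "T1",
            actives=[active("P", "CCO", 7.5), active("Q", "CCN", 7.5),
                     active("L", "CCC", 4.0)],
        )
        pairs = [MatchedPair("L", "P", "*C", "*N", "*O", MMP, 12, 1, 1)]
        th = compute_set_threshold(pairs, ts.pki_map, "T1", MMP)
        cliffs = call_sd_cliffs(pairs, ts.pki_map, th)
        acrp = determine_acrp_compounds(cliffs, ts)
        assert acrp.acrp_threshold == pytest.approx(7.5)
        assert acrp.acrp_compound_ids == {"P", "Q"}

    def test_no_cliffs_no_acrp(self):
        ts = TargetSet("T1", actives=[active("A", "CCO", 7.0)])
        assert determine_acrp_compounds([], ts) is None

    def test_acrp_subset_of_actives(self):
        ts, cliffs = self._set_and_cliffs()
        acrp = determine_acrp_compounds(cliffs, ts)
        assert acrp.acrp_compound_ids <= ts.active_ids


class TestCallIsdCliffs:
    def _scenario(self, acrp_has_partner=True):
        # analog series on a decent-sized core so tsr passes
        core = "c1ccc2ncccc2c1"
        a1 = active("A1", f"CC{core}", 9.0)
        a2 = active("A2", f"CCC{core}", 4.0)
        i1 = inactive("I1", f"CCO{core}")
        ts = TargetSet("T1", actives=[a1, a2], inactives=[i1])
        pairs = tsr_pairs(find_matched_pairs(ts.actives, MMP))
        th = compute_set_threshold(pairs, ts.pki_map, "T1", MMP)
        cliffs = call_sd_cliffs(pairs, ts.pki_map, th)
        acrp = determine_acrp_compounds(cliffs, ts)
        return ts, acrp

    def test_acrp_with_inactive_analog(self):
        ts, acrp = self._scenario()
        assert "A1" in acrp.acrp_compound_ids
        cliffs = call_isd_cliffs(acrp, ts, MMP)
        assert {(c.potent_partner, c.other_partner) for c in cliffs} == {("A1", "I1")}
        (cliff,) = cliffs
        assert cliff.cliff_type == CLIFF_ISD
        assert cliff.delta_pki is None

    def test_non_acrp_active_not_paired(self):
        ts, acrp = self._scenario()
        assert "A2" not in acrp.acrp_compound_ids
        cliffs = call_isd_cliffs(acrp, ts, MMP)
        assert all(c.potent_partner != "A2" for c in cliffs)

    def test_no_inactives_empty(self):
        ts, acrp = self._scenario()
        bare = TargetSet("T1", actives=ts.actives, inactives=[])
        assert call_isd_cliffs(acrp, bare, MMP) == []

    def test_two_inactive_analogs_no_pair(self):
        core = "c1ccc2ncccc2c1"
        ts = TargetSet(
            "T1",
            actives=[active("A1", f"CC{core}", 9.0), active("A2", f"CCC{core}", 4.0)],
            inactives=[inactive("I1", f"CCO{core}"), inactive("I2", f"CCN{core}")],
        )
        _, acrp = self._scenario()
        cliffs = call_isd_cliffs(acrp, ts, MMP)
        for c in cliffs:
            assert {c.potent_partner, c.other_partner} != {"I1", "I2"}

    def test_isd_rmmp_subset_of_mmp(self, small_synthetic_set):
        ts, _, _ = small_synthetic_set
        for family in (MMP,):
            pairs = tsr_pairs(find_matched_pairs(ts.actives, family))
            th = compute_set_threshold(pairs, ts.pki_map, ts.target_id, family)
            sd = call_sd_cliffs(pairs, ts.pki_map, th)
            acrp = determine_acrp_compounds(sd, ts)
            if acrp is None:
                continue
            mmp_isd = {c.ids for c in call_isd_cliffs(acrp, ts, MMP)}
            rmmp_isd = {c.ids for c in call_isd_cliffs(acrp, ts, RMMP)}
            assert rmmp_isd <= mmp_isd


class TestShiftInvariance:
    def test_shift_preserves_thresholds_and_cliffs(self, small_synthetic_set):
        ts, _, _ = small_synthetic_set
        shifted = ts.shifted(1.7)
        pairs = tsr_pairs(find_matched_pairs(ts.actives, MMP))
        pairs_s = tsr_pairs(find_matched_pairs(shifted.actives, MMP))
        assert {p.ids for p in pairs} == {p.ids for p in pairs_s}
        th = compute_set_threshold(pairs, ts.pki_map, "T", MMP)
        th_s = compute_set_threshold(pairs_s, shifted.pki_map, "T", MMP)
        assert th_s.threshold == pytest.approx(th.threshold)
        sd = {c.ids for c in call_sd_cliffs(pairs, ts.pki_map, th)}
        sd_s = {c.ids for c in call_sd_cliffs(pairs_s, shifted.pki_map, th_s)}
        assert sd == sd_s


class TestThresholdConsistency:
    def test_half_normal_convergence(self):
        # |N(0, sigma^2)| at n = 10^4: sample mean/sd within 5% of population
        rng = np.random.default_rng(42)
        sigma = 1.3
        deltas = np.abs(rng.normal(0.0, sigma, size=10_000))
        pairs, pki = _pairs_from_deltas(deltas.tolist())
        th = compute_set_threshold(pairs, pki, "T1", MMP)
        pop_mean = sigma * np.sqrt(2 / np.pi)
        pop_sd = sigma * np.sqrt(1 - 2 / np.pi)
        assert th.mean_delta == pytest.approx(pop_mean, rel=0.05)
        assert th.sigma_delta == pytest.approx(pop_sd, rel=0.05)
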