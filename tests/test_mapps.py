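"""Peptide mapping, cluster detection and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mappskit.constructs import ProteinConstruct, RegionWindow
from mappskit.errors import ConsistencyError, CoverageError, OutOfBoundsError
from mappskit.mapps import (
    EluateRecord,
    MappedPeptide,
    cluster_frequency,
    cluster_presence,
    cluster_responder_rate,
    detect_clusters,
    map_peptides,
    peptide_count_decrease,
    peptides_overlapping,
    percent_inhibition,
    position_coverage,
    summarize_donor,
    summarize_donor_construct,
    within_donor_cluster_pct,
)
from mappskit.reference_tables import (
    DONOR_CONSTRUCT_SUMMARY,
    presence_pattern,
    within_donor_pct,
)
from mappskit.rounding import round_half_away


def _mp(start, end, donor="d", construct="c"):
    rec = EluateRecord(donor, construct, "A" * (end - start + 1))
    return MappedPeptide(rec, start, end)


class TestMapPeptides:
    CONSTRUCT = {"c": ProteinConstruct("c", "DRGATALELMVLNVPRL")}

    def test_substring_search(self):
        # hand indexing: D1 R2 G3 A4 T5 A6 L7 E8 L9 M10 -> L-E-L-M at 7..10
        mapped, unmapped = map_peptides(
            [EluateRecord("d", "c", "LELM")], self.CONSTRUCT
        )
        assert not unmapped
        assert (mapped[0].start, mapped[0].end) == (7, 10)

    def test_whole_construct(self):
        mapped, _ = map_peptides(
            [EluateRecord("d", "c", "DRGATALELMVLNVPRL")], self.CONSTRUCT
        )
        assert (mapped[0].start, mapped[0].end) == (1, 17)

    def test_missing_peptide_reported_unmapped(self):
        mapped, unmapped = map_peptides([EluateRecord("d", "c", "WWWW")], self.CONSTRUCT)
        assert mapped == [] and len(unmapped) == 1

    def test_multiple_occurrences_flagged_ambiguous(self):
        cons = {"c": ProteinConstruct("c", "ACACA")}
        mapped, _ = map_peptides([EluateRecord("d", "c", "ACA")], cons)
        assert [m.start for m in mapped] == [1, 3]
        assert all(m.ambiguous for m in mapped)

    def test_il_equivalent_matching(self):
        cons = {"c": ProteinConstruct("c", "GGILGG")}
        mapped, unmapped = map_peptides(
            [EluateRecord("d", "c", "LL")], cons, il_equivalent=True
        )
        assert not unmapped and mapped[0].ambiguous

    def test_unknown_construct(self):
        with pytest.raises(KeyError):
            map_peptides([EluateRecord("d", "zz", "AC")], self.CONSTRUCT)

    def test_mapped_subsequence_equals_peptide(self, default_study):
        cons = default_study.config.constructs
        records = [r for recs in default_study.eluates.values() for r in recs]
        mapped, unmapped = map_peptides(records, cons)
        assert not unmapped
        for m in mapped:
            seq = cons[m.record.construct_id].sequence
            assert seq[m.start - 1 : m.end] == m.record.peptide


class TestPositionCoverage:
    def test_empty(self):
        assert (position_coverage([], 10) == 0).all()

    def test_single_interval(self):
        cov = position_coverage([_mp(5, 9)], 15)
        assert cov[4:9].tolist() == [1] * 5 and cov.sum() == 5

    def test_overlay(self):
        cov = position_coverage([_mp(1, 10), _mp(6, 15)], 15)
        assert cov[5:10].tolist() == [2] * 5
        assert cov[:5].tolist() == [1] * 5 and cov[10:].tolist() == [1] * 5

    def test_out_of_bounds(self):
        with pytest.raises(OutOfBoundsError):
            position_coverage([_mp(8, 12)], 10)

    @given(st.data())
    def test_mass_conservation(self, data):
        intervals = data.draw(
            st.lists(
                st.tuples(st.integers(1, 40), st.integers(1, 15)), max_size=30
            )
        )
        mapped = [_mp(s, min(50, s + l - 1)) for s, l in intervals]
        cov = position_coverage(mapped, 50)
        assert cov.sum() == sum(m.end - m.start + 1 for m in mapped)


def _oracle_components(intervals):
    """Brute-force connected components under pairwise interval overlap."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 <= e2 and s2 <= e1:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    return sorted(
        (min(s for s, _ in c), max(e for _, e in c)) for c in comps.values()
    )


class TestDetectClusters:
    def test_two_components(self):
        clusters = detect_clusters([_mp(1, 10), _mp(5, 14), _mp(20, 30)])
        assert [(c.start, c.end) for c in clusters] == [(1, 14), (20, 30)]
        assert [c.id for c in clusters] == [1, 2]

    def test_single_peptide(self):
        clusters = detect_clusters([_mp(4, 9)])
        assert [(c.start, c.end) for c in clusters] == [(4, 9)]

    def test_overlap_by_one_residue_merges(self):
        clusters = detect_clusters([_mp(1, 10), _mp(10, 15)])
        assert [(c.start, c.end) for c in clusters] == [(1, 15)]

    def test_adjacent_without_overlap_stays_split(self):
        clusters = detect_clusters([_mp(1, 10), _mp(11, 15)])
        assert len(clusters) == 2

    def test_max_gap_bridges(self):
        clusters = detect_clusters([_mp(1, 10), _mp(12, 15)], max_gap=1)
        assert len(clusters) == 1

    def test_min_overlap_two_requires_two_shared(self):
        assert len(detect_clusters([_mp(1, 10), _mp(10, 15)], min_overlap=2)) == 2
        assert len(detect_clusters([_mp(1, 10), _mp(9, 15)], min_overlap=2)) == 1

    def test_empty_input(self):
        assert detect_clusters([]) == []

    def test_spanning_sequence_read_from_construct(self):
        c = ProteinConstruct("c", "DRGATALELMVLNVPRL")
        clusters = detect_clusters([_mp(2, 6), _mp(4, 9)], construct=c)
        assert clusters[0].spanning_sequence == "RGATALEL"

    @given(st.data())
    def test_agrees_with_bruteforce_oracle(self, data):
        intervals = data.draw(
            st.lists(
                st.tuples(st.integers(1, 60), st.integers(1, 20)),
                min_size=1, max_size=50,
            )
        )
        intervals = [(s, s + l - 1) for s, l in intervals]
        mapped = [_mp(s, e) for s, e in intervals]
        perm = data.draw(st.permutations(mapped))
        got = [(c.start, c.end) for c in detect_clusters(perm)]
        assert got == _oracle_components(intervals)


class TestPeptidesOverlapping:
    def test_disjoint(self):
        assert peptides_overlapping([_mp(1, 5)], RegionWindow(10, 12)) == []

    def test_single_residue_overlap_included(self):
        out = peptides_overlapping([_mp(5, 9)], RegionWindow(9, 12))
        assert len(out) == 1

    def test_hand_intersection(self):
        out = peptides_overlapping([_mp(1, 10), _mp(11, 20)], RegionWindow(8, 12))
        assert len(out) == 2


class TestSummaries:
    def test_hand_arithmetic(self):
        recs = [
            EluateRecord("d", "c", "A" * 13),
            EluateRecord("d", "c", "C" * 17),
            EluateRecord("d", "c", "D" * 24),
        ]
        s = summarize_donor_construct(recs)
        assert (s.total_peptides, s.unique_peptides) == (3, 3)
        assert (s.min_length, s.max_length) == (13, 24)
        assert s.mean_length_report == 18

    def test_duplicates_counted_in_total_only(self):
        recs = [EluateRecord("d", "c", "ACDEF" * 3)] * 2
        s = summarize_donor_construct(recs)
        assert (s.total_peptides, s.unique_peptides) == (2, 1)

    def test_singleton(self):
        s = summarize_donor_construct([EluateRecord("d", "c", "A" * 16)])
        assert s.min_length == s.max_length == s.mean_length == 16

    def test_empty_flagged(self):
        assert summarize_donor_construct([]).empty

    def test_mixed_donors_rejected(self):
        with pytest.raises(ConsistencyError):
            summarize_donor_construct(
                [EluateRecord("d1", "c", "ACDEF" * 2), EluateRecord("d2", "c", "ACDEF" * 2)]
            )

    def test_donor_aggregation_reproduces_published_row(self):
        """D1's four per-construct rows aggregate to total 93, max length 26."""
        summaries = []
        for (donor, cid), (total, unique, mean, mn, mx) in DONOR_CONSTRUCT_SUMMARY.items():
            if donor != "D1":
                continue
            from mappskit.mapps import DonorConstructSummary

            summaries.append(
                DonorConstructSummary(donor, cid, total, unique, float(mean), mn, mx)
            )
        d = summarize_donor(summaries)
        assert d.total_peptides == 93
        assert d.max_length == 26
        assert d.min_length == 13
        assert d.unique_peptides is None  # pooled sequences unavailable

    def test_single_construct_identity(self):
        from mappskit.mapps import DonorConstructSummary

        s = DonorConstructSummary("d", "c", 5, 4, 15.0, 12, 20)
        d = summarize_donor([s])
        assert (d.total_peptides, d.min_length, d.max_length) == (5, 12, 20)


class TestClusterPresence:
    def test_presence_logic(self):
        from mappskit.mapps import Cluster

        cl = Cluster(1, 10, 30)
        inside = _mp(12, 25, donor="d1")
        outside = _mp(40, 55, donor="d2")
        mapped = [inside, outside]
        assert cluster_presence(mapped, cl, "d1", "c")
        assert not cluster_presence(mapped, cl, "d2", "c")
        assert not cluster_presence(mapped, cl, "d3", "c")


class TestClusterFrequency:
    @pytest.mark.parametrize(
        "construct,expected", [("WT", 18), ("VA", 82), ("DI-1", 45), ("DI-2", 73)]
    )
    def test_published_cohort_frequencies(self, construct, expected):
        freq = cluster_frequency(presence_pattern(construct), 11)
        assert round_half_away(freq) == expected

    def test_all_present(self):
        assert cluster_frequency({"a": True, "b": True}, 2) == 100.0

    def test_invalid_n_donors(self):
        with pytest.raises(ValueError):
            cluster_frequency({}, 0)

    @given(st.dictionaries(st.text("abc", min_size=1, max_size=2), st.booleans(), max_size=8))
    def test_adding_presenting_donor_never_decreases(self, presence):
        n = max(len(presence) + 1, 1)
        base = cluster_frequency(presence, n)
        presence2 = dict(presence)
        presence2["zz_new"] = True
        assert cluster_frequency(presence2, n) >= base


class TestWithinDonorPct:
    def test_zero_and_hand_value(self):
        assert within_donor_cluster_pct(0, 30) == 0.0
        assert round_half_away(within_donor_cluster_pct(5, 26)) == 19

    def test_absent_for_empty_donor(self):
        assert within_donor_cluster_pct(0, 0) is None

    def test_inconsistent_counts(self):
        with pytest.raises(ConsistencyError):
            within_donor_cluster_pct(5, 3)


class TestPercentInhibition:
    def test_no_change(self):
        assert percent_inhibition(40.0, 40.0) == 0.0

    def test_hand_value(self):
        assert percent_inhibition(58.0, 48.0) == pytest.approx(17.241, abs=1e-3)

    def test_reference_zero_is_absent(self):
        assert percent_inhibition(0.0, 10.0) is None
        assert percent_inhibition(None, 10.0) is None

    def test_negative_when_variant_exceeds(self):
        assert percent_inhibition(10.0, 20.0) == -100.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            percent_inhibition(120.0, 10.0)


class TestClusterResponderRate:
    def test_published_responder_rates(self):
        va = within_donor_pct("VA")
        rate1, n1 = cluster_responder_rate(va, within_donor_pct("DI-1"))
        rate2, n2 = cluster_responder_rate(va, within_donor_pct("DI-2"))
        assert (round_half_away(rate1), n1) == (67, 9)
        assert (round_half_away(rate2), n2) == (78, 9)

    def test_tie_is_not_a_responder(self):
        rate, n = cluster_responder_rate({"a": 5.0, "b": 10.0}, {"a": 5.0, "b": 4.0})
        assert (rate, n) == (50.0, 2)

    def test_absent_variant_counts_as_zero(self):
        rate, _ = cluster_responder_rate({"a": 5.0}, {"a": None})
        assert rate == 100.0

    def test_no_evaluable_donors(self):
        with pytest.raises(CoverageError):
            cluster_responder_rate({"a": 0.0, "b": None}, {"a": 1.0, "b": 1.0})

    def test_mismatched_keys(self):
        with pytest.raises(ValueError):
            cluster_responder_rate({"a": 5.0}, {"b": 5.0})


class TestPeptideCountDecrease:
    def test_halving(self):
        out = peptide_count_decrease({"d": 10}, {"d": 5})
        assert out.per_donor["d"] == 50.0

    def test_reference_zero_excluded(self):
        out = peptide_count_decrease({"d1": 10, "d2": 0}, {"d1": 5, "d2": 3})
        assert out.excluded == ["d2"]
        assert "d2" not in out.per_donor

    def test_hand_arithmetic(self):
        out = peptide_count_decrease({"d1": 10, "d2": 4}, {"d1": 0, "d2": 4})
        assert out.per_donor == {"d1": 100.0, "d2": 0.0}
        assert out.mean_decrease == 50.0
        assert out.pct_any_decrease == 50.0
        assert out.pct_full_decrease == 50.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            peptide_count_decrease({"d": -1}, {"d": 0})
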