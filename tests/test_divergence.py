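"""Divergence statistics: p-distances, closest pairs, diagnostic sites."""

import numpy as np
import pytest

import _oracles as oracle
from barcodiv import (
    Alignment,
    GroupingMap,
    InputError,
    SitePolicy,
    UndefinedDistanceError,
    distance_matrix,
    divergence_summary,
    fixed_substitutions,
    min_intergroup,
    p_distance,
    render_percent,
)

PAIRWISE = SitePolicy()
COMPLETE = SitePolicy(mode="complete_deletion")
STRICT = SitePolicy(ambiguity="strict_mismatch")

POLICIES = [
    SitePolicy(mode=m, ambiguity=a)
    for m in ("pairwise_deletion", "complete_deletion")
    for a in ("treat_as_missing", "strict_mismatch")
]


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance("ACGT", "ACGT", PAIRWISE)
        assert d.value == 0.0
        assert d.compared_sites == 4

    def test_hand_arithmetic_16_of_658(self):
        # 16 unmasked differences over 658 sites: p = 0.024316..., "2.4 %"
        a = "A" * 658
        b = "C" * 16 + "A" * 642
        d = p_distance(a, b, PAIRWISE)
        assert d.differing_sites == 16
        assert d.compared_sites == 658
        assert d.value == pytest.approx(16 / 658)
        assert d.render_percent() == "2.4 %"

    def test_gap_masked_under_pairwise_deletion(self):
        d = p_distance("AC-T", "ACGT", PAIRWISE)
        assert d.compared_sites == 3
        assert d.value == 0.0

    def test_ambiguity_masked_vs_strict_mismatch(self):
        assert p_distance("ARGT", "AAGT", PAIRWISE).compared_sites == 3
        strict = p_distance("ARGT", "ARGT", STRICT)
        assert strict.compared_sites == 4
        assert strict.differing_sites == 1  # R never matches, even itself

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError, match="unequal"):
            p_distance("ACG", "ACGT", PAIRWISE)

    def test_all_masked_pair_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN--", "ACGT", PAIRWISE)

    @pytest.mark.parametrize("policy", POLICIES, ids=str)
    def test_matches_per_site_loop_oracle(self, policy):
        rng = np.random.default_rng(11)
        for _ in range(50):
            recs = oracle.random_alignment(rng, n_max=2)
            a, b = recs["s00"], recs["s01"]
            diff, comp = oracle.bf_p_distance(a, b, policy)
            if comp == 0:
                with pytest.raises(UndefinedDistanceError):
                    p_distance(a, b, policy)
                continue
            d = p_distance(a, b, policy)
            assert (d.differing_sites, d.compared_sites) == (diff, comp)


class TestRenderPercent:
    @pytest.mark.parametrize(
        "fraction, rendered",
        [(13 / 658, "2.0 %"), (15 / 658, "2.3 %"), (16 / 658, "2.4 %"),
         (0.0, "0.0 %"), (0.0245, "2.5 %")],  # round-half-up at one decimal
    )
    def test_one_decimal_round_half_up(self, fraction, rendered):
        assert render_percent(fraction) == rendered


class TestDistanceMatrix:
    def test_identical_records_give_zero_matrix(self):
        aln = Alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        m = distance_matrix(aln, PAIRWISE)
        assert all(d.value == 0.0 for d in m.entries.values())
        assert len(m.entries) == 3

    def test_two_records_single_entry(self):
        aln = Alignment({"a": "ACGT", "b": "ACGA"})
        m = distance_matrix(aln, PAIRWISE)
        assert m.get("b", "a").value == pytest.approx(0.25)

    def test_single_record_rejected(self):
        with pytest.raises(InputError):
            distance_matrix(Alignment({"a": "ACGT"}), PAIRWISE)

    def test_symmetry_and_entry_count(self, fixture_matrix, fixture_data):
        n = len(fixture_data.alignment)
        assert len(fixture_matrix.entries) == n * (n - 1) // 2
        df = fixture_matrix.to_dataframe()
        assert (df.values == df.values.T).all()
        assert (np.diag(df.values) == 0).all()

    @pytest.mark.parametrize("policy", POLICIES, ids=str)
    def test_matches_brute_force_double_loop(self, policy):
        """Exact agreement with the naive implementation on ≥100 random
        alignments per policy (n ≤ 12, L ≤ 100, random gaps/ambiguities)."""
        rng = np.random.default_rng(29)
        checked = 0
        while checked < 100:
            recs = oracle.random_alignment(rng)
            expected = oracle.bf_distance_matrix(recs, policy)
            if any(comp == 0 for _, comp in expected.values()):
                continue
            m = distance_matrix(Alignment(recs), policy)
            for pair, (diff, comp) in expected.items():
                d = m.entries[pair]
                assert (d.differing_sites, d.compared_sites) == (diff, comp)
            checked += 1


class TestMinIntergroup:
    def test_singleton_groups(self):
        aln = Alignment({"a": "ACGT", "b": "ACGA"})
        m = distance_matrix(aln, PAIRWISE)
        gm = GroupingMap({"a": "G1", "b": "G2"})
        res = min_intergroup(m, gm, "G1", "G2")
        assert res.pair == ("a", "b")
        assert res.distance.value == pytest.approx(0.25)

    def test_fixture_a_vs_p1_renders_2_4_percent(self, fixture_matrix, fixture_data):
        res = min_intergroup(fixture_matrix, fixture_data.haplogroups, "A", "P1")
        assert res.distance.render_percent() == "2.4 %"

    def test_same_group_rejected(self, fixture_matrix, fixture_data):
        with pytest.raises(InputError):
            min_intergroup(fixture_matrix, fixture_data.haplogroups, "A", "A")

    def test_ties_all_reported_lexicographic_winner(self):
        aln = Alignment({"a1": "ACGT", "a2": "ACGT", "b1": "ACGA"})
        m = distance_matrix(aln, PAIRWISE)
        gm = GroupingMap({"a1": "G1", "a2": "G1", "b1": "G2"})
        res = min_intergroup(m, gm, "G1", "G2")
        assert res.ties == [("a1", "b1"), ("a2", "b1")]
        assert res.pair == ("a1", "b1")

    def test_exhaustive_minimum_over_five_groups(self, fixture_matrix, fixture_data):
        """Matches the brute-force minimum for every inter-group pair of the
        five fixture haplogroups."""
        gm = fixture_data.haplogroups
        labels = ["P1", "P2", "P3", "A", "H"]
        distances = {
            pair: (d.differing_sites, d.compared_sites)
            for pair, d in fixture_matrix.entries.items()
        }
        for i, ga in enumerate(labels):
            for gb in labels[i + 1:]:
                expected_pair, expected_p = oracle.bf_min_intergroup(
                    distances, gm.members(ga), gm.members(gb)
                )
                res = min_intergroup(fixture_matrix, gm, ga, gb)
                assert res.distance.value == pytest.approx(expected_p)


class TestFixedSubstitutions:
    def test_within_group_polymorphism_blocks_diagnosis(self):
        aln = Alignment(
            {"a1": "ACGT", "a2": "ACGA", "b1": "TCGT", "b2": "TCGA"}
        )
        gm = GroupingMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = fixed_substitutions(aln, gm, "A", "B", PAIRWISE)
        assert rep.count == 1
        assert rep.sites == [(1, "A", "T")]  # site 4 polymorphic in both

    def test_identical_groups_have_no_fixed_differences(self):
        aln = Alignment({"a": "ACGT", "b": "ACGT"})
        gm = GroupingMap({"a": "A", "b": "B"})
        assert fixed_substitutions(aln, gm, "A", "B", PAIRWISE).count == 0

    def test_fixture_a_vs_p1_eleven_sites(self, fixture_data):
        rep = fixed_substitutions(
            fixture_data.alignment, fixture_data.haplogroups, "A", "P1"
        )
        assert rep.count == 11
        assert rep.evaluated_sites == 658

    def test_fully_masked_group_site_not_evaluated(self):
        aln = Alignment({"a1": "NCGT", "a2": "NCGT", "b1": "ACGA"})
        gm = GroupingMap({"a1": "A", "a2": "A", "b1": "B"})
        rep = fixed_substitutions(aln, gm, "A", "B", PAIRWISE)
        assert rep.evaluated_sites == 3
        assert rep.count == 1  # site 4: T vs A

    def test_positions_strictly_increasing_and_one_based(self, fixture_data):
        rep = fixed_substitutions(
            fixture_data.alignment, fixture_data.haplogroups, "H", "P1"
        )
        positions = [pos for pos, _, _ in rep.sites]
        assert positions == sorted(positions)
        assert all(1 <= p <= 658 for p in positions)

    def test_symmetric_up_to_state_swap(self, fixture_data):
        fwd = fixed_substitutions(
            fixture_data.alignment, fixture_data.haplogroups, "P3", "P1"
        )
        rev = fixed_substitutions(
            fixture_data.alignment, fixture_data.haplogroups, "P1", "P3"
        )
        assert [(p, b, a) for p, a, b in fwd.sites] == rev.sites

    @pytest.mark.parametrize("policy", POLICIES, ids=str)
    def test_matches_per_site_set_oracle(self, policy):
        rng = np.random.default_rng(37)
        for _ in range(40):
            recs = oracle.random_alignment(rng, n_max=8, length_max=60)
            ids = list(recs)
            half = len(ids) // 2 or 1
            members_a, members_b = ids[:half], ids[half:] or ids[:1]
            if members_a == members_b:
                continue
            gm = GroupingMap(
                {s: ("A" if s in members_a else "B") for s in ids}
            )
            expected_sites, expected_eval = oracle.bf_fixed_substitutions(
                recs, members_a, members_b, policy
            )
            rep = fixed_substitutions(Alignment(recs), gm, "A", "B", policy)
            assert rep.sites == expected_sites
            assert rep.evaluated_sites == expected_eval

    def test_monotone_under_group_shrinkage(self):
        """Dropping a member can only keep or grow the diagnostic count."""
        rng = np.random.default_rng(43)
        for _ in range(30):
            recs = oracle.random_alignment(rng, n_max=8, length_max=40)
            ids = list(recs)
            if len(ids) < 4:
                continue
            members_a, members_b = ids[: len(ids) // 2], ids[len(ids) // 2:]
            full, _ = oracle.bf_fixed_substitutions(
                recs, members_a, members_b, PAIRWISE
            )
            if len(members_a) > 1:
                gm = GroupingMap(
                    {
                        s: ("A" if s in members_a[:-1] else "B")
                        for s in members_a[:-1] + members_b
                    }
                )
                shrunk = fixed_substitutions(
                    Alignment({s: recs[s] for s in members_a[:-1] + members_b}),
                    gm,
                    "A",
                    "B",
                    PAIRWISE,
                )
                assert shrunk.count >= len(full)

    def test_diagnostic_fraction_bounds_min_p_without_masking(self, fixture_data):
        """With no masked residues, count/evaluated ≤ minimal inter-group p:
        every diagnostic site separates every inter-group pair."""
        aln, gm = fixture_data.alignment, fixture_data.haplogroups
        matrix = distance_matrix(aln, COMPLETE)
        for ga, gb in [("A", "P1"), ("P2", "P1"), ("P3", "H"), ("A", "P2")]:
            rep = fixed_substitutions(aln, gm, ga, gb, COMPLETE)
            res = min_intergroup(matrix, gm, ga, gb)
            assert rep.count / rep.evaluated_sites <= res.distance.value


class TestDivergenceSummary:
    def test_two_groups_one_row(self):
        aln = Alignment({"a": "ACGT", "b": "ACGA"})
        gm = GroupingMap({"a": "G1", "b": "G2"})
        table = divergence_summary(aln, gm, PAIRWISE)
        assert len(table) == 1

    def test_fixture_rows_match_planted_statistics(self, fixture_data):
        table = divergence_summary(
            fixture_data.alignment, fixture_data.haplogroups
        )
        rows = {
            frozenset((r.group_a, r.group_b)): r
            for r in table.itertuples()
        }
        expected = {
            "P2": (7, "2.0 %"),
            "P3": (10, "2.3 %"),
            "A": (11, "2.4 %"),
            "H": (10, "2.4 %"),
        }
        for group, (count, pct) in expected.items():
            row = rows[frozenset((group, "P1"))]
            assert row.fixed_substitutions == count
            assert row.min_p_percent == pct

    def test_deterministic_row_ordering(self, fixture_data):
        t1 = divergence_summary(fixture_data.alignment, fixture_data.haplogroups)
        t2 = divergence_summary(fixture_data.alignment, fixture_data.haplogroups)
        assert t1.equals(t2)

    def test_single_group_rejected(self):
        aln = Alignment({"a": "ACGT", "b": "ACGA"})
        gm = GroupingMap({"a": "G1", "b": "G1"})
        with pytest.raises(InputError):
            divergence_summary(aln, gm, PAIRWISE)
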