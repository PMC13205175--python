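"""Invariance profiles, tripartite classes, neighbor bias, runs, completion."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import regevol as rv
from regevol.conservation import (
    CODON_FIXED_INVARIANT,
    FLANK_INVARIANT,
    VARIABLE,
    WOBBLE_INVARIANT,
    EXONIC_SILENCER_NEIGHBOR_TABLE,
)

from _oracles import naive_invariance, naive_maximal_runs


def seq(residues, sid="s"):
    return rv.AnnotatedSequence(id=sid, residues=residues)


def msa(*rows):
    return rv.MultipleAlignment(
        rows=tuple((f"r{i}", r) for i, r in enumerate(rows))
    )


class TestColumnInvariance:
    def test_identical_rows_all_invariant(self):
        profile = rv.column_invariance(msa("ACGT", "ACGT", "ACGT"))
        assert all(profile.invariant)
        assert profile.n_compared == 2

    def test_gap_breaks_invariance(self):
        profile = rv.column_invariance(msa("ACGT", "AC-T"))
        assert profile.invariant == (True, True, False, True)

    def test_n_breaks_invariance(self):
        profile = rv.column_invariance(msa("ACGT", "ACNT"))
        assert profile.invariant == (True, True, False, True)

    def test_reference_positions_are_ungapped(self):
        profile = rv.column_invariance(msa("AC-GT", "ACCGT"))
        assert len(profile) == 4  # gap column of the reference dropped
        assert profile.bases == "ACGT"

    def test_missing_reference_row(self):
        with pytest.raises(ValueError):
            rv.column_invariance(msa("ACGT", "ACGT"), reference="human")

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            rv.column_invariance(msa("ACGT", "ACGT"), subset=set())

    def test_random_two_row_alignments_match_column_scan(self):
        rng = random.Random(12)
        for _ in range(80):
            n = rng.randint(1, 10)
            a = "".join(rng.choice("ACGTN") for _ in range(n))
            b = "".join(rng.choice("ACGTN") for _ in range(n))
            if set(a) <= {"N"} or set(b) <= {"N"}:
                continue
            profile = rv.column_invariance(msa(a, b))
            assert list(profile.invariant) == naive_invariance([a, b])

    def test_ladder_input_aligns_members_first(self, exonic):
        # a member with one substitution at position 6, aligned pairwise
        mutated = exonic.with_substitution(6, "C")
        ladder = rv.OrthologLadder(
            reference=exonic,
            members=[(rv.SpeciesRecord("other", 100), mutated)],
        )
        profile = rv.column_invariance(ladder)
        assert profile.invariant_positions() == [
            p for p in range(1, 39) if p != 6
        ]


class TestClassifyBases:
    def test_saturated_element(self, exonic):
        profile = rv.column_invariance(
            msa(exonic.residues, exonic.residues)
        )
        overlay = rv.overlay_frame(exonic, 3)
        classes = rv.classify_bases(profile, overlay)
        assert classes.counts[CODON_FIXED_INVARIANT] == 24
        assert classes.counts[WOBBLE_INVARIANT] == 12
        assert classes.counts[FLANK_INVARIANT] == 2
        assert classes.counts[VARIABLE] == 0

    def test_counts_partition_element(self, exonic):
        rng = random.Random(9)
        other = "".join(rng.choice("ACGT") for _ in range(38))
        profile = rv.column_invariance(msa(exonic.residues, other))
        classes = rv.classify_bases(profile, rv.overlay_frame(exonic, 3))
        assert sum(classes.counts.values()) == 38

    def test_no_overlay_gives_flank_classes(self):
        profile = rv.column_invariance(msa("ACGT", "ACGT"))
        classes = rv.classify_bases(profile, None)
        assert classes.counts[FLANK_INVARIANT] == 4

    def test_length_mismatch_rejected(self, exonic):
        profile = rv.column_invariance(msa("ACGT", "ACGT"))
        with pytest.raises(ValueError):
            rv.classify_bases(profile, rv.overlay_frame(exonic, 3))

    def test_simulated_ground_truth_recovered(self):
        frozen = frozenset({5, 12, 13, 14, 30})
        config = rv.SimulationConfig(
            ladder=tuple(
                rv.SpeciesRecord(f"sp{i}", age)
                for i, age in enumerate((10, 20, 40, 60, 80, 100, 120, 150))
            ),
            seed=77,
            length=40,
            mu=0.12,  # saturation: every free site hit in some member
            frozen_positions=frozen,
        )
        sim = rv.simulate_ladder(config)
        profile = rv.column_invariance(sim.as_alignment())
        assert set(profile.invariant_positions()) == frozen

    def test_simulated_wobble_invariants_recovered_with_overlay(self):
        # freeze a handful of wobble positions of an in-frame element and
        # check the tripartite classification finds exactly those
        frozen = frozenset({3, 12, 24, 33})  # wobble positions for frame 1
        config = rv.SimulationConfig(
            ladder=tuple(
                rv.SpeciesRecord(f"sp{i}", age)
                for i, age in enumerate((20, 40, 60, 80, 100, 130, 160, 200))
            ),
            seed=31,
            length=36,
            frame_start=1,
            mu=0.15,
            frozen_positions=frozen,
        )
        sim = rv.simulate_ladder(config)
        profile = rv.column_invariance(sim.as_alignment())
        overlay = rv.overlay_frame(sim.ladder.reference, 1)
        classes = rv.classify_bases(profile, overlay)
        assert set(classes.wobble_invariant_positions) == frozen


class TestNeighborBias:
    def test_empty_invariant_set(self, exonic):
        table = rv.neighbor_bias_table(exonic, [])
        assert table.n_considered == 0
        assert table.gc_fraction is None

    def test_all_gc_sequence_has_gc_fraction_one(self):
        table = rv.neighbor_bias_table(seq("GCGCGCGC"), [3, 6])
        assert table.gc_fraction == 1.0

    def test_neighbors_of_printed_invariant_set(self, exonic):
        # the five-prime neighbors of the published invariant positions,
        # read directly from the 38-mer
        inv = [3, 6, 9, 10, 13, 15, 18, 20, 22, 26, 28, 31, 34]
        table = rv.neighbor_bias_table(exonic, inv)
        five = {
            r.neighbor_position: r.neighbor_base
            for r in table.rows
            if r.side == "five_prime"
        }
        assert {p: five[p] for p in (2, 5, 8, 12, 17, 25, 33)} == {
            2: "G", 5: "C", 8: "C", 12: "C", 17: "C", 25: "G", 33: "G"
        }
        # neighbors that are themselves invariant are never listed
        assert all(r.neighbor_position not in inv for r in table.rows)

    def test_exclude_forced_policy(self):
        # TGG (Trp) admits no change at any codon position; its bases are
        # excluded as neighbors under the degeneracy-aware policy
        s = rv.AnnotatedSequence(id="s", residues="ATGGA", frame_start=2)
        overlay = rv.overlay_frame(s, 2)
        table = rv.neighbor_bias_table(
            s, [1], overlay=overlay, policy="exclude_forced"
        )
        (row,) = table.rows
        assert row.neighbor_position == 2
        assert row.excluded
        assert table.n_considered == 0

    def test_exclude_forced_requires_overlay(self, exonic):
        with pytest.raises(ValueError):
            rv.neighbor_bias_table(exonic, [3], policy="exclude_forced")

    def test_position_out_of_range(self, exonic):
        with pytest.raises(ValueError):
            rv.neighbor_bias_table(exonic, [39])


class TestReferenceNeighborTable:
    def test_twelve_of_thirteen_printed_bases_are_gc(self, exonic):
        rows, n_gc, n_rows = rv.evaluate_reference_neighbor_table(exonic)
        assert (n_rows, n_gc) == (13, 12)

    def test_five_prime_column_matches_extant_bases(self, exonic):
        rows, _, _ = rv.evaluate_reference_neighbor_table(exonic)
        five = [r for r in rows if r.side == "five_prime"]
        assert len(five) == 7
        assert all(r.matches_extant for r in five)

    def test_single_discrepant_row_is_flagged(self, exonic):
        rows, _, _ = rv.evaluate_reference_neighbor_table(exonic)
        mismatched = [r for r in rows if not r.matches_extant]
        assert [r.printed_neighbor_label for r in mismatched] == ["T23"]
        assert mismatched[0].extant_base == "C"

    def test_table_is_validated_against_sequence(self):
        with pytest.raises(ValueError):
            rv.evaluate_reference_neighbor_table(
                seq("A" * 38), EXONIC_SILENCER_NEIGHBOR_TABLE
            )


class TestInvariantRuns:
    def test_all_variable_profile(self):
        profile = rv.column_invariance(msa("AAAA", "CCCC"))
        assert rv.longest_invariant_runs(profile) == []

    def test_tie_break_prefers_five_prime_run(self):
        profile = rv.column_invariance(msa("AATAA", "AACAA"))
        runs = rv.longest_invariant_runs(profile)
        assert [(r.start, r.end) for r in runs] == [(1, 2), (4, 5)]

    @given(st.lists(st.booleans(), min_size=1, max_size=20))
    def test_runs_match_exhaustive_scan(self, flags):
        bases = "A" * len(flags)
        profile = rv.ConservationProfile(
            bases=bases, invariant=tuple(flags), n_compared=1
        )
        got = sorted((r.start, r.end) for r in rv.longest_invariant_runs(profile))
        assert got == naive_maximal_runs(flags)

    def test_runs_are_maximal_and_non_overlapping(self):
        rng = random.Random(3)
        for _ in range(40):
            flags = [rng.random() < 0.5 for _ in range(20)]
            profile = rv.ConservationProfile(
                bases="G" * 20, invariant=tuple(flags), n_compared=2
            )
            runs = rv.longest_invariant_runs(profile)
            spans = sorted((r.start, r.end) for r in runs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2 - 1  # separated by at least one variable column
            for r in runs:
                assert all(flags[r.start - 1:r.end])
                assert r.start == 1 or not flags[r.start - 2]
                assert r.end == len(flags) or not flags[r.end]


class TestDifferences:
    def test_identical_sequences(self, exonic):
        assert rv.count_differences(exonic, exonic) == (0, 0)

    def test_substitution_plus_terminal_deletion(self):
        a = seq("ACGTACGT")
        b = seq("ACGAACG")
        assert rv.count_differences(a, b) == (1, 1)

    def test_simulated_substitutions_only(self):
        rng = random.Random(21)
        base = "".join(rng.choice("ACGT") for _ in range(60))
        positions = rng.sample(range(60), 5)
        mutated = list(base)
        for p in positions:
            mutated[p] = rng.choice([b for b in "ACGT" if b != base[p]])
        assert rv.count_differences(seq(base), seq("".join(mutated))) == (5, 0)


class TestCompletionCall:
    @staticmethod
    def ladder(ref, members):
        return rv.OrthologLadder(
            reference=seq(ref, "human"),
            members=[
                (rv.SpeciesRecord(name, age), seq(s, name))
                for name, age, s in members
            ],
        )

    def test_identical_older_member_wins(self):
        ref = "ACGTACGTACGTACGTACGTACGT"
        gorilla = "ACGTACGAACGAACGTACCTACGA"  # 4 substitutions
        call = rv.completion_call(
            self.ladder(ref, [("chimp", 6, ref), ("gorilla", 9, gorilla)])
        )
        assert call.completion_species == "chimp"
        assert call.completion_age == 6
        assert not call.human_specific
        by_species = {d.species: d for d in call.differences}
        assert by_species["gorilla"].n_point_differences == 4

    def test_all_members_differ_means_reference_specific(self):
        ref = "ACGTACGTACGT"
        call = rv.completion_call(
            self.ladder(ref, [("chimp", 6, "ACGTACGAACGT")])
        )
        assert call.human_specific
        assert call.completion_species is None

    def test_all_identical_gives_oldest(self):
        ref = "ACGTACGTACGT"
        call = rv.completion_call(
            self.ladder(ref, [("chimp", 6, ref), ("gorilla", 9, ref)])
        )
        assert call.completion_species == "gorilla"

    def test_monotone_in_substitutions(self):
        # adding substitutions to a member never moves completion deeper
        ref = "ACGTACGTACGTACGT"
        damaged = ref
        ages = []
        for k in (0, 2, 4):
            m = list(ref)
            for p in range(k):
                m[p] = "A" if ref[p] != "A" else "C"
            call = rv.completion_call(
                self.ladder(ref, [("old", 50, "".join(m)), ("young", 5, ref)])
            )
            ages.append(call.completion_age)
        assert ages[0] == 50 and ages[1] == 5 and ages[2] == 5

    def test_empty_ladder_rejected(self):
        with pytest.raises(ValueError):
            rv.completion_call(
                rv.OrthologLadder(reference=seq("ACGT"), members=[])
            )
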