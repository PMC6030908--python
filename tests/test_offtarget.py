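"""Off-target search equivalence, per-hit scores, aggregation and filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from guidescout.errors import ConfigurationError, UsageError
from guidescout.offtarget import (
    OffTargetHit,
    ScoreTables,
    brute_force_scan,
    cfd_score,
    color_class,
    enumerate_offtargets,
    filter_hits,
    mit_hit_score,
    mm_counts,
    specificity_score,
)
from guidescout.sequence_io import (
    ExonAnnotation,
    ExonInterval,
    GenomeIndex,
    generate_toy_genome,
)

GUIDE = "GTACGTTCAGGATCAGGTAC"


def _mutate_at(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestScoreTables:
    def test_weight_count_must_match_guide_len(self):
        with pytest.raises(ConfigurationError):
            ScoreTables(20, (0.5,) * 19)

    def test_penalties_must_be_probabilities(self):
        with pytest.raises(ConfigurationError):
            ScoreTables(20, (1.5,) * 20)

    def test_default_tables_load(self):
        t = ScoreTables.load_default(20)
        assert len(t.mit_weights) == 20
        assert len(t.cfd_mm) == 20 * 12
        assert t.cfd_pam["GG"] == 1.0
        assert all(v < 1.0 for k, v in t.cfd_pam.items() if k != "GG")

    def test_nonstandard_guide_len_gets_uniform_tables(self):
        t = ScoreTables.load_default(23)
        assert len(t.mit_weights) == 23


class TestMitHitScore:
    def test_perfect_match_scores_100(self, uniform_tables):
        assert mit_hit_score(GUIDE, GUIDE, uniform_tables) == 100.0

    def test_single_mismatch_collapses_to_weight(self, uniform_tables):
        rng = np.random.default_rng(1)
        for p in (1, 7, 20):
            site = _mutate_at(GUIDE, [p - 1], rng)
            expected = 100.0 * (1 - uniform_tables.mit_weights[p - 1])
            assert mit_hit_score(GUIDE, site, uniform_tables) == pytest.approx(expected)

    def test_two_terminal_mismatches_hand_value(self, uniform_tables):
        # W=0.5 everywhere, mismatches at positions 1 and 20, dmean = 19:
        # 100 * 0.25 * 1/1 * 1/4 = 6.25
        site = _mutate_at(GUIDE, [0, 19], np.random.default_rng(1))
        assert mit_hit_score(GUIDE, site, uniform_tables) == pytest.approx(6.25)

    def test_length_mismatch_rejected(self, uniform_tables):
        with pytest.raises(UsageError):
            mit_hit_score(GUIDE, GUIDE[:19], uniform_tables)


class TestCfdScore:
    def test_perfect_canonical_is_exactly_one(self, uniform_tables, spcas9):
        assert cfd_score(GUIDE, GUIDE, "AGG", uniform_tables, spcas9) == 1.0

    def test_single_mismatch_is_one_table_entry(self, spcas9):
        tables = ScoreTables.load_default(20)
        site = _mutate_at(GUIDE, [4], np.random.default_rng(1))
        expected = tables.cfd_mm[(5, GUIDE[4], site[4])] * tables.cfd_pam["GG"]
        assert cfd_score(GUIDE, site, "TGG", tables, spcas9) == pytest.approx(expected)

    def test_three_mismatches_uniform_tables(self, uniform_tables, spcas9):
        site = _mutate_at(GUIDE, [0, 5, 10], np.random.default_rng(1))
        assert cfd_score(GUIDE, site, "AGG", uniform_tables, spcas9) == pytest.approx(0.125)

    def test_noncanonical_pam_below_one(self, uniform_tables, spcas9):
        assert cfd_score(GUIDE, GUIDE, "AAG", uniform_tables, spcas9) < 1.0

    def test_missing_entry_names_key(self, spcas9):
        tables = ScoreTables(20, (0.5,) * 20, cfd_mm={}, cfd_pam={})
        site = _mutate_at(GUIDE, [2], np.random.default_rng(1))
        with pytest.raises(ConfigurationError, match=r"\(3,"):
            cfd_score(GUIDE, site, "AGG", tables, spcas9)


class TestSpecificity:
    def _hit(self, mit):
        return OffTargetHit(
            "c1", 0, "+", GUIDE, "AGG", 20, 1, (5,), mit, 0.5
        )

    def test_no_offtargets_scores_100(self):
        assert specificity_score([]) == 100.0

    def test_single_full_hit_scores_50(self):
        assert specificity_score([self._hit(100.0)]) == 50.0

    @given(st.lists(st.floats(0.01, 100.0), min_size=0, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adding_a_hit_strictly_decreases(self, mits):
        hits = [self._hit(m) for m in mits]
        base = specificity_score(hits)
        assert specificity_score(hits + [self._hit(1.0)]) < base

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        hits = [self._hit(float(m)) for m in rng.uniform(0, 100, 20)]
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert specificity_score(hits) == specificity_score(shuffled)

    def test_on_target_hits_skipped(self):
        on = self._hit(100.0)
        on.is_on_target = True
        assert specificity_score([on]) == 100.0


class TestColorClass:
    @pytest.mark.parametrize(
        "score,expected",
        [(100, "green"), (50, "green"), (49.9, "yellow"), (30, "yellow"),
         (29.9, "red"), (0, "red")],
    )
    def test_defaults(self, score, expected):
        assert color_class(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            color_class(101)


class TestSearchEquivalence:
    @pytest.mark.parametrize("nuclease_name", ["spcas9", "cpf1"])
    def test_enumerate_equals_brute_force_random(self, nuclease_name, request):
        profile = request.getfixturevalue(nuclease_name)
        rng = np.random.default_rng(101)
        for trial in range(12):
            guide = random_dna(rng, profile.guide_len)
            genome = GenomeIndex({"c1": random_dna(rng, 6000)})
            max_mm = trial % 5
            fast = enumerate_offtargets(guide, genome, profile, max_mm=max_mm)
            slow = brute_force_scan(guide, genome, profile, max_mm=max_mm)
            assert fast == slow

    def test_planted_sites_recovered_exactly(self, spcas9):
        plan = [(0, "+"), (2, "-"), (4, "+")]
        genome, records = generate_toy_genome(2, 6000, GUIDE, plan, spcas9, seed=13)
        hits = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=4)
        assert {(h.contig, h.start, h.strand, h.mismatches) for h in hits} == {
            (r.contig, r.start, r.strand, r.mismatches) for r in records
        }

    def test_budget_zero_keeps_only_perfect_site(self, spcas9):
        plan = [(0, "+"), (2, "-"), (4, "+")]
        genome, _ = generate_toy_genome(2, 6000, GUIDE, plan, spcas9, seed=13)
        hits = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=0)
        assert [h.mismatches for h in hits] == [0]

    def test_five_mismatch_site_needs_budget_five(self, spcas9):
        genome, records = generate_toy_genome(
            1, 4000, GUIDE, [(0, "+"), (5, "-")], spcas9, seed=19
        )
        default_hits = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=4)
        assert sorted(h.mismatches for h in default_hits) == [0]
        wide = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=5)
        assert sorted(h.mismatches for h in wide) == [0, 5]

    def test_n_containing_sites_excluded(self, spcas9):
        genome, records = generate_toy_genome(
            1, 3000, GUIDE, [(0, "+")], spcas9, seed=23
        )
        (rec,) = records
        seq = genome.contigs["c1"]
        masked = seq[: rec.start + 4] + "N" + seq[rec.start + 5 :]
        hits = enumerate_offtargets(
            GUIDE, GenomeIndex({"c1": masked}), spcas9, max_mm=4
        )
        assert hits == []

    def test_on_target_marking(self, spcas9):
        genome, records = generate_toy_genome(
            1, 3000, GUIDE, [(0, "+"), (2, "+")], spcas9, seed=29
        )
        on = next(r for r in records if r.mismatches == 0)
        hits = enumerate_offtargets(
            GUIDE, genome, spcas9, max_mm=4,
            target_locus=(on.contig, on.start, on.strand),
        )
        assert [h.mismatches for h in hits if h.is_on_target] == [0]

    def test_wrong_guide_length_rejected(self, spcas9):
        genome = GenomeIndex({"c1": "ACGT" * 100})
        with pytest.raises(UsageError):
            enumerate_offtargets(GUIDE[:18], genome, spcas9)

    def test_hits_sorted_by_mismatch_then_cfd(self, spcas9):
        rng = np.random.default_rng(43)
        genome = GenomeIndex({"c1": random_dna(rng, 20000)})
        hits = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=4)
        keys = [(h.mismatches, -h.cfd) for h in hits]
        assert keys == sorted(keys)


class TestFilters:
    def _hits(self):
        out = []
        for contig, start in [("c1", 10), ("c1", 500), ("c2", 50)]:
            out.append(
                OffTargetHit(contig, start, "+", GUIDE, "AGG", start + 20,
                             1, (3,), 50.0, 0.5)
            )
        return out

    def test_exon_and_contig_filters_compose(self):
        ann = ExonAnnotation([ExonInterval("c1", 0, 100, "ex1", "+")])
        hits = self._hits()
        exonic = filter_hits(hits, ann, exonic_only=True)
        assert [(h.contig, h.start) for h in exonic] == [("c1", 10)]
        same = filter_hits(hits, same_contig_only=True, target_contig="c1")
        assert {h.contig for h in same} == {"c1"}
        both = filter_hits(
            hits, ann, exonic_only=True, same_contig_only=True,
            target_contig="c2",
        )
        assert both == []

    def test_exonic_without_annotation_rejected(self):
        with pytest.raises(UsageError):
            filter_hits(self._hits(), exonic_only=True)

    def test_overlap_matches_quadratic_oracle(self):
        rng = np.random.default_rng(47)
        ivs = []
        for i in range(60):
            s = int(rng.integers(0, 5000))
            ivs.append(ExonInterval(f"c{rng.integers(1, 3)}", s, s + int(rng.integers(1, 300)), f"e{i}"))
        ann = ExonAnnotation(ivs)
        hits = [
            OffTargetHit(f"c{rng.integers(1, 3)}", int(rng.integers(0, 5000)),
                         "+", GUIDE, "AGG", 0, 1, (1,), 10.0, 0.5)
            for _ in range(200)
        ]
        kept = filter_hits(hits, ann, exonic_only=True)
        expected = [
            h for h in hits
            if any(
                iv.contig == h.contig and not (h.start + 20 <= iv.start or iv.end <= h.start)
                for iv in ivs
            )
        ]
        assert [(h.contig, h.start) for h in kept] == [
            (h.contig, h.start) for h in expected
        ]

    def test_mm_counts_histogram_sums_to_hits(self, spcas9):
        rng = np.random.default_rng(53)
        genome = GenomeIndex({"c1": random_dna(rng, 30000)})
        hits = enumerate_offtargets(GUIDE, genome, spcas9, max_mm=4)
        hist = mm_counts(hits, 4)
        assert sum(int(x) for x in hist.split("-")) == len(hits)
        assert len(hist.split("-")) == 5
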