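"""Read-pair assignment rules, positional counting, sample summaries."""

import itertools

import pytest

from xenolink.assignment import (
    AlignedPair,
    Placement,
    TranscriptInfo,
    TranscriptSet,
    accumulate_counts,
    assign_pair,
    read_placements_sam,
    read_placements_tsv,
    summarize_sample,
    write_placements_tsv,
)


def _pair(read_id, *placements):
    return AlignedPair(read_id=read_id, placements=list(placements))


def _pl(species, gene, mm, tx=None, start=0, end=100):
    return Placement(species, tx or f"{gene}_tx", gene, start, end, mm)


class TestAssignPair:
    def test_single_candidate_assigned(self):
        a = assign_pair(_pair("r", _pl("human", "GENE1", 0)))
        assert a.assigned and a.species == "human" and a.gene_id == "GENE1"

    def test_cross_species_tie_excluded(self):
        a = assign_pair(
            _pair("r", _pl("human", "GENE1", 0), _pl("mouse", "Gene2", 0))
        )
        assert not a.assigned
        assert a.reason == "cross-species tie"

    def test_fewer_mismatch_placement_wins_across_species(self):
        a = assign_pair(
            _pair("r", _pl("human", "GENE1", 0), _pl("mouse", "Gene2", 1))
        )
        assert a.assigned and a.species == "human" and a.gene_id == "GENE1"

    def test_multi_gene_tie_within_species_excluded(self):
        a = assign_pair(
            _pair("r", _pl("human", "GENE1", 0), _pl("human", "GENE3", 0))
        )
        assert not a.assigned
        assert a.reason == "multi-gene tie"

    def test_splice_variants_of_one_gene_count_once(self):
        a = assign_pair(
            _pair("r", _pl("human", "GENE1", 0, tx="tx1"),
                  _pl("human", "GENE1", 0, tx="tx2"))
        )
        assert a.assigned and a.gene_id == "GENE1"

    def test_no_placements_excluded_unmapped(self):
        a = assign_pair(_pair("r"))
        assert not a.assigned and a.reason == "unmapped"

    def test_matches_bruteforce_rule_on_all_mismatch_combinations(self):
        """Oracle: enumerate the exclusion rule over mm pairs in {0,1,2}^2.

        The stated rule excludes only equal-mismatch ties; otherwise the
        placement with strictly fewer mismatches wins.
        """
        for mm_h, mm_m in itertools.product(range(3), repeat=2):
            a = assign_pair(
                _pair("r", _pl("human", "GENE1", mm_h), _pl("mouse", "Gene2", mm_m))
            )
            if mm_h == mm_m:
                expected = ("excluded", None)
            elif mm_h < mm_m:
                expected = ("assigned", "human")
            else:
                expected = ("assigned", "mouse")
            assert (a.status, a.species) == expected, (mm_h, mm_m)

    def test_order_independent_over_placement_list(self):
        placements = [
            _pl("human", "GENE1", 1), _pl("mouse", "Gene2", 0),
            _pl("human", "GENE3", 2),
        ]
        results = {
            (assign_pair(AlignedPair("r", list(perm))).status,
             assign_pair(AlignedPair("r", list(perm))).species)
            for perm in itertools.permutations(placements)
        }
        assert results == {("assigned", "mouse")}


@pytest.fixture
def one_gene_transcripts():
    return TranscriptSet(
        [TranscriptInfo("tx1", "GENE1", "human", 1000, "A" * 1000)]
    )


class TestAccumulateCounts:
    def test_fragment_positions_flip_to_poly_a_distance(self, one_gene_transcripts):
        # fragment over transcript positions 0..99 (5' end) of a 1000 nt
        # transcript lies 901..1000 nucleotides from the poly-A tail
        a = assign_pair(_pair("r", _pl("human", "GENE1", 0, tx="tx1", start=0, end=100)))
        counts = accumulate_counts([a], one_gene_transcripts)
        cov = counts.coverage[("human", "GENE1")]
        assert cov[900:1000].tolist() == [1] * 100
        assert cov[:900].sum() == 0
        cs = counts.read_start[("human", "GENE1")]
        assert cs[900] == 1 and cs.sum() == 1

    def test_zero_assignments_give_all_zero_counts(self, one_gene_transcripts):
        counts = accumulate_counts([], one_gene_transcripts)
        assert counts.coverage == {}
        assert counts.total_pairs == 0

    def test_identical_pairs_stack_read_starts(self, one_gene_transcripts):
        pairs = [
            assign_pair(_pair(f"r{i}", _pl("human", "GENE1", 0, tx="tx1",
                                           start=500, end=700)))
            for i in range(10)
        ]
        counts = accumulate_counts(pairs, one_gene_transcripts)
        cs = counts.read_start[("human", "GENE1")]
        assert cs[1000 - 700] == 10
        assert counts.coverage[("human", "GENE1")].max() == 10

    def test_out_of_bounds_fragment_dropped(self, one_gene_transcripts):
        a = assign_pair(_pair("r", _pl("human", "GENE1", 0, tx="tx1",
                                       start=950, end=1050)))
        counts = accumulate_counts([a], one_gene_transcripts)
        assert counts.dropped_out_of_bounds == 1
        assert ("human", "GENE1") not in counts.coverage or \
            counts.coverage[("human", "GENE1")].sum() == 0

    def test_partition_of_evaluated_pairs(self, small_assignments, small_counts):
        assigned = sum(small_counts.assigned.values())
        excluded = sum(small_counts.excluded.values())
        assert assigned + excluded == len(small_assignments)
        assert small_counts.total_pairs == len(small_assignments)

    def test_read_start_totals_equal_assigned_pairs(self, small_counts):
        total_starts = sum(v.sum() for v in small_counts.read_start.values())
        assert total_starts + small_counts.dropped_out_of_bounds == sum(
            small_counts.assigned.values()
        )

    def test_coverage_dominates_read_starts(self, small_counts):
        for key, cov in small_counts.coverage.items():
            assert cov.sum() >= small_counts.read_start[key].sum()


class TestSummarizeSample:
    @pytest.mark.parametrize(
        "human,mouse,expected",
        [
            (18_147_400, 2_041_946, 10.11),  # Capan-1 xenograft
            (11_713_564, 9_796_740, 45.54),  # PK-45P xenograft
            (20_439_739, 2_037_175, 9.06),  # MiaPaca-2 xenograft
        ],
    )
    def test_mouse_read_percentage(self, human, mouse, expected):
        s = summarize_sample(assigned_human=human, assigned_mouse=mouse)
        assert s.mouse_percent == expected

    @pytest.mark.parametrize(
        "human,mouse,truth,expected",
        [
            (32_194_053, 1_821, "human", 0.0057),  # PANC-1 pure culture
            (1_052, 18_625_926, "mouse", 0.0056),  # SVEC4-10 pure culture
        ],
    )
    def test_misassignment_rate_on_pure_samples(self, human, mouse, truth, expected):
        s = summarize_sample(
            assigned_human=human, assigned_mouse=mouse, truth_species=truth
        )
        assert s.misassignment_percent == expected

    def test_no_assigned_pairs_is_error(self):
        with pytest.raises(ValueError):
            summarize_sample(assigned_human=0, assigned_mouse=0)

    def test_summary_from_counts_partitions(self, small_counts):
        s = summarize_sample(small_counts)
        assert s.assigned_human + s.assigned_mouse + s.excluded == s.total_pairs
        assert 0 <= s.mouse_percent <= 100


class TestIO:
    def test_placements_tsv_round_trip(self, tmp_path, small_reads):
        path = tmp_path / "placements.tsv"
        write_placements_tsv(small_reads.pairs[:200], path)
        back = list(read_placements_tsv(path))
        assert len(back) == 200
        assert back[0].placements == small_reads.pairs[0].placements

    def test_sam_round_trip_preserves_assignments(self, tmp_path, small_reads,
                                                  small_transcriptomes):
        from xenolink.synthetic import SimulatedReads, write_sam

        subset = SimulatedReads(
            pairs=small_reads.pairs[:300],
            truth=small_reads.truth.iloc[:300],
            config=small_reads.config,
        )
        sam = tmp_path / "pairs.sam"
        write_sam(subset, small_transcriptomes, sam)
        back = list(read_placements_sam(sam))
        assert len(back) == 300
        for orig, parsed in zip(subset.pairs, back):
            a, b = assign_pair(orig), assign_pair(parsed)
            assert (a.status, a.species, a.gene_id) == (b.status, b.species, b.gene_id)
            if a.assigned:
                assert (a.placement.start, a.placement.end) == (
                    b.placement.start, b.placement.end)
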