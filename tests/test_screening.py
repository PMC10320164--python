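"""Screening criteria: duplication flag, proximity overlap, aggregation."""
import random

import pytest

from mycomine.detect import HmmHit
from mycomine.formats import BgcRegion, GeneFeature, GenomeRecord
from mycomine.refset import CoreGeneModel
from mycomine.screening import (aggregate_multi, flag_duplication,
                                intervals_overlap, proximity_pairs, screen_genome)

from .oracles import oracle_overlaps


def _model(threshold: float) -> CoreGeneModel:
    return CoreGeneModel(model_id="m", count_median=1.0,
                         count_stdev=max(0.0, threshold - 1.0),
                         duplication_threshold=threshold)


class TestDuplicationFlag:
    def test_above_threshold(self):
        assert flag_duplication(2, _model(1.35)) is True

    def test_boundary_is_strict(self):
        assert flag_duplication(1, _model(1.0)) is False
        assert flag_duplication(2, _model(2.0)) is False

    def test_zero_copies_never_flag(self):
        assert flag_duplication(0, _model(0.0)) is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flag_duplication(-1, _model(1.0))


def _toy_genome(genes, bgcs, contig_len=10_000) -> GenomeRecord:
    contigs = {c: contig_len for c in
               {g.contig_id for g in genes} | {b.contig_id for b in bgcs} | {"chr1"}}
    g = GenomeRecord("toy", genes=list(genes), bgcs=list(bgcs), contigs=contigs)
    g.validate()
    return g


class TestProximity:
    def test_overlap_emits_pair(self):
        genome = _toy_genome([GeneFeature("g1", "chr1", 100, 500, "+", "M")],
                             [BgcRegion("b1", "chr1", 400, 900)])
        hits = [HmmHit("m", "g1", 50, 1e-9)]
        assert proximity_pairs(hits, genome) == [("g1", "b1")]

    def test_half_open_touch_is_not_overlap(self):
        genome = _toy_genome([GeneFeature("g1", "chr1", 100, 400, "+", "M")],
                             [BgcRegion("b1", "chr1", 400, 900)])
        assert proximity_pairs([HmmHit("m", "g1", 50, 1e-9)], genome) == []

    def test_different_contigs_never_pair(self):
        genome = _toy_genome([GeneFeature("g1", "chr2", 100, 500, "+", "M")],
                             [BgcRegion("b1", "chr1", 100, 500)])
        assert proximity_pairs([HmmHit("m", "g1", 50, 1e-9)], genome) == []

    def test_gene_spanning_two_bgcs_pairs_twice(self):
        genome = _toy_genome([GeneFeature("g1", "chr1", 100, 900, "+", "M")],
                             [BgcRegion("b1", "chr1", 50, 200),
                              BgcRegion("b2", "chr1", 800, 1000)])
        assert proximity_pairs([HmmHit("m", "g1", 50, 1e-9)], genome) == \
            [("g1", "b1"), ("g1", "b2")]

    def test_random_layouts_match_positionwise_oracle(self):
        """proximity_pairs equals per-position brute-force intersection on
        random gene/BGC layouts over two contigs."""
        rng = random.Random(17)
        for trial in range(30):
            genes, bgcs = [], []
            for i in range(50):
                contig = rng.choice(["c1", "c2"])
                start = rng.randrange(0, 2000)
                genes.append(GeneFeature(f"g{i}", contig, start,
                                         start + rng.randrange(1, 120), "+", "M"))
            for j in range(5):
                contig = rng.choice(["c1", "c2"])
                start = rng.randrange(0, 2000)
                bgcs.append(BgcRegion(f"b{j}", contig, start, start + rng.randrange(1, 400)))
            genome = _toy_genome(genes, bgcs, contig_len=5000)
            hits = [HmmHit("m", g.gene_id, 50, 1e-9) for g in genes]
            expected = oracle_overlaps(
                {g.gene_id: (g.contig_id, g.start, g.end) for g in genes},
                {b.cluster_id: (b.contig_id, b.start, b.end) for b in bgcs})
            assert set(proximity_pairs(hits, genome)) == expected

    def test_overlap_predicate_half_open(self):
        assert intervals_overlap(0, 10, 9, 20)
        assert not intervals_overlap(0, 10, 10, 20)


class TestScreenGenome:
    def test_planted_duplication_in_bgc_flags_d_and_b(self, collection, results):
        res = results["qry01"]
        row = next(r for r in res.rows if r.model_id == "og0003")
        assert row.flags.duplication and row.flags.proximity
        assert row.flags.label() == "D, B"
        assert row.copy_number == 2
        assert len(row.proximity) == 1 and row.proximity[0][0].startswith("qry01_og0003")

    def test_outside_bgc_duplication_flags_d_only(self, results):
        row = next(r for r in results["qry01"].rows if r.model_id == "og0006")
        assert row.flags.duplication and not row.flags.proximity
        assert row.copy_number == 3 and row.proximity == []

    def test_resistance_hit_row(self, results):
        row = next(r for r in results["qry01"].rows if r.category == "resistance")
        assert row.flags.resistance_model
        assert row.flags.proximity  # planted inside a BGC
        assert row.duplication_threshold is None

    def test_unplanted_models_have_no_flags(self, results):
        for r in results["qry01"].rows:
            if r.category == "core" and r.model_id not in ("og0003", "og0006"):
                assert r.flags.n_true == 0 and r.copy_number == 1

    def test_totals_recomputable_from_rows(self, results):
        res = results["qry01"]
        recomputed = res.recompute_totals()
        for key, value in recomputed.items():
            assert res.totals[key] == value

    def test_rows_sorted_by_flag_count_then_copies(self, results):
        rows = results["qry01"].rows
        keys = [(-r.flags.n_true, -r.copy_number, r.model_id) for r in rows]
        assert keys == sorted(keys)

    def test_zero_bgc_genome_all_b_false(self, refset, collection, tmp_path):
        from mycomine.detect import detect_core_genes
        genome = collection.query_genomes[0]
        stripped = GenomeRecord(genome.genome_id, genome.genes, [], genome.contigs)
        hits = detect_core_genes(stripped, refset, "default")
        res = screen_genome(stripped, refset, hits)
        assert all(not r.flags.proximity for r in res.rows)
        assert res.bgc_summary == []
        assert res.totals["n_bgcs"] == 0
        assert res.totals["n_bgcs_with_core_hit"] == 0
        assert res.totals["n_bgcs_with_res_hit"] == 0

    def test_aux_toggle_does_not_change_core_flags(self, refset, collection, tmp_path_factory):
        from mycomine.detect import detect_core_genes
        genome = collection.query_genomes[0]
        hits = detect_core_genes(genome, refset, "default")
        without_aux = screen_genome(genome, refset, hits, aux_hits=())
        from mycomine.fixtures import write_hmms
        from mycomine.detect import detect_auxiliary
        res_paths = write_hmms(collection.resistance_hmms, tmp_path_factory.mktemp("rr"))
        with_aux = screen_genome(genome, refset, hits,
                                 detect_auxiliary(genome, res_paths, {}))
        core_a = {r.model_id: r.flags for r in without_aux.rows if r.category == "core"}
        core_b = {r.model_id: r.flags for r in with_aux.rows if r.category == "core"}
        assert core_a == core_b


class TestAggregateMulti:
    def _result(self, genome_id, model_hits):
        from mycomine.screening import CriteriaFlags, ModelRow, ScreeningResult
        rows = [ModelRow(m, "core", 1, 1.0, CriteriaFlags()) for m in model_hits]
        return ScreeningResult(genome_id, rows, [], {
            "n_bgcs": 0, "n_bgcs_with_core_hit": 0, "n_bgcs_with_res_hit": 0,
            "n_core_genes_found": len(model_hits), "n_genes_total": 10,
            "n_models_hit": len(model_hits), "n_criteria_hit_models": 0,
            "n_criteria_hit_genes": 0})

    def test_frequency_is_hit_genomes_over_total(self):
        results = [self._result(f"g{i}", ["a"] if i < 2 else []) for i in range(4)]
        summary = aggregate_multi(results)
        (row,) = summary.rows
        assert row["model_id"] == "a" and row["frequency"] == 0.5

    def test_model_hit_everywhere_is_one(self):
        summary = aggregate_multi([self._result(f"g{i}", ["a"]) for i in range(3)])
        assert summary.rows[0]["frequency"] == 1.0

    def test_model_hit_nowhere_absent(self):
        summary = aggregate_multi([self._result("g1", []), self._result("g2", [])])
        assert summary.rows == []

    def test_needs_two_results(self):
        with pytest.raises(ValueError):
            aggregate_multi([self._result("g1", ["a"])])

    def test_frequencies_in_unit_interval(self, results, refset, collection, tmp_path_factory):
        from mycomine.fixtures import FixtureSpec, PlantedEvent, generate_collection, screen_collection
        spec = FixtureSpec(seed=9, n_query_genomes=3,
                           planted_events=[PlantedEvent("og0001", "qry01"),
                                           PlantedEvent("og0001", "qry03")])
        coll = generate_collection(spec)
        _, res = screen_collection(coll, tmp_path_factory.mktemp("agg"))
        summary = aggregate_multi(list(res.values()))
        assert all(0.0 < r["frequency"] <= 1.0 for r in summary.rows)
        row = next(r for r in summary.rows if r["model_id"] == "og0001")
        assert row["frequency"] == 1.0           # hit (not necessarily flagged) everywhere
        assert row["n_duplication"] == 2         # flagged in exactly the two planted genomes
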