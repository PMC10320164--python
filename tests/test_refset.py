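"""Duplication thresholds, ubiquity, single-copy frequency and mode filtering."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycomine.refset import (CoreGeneModel, OrthologTable, build_refset,
                             classify_and_filter, count_stats, load_refset,
                             read_ortholog_table, save_refset, single_copy_freq,
                             ubiquity, write_ortholog_table)

count_vectors = st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=40)


class TestCountStats:
    def test_constant_counts_give_zero_spread(self):
        assert count_stats([1, 1, 1, 1, 1]) == (1.0, 0.0, 1.0)

    def test_single_duplication_hand_computed(self):
        med, sd, thr = count_stats([1, 1, 1, 1, 2, 1, 1])
        assert med == 1.0
        assert sd == pytest.approx(math.sqrt(6 / 49), abs=1e-4)  # ≈ 0.3499
        assert thr == pytest.approx(1.0 + math.sqrt(6 / 49), abs=1e-4)

    def test_zeros_are_observations(self):
        med, sd, thr = count_stats([0, 0, 0, 2])
        assert med == 0.0
        assert sd == pytest.approx(np.std([0, 0, 0, 2]))
        assert thr == pytest.approx(sd)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="no reference observations"):
            count_stats([])

    @settings(max_examples=200, deadline=None)
    @given(count_vectors, st.floats(min_value=0.0, max_value=3.0))
    def test_matches_numpy_brute_force(self, counts, k):
        med, sd, thr = count_stats(counts, k=k)
        assert med == pytest.approx(float(np.median(counts)))
        assert sd == pytest.approx(float(np.std(counts, ddof=0)))
        assert thr == pytest.approx(med + k * sd)
        assert thr >= med
        if len(set(counts)) == 1:
            assert thr == med


class TestOccupancyStats:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 2, 0, 1, 1, 0, 1, 1, 1, 1], 0.8),
        ([0, 0, 0], 0.0),
        ([3, 1, 2], 1.0),
    ])
    def test_ubiquity(self, counts, expected):
        assert ubiquity(counts) == pytest.approx(expected)

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 2, 1], 0.75),
        ([2, 2, 2], 0.0),
    ])
    def test_single_copy_freq(self, counts, expected):
        assert single_copy_freq(counts) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None)
    @given(count_vectors)
    def test_fractions_match_enumeration_and_stay_in_range(self, counts):
        assert ubiquity(counts) == sum(c >= 1 for c in counts) / len(counts)
        assert single_copy_freq(counts) == counts.count(1) / len(counts)
        assert 0.0 <= ubiquity(counts) <= 1.0
        assert 0.0 <= single_copy_freq(counts) <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ubiquity([])
        with pytest.raises(ValueError):
            single_copy_freq([])


def _model(mid: str, fclass: str) -> CoreGeneModel:
    return CoreGeneModel(model_id=mid, function_class=fclass)


class TestModeFilter:
    def test_default_removes_biosynthesis_class(self):
        models = [_model("a", "Q"), _model("b", "J")]
        kept = classify_and_filter(models, "default")
        assert [m.model_id for m in kept] == ["b"]

    def test_exploration_is_identity(self):
        models = [_model("a", "Q"), _model("b", "K"), _model("c", "J")]
        assert classify_and_filter(models, "exploration") == models

    def test_translation_class_survives_both_modes(self):
        models = [_model("a", "J")]
        assert classify_and_filter(models, "default") == models
        assert classify_and_filter(models, "exploration") == models

    def test_unknown_class_retained_with_warning(self, caplog):
        models = [_model("a", "?")]
        with caplog.at_level("WARNING"):
            kept = classify_and_filter(models, "default")
        assert kept == models
        assert "unknown function class" in caplog.text

    def test_default_output_is_subset(self):
        models = [_model(f"m{i}", c) for i, c in enumerate("QKJPUCOE")]
        kept = classify_and_filter(models, "default")
        assert set(m.model_id for m in kept) <= {m.model_id for m in models}


class TestBuildRefset:
    def test_cardinality(self, collection, refset):
        assert len(refset.models) == collection.spec.n_models
        assert refset.n_reference_genomes == collection.spec.n_ref_genomes

    def test_all_single_copy_references_give_unit_threshold(self, refset):
        for m in refset.models:
            assert m.count_median == 1.0
            assert m.duplication_threshold == 1.0
            assert m.ubiquity == 1.0
            assert m.single_copy_freq == 1.0

    def test_group_absent_everywhere(self):
        table = OrthologTable({"og1": {}}, ["gA", "gB"])
        from mycomine.formats import GenomeRecord
        genomes = [GenomeRecord("gA"), GenomeRecord("gB")]
        rs = build_refset(genomes, table, "t")
        (m,) = rs.models
        assert m.ubiquity == 0.0 and m.duplication_threshold == 0.0

    def test_planted_reference_duplication_threshold_between_1_and_2(self):
        from mycomine.formats import GenomeRecord
        genomes = [GenomeRecord(f"g{i}") for i in range(5)]
        table = OrthologTable(
            {"og1": {f"g{i}": (["a", "b"] if i == 0 else ["a"]) for i in range(5)}},
            [f"g{i}" for i in range(5)])
        rs = build_refset(genomes, table, "t")
        assert 1.0 < rs.models[0].duplication_threshold < 2.0

    def test_missing_genome_listed_in_error(self):
        from mycomine.formats import GenomeRecord
        table = OrthologTable({"og1": {"gA": ["x"]}}, ["gA", "gB"])
        with pytest.raises(ValueError, match="gB"):
            build_refset([GenomeRecord("gA")], table, "t")

    def test_deterministic(self, collection, tmp_path):
        a = build_refset(collection.ref_genomes, collection.ortholog_table, "t")
        b = build_refset(collection.ref_genomes, collection.ortholog_table, "t")
        assert a == b

    def test_dnds_metadata_populated(self, refset):
        values = [m.dnds_median for m in refset.models if m.dnds_median is not None]
        assert values, "at least some families should yield a defined dN/dS median"
        assert all(v >= 0 for v in values)


class TestBundleRoundTrip:
    def test_save_load_identity(self, refset, refset_bundle):
        back = load_refset(refset_bundle)
        assert back.name == refset.name
        assert back.n_reference_genomes == refset.n_reference_genomes
        for orig, loaded in zip(sorted(refset.models, key=lambda m: m.model_id),
                                sorted(back.models, key=lambda m: m.model_id)):
            assert loaded.model_id == orig.model_id
            assert loaded.duplication_threshold == pytest.approx(orig.duplication_threshold)
            assert loaded.ubiquity == pytest.approx(orig.ubiquity)
            assert (loaded.dnds_median is None) == (orig.dnds_median is None)
            if orig.dnds_median is not None:
                assert loaded.dnds_median == pytest.approx(orig.dnds_median)
            assert loaded.hmm_path is not None and loaded.hmm_path.exists()

    def test_ortholog_table_round_trip(self, collection, tmp_path):
        path = tmp_path / "orth.tsv"
        write_ortholog_table(collection.ortholog_table, path)
        back = read_ortholog_table(path, roster=collection.ortholog_table.roster)
        assert back.groups == collection.ortholog_table.groups
        assert back.annotations == collection.ortholog_table.annotations
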