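"""Screening criteria: duplication (D), BGC proximity (B), resistance model (R).

The duplication criterion flags a model whose copy number in the query
genome strictly exceeds its reference-derived threshold (median + k·stdev).
The proximity criterion flags any hit gene whose genomic envelope overlaps a
BGC interval on the same contig (half-open semantics: a shared boundary is
not an overlap).  The resistance criterion marks hits of known resistance
profiles.  The flags are independent — a self-resistant target typically
shows D and B together, which is what prioritization looks for.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .detect import CoreGeneHitSet, HmmHit
from .formats import BgcRegion, GenomeRecord
from .refset import CoreGeneModel, ReferenceSet

__all__ = [
    "CriteriaFlags", "ModelRow", "ScreeningResult", "MultiGenomeSummary",
    "flag_duplication", "proximity_pairs", "screen_genome", "aggregate_multi",
]


@dataclass(frozen=True)
class CriteriaFlags:
    duplication: bool = False
    proximity: bool = False
    resistance_model: bool = False

    @property
    def n_true(self) -> int:
        return int(self.duplication) + int(self.proximity) + int(self.resistance_model)

    def label(self) -> str:
        """Human-readable criteria string, e.g. ``D, B, R`` or ``Core``."""
        parts = [c for c, on in (("D", self.duplication), ("B", self.proximity),
                                 ("R", self.resistance_model)) if on]
        return ", ".join(parts) if parts else "Core"


@dataclass
class ModelRow:
    """One screened model in one genome."""

    model_id: str
    category: str
    copy_number: int
    duplication_threshold: float | None
    flags: CriteriaFlags
    proximity: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, cluster_id)
    function_class: str = ""
    dnds_median: float | None = None
    ubiquity: float | None = None
    single_copy_freq: float | None = None


@dataclass
class ScreeningResult:
    genome_id: str
    rows: list[ModelRow]
    bgc_summary: list[tuple[str, int, int, str]]  # cluster_id, n_core_hits, n_res_hits, product
    totals: dict[str, int]

    def recompute_totals(self) -> dict[str, int]:
        """Totals derivable from rows/bgc_summary alone; self-consistency check."""
        return {
            "n_bgcs": len(self.bgc_summary),
            "n_bgcs_with_core_hit": sum(1 for b in self.bgc_summary if b[1] > 0),
            "n_bgcs_with_res_hit": sum(1 for b in self.bgc_summary if b[2] > 0),
            "n_models_hit": sum(1 for r in self.rows if r.category == "core"),
            "n_criteria_hit_models": sum(1 for r in self.rows
                                         if r.category == "core" and r.flags.n_true > 0),
        }


@dataclass
class MultiGenomeSummary:
    """Cross-genome aggregation: per-model hit frequency over successful runs."""

    n_genomes: int
    rows: list[dict]          # model_id, category, n_genomes_hit, frequency, flag counts
    per_genome: list[dict]    # genome_id + totals


def flag_duplication(copy_number: int, model: CoreGeneModel) -> bool:
    """True iff the query copy number strictly exceeds the model threshold."""
    if copy_number < 0:
        raise ValueError("copy_number must be non-negative")
    return copy_number > model.duplication_threshold


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Nonempty intersection of two half-open intervals."""
    return max(a_start, b_start) < min(a_end, b_end)


def proximity_pairs(hits: Sequence[HmmHit], genome: GenomeRecord) -> list[tuple[str, str]]:
    """(gene_id, cluster_id) for every hit gene overlapping a BGC.

    A gene overlapping two BGCs yields two pairs; duplicate hits of one gene
    collapse to one pair per BGC.  Pairs are sorted for deterministic output.
    """
    gene_index = {g.gene_id: g for g in genome.genes}
    pairs: set[tuple[str, str]] = set()
    gene_ids = {h.gene_id for h in hits}
    for gid in gene_ids:
        gene = gene_index.get(gid)
        if gene is None:
            raise KeyError(f"hit references unknown gene {gid}")
        for bgc in genome.bgcs:
            if bgc.contig_id == gene.contig_id and \
                    intervals_overlap(gene.start, gene.end, bgc.start, bgc.end):
                pairs.add((gid, bgc.cluster_id))
    return sorted(pairs)


def screen_genome(genome: GenomeRecord, refset: ReferenceSet,
                  core_hits: Mapping[str, CoreGeneHitSet],
                  aux_hits: Sequence[HmmHit] = (),
                  suppress_duplication: bool = False) -> ScreeningResult:
    """Assemble the per-genome screening result.

    ``suppress_duplication`` disables the D flag, for BGC-only inputs where
    genome-wide copy numbers are meaningless.
    """
    rows: list[ModelRow] = []
    core_hit_genes: set[str] = set()
    res_hit_genes: set[str] = set()

    for model_id in sorted(core_hits):
        hs = core_hits[model_id]
        model = refset.model(model_id)
        pairs = proximity_pairs(hs.hits, genome)
        dup = (not suppress_duplication) and flag_duplication(hs.copy_number, model)
        rows.append(ModelRow(
            model_id=model_id, category="core", copy_number=hs.copy_number,
            duplication_threshold=model.duplication_threshold,
            flags=CriteriaFlags(duplication=dup, proximity=bool(pairs)),
            proximity=pairs, function_class=model.function_class,
            dnds_median=model.dnds_median, ubiquity=model.ubiquity,
            single_copy_freq=model.single_copy_freq))
        core_hit_genes.update(hs.gene_ids)

    aux_by_model: dict[tuple[str, str], list[HmmHit]] = {}
    for h in aux_hits:
        aux_by_model.setdefault((h.category, h.model_id), []).append(h)
    for (category, model_id), hits in sorted(aux_by_model.items()):
        pairs = proximity_pairs(hits, genome)
        rows.append(ModelRow(
            model_id=model_id, category=category,
            copy_number=len({h.gene_id for h in hits}), duplication_threshold=None,
            flags=CriteriaFlags(proximity=bool(pairs),
                                resistance_model=(category == "resistance")),
            proximity=pairs))
        if category == "resistance":
            res_hit_genes.update(h.gene_id for h in hits)

    rows.sort(key=lambda r: (-r.flags.n_true, -r.copy_number, r.model_id))

    gene_index = {g.gene_id: g for g in genome.genes}
    bgc_summary = []
    for bgc in sorted(genome.bgcs, key=lambda b: (b.contig_id, b.start, b.cluster_id)):
        n_core = _genes_in_bgc(core_hit_genes, gene_index, bgc)
        n_res = _genes_in_bgc(res_hit_genes, gene_index, bgc)
        bgc_summary.append((bgc.cluster_id, n_core, n_res, bgc.product_class))

    totals = {
        "n_bgcs": len(genome.bgcs),
        "n_bgcs_with_core_hit": sum(1 for b in bgc_summary if b[1] > 0),
        "n_bgcs_with_res_hit": sum(1 for b in bgc_summary if b[2] > 0),
        "n_core_genes_found": len(core_hit_genes),
        "n_genes_total": len(genome.genes),
        "n_models_hit": sum(1 for r in rows if r.category == "core"),
        "n_criteria_hit_models": sum(1 for r in rows if r.category == "core" and r.flags.n_true > 0),
        "n_criteria_hit_genes": len({g for r in rows if r.category == "core" and r.flags.n_true > 0
                                     for g, _ in r.proximity}),
    }
    result = ScreeningResult(genome.genome_id, rows, bgc_summary, totals)
    _assert_consistent(result)
    return result


def _genes_in_bgc(gene_ids: Iterable[str], gene_index: Mapping[str, object], bgc: BgcRegion) -> int:
    n = 0
    for gid in gene_ids:
        g = gene_index[gid]
        if g.contig_id == bgc.contig_id and intervals_overlap(g.start, g.end, bgc.start, bgc.end):
            n += 1
    return n


def _assert_consistent(result: ScreeningResult) -> None:
    known_clusters = {b[0] for b in result.bgc_summary}
    for r in result.rows:
        for _, cid in r.proximity:
            if cid not in known_clusters:
                raise AssertionError(f"row references unknown cluster {cid}")
    assert result.totals["n_bgcs"] == len(result.bgc_summary)
    assert result.totals["n_bgcs_with_core_hit"] == sum(1 for b in result.bgc_summary if b[1] > 0)
    assert result.totals["n_bgcs_with_res_hit"] == sum(1 for b in result.bgc_summary if b[2] > 0)


def aggregate_multi(results: Sequence[ScreeningResult]) -> MultiGenomeSummary:
    """Cross-genome summary: per model, the frequency (0.0–1.0) of genomes
    with at least one hit, denominator = number of supplied (successful) runs.

    Models hit in no genome do not appear (there is nothing to report)."""
    if len(results) < 2:
        raise ValueError("multi-genome aggregation needs at least two results")
    n = len(results)
    acc: dict[tuple[str, str], dict] = {}
    for res in results:
        seen: set[tuple[str, str]] = set()
        for r in res.rows:
            key = (r.category, r.model_id)
            if key in seen:
                continue
            seen.add(key)
            entry = acc.setdefault(key, {"model_id": r.model_id, "category": r.category,
                                         "n_genomes_hit": 0, "n_duplication": 0,
                                         "n_proximity": 0, "n_resistance": 0})
            entry["n_genomes_hit"] += 1
            entry["n_duplication"] += int(r.flags.duplication)
            entry["n_proximity"] += int(r.flags.proximity)
            entry["n_resistance"] += int(r.flags.resistance_model)
    rows = []
    for (category, model_id) in sorted(acc):
        e = acc[(category, model_id)]
        e["frequency"] = e["n_genomes_hit"] / n
        rows.append(e)
    rows.sort(key=lambda e: (-e["frequency"], e["category"], e["model_id"]))
    per_genome = [{"genome_id": r.genome_id, **r.totals} for r in results]
    return MultiGenomeSummary(n_genomes=n, rows=rows, per_genome=per_genome)
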