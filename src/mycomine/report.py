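"""Run orchestration, tabular/HTML report rendering, and the run manifest.

Single-genome runs produce a directory with five TSVs (core genes,
duplications, proximity pairs, per-BGC summary, totals), a static
``report.html`` and ``manifest.json``.  Multi-genome runs add per-genome
subdirectories plus ``multi_summary.tsv`` with the per-model hit frequency
(0.0–1.0, denominator = genomes that ran successfully).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .detect import PyhmmerEngine, detect_auxiliary, detect_core_genes
from .formats import BgcRegion, GenomeRecord, read_bgc_regions, read_genome, write_tsv
from .refset import CoreGeneModel, ReferenceSet, load_refset
from .screening import MultiGenomeSummary, ScreeningResult, aggregate_multi, screen_genome

logger = logging.getLogger(__name__)

TSV_FILES = ("coregenes.tsv", "duplications.tsv", "proximity.tsv",
             "bgc_summary.tsv", "summary.tsv")


@dataclass
class RunConfig:
    """Validated run options; echoed verbatim into the manifest."""

    refset_path: Path
    mode: str = "default"
    search_resistance: bool = True
    search_duf: bool = True
    resistance_models: dict[str, Path] = field(default_factory=dict)
    duf_models: dict[str, Path] = field(default_factory=dict)
    custom_core_models: dict[str, Path] = field(default_factory=dict)
    duplication_k: float | None = None   # None: keep thresholds stored in the refset
    bgc_only: bool = False
    gene_table: Path | None = None       # sidecar for FASTA input
    bgc_feature_type: str = "region"
    emit_bigscape_input: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("default", "exploration"):
            raise ValueError(f"mode must be 'default' or 'exploration', got {self.mode!r}")
        self.refset_path = Path(self.refset_path)
        if not self.refset_path.exists():
            raise FileNotFoundError(f"reference set not found: {self.refset_path}")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, dict):
                d[k] = {kk: str(vv) for kk, vv in v.items()}
        return d


# ---------------------------------------------------------------------------
# table renderers
# ---------------------------------------------------------------------------

def _fmt(x) -> object:
    return "NA" if x is None else x


def coregenes_table(result: ScreeningResult) -> pd.DataFrame:
    rows = []
    for r in result.rows:
        rows.append({
            "model_id": r.model_id, "category": r.category, "criteria": r.flags.label(),
            "copy_number": r.copy_number,
            "duplication_threshold": _fmt(r.duplication_threshold),
            "duplication": r.flags.duplication, "proximity": r.flags.proximity,
            "resistance_model": r.flags.resistance_model,
            "function_class": r.function_class,
            "dnds_median": _fmt(r.dnds_median), "ubiquity": _fmt(r.ubiquity),
            "single_copy_freq": _fmt(r.single_copy_freq),
            "proximity_pairs": ";".join(f"{g}:{c}" for g, c in r.proximity),
        })
    return pd.DataFrame(rows, columns=[
        "model_id", "category", "criteria", "copy_number", "duplication_threshold",
        "duplication", "proximity", "resistance_model", "function_class",
        "dnds_median", "ubiquity", "single_copy_freq", "proximity_pairs"])


def duplications_table(result: ScreeningResult) -> pd.DataFrame:
    rows = [{"model_id": r.model_id, "copy_number": r.copy_number,
             "duplication_threshold": r.duplication_threshold,
             "function_class": r.function_class}
            for r in result.rows if r.flags.duplication]
    return pd.DataFrame(rows, columns=["model_id", "copy_number",
                                       "duplication_threshold", "function_class"])


def proximity_table(result: ScreeningResult) -> pd.DataFrame:
    rows = [{"model_id": r.model_id, "category": r.category, "gene_id": g, "cluster_id": c}
            for r in result.rows for g, c in r.proximity]
    return pd.DataFrame(rows, columns=["model_id", "category", "gene_id", "cluster_id"])


def bgc_summary_table(result: ScreeningResult) -> pd.DataFrame:
    rows = [{"cluster_id": cid, "n_core_hits": nc, "n_resistance_hits": nr,
             "product_class": prod} for cid, nc, nr, prod in result.bgc_summary]
    return pd.DataFrame(rows, columns=["cluster_id", "n_core_hits",
                                       "n_resistance_hits", "product_class"])


def summary_table(result: ScreeningResult) -> pd.DataFrame:
    rows = [{"metric": k, "value": v} for k, v in sorted(result.totals.items())]
    return pd.DataFrame(rows, columns=["metric", "value"])


def multi_summary_table(summary: MultiGenomeSummary) -> pd.DataFrame:
    return pd.DataFrame(summary.rows, columns=[
        "model_id", "category", "n_genomes_hit", "n_duplication", "n_proximity",
        "n_resistance", "frequency"])


def genomes_table(summary: MultiGenomeSummary) -> pd.DataFrame:
    return pd.DataFrame(summary.per_genome)


def write_result_tables(result: ScreeningResult, outdir: Path) -> None:
    write_tsv(coregenes_table(result), outdir / "coregenes.tsv")
    write_tsv(duplications_table(result), outdir / "duplications.tsv")
    write_tsv(proximity_table(result), outdir / "proximity.tsv")
    write_tsv(bgc_summary_table(result), outdir / "bgc_summary.tsv")
    write_tsv(summary_table(result), outdir / "summary.tsv")


# ---------------------------------------------------------------------------
# HTML (static, one summary page)
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 8px}}th{{background:#eee}}</style></head>
<body><h1>{title}</h1>
<!-- generated: {timestamp} -->
{body}
</body></html>
"""


def _df_html(df: pd.DataFrame, caption: str) -> str:
    return f"<h2>{caption}</h2>\n" + df.to_html(index=False, border=0)


def render_single_html(result: ScreeningResult, note: str = "") -> str:
    body = ""
    if note:
        body += f"<p><em>{note}</em></p>\n"
    body += _df_html(summary_table(result), "Summary")
    body += _df_html(coregenes_table(result), "Core genes and criteria")
    body += _df_html(bgc_summary_table(result), "BGC summary")
    return _PAGE.format(title=f"Screening result: {result.genome_id}",
                        timestamp=time.strftime("%Y-%m-%d %H:%M:%S"), body=body)


def render_multi_html(summary: MultiGenomeSummary) -> str:
    body = _df_html(genomes_table(summary), "Per-genome runs")
    body += _df_html(multi_summary_table(summary), "Model hit frequency across genomes")
    return _PAGE.format(title=f"Multi-genome screening ({summary.n_genomes} genomes)",
                        timestamp=time.strftime("%Y-%m-%d %H:%M:%S"), body=body)


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".embl",):
        return "embl"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot infer genome format from {path.name}")


def _apply_duplication_k(refset: ReferenceSet, k: float) -> ReferenceSet:
    models = [dataclasses.replace(m, duplication_threshold=m.count_median + k * m.count_stdev)
              for m in refset.models]
    return ReferenceSet(refset.name, models, refset.n_reference_genomes, refset.mode_filter)


def load_genome_with_bgcs(genome_path: Path, bgc_path: Path | None,
                          config: RunConfig) -> GenomeRecord:
    fmt = _infer_format(genome_path)
    genome = read_genome(genome_path, fmt, gene_table=config.gene_table)
    if bgc_path is not None:
        dialect = "tsv_table" if bgc_path.suffix.lower() in (".tsv", ".txt") \
            else "antismash_region_gbk"
        genome.bgcs = read_bgc_regions(bgc_path, dialect, config.bgc_feature_type)
    elif fmt in ("genbank", "embl"):
        try:
            genome.bgcs = read_bgc_regions(genome_path, "antismash_region_gbk",
                                           config.bgc_feature_type)
        except Exception:
            genome.bgcs = []
    if config.bgc_only and not genome.bgcs:
        # single-BGC input with no flanking genome: the whole record is the cluster
        genome.bgcs = [BgcRegion(f"{cid}_whole", cid, 0, length, "", "coordinate_table")
                       for cid, length in genome.contigs.items()]
    genome.validate()
    return genome


def run_single(genome_path: str | Path, bgc_path: str | Path | None,
               config: RunConfig, outdir: str | Path,
               engine=None) -> ScreeningResult:
    """Screen one genome and write the full report directory."""
    genome_path = Path(genome_path)
    bgc_path = Path(bgc_path) if bgc_path else None
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    engine = engine or PyhmmerEngine()

    refset = load_refset(config.refset_path)
    if config.duplication_k is not None:
        refset = _apply_duplication_k(refset, config.duplication_k)
    if config.custom_core_models:
        refset = _attach_custom_core(refset, config.custom_core_models)

    genome = load_genome_with_bgcs(genome_path, bgc_path, config)
    core_hits = detect_core_genes(genome, refset, config.mode, engine=engine)
    aux_hits = detect_auxiliary(genome, config.resistance_models, config.duf_models,
                                config.search_resistance, config.search_duf, engine=engine)
    result = screen_genome(genome, refset, core_hits, aux_hits,
                           suppress_duplication=config.bgc_only)

    write_result_tables(result, outdir)
    note = ("BGC-only input: genome-wide copy numbers unavailable, duplication "
            "flags suppressed." if config.bgc_only else "")
    (outdir / "report.html").write_text(render_single_html(result, note))
    manifest = {
        "tool_version": __version__, "engine_version": engine.version,
        "config": config.to_json(),
        "inputs": {str(genome_path): _sha256(genome_path),
                   **({str(bgc_path): _sha256(bgc_path)} if bgc_path else {})},
        "genomes": {genome.genome_id: "ok"},
        "refset": refset.name,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def _attach_custom_core(refset: ReferenceSet, custom: dict[str, Path]) -> ReferenceSet:
    """Add user-supplied core models; they screen with profile cutoffs and a
    zero-information duplication threshold of median 1 + stdev 0."""
    from .refset import _profile_cutoff

    extra = [CoreGeneModel(model_id=mid, description="custom core model",
                           count_median=1.0, count_stdev=0.0, duplication_threshold=1.0,
                           ubiquity=0.0, single_copy_freq=0.0,
                           hmm_path=Path(p), bitscore_cutoff=_profile_cutoff(Path(p), 25.0))
             for mid, p in sorted(custom.items())]
    return ReferenceSet(refset.name, refset.models + extra,
                        refset.n_reference_genomes, refset.mode_filter)


def run_multi(genome_paths: list[str | Path], config: RunConfig,
              outdir: str | Path, bgc_paths: dict[str, Path] | None = None,
              engine=None) -> MultiGenomeSummary | None:
    """Screen several genomes; failures are recorded and excluded from the
    frequency denominator rather than aborting the batch."""
    if len(genome_paths) < 2:
        raise ValueError("multi-genome run needs at least two genomes")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    engine = engine or PyhmmerEngine()
    bgc_paths = bgc_paths or {}

    results: list[ScreeningResult] = []
    statuses: dict[str, str] = {}
    for path in map(Path, genome_paths):
        sub = outdir / path.stem
        try:
            res = run_single(path, bgc_paths.get(path.stem), config, sub, engine=engine)
            results.append(res)
            statuses[path.stem] = "ok"
        except Exception as exc:
            logger.error("genome %s failed: %s", path.stem, exc)
            statuses[path.stem] = f"failed: {exc}"

    summary = None
    if len(results) >= 2:
        summary = aggregate_multi(results)
        write_tsv(multi_summary_table(summary), outdir / "multi_summary.tsv")
        write_tsv(genomes_table(summary), outdir / "genomes.tsv")
        (outdir / "report.html").write_text(render_multi_html(summary))
    if config.emit_bigscape_input:
        big = outdir / "bigscape_input"
        big.mkdir(exist_ok=True)
        for path in map(Path, genome_paths):
            if statuses.get(path.stem) == "ok" and path.suffix.lower() in (".gb", ".gbk", ".gbff"):
                (big / path.name).write_bytes(path.read_bytes())
    manifest = {
        "tool_version": __version__, "engine_version": engine.version,
        "config": config.to_json(), "genomes": statuses,
        "n_successful": len(results),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
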