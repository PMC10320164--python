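"""Reference-set construction from a genome collection and an ortholog table.

A reference set is, per essential-gene ortholog group, a profile HMM plus
the metadata needed for screening: the duplication threshold derived from
ortholog copy numbers across the reference genomes (median + k·stdev,
population stdev, absences counted as zero), the fraction of reference
genomes carrying at least one copy (ubiquity), the fraction carrying exactly
one copy (single-copy frequency), a one-letter COG functional class, and the
median pairwise Nei–Gojobori dN/dS across reference orthologs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dnds import codon_align, pairwise_dnds
from .formats import GenomeRecord, read_tsv, write_tsv

logger = logging.getLogger(__name__)

#: COG categories removed in default mode: secondary-metabolite biosynthesis,
#: transport and catabolism (Q), transcription/regulation (K), and the
#: transport-annotated categories (P: inorganic ion transport, U:
#: trafficking/secretion/vesicular transport).  Configurable per run.
DEFAULT_EXCLUDED_CLASSES = frozenset({"Q", "K", "P", "U"})

#: Known one-letter COG functional categories.
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

MODELS_TSV_COLUMNS = [
    "model_id", "description", "function_class", "count_median", "count_stdev",
    "duplication_threshold", "ubiquity", "single_copy_freq", "dnds_median",
    "bitscore_cutoff", "hmm_file",
]


@dataclass
class OrthologTable:
    """Ortholog-group membership: group id -> genome id -> member gene ids."""

    groups: dict[str, dict[str, list[str]]]
    roster: list[str]
    annotations: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (description, class)

    def __post_init__(self) -> None:
        roster = set(self.roster)
        for gid, per_genome in self.groups.items():
            unknown = set(per_genome) - roster
            if unknown:
                raise ValueError(f"ortholog group {gid}: genomes {sorted(unknown)} not in roster")

    def counts(self, group_id: str) -> list[int]:
        """Copy number per roster genome, zeros for absences."""
        per_genome = self.groups[group_id]
        return [len(per_genome.get(g, [])) for g in self.roster]

    def members(self, group_id: str) -> list[tuple[str, str]]:
        """(genome_id, gene_id) pairs for all member genes."""
        return [(g, gene) for g in self.roster for gene in self.groups[group_id].get(g, [])]


def read_ortholog_table(path: str | Path, roster: Sequence[str] | None = None) -> OrthologTable:
    """Read the long-format TSV: ortholog_group_id, genome_id, gene_id
    (optionally description and function_class, constant within a group)."""
    df = read_tsv(path)
    groups: dict[str, dict[str, list[str]]] = {}
    annotations: dict[str, tuple[str, str]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(row.ortholog_group_id, {}).setdefault(row.genome_id, []).append(row.gene_id)
        desc = str(getattr(row, "description", "") or "")
        fclass = str(getattr(row, "function_class", "") or "")
        if desc or fclass:
            annotations[row.ortholog_group_id] = (desc, fclass)
    full_roster = list(roster) if roster is not None else sorted({g for m in groups.values() for g in m})
    return OrthologTable(groups, full_roster, annotations)


def write_ortholog_table(table: OrthologTable, path: str | Path) -> Path:
    rows = []
    for gid in sorted(table.groups):
        desc, fclass = table.annotations.get(gid, ("", ""))
        for genome_id in table.roster:
            for gene_id in table.groups[gid].get(genome_id, []):
                rows.append({"ortholog_group_id": gid, "genome_id": genome_id,
                             "gene_id": gene_id, "description": desc, "function_class": fclass})
    df = pd.DataFrame(rows, columns=["ortholog_group_id", "genome_id", "gene_id",
                                     "description", "function_class"])
    return write_tsv(df, path)


@dataclass
class CoreGeneModel:
    """One essential-gene ortholog model with screening metadata."""

    model_id: str
    description: str = ""
    function_class: str = ""
    count_median: float = 0.0
    count_stdev: float = 0.0
    duplication_threshold: float = 0.0
    ubiquity: float = 0.0
    single_copy_freq: float = 0.0
    dnds_median: float | None = None
    hmm_path: Path | None = None
    bitscore_cutoff: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ubiquity <= 1.0):
            raise ValueError(f"model {self.model_id}: ubiquity {self.ubiquity} outside [0, 1]")
        if not (0.0 <= self.single_copy_freq <= 1.0):
            raise ValueError(f"model {self.model_id}: single_copy_freq outside [0, 1]")
        if self.count_stdev < 0:
            raise ValueError(f"model {self.model_id}: negative stdev")


@dataclass
class ReferenceSet:
    """A named collection of core-gene models for one taxon group."""

    name: str
    models: list[CoreGeneModel]
    n_reference_genomes: int
    mode_filter: frozenset[str] = DEFAULT_EXCLUDED_CLASSES

    def __post_init__(self) -> None:
        if self.n_reference_genomes < 1:
            raise ValueError("reference set needs at least one genome")
        ids = [m.model_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate model_ids in reference set")

    def model(self, model_id: str) -> CoreGeneModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


# ---------------------------------------------------------------------------
# per-model statistics
# ---------------------------------------------------------------------------

def count_stats(counts: Sequence[int], k: float = 1.0) -> tuple[float, float, float]:
    """Median, population standard deviation and duplication threshold
    (median + k·stdev) of per-genome ortholog copy numbers.

    Zeros (absences) are included — the spread over the whole reference
    collection, not just carriers, sets the threshold.
    """
    if len(counts) == 0:
        raise ValueError("model has no reference observations")
    arr = np.asarray(counts, dtype=float)
    med = float(np.median(arr))
    stdev = float(arr.std(ddof=0))
    return med, stdev, med + k * stdev


def ubiquity(counts_per_genome: Sequence[int]) -> float:
    """Fraction of reference genomes carrying at least one copy."""
    if len(counts_per_genome) == 0:
        raise ValueError("empty count vector")
    return sum(1 for c in counts_per_genome if c >= 1) / len(counts_per_genome)


def single_copy_freq(counts_per_genome: Sequence[int]) -> float:
    """Fraction of reference genomes carrying exactly one copy."""
    if len(counts_per_genome) == 0:
        raise ValueError("empty count vector")
    return sum(1 for c in counts_per_genome if c == 1) / len(counts_per_genome)


def classify_and_filter(models: Iterable[CoreGeneModel], mode: str = "default",
                        excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
                        ) -> list[CoreGeneModel]:
    """Apply the search-mode functional filter.

    ``exploration`` keeps every model; ``default`` drops models whose COG
    class intersects the excluded set (regulatory, transport and
    biosynthesis-associated functions, which are unlikely resistance
    targets).  Unknown class letters are retained with a warning.
    """
    models = list(models)
    if mode == "exploration":
        return models
    if mode != "default":
        raise ValueError(f"unknown mode {mode!r}")
    kept = []
    for m in models:
        classes = set(m.function_class)
        unknown = classes - COG_CATEGORIES
        if unknown:
            logger.warning("model %s: unknown function class %s, retained",
                           m.model_id, "".join(sorted(unknown)))
        if classes & excluded_classes:
            continue
        kept.append(m)
    return kept


def _model_dnds_median(cds_list: list[str]) -> float | None:
    """Median pairwise omega over member CDS, codon-aligning unequal lengths."""
    from itertools import combinations
    from statistics import median

    omegas = []
    for a, b in combinations(cds_list, 2):
        if len(a) != len(b):
            a, b = codon_align(a, b)
        r = pairwise_dnds(a, b)
        if r.status == "ok":
            omegas.append(r.omega)
    return float(median(omegas)) if omegas else None


def build_refset(genomes: Sequence[GenomeRecord], orthologs: OrthologTable,
                 name: str, mode_filter: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
                 duplication_k: float = 1.0,
                 hmms: Mapping[str, Path] | None = None,
                 bitscore_floor: float = 25.0) -> ReferenceSet:
    """Build a ReferenceSet with all per-model statistics populated.

    ``hmms`` maps model_id to a profile file; models without a profile get
    ``hmm_path=None`` and cannot be searched until one is attached.
    The dN/dS median is computed when member genes carry coding sequences.
    """
    by_id = {g.genome_id: g for g in genomes}
    missing = [g for g in orthologs.roster if g not in by_id]
    if missing:
        raise ValueError(f"genomes in ortholog table but not supplied: {missing}")
    gene_index = {(g.genome_id, gene.gene_id): gene for g in genomes for gene in g.genes}
    models = []
    for gid in sorted(orthologs.groups):
        counts = orthologs.counts(gid)
        med, stdev, threshold = count_stats(counts, k=duplication_k)
        cds_list = [f.cds_seq for genome_id, gene_id in orthologs.members(gid)
                    if (f := gene_index.get((genome_id, gene_id))) is not None and f.cds_seq]
        dnds_med = _model_dnds_median(cds_list) if len(cds_list) >= 2 else None
        desc, fclass = orthologs.annotations.get(gid, ("", ""))
        hmm_path = Path(hmms[gid]) if hmms and gid in hmms else None
        cutoff = _profile_cutoff(hmm_path, bitscore_floor) if hmm_path else bitscore_floor
        models.append(CoreGeneModel(
            model_id=gid, description=desc, function_class=fclass,
            count_median=med, count_stdev=stdev, duplication_threshold=threshold,
            ubiquity=ubiquity(counts), single_copy_freq=single_copy_freq(counts),
            dnds_median=dnds_med, hmm_path=hmm_path, bitscore_cutoff=cutoff))
    return ReferenceSet(name=name, models=models,
                        n_reference_genomes=len(orthologs.roster), mode_filter=mode_filter)


def _profile_cutoff(hmm_path: Path, floor: float) -> float:
    """Per-model bitscore cutoff: the profile's trusted cutoff when present,
    otherwise the configured floor."""
    import pyhmmer

    with pyhmmer.plan7.HMMFile(str(hmm_path)) as fh:
        hmm = fh.read()
    trusted = hmm.cutoffs.trusted
    if trusted is not None:
        return float(trusted[0])
    return floor


# ---------------------------------------------------------------------------
# bundle serialization: <dir>/models.tsv, <dir>/hmms/<model>.hmm, manifest.json
# ---------------------------------------------------------------------------

def save_refset(refset: ReferenceSet, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "hmms").mkdir(parents=True, exist_ok=True)
    rows = []
    for m in sorted(refset.models, key=lambda m: m.model_id):
        hmm_file = ""
        if m.hmm_path is not None:
            hmm_file = f"hmms/{m.model_id}.hmm"
            dest = outdir / hmm_file
            if Path(m.hmm_path).resolve() != dest.resolve():
                dest.write_bytes(Path(m.hmm_path).read_bytes())
        rows.append({
            "model_id": m.model_id, "description": m.description,
            "function_class": m.function_class, "count_median": m.count_median,
            "count_stdev": m.count_stdev, "duplication_threshold": m.duplication_threshold,
            "ubiquity": m.ubiquity, "single_copy_freq": m.single_copy_freq,
            "dnds_median": "NA" if m.dnds_median is None else m.dnds_median,
            "bitscore_cutoff": m.bitscore_cutoff, "hmm_file": hmm_file,
        })
    df = pd.DataFrame(rows, columns=MODELS_TSV_COLUMNS)
    write_tsv(df, outdir / "models.tsv")
    manifest = {
        "name": refset.name,
        "n_reference_genomes": refset.n_reference_genomes,
        "excluded_classes_default_mode": sorted(refset.mode_filter),
        "n_models": len(refset.models),
        "models_sha256": hashlib.sha256((outdir / "models.tsv").read_bytes()).hexdigest(),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def load_refset(path: str | Path) -> ReferenceSet:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    df = read_tsv(path / "models.tsv")
    models = []
    for row in df.itertuples(index=False):
        hmm_path = path / row.hmm_file if row.hmm_file else None
        dnds = None if (isinstance(row.dnds_median, float) and np.isnan(row.dnds_median)) else float(row.dnds_median)
        models.append(CoreGeneModel(
            model_id=str(row.model_id), description=str(row.description or ""),
            function_class=str(row.function_class or ""),
            count_median=float(row.count_median), count_stdev=float(row.count_stdev),
            duplication_threshold=float(row.duplication_threshold),
            ubiquity=float(row.ubiquity), single_copy_freq=float(row.single_copy_freq),
            dnds_median=dnds, hmm_path=hmm_path, bitscore_cutoff=float(row.bitscore_cutoff)))
    return ReferenceSet(name=manifest["name"], models=models,
                        n_reference_genomes=int(manifest["n_reference_genomes"]),
                        mode_filter=frozenset(manifest["excluded_classes_default_mode"]))
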