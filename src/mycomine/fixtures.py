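"""Deterministic synthetic genomes with planted core-gene families.

The generator emulates the screening problem end to end at desk scale:
a small collection of reference genomes sharing single-copy ortholog
families (from which profile HMMs and duplication thresholds are built),
plus query genomes with planted duplications, BGC regions, resistance genes
and DUF genes, together with a truth ledger naming exactly what was planted.

Family members derive from a random ancestor coding sequence by uniform
per-codon substitution at a configurable rate; proteins are single-exon and
free of internal stops.  The composition is not biologically realistic (no
introns, no codon bias, uniform intergenic sequence) — it exercises the
machinery, not fungal genome structure.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from Bio.Seq import Seq

from .formats import (BgcRegion, GeneFeature, GenomeRecord, bgcs_to_table,
                      genes_to_table, write_genome_genbank, write_tsv)
from .refset import OrthologTable

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted({a + b + c for a in _BASES for b in _BASES for c in _BASES} - _STOPS)

#: COG letters never filtered by default mode; used for round-robin class
#: assignment unless the spec pins classes explicitly.
_SAFE_CLASSES = ["J", "O", "C", "E", "F", "G", "H", "I", "D", "A"]


@dataclass(frozen=True)
class PlantedEvent:
    """One planted duplication: extra copies of a core-gene family in a query
    genome, optionally placed inside a BGC."""

    model_id: str
    genome_id: str
    extra_copies: int = 1
    inside_bgc: bool = True


@dataclass
class FixtureSpec:
    seed: int = 0
    n_ref_genomes: int = 5
    n_models: int = 10
    n_query_genomes: int = 1
    genome_length: int = 120_000
    n_bgcs: int = 3
    planted_events: list[PlantedEvent] = field(default_factory=list)
    codon_mutation_rate: float = 0.05
    protein_length: int = 120          # codons, incl. start
    fillers_per_bgc: int = 3
    n_intergenic_fillers: int = 6
    plant_resistance: bool = False
    n_duf_genes: int = 0
    function_classes: list[str] | None = None
    #: (model_id, genome_id) pairs whose baseline copy is left out of that
    #: query genome, to emulate lineage-specific gene loss.
    omitted_models: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.codon_mutation_rate <= 1.0):
            raise ValueError("codon_mutation_rate must lie in [0, 1]")
        self.omitted_models = [tuple(t) for t in self.omitted_models]
        models = {f"og{i + 1:04d}" for i in range(self.n_models)}
        genomes = {f"qry{i + 1:02d}" for i in range(self.n_query_genomes)}
        for ev in self.planted_events:
            if ev.model_id not in models:
                raise ValueError(f"planted event references unknown model {ev.model_id}")
            if ev.genome_id not in genomes:
                raise ValueError(f"planted event references unknown genome {ev.genome_id}")
        for m, g in self.omitted_models:
            if m not in models or g not in genomes:
                raise ValueError(f"omitted model ({m}, {g}) not declared")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        data = yaml.safe_load(Path(path).read_text())
        events = [PlantedEvent(**e) for e in data.pop("planted_events", [])]
        return cls(planted_events=events, **data)


@dataclass
class FixtureCollection:
    spec: FixtureSpec
    ref_genomes: list[GenomeRecord]
    ref_seqs: dict[str, dict[str, str]]          # genome_id -> contig_id -> seq
    query_genomes: list[GenomeRecord]
    query_seqs: dict[str, dict[str, str]]
    ortholog_table: OrthologTable
    hmms: dict[str, object]                      # model_id -> pyhmmer plan7.HMM
    resistance_hmms: dict[str, object] = field(default_factory=dict)
    duf_hmms: dict[str, object] = field(default_factory=dict)
    truth: list[PlantedEvent] = field(default_factory=list)

    def model_ids(self) -> list[str]:
        return sorted(self.hmms)


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)]
    return "".join(codons)


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    out = []
    for codon in codons:
        if rng.random() < rate:
            for _ in range(20):  # resample substitutions that would create a stop
                pos = int(rng.integers(0, 3))
                base = _BASES[int(rng.integers(0, 4))]
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1:]
                if mutant not in _STOPS:
                    codon = mutant
                    break
        out.append(codon)
    return "".join(out)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _build_hmm(name: str, proteins: list[str]):
    """Profile HMM from an ungapped family alignment (equal-length members)."""
    from pyhmmer import easel, plan7

    alphabet = easel.Alphabet.amino()
    seqs = [easel.TextSequence(name=f"m{i}".encode(), sequence=p)
            for i, p in enumerate(proteins)]
    msa = easel.TextMSA(name=name.encode(), sequences=seqs).digitize(alphabet)
    builder = plan7.Builder(alphabet)
    hmm, _, _ = builder.build_msa(msa, plan7.Background(alphabet))
    import datetime
    hmm.creation_time = datetime.datetime(2000, 1, 1)  # byte-stable profile files
    return hmm


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _assemble_genome(rng: np.random.Generator, genome_id: str,
                     outside_genes: list[tuple[str, str]],
                     bgc_blocks: list[list[tuple[str, str]]],
                     genome_length: int,
                     bgc_products: list[str]) -> tuple[GenomeRecord, dict[str, str]]:
    """Lay genes on one contig: outside chunks interleaved with BGC blocks.

    Each entry is (gene_id, cds).  Returns the record plus contig sequences.
    """
    contig_id = f"{genome_id}_c1"
    n_chunks = len(bgc_blocks) + 1
    order = list(rng.permutation(len(outside_genes)))
    chunks: list[list[tuple[str, str]]] = [[] for _ in range(n_chunks)]
    for i, idx in enumerate(order):
        chunks[i % n_chunks].append(outside_genes[idx])

    parts: list[str] = []
    cursor = 0
    genes: list[GeneFeature] = []
    bgcs: list[BgcRegion] = []

    def _place(gene_id: str, cds: str) -> None:
        nonlocal cursor
        spacer = int(rng.integers(60, 151))
        parts.append(_random_dna(rng, spacer))
        cursor += spacer
        strand = "+" if rng.random() < 0.5 else "-"
        seq = cds if strand == "+" else str(Seq(cds).reverse_complement())
        start, end = cursor, cursor + len(cds)
        parts.append(seq)
        cursor = end
        genes.append(GeneFeature(gene_id, contig_id, start, end, strand,
                                 _translate(cds), cds))

    for block_idx in range(n_chunks):
        for gene_id, cds in chunks[block_idx]:
            _place(gene_id, cds)
        if block_idx < len(bgc_blocks):
            first = len(genes)
            for gene_id, cds in bgc_blocks[block_idx]:
                _place(gene_id, cds)
            block_genes = genes[first:]
            if block_genes:
                start = max(0, block_genes[0].start - 15)
                end = block_genes[-1].end + 15
                bgcs.append(BgcRegion(f"{genome_id}_bgc{block_idx + 1}", contig_id,
                                      start, end, bgc_products[block_idx],
                                      "coordinate_table"))
    if cursor > genome_length:
        raise ValueError(f"infeasible packing: genes need {cursor} bp, "
                         f"genome_length is {genome_length}")
    parts.append(_random_dna(rng, genome_length - cursor))
    record = GenomeRecord(genome_id=genome_id, genes=genes, bgcs=bgcs,
                          contigs={contig_id: genome_length})
    record.validate()
    return record, {contig_id: "".join(parts)}


_PRODUCT_CLASSES = ["NRPS", "terpene", "T1PKS", "indole", "NRPS-like", "fungal-RiPP"]


def generate_collection(spec: FixtureSpec) -> FixtureCollection:
    """Generate the full synthetic study: reference genomes, ortholog table,
    profile HMMs, query genomes with planted events, and the truth ledger.

    Deterministic: the same spec (including seed) yields identical sequences,
    coordinates and profiles.
    """
    rng = np.random.default_rng(spec.seed)
    model_ids = [f"og{i + 1:04d}" for i in range(spec.n_models)]
    classes = spec.function_classes or [_SAFE_CLASSES[i % len(_SAFE_CLASSES)]
                                        for i in range(spec.n_models)]
    if len(classes) != spec.n_models:
        raise ValueError("function_classes must have one entry per model")
    ancestors = {m: _random_cds(rng, spec.protein_length) for m in model_ids}

    # reference genomes: one copy of every family, no BGCs
    ref_ids = [f"ref{i + 1:02d}" for i in range(spec.n_ref_genomes)]
    ref_members: dict[str, dict[str, list[str]]] = {m: {} for m in model_ids}
    ref_genomes, ref_seqs = [], {}
    family_proteins: dict[str, list[str]] = {m: [] for m in model_ids}
    for gid in ref_ids:
        outside = []
        for m in model_ids:
            cds = _mutate_cds(rng, ancestors[m], spec.codon_mutation_rate)
            gene_id = f"{gid}_{m}"
            outside.append((gene_id, cds))
            ref_members[m][gid] = [gene_id]
            family_proteins[m].append(_translate(cds))
        genome, seqs = _assemble_genome(rng, gid, outside, [], spec.genome_length, [])
        ref_genomes.append(genome)
        ref_seqs[gid] = seqs

    annotations = {m: (f"synthetic essential gene family {m}", classes[i])
                   for i, m in enumerate(model_ids)}
    table = OrthologTable(ref_members, ref_ids, annotations)
    hmms = {m: _build_hmm(m, family_proteins[m]) for m in model_ids}

    # optional auxiliary families
    resistance_hmms: dict[str, object] = {}
    res_ancestor = None
    if spec.plant_resistance:
        res_ancestor = _random_cds(rng, spec.protein_length)
        res_family = [_translate(_mutate_cds(rng, res_ancestor, spec.codon_mutation_rate))
                      for _ in range(4)]
        resistance_hmms["resfam0001"] = _build_hmm("resfam0001", res_family)
    duf_hmms: dict[str, object] = {}
    duf_ancestor = None
    if spec.n_duf_genes > 0:
        duf_ancestor = _random_cds(rng, spec.protein_length)
        duf_family = [_translate(_mutate_cds(rng, duf_ancestor, spec.codon_mutation_rate))
                      for _ in range(4)]
        duf_hmms["duffam0001"] = _build_hmm("duffam0001", duf_family)

    # query genomes with planted events
    query_ids = [f"qry{i + 1:02d}" for i in range(spec.n_query_genomes)]
    query_genomes, query_seqs = [], {}
    for qid in query_ids:
        events = [e for e in spec.planted_events if e.genome_id == qid]
        outside: list[tuple[str, str]] = []
        counters: dict[str, int] = {}

        def _gene(qid: str, m: str, cds: str) -> tuple[str, str]:
            counters[m] = counters.get(m, 0) + 1
            return (f"{qid}_{m}_{counters[m]}", cds)

        for m in model_ids:
            cds = _mutate_cds(rng, ancestors[m], spec.codon_mutation_rate)
            if (m, qid) in spec.omitted_models:
                continue  # draw consumed either way, so omission doesn't shift the stream
            outside.append(_gene(qid, m, cds))
        for _ in range(spec.n_intergenic_fillers):
            counters["fill"] = counters.get("fill", 0) + 1
            outside.append((f"{qid}_fill_{counters['fill']}", _random_cds(rng, spec.protein_length)))
        for i in range(spec.n_duf_genes):
            outside.append(_gene(qid, "duf", _mutate_cds(rng, duf_ancestor, spec.codon_mutation_rate)))

        bgc_blocks: list[list[tuple[str, str]]] = [[] for _ in range(spec.n_bgcs)]
        for b in range(spec.n_bgcs):
            for _ in range(spec.fillers_per_bgc):
                counters["fill"] = counters.get("fill", 0) + 1
                bgc_blocks[b].append((f"{qid}_fill_{counters['fill']}",
                                      _random_cds(rng, spec.protein_length)))
        next_bgc = 0
        for ev in events:
            for _ in range(ev.extra_copies):
                entry = _gene(qid, ev.model_id,
                              _mutate_cds(rng, ancestors[ev.model_id], spec.codon_mutation_rate))
                if ev.inside_bgc:
                    if spec.n_bgcs == 0:
                        raise ValueError("inside_bgc event but n_bgcs == 0")
                    bgc_blocks[next_bgc % spec.n_bgcs].append(entry)
                    next_bgc += 1
                else:
                    outside.append(entry)
        if spec.plant_resistance and spec.n_bgcs > 0:
            bgc_blocks[0].append((f"{qid}_res_1",
                                  _mutate_cds(rng, res_ancestor, spec.codon_mutation_rate)))

        products = [_PRODUCT_CLASSES[i % len(_PRODUCT_CLASSES)] for i in range(spec.n_bgcs)]
        genome, seqs = _assemble_genome(rng, qid, outside, bgc_blocks,
                                        spec.genome_length, products)
        query_genomes.append(genome)
        query_seqs[qid] = seqs

    return FixtureCollection(spec=spec, ref_genomes=ref_genomes, ref_seqs=ref_seqs,
                             query_genomes=query_genomes, query_seqs=query_seqs,
                             ortholog_table=table, hmms=hmms,
                             resistance_hmms=resistance_hmms, duf_hmms=duf_hmms,
                             truth=list(spec.planted_events))


def screen_collection(coll: FixtureCollection, workdir: str | Path,
                      mode: str = "default", engine=None):
    """Run the whole pipeline on a generated collection: build the reference
    set from the synthetic references, then detect and screen every query
    genome.  Returns (ReferenceSet, {genome_id: ScreeningResult}).
    """
    from .detect import detect_auxiliary, detect_core_genes
    from .refset import build_refset
    from .screening import screen_genome

    workdir = Path(workdir)
    hmm_paths = write_hmms(coll.hmms, workdir / "hmms")
    refset = build_refset(coll.ref_genomes, coll.ortholog_table,
                          name=f"fixture_seed{coll.spec.seed}", hmms=hmm_paths)
    res_paths = write_hmms(coll.resistance_hmms, workdir / "hmms_resistance") \
        if coll.resistance_hmms else {}
    duf_paths = write_hmms(coll.duf_hmms, workdir / "hmms_duf") if coll.duf_hmms else {}
    results = {}
    for genome in coll.query_genomes:
        core = detect_core_genes(genome, refset, mode, engine=engine)
        aux = detect_auxiliary(genome, res_paths, duf_paths, engine=engine)
        results[genome.genome_id] = screen_genome(genome, refset, core, aux)
    return refset, results


def truth_flag_map(coll: FixtureCollection) -> dict[tuple[str, str], dict[str, bool]]:
    """Expected (D, B) flags per (query genome, model) implied by the ledger.

    With all-single-copy references the duplication threshold is exactly 1,
    so any planted extra copy must flag D; B is expected iff at least one
    extra copy was placed inside a BGC.  Unmentioned (genome, model) pairs
    must stay all-false.
    """
    expected: dict[tuple[str, str], dict[str, bool]] = {}
    for g in coll.query_genomes:
        for m in coll.model_ids():
            expected[(g.genome_id, m)] = {"D": False, "B": False}
    for ev in coll.truth:
        e = expected[(ev.genome_id, ev.model_id)]
        e["D"] = e["D"] or ev.extra_copies >= 1
        e["B"] = e["B"] or (ev.inside_bgc and ev.extra_copies >= 1)
    return expected


# ---------------------------------------------------------------------------
# on-disk form: the same formats the pipeline reads
# ---------------------------------------------------------------------------

def write_hmms(hmms: Mapping[str, object], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for model_id in sorted(hmms):
        p = outdir / f"{model_id}.hmm"
        with open(p, "wb") as fh:
            hmms[model_id].write(fh, binary=False)
        paths[model_id] = p
    return paths


def _relativize(obj, root: Path):
    if isinstance(obj, dict):
        return {k: _relativize(v, root) for k, v in obj.items()}
    if isinstance(obj, str) and obj.startswith(str(root)):
        return str(Path(obj).relative_to(root))
    return obj


def _absolutize(obj, root: Path):
    if isinstance(obj, dict):
        return {k: _absolutize(v, root) for k, v in obj.items()}
    if isinstance(obj, str):
        return str(root / obj)
    return obj


def read_layout(outdir: str | Path) -> dict:
    """Load a written collection's file index with absolute paths."""
    outdir = Path(outdir)
    return _absolutize(json.loads((outdir / "layout.json").read_text()), outdir)


def write_collection(coll: FixtureCollection, outdir: str | Path) -> dict:
    """Write the collection as GenBank/FASTA/TSV/HMM files; returns a layout
    dict with absolute paths.  ``layout.json`` stores paths relative to the
    output directory so identical seeds give byte-identical trees anywhere."""
    from .refset import write_ortholog_table

    outdir = Path(outdir)
    layout: dict = {"refs": {}, "queries": {}, "hmms": {}, "resistance_hmms": {},
                    "duf_hmms": {}}
    refs_dir = outdir / "refs"
    refs_dir.mkdir(parents=True, exist_ok=True)
    for genome in coll.ref_genomes:
        p = refs_dir / f"{genome.genome_id}.gbk"
        write_genome_genbank(genome, coll.ref_seqs[genome.genome_id], p)
        layout["refs"][genome.genome_id] = str(p)
    write_ortholog_table(coll.ortholog_table, refs_dir / "orthologs.tsv")
    layout["orthologs"] = str(refs_dir / "orthologs.tsv")

    layout["hmms"] = {k: str(v) for k, v in write_hmms(coll.hmms, outdir / "hmms").items()}
    if coll.resistance_hmms:
        layout["resistance_hmms"] = {k: str(v) for k, v in
                                     write_hmms(coll.resistance_hmms, outdir / "hmms_resistance").items()}
    if coll.duf_hmms:
        layout["duf_hmms"] = {k: str(v) for k, v in
                              write_hmms(coll.duf_hmms, outdir / "hmms_duf").items()}

    q_dir = outdir / "queries"
    q_dir.mkdir(parents=True, exist_ok=True)
    for genome in coll.query_genomes:
        gid = genome.genome_id
        gbk = q_dir / f"{gid}.gbk"
        write_genome_genbank(genome, coll.query_seqs[gid], gbk, include_regions=True)
        fasta = q_dir / f"{gid}.fasta"
        with open(fasta, "w") as fh:
            for contig_id, seq in coll.query_seqs[gid].items():
                fh.write(f">{contig_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        write_tsv(genes_to_table(genome.genes), q_dir / f"{gid}.genes.tsv")
        write_tsv(bgcs_to_table(genome.bgcs), q_dir / f"{gid}.bgcs.tsv")
        layout["queries"][gid] = {"genbank": str(gbk), "fasta": str(fasta),
                                  "genes": str(q_dir / f"{gid}.genes.tsv"),
                                  "bgcs": str(q_dir / f"{gid}.bgcs.tsv")}
    (outdir / "truth.json").write_text(json.dumps([asdict(e) for e in coll.truth], indent=2) + "\n")
    layout["truth"] = str(outdir / "truth.json")
    (outdir / "layout.json").write_text(
        json.dumps(_relativize(layout, outdir), indent=2) + "\n")
    return layout
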