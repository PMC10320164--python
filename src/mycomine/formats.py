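"""Genome and BGC annotation I/O.

All coordinates inside the package are 0-based half-open ``[start, end)``;
the 1-based inclusive convention of GenBank/EMBL flat files is converted at
the format boundary and nowhere else.  Multi-exon (joined) CDS locations are
flattened to their outer envelope for interval arithmetic, while the coding
sequence itself is spliced across exons.
"""
from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "protein_seq", "cds_seq"]
BGC_TABLE_COLUMNS = ["cluster_id", "contig_id", "start", "end", "product_class"]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into domain objects."""


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded coding gene.

    ``start``/``end`` are 0-based half-open on the contig; ``protein_seq``
    and ``cds_seq`` are optional because some inputs carry only coordinates.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str | None = None
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.cds_seq is not None and len(self.cds_seq) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: CDS length {len(self.cds_seq)} not divisible by 3")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class BgcRegion:
    """One biosynthetic gene cluster region (consumed, never predicted here)."""

    cluster_id: str
    contig_id: str
    start: int
    end: int
    product_class: str = ""
    source: str = "coordinate_table"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"BGC {self.cluster_id}: invalid interval [{self.start}, {self.end})")


@dataclass
class GenomeRecord:
    """A query or reference genome: contigs, genes and (optionally) BGCs."""

    genome_id: str
    genes: list[GeneFeature] = field(default_factory=list)
    bgcs: list[BgcRegion] = field(default_factory=list)
    contigs: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id} in genome {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig_id}")
            if g.end > self.contigs[g.contig_id]:
                raise ValueError(f"gene {g.gene_id} extends past contig end")
        cids = set()
        for b in self.bgcs:
            if b.cluster_id in cids:
                raise ValueError(f"duplicate cluster_id {b.cluster_id}")
            cids.add(b.cluster_id)
            if b.contig_id not in self.contigs:
                raise ValueError(f"BGC {b.cluster_id} on unknown contig {b.contig_id}")

    @property
    def proteins(self) -> dict[str, str]:
        """gene_id -> amino-acid sequence for genes that carry a translation."""
        return {g.gene_id: g.protein_seq for g in self.genes if g.protein_seq}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _feature_gene_id(feat, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"cds_{index:05d}"


def _extract_cds_features(record: SeqRecord) -> list[GeneFeature]:
    genes: list[GeneFeature] = []
    try:
        has_seq = len(record.seq) > 0 and bool(str(record.seq))
    except Exception:  # undefined sequence content (e.g. header-only records)
        has_seq = False
    for i, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        loc = feat.location
        if loc is None:
            continue
        start, end = int(loc.start), int(loc.end)  # Biopython already half-open
        strand = "-" if loc.strand == -1 else "+"
        gene_id = _feature_gene_id(feat, i)
        protein = feat.qualifiers.get("translation", [None])[0]
        cds = None
        if has_seq:
            try:
                spliced = str(feat.extract(record.seq))
                if len(spliced) % 3 == 0:
                    cds = spliced.upper()
            except Exception:  # pragma: no cover - malformed location
                cds = None
        if protein is None and cds is not None:
            aa = str(Seq(cds).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            if "*" in aa:
                logger.warning("gene %s: internal stop in translation, feature skipped", gene_id)
                continue
            protein = aa
        if protein is None and cds is None:
            logger.warning("gene %s: no translation available, feature skipped", gene_id)
            continue
        genes.append(GeneFeature(gene_id, record.id, start, end, strand, protein, cds))
    return genes


def read_genome(path: str | Path, format: str = "genbank", gene_table: str | Path | None = None,
                genome_id: str | None = None) -> GenomeRecord:
    """Read a genome from GenBank, EMBL, or FASTA plus a gene-coordinate table.

    Parameters
    ----------
    path
        Flat file with one or more contigs.
    format
        ``genbank``, ``embl``, or ``fasta``.  FASTA carries no annotation, so
        ``gene_table`` (TSV with 0-based half-open coordinates) is required.
    gene_table
        Sidecar TSV with columns ``gene_id contig_id start end strand
        protein_seq [cds_seq]``; only used for ``fasta``.
    genome_id
        Identifier for the record; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gid = genome_id or path.stem
    if format in ("genbank", "embl"):
        try:
            records = list(SeqIO.parse(str(path), format))
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
        if not records:
            raise FormatError(f"{path}: no records found (is this really {format}?)")
        genome = GenomeRecord(genome_id=gid)
        for rec in records:
            genome.contigs[rec.id] = len(rec.seq)
            genome.genes.extend(_extract_cds_features(rec))
        genome.validate()
        return genome
    if format == "fasta":
        if gene_table is None:
            raise ValueError("FASTA input requires a sidecar gene-coordinate table")
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise FormatError(f"{path}: no FASTA records")
        genome = GenomeRecord(genome_id=gid, contigs={k: len(v) for k, v in contigs.items()})
        genome.genes = list(_read_gene_table(gene_table, contigs))
        genome.validate()
        return genome
    raise ValueError(f"unknown genome format {format!r}")


def _read_gene_table(path: str | Path, contigs: Mapping[str, str]) -> Iterable[GeneFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "contig_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene table {path}: missing columns {sorted(missing)}")
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        protein = getattr(row, "protein_seq", "") or None
        cds = getattr(row, "cds_seq", "") or None
        if cds is None and row.contig_id in contigs:
            raw = contigs[row.contig_id][start:end]
            if row.strand == "-":
                raw = str(Seq(raw).reverse_complement())
            if len(raw) % 3 == 0:
                cds = raw
        if protein is None and cds is not None:
            aa = str(Seq(cds).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            if "*" in aa:
                logger.warning("gene table row %d (%s): internal stop, skipped", row_no, row.gene_id)
                continue
            protein = aa
        yield GeneFeature(row.gene_id, row.contig_id, start, end, row.strand, protein, cds)


_REGION_FEATURE_TYPES = ("region", "cluster", "protocluster")


def read_bgc_regions(path: str | Path, dialect: str = "antismash_region_gbk",
                     feature_type: str = "region") -> list[BgcRegion]:
    """Read BGC intervals from an antiSMASH-style region GenBank or a TSV table.

    ``feature_type`` selects between ``region`` (antiSMASH outer boundaries,
    the default) and ``cluster``/``protocluster`` sub-features when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regions: list[BgcRegion] = []
    if dialect == "antismash_region_gbk":
        wanted = {feature_type} if feature_type in _REGION_FEATURE_TYPES else {"region"}
        n = 0
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type not in wanted:
                    continue
                n += 1
                quals = feat.qualifiers
                cid = str(quals.get("region_number", quals.get("cluster_number", [n]))[0])
                cid = f"region_{cid}" if not cid.startswith(("region", "cluster", "bgc")) else cid
                product = ";".join(quals.get("product", []))
                regions.append(BgcRegion(cid, rec.id, int(feat.location.start),
                                         int(feat.location.end), product, "antismash_region"))
    elif dialect == "tsv_table":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row_no, row in enumerate(reader, start=1):
                if not row or row[0].startswith("#") or row[0] == "cluster_id":
                    continue
                if len(row) < 4:
                    raise FormatError(f"{path} row {row_no}: expected ≥4 columns, got {len(row)}")
                cid, contig, start, end = row[0], row[1], int(row[2]), int(row[3])
                product = row[4] if len(row) > 4 else ""
                if end <= start:
                    raise FormatError(f"{path} row {row_no}: end ({end}) ≤ start ({start})")
                regions.append(BgcRegion(cid, contig, start, end, product, "coordinate_table"))
    else:
        raise ValueError(f"unknown BGC dialect {dialect!r}")
    regions.sort(key=lambda r: (r.contig_id, r.start, r.cluster_id))
    return regions


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def sanitize_field(value: object) -> object:
    """Replace tab/newline inside free text so TSV cells stay one cell."""
    if isinstance(value, str) and any(c in value for c in "\t\n\r"):
        logger.warning("tab/newline inside field sanitized to space: %.40r", value)
        return " ".join(value.replace("\t", " ").split("\n"))
    return value


def write_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 TSV with a header row, deterministically.

    String cells containing a tab or newline are sanitized to spaces so the
    file stays strictly one-row-per-record.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].map(sanitize_field)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])


def write_genome_genbank(genome: GenomeRecord, contig_seqs: Mapping[str, str],
                         path: str | Path, include_regions: bool = True) -> Path:
    """Serialize a GenomeRecord (with contig sequences) to GenBank.

    Used by the synthetic-genome generator and the round-trip tests; BGCs are
    emitted as antiSMASH-style ``region`` features when ``include_regions``.
    """
    path = Path(path)
    records = []
    bgc_by_contig: dict[str, list[BgcRegion]] = {}
    for b in genome.bgcs:
        bgc_by_contig.setdefault(b.contig_id, []).append(b)
    for contig_id, seq in contig_seqs.items():
        rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16],
                        description=f"{genome.genome_id} synthetic contig",
                        annotations={"molecule_type": "DNA"})
        if include_regions:
            for i, b in enumerate(sorted(bgc_by_contig.get(contig_id, []),
                                         key=lambda r: r.start), start=1):
                feat = SeqFeature(SimpleLocation(b.start, b.end, strand=1), type="region")
                feat.qualifiers["region_number"] = [str(i)]
                feat.qualifiers["product"] = [b.product_class] if b.product_class else []
                rec.features.append(feat)
        for g in sorted(genome.genes, key=lambda g: g.start):
            if g.contig_id != contig_id:
                continue
            strand = -1 if g.strand == "-" else 1
            feat = SeqFeature(SimpleLocation(g.start, g.end, strand=strand), type="CDS")
            feat.qualifiers["locus_tag"] = [g.gene_id]
            if g.protein_seq:
                feat.qualifiers["translation"] = [g.protein_seq]
            rec.features.append(feat)
        records.append(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # BiopythonWarning on long locus names
        SeqIO.write(records, str(path), "genbank")
    return path


def genes_to_table(genes: Sequence[GeneFeature]) -> pd.DataFrame:
    rows = [{"gene_id": g.gene_id, "contig_id": g.contig_id, "start": g.start,
             "end": g.end, "strand": g.strand, "protein_seq": g.protein_seq or "",
             "cds_seq": g.cds_seq or ""} for g in genes]
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def bgcs_to_table(bgcs: Sequence[BgcRegion]) -> pd.DataFrame:
    rows = [{"cluster_id": b.cluster_id, "contig_id": b.contig_id, "start": b.start,
             "end": b.end, "product_class": b.product_class} for b in bgcs]
    return pd.DataFrame(rows, columns=BGC_TABLE_COLUMNS)
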