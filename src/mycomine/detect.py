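"""Core-gene, resistance-factor and DUF detection by profile-HMM search.

Query proteomes are scanned with HMMER3-format profiles.  The search engine
is injected behind a small interface so runs record the exact engine version
in their manifest; the default engine is pyhmmer, run single-threaded for
reproducibility.  Copy numbers are gene-level: one gene counts at most once
per model regardless of how many domains repeat within it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .formats import GenomeRecord
from .refset import ReferenceSet, classify_and_filter

logger = logging.getLogger(__name__)

CATEGORIES = ("core", "resistance", "duf", "custom")


@dataclass(frozen=True)
class HmmHit:
    """Best full-sequence hit of one profile against one gene product."""

    model_id: str
    gene_id: str
    bitscore: float
    evalue: float
    category: str = "core"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown hit category {self.category!r}")
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError("bitscore must be finite")


@dataclass
class CoreGeneHitSet:
    """All qualifying gene hits for one model, best score first."""

    model_id: str
    hits: list[HmmHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits.sort(key=lambda h: (-h.bitscore, h.gene_id))

    @property
    def copy_number(self) -> int:
        return len({h.gene_id for h in self.hits})

    @property
    def gene_ids(self) -> list[str]:
        return sorted({h.gene_id for h in self.hits})


class HmmEngine(Protocol):
    """Minimal profile-search interface so the engine is swappable."""

    @property
    def version(self) -> str: ...

    def search(self, hmm_paths: Mapping[str, Path],
               proteins: Mapping[str, str]) -> list[tuple[str, str, float, float]]:
        """Return (model_id, gene_id, bitscore, evalue) for every reported hit."""
        ...


class PyhmmerEngine:
    """Default engine: pyhmmer's reimplementation of the HMMER3 pipeline."""

    def __init__(self, cpus: int = 1):
        self.cpus = cpus

    @property
    def version(self) -> str:
        import pyhmmer
        return f"pyhmmer-{pyhmmer.__version__}"

    def search(self, hmm_paths: Mapping[str, Path],
               proteins: Mapping[str, str]) -> list[tuple[str, str, float, float]]:
        import pyhmmer
        from pyhmmer import easel, plan7

        if not proteins or not hmm_paths:
            return []
        alphabet = easel.Alphabet.amino()
        seqs = easel.DigitalSequenceBlock(alphabet, [
            easel.TextSequence(name=gene_id.encode(), sequence=aa).digitize(alphabet)
            for gene_id, aa in sorted(proteins.items())
        ])
        def _as_str(name) -> str:
            return name.decode() if isinstance(name, bytes) else str(name)

        hmms = []
        name_to_model: dict[str, str] = {}
        for model_id, path in sorted(hmm_paths.items()):
            try:
                with plan7.HMMFile(str(path)) as fh:
                    for hmm in fh:
                        hmms.append(hmm)
                        name_to_model[_as_str(hmm.name)] = model_id
            except Exception as exc:
                raise ValueError(f"malformed profile file for model {model_id}: {path}") from exc
        out = []
        for tophits in pyhmmer.hmmsearch(hmms, seqs, cpus=self.cpus):
            model_id = name_to_model[_as_str(tophits.query.name)]
            for hit in tophits:
                out.append((model_id, _as_str(hit.name), float(hit.score), float(hit.evalue)))
        return out


def search_models(proteins: Mapping[str, str], hmm_paths: Mapping[str, Path],
                  cutoffs: Mapping[str, float], category: str = "core",
                  engine: HmmEngine | None = None) -> list[HmmHit]:
    """Search a proteome with a set of profiles, keeping hits scoring at or
    above each model's bitscore cutoff (best hit per model × gene)."""
    engine = engine or PyhmmerEngine()
    raw = engine.search(hmm_paths, proteins)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for model_id, gene_id, score, evalue in raw:
        key = (model_id, gene_id)
        if key not in best or score > best[key][0]:
            best[key] = (score, evalue)
    hits = []
    for (model_id, gene_id), (score, evalue) in sorted(best.items()):
        cutoff = cutoffs.get(model_id, float("-inf"))
        if score >= cutoff:
            hits.append(HmmHit(model_id, gene_id, score, evalue, category))
    return hits


def detect_core_genes(genome: GenomeRecord, refset: ReferenceSet, mode: str = "default",
                      engine: HmmEngine | None = None,
                      excluded_classes: frozenset[str] | None = None,
                      ) -> dict[str, CoreGeneHitSet]:
    """Locate core genes in a query genome using a reference set.

    Models are passed through the mode filter before the search, so a model
    excluded by default mode is never searched nor reported.  Only models
    with at least one qualifying hit appear in the result.
    """
    excluded = excluded_classes if excluded_classes is not None else refset.mode_filter
    models = classify_and_filter(refset.models, mode, excluded)
    searchable = [m for m in models if m.hmm_path is not None]
    skipped = len(models) - len(searchable)
    if skipped:
        logger.warning("%d models lack profiles and were not searched", skipped)
    hits = search_models(genome.proteins,
                         {m.model_id: m.hmm_path for m in searchable},
                         {m.model_id: m.bitscore_cutoff for m in searchable},
                         category="core", engine=engine)
    out: dict[str, CoreGeneHitSet] = {}
    for h in hits:
        out.setdefault(h.model_id, CoreGeneHitSet(h.model_id)).hits.append(h)
    for hs in out.values():
        hs.hits.sort(key=lambda h: (-h.bitscore, h.gene_id))
    return out


def detect_auxiliary(genome: GenomeRecord,
                     resistance_models: Mapping[str, Path] | None = None,
                     duf_models: Mapping[str, Path] | None = None,
                     search_resistance: bool = True, search_duf: bool = True,
                     bitscore_floor: float = 25.0,
                     engine: HmmEngine | None = None) -> list[HmmHit]:
    """Optional screens for known resistance factors and DUF domains.

    Each category is independently togglable; a disabled category returns no
    hits.  Cutoffs come from each profile's trusted-cutoff line when present,
    else the configured floor.
    """
    from .refset import _profile_cutoff

    hits: list[HmmHit] = []
    for enabled, models, category in ((search_resistance, resistance_models, "resistance"),
                                      (search_duf, duf_models, "duf")):
        if not enabled or not models:
            continue
        cutoffs = {mid: _profile_cutoff(Path(p), bitscore_floor) for mid, p in models.items()}
        hits.extend(search_models(genome.proteins, models, cutoffs,
                                  category=category, engine=engine))
    return hits
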