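"""Pairwise dN/dS by the Nei–Gojobori counting method.

The estimator counts, per codon, the number of synonymous (S) and
nonsynonymous (N) *sites* — the expected fraction of single-nucleotide
changes that preserve the encoded amino acid — and the observed synonymous
(Sd) and nonsynonymous (Nd) *differences* between two codon-aligned coding
sequences.  Codon pairs differing at more than one position are resolved by
averaging over all shortest substitution pathways with equal weight;
pathways passing through a stop codon are excluded.  Proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3), and omega = dN/dS.

Mutational saturation (4p/3 ≥ 1) and dS = 0 make the correction or the
ratio undefined; both conditions are reported explicitly in the result
status rather than silently dropped.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from statistics import median

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def _codon_map(table_id: int = 1) -> dict[str, str]:
    table = unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_STANDARD = _codon_map(1)


@dataclass(frozen=True)
class DnDsResult:
    """Site/difference counts and corrected rates for one sequence pair."""

    n_sites: float = 0.0
    s_sites: float = 0.0
    n_diffs: float = 0.0
    s_diffs: float = 0.0
    pn: float = 0.0
    ps: float = 0.0
    dn: float | None = None
    ds: float | None = None
    omega: float | None = None
    status: str = "ok"
    n_codons: int = 0


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts (n, s) for one sense codon.

    ``s`` is the sum over the three positions of the fraction of possible
    single-base changes that are synonymous; changes creating a stop codon
    are removed from the denominator.  ``n = 3 - s`` so every codon always
    contributes exactly three sites.
    """
    codon = codon.upper()
    code = _codon_map(table_id)
    if any(b not in _BASES for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if code[mutant] == "*":
                continue  # stop targets excluded from the denominator
            possible += 1
            if code[mutant] == aa:
                syn += 1
        if possible:
            s += syn / possible
    return (3.0 - s, s)


@lru_cache(maxsize=None)
def _pathway_diffs(codon1: str, codon2: str, table_id: int = 1) -> tuple[float, float] | None:
    """Average (nonsyn, syn) substitution counts over all valid shortest
    pathways between two sense codons; None when every pathway crosses a stop.
    """
    code = _codon_map(table_id)
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return (0.0, 0.0)
    totals = []
    for order in permutations(diff_pos):
        current = codon1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if code[nxt] == "*":
                blocked = True
                break
            steps.append((code[current], code[nxt]))
            current = nxt
        if blocked:
            continue
        nd = sum(1 for a, b in steps if a != b)
        sd = len(steps) - nd
        totals.append((nd, sd))
    if not totals:
        return None
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return (nd, sd)


def jukes_cantor(p: float) -> float | None:
    """JC69 distance for a proportion of differences; None at saturation."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0.0:
        return 0.0
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0:
        return None
    return -0.75 * math.log(x)


def pairwise_dnds(cds1: str, cds2: str, table_id: int = 1) -> DnDsResult:
    """Nei–Gojobori dN/dS for two codon-aligned coding sequences.

    Sequences must be equal length, a multiple of 3.  Gap codons (containing
    ``-``), codons with ambiguity characters, and stop codons are skipped.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2) or len(cds1) % 3 != 0:
        return DnDsResult(status="length_mismatch")
    code = _codon_map(table_id)
    n_sites = s_sites = n_diffs = s_diffs = 0.0
    n_codons = 0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i:i + 3], cds2[i:i + 3]
        if "-" in c1 or "-" in c2:
            continue
        if any(b not in _BASES for b in c1 + c2):
            logger.warning("ambiguous codon pair (%s, %s) skipped", c1, c2)
            continue
        if code[c1] == "*" or code[c2] == "*":
            logger.warning("stop codon in pair (%s, %s) skipped", c1, c2)
            continue
        diffs = _pathway_diffs(c1, c2, table_id)
        if diffs is None:
            logger.warning("all pathways between %s and %s blocked by stops; codon skipped", c1, c2)
            continue
        n1, s1 = codon_site_counts(c1, table_id)
        n2, s2 = codon_site_counts(c2, table_id)
        n_sites += (n1 + n2) / 2.0
        s_sites += (s1 + s2) / 2.0
        n_diffs += diffs[0]
        s_diffs += diffs[1]
        n_codons += 1
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    if dn is None or ds is None:
        return DnDsResult(n_sites, s_sites, n_diffs, s_diffs, pn, ps, dn, ds,
                          None, "saturated", n_codons)
    if ds == 0.0:
        return DnDsResult(n_sites, s_sites, n_diffs, s_diffs, pn, ps, dn, ds,
                          None, "undefined_dS_zero", n_codons)
    return DnDsResult(n_sites, s_sites, n_diffs, s_diffs, pn, ps, dn, ds,
                      dn / ds, "ok", n_codons)


def model_dnds_median(members: list[str], table_id: int = 1) -> float | None:
    """Median omega over all unordered pairs of member coding sequences.

    Pairs whose ratio is undefined (saturation, dS = 0, length mismatch) are
    excluded; returns None when no pair yields a defined ratio.
    """
    omegas = [r.omega for a, b in combinations(members, 2)
              if (r := pairwise_dnds(a, b, table_id)).status == "ok"]
    if not omegas:
        return None
    return float(median(omegas))


def codon_align(cds1: str, cds2: str, table_id: int = 1) -> tuple[str, str]:
    """Codon-align two unaligned coding sequences via their protein sequences.

    Global Needleman–Wunsch on the translations (BLOSUM62, gap open 10,
    extend 0.5), with each protein gap expanded to a ``---`` codon gap.
    Trailing stop codons are trimmed before alignment.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.Seq import Seq

    def _trim(cds: str) -> str:
        code = _codon_map(table_id)
        if len(cds) >= 3 and code.get(cds[-3:].upper()) == "*":
            return cds[:-3]
        return cds

    cds1, cds2 = _trim(cds1.upper()), _trim(cds2.upper())
    aa1, aa2 = str(Seq(cds1).translate(table=table_id)), str(Seq(cds2).translate(table=table_id))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(aa1, aa2)[0]
    out1, out2 = [], []
    i = j = 0
    for a, b in zip(aln[0], aln[1]):
        if a == "-":
            out1.append("---")
        else:
            out1.append(cds1[3 * i:3 * i + 3])
            i += 1
        if b == "-":
            out2.append("---")
        else:
            out2.append(cds2[3 * j:3 * j + 3])
            j += 1
    return "".join(out1), "".join(out2)
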