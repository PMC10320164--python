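"""Independent brute-force oracles used to check the main implementation.

These deliberately share no code with the package: codon translation goes
through Biopython, pathway enumeration is recursive rather than
permutation-based, and interval intersection is tested position by position.
"""
from __future__ import annotations

from functools import lru_cache

from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def oracle_site_counts(codon: str) -> tuple[float, float]:
    """(n, s) for one codon: per position, the synonymous fraction of
    single-base changes not creating a stop; n defined as 3 - s."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn, denom = 0, 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            maa = translate_codon(mut)
            if maa == "*":
                continue
            denom += 1
            if maa == aa:
                syn += 1
        if denom:
            s += syn / denom
    return 3.0 - s, s


def oracle_pathways(c1: str, c2: str) -> list[tuple[int, int]]:
    """All stop-free shortest substitution pathways as (nd, sd) step counts,
    enumerated recursively."""
    results: list[tuple[int, int]] = []

    def walk(current: str, nd: int, sd: int) -> None:
        diffs = [i for i in range(3) if current[i] != c2[i]]
        if not diffs:
            results.append((nd, sd))
            return
        for pos in diffs:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if translate_codon(nxt) == "*":
                continue
            if translate_codon(current) == translate_codon(nxt):
                walk(nxt, nd, sd + 1)
            else:
                walk(nxt, nd + 1, sd)

    walk(c1, 0, 0)
    return results


@lru_cache(maxsize=None)
def oracle_codon_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    paths = oracle_pathways(c1, c2)
    if not paths:
        return None
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def oracle_pn_ps(cds1: str, cds2: str) -> tuple[float, float, float, float, float, float]:
    """(N, S, Nd, Sd, pN, pS) for two codon-aligned sequences, skipping gap,
    ambiguous, stop, and fully-blocked codon pairs."""
    N = S = Nd = Sd = 0.0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if "-" in a or "-" in b or any(ch not in BASES for ch in a + b):
            continue
        if translate_codon(a) == "*" or translate_codon(b) == "*":
            continue
        diffs = oracle_codon_diffs(a, b)
        if diffs is None:
            continue
        na, sa = oracle_site_counts(a)
        nb, sb = oracle_site_counts(b)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        Nd += diffs[0]
        Sd += diffs[1]
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    return N, S, Nd, Sd, pn, ps


def oracle_overlaps(gene_ivs: dict[str, tuple[str, int, int]],
                    bgc_ivs: dict[str, tuple[str, int, int]]) -> set[tuple[str, str]]:
    """All (gene, bgc) pairs whose half-open intervals share ≥1 position,
    checked position by position (intervals assumed small)."""
    pairs = set()
    for gid, (gc, gs, ge) in gene_ivs.items():
        gpos = set(range(gs, ge))
        for bid, (bc, bs, be) in bgc_ivs.items():
            if gc == bc and gpos & set(range(bs, be)):
                pairs.add((gid, bid))
    return pairs


SENSE_CODONS = sorted(
    c for c in (a + b + d for a in BASES for b in BASES for d in BASES)
    if translate_codon(c) != "*"
)
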