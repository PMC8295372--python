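"""Genetic-code tables and Nei-Gojobori (1986) dN/dS counting.

Universal code; the 61 sense codons are indexed in lexicographic order.
NG86 conventions: synonymous site fraction per codon position is the
fraction of the three possible single-base changes that are synonymous
(changes to stop codons count as nonsynonymous), sites are averaged over
the two sequences; differences are averaged over all minimal mutational
pathways with equal weights; Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

_TABLE = standard_dna_table
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)
CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))  # 61 sense codons
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)
BASES = "ACGT"
_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3, no internal stops)."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        aas.append(GENETIC_CODE[codon])
    return "".join(aas)


class SaturationError(ValueError):
    """Proportion of differences beyond the Jukes-Cantor ceiling."""


@dataclass
class Ng86Result:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    dS: float
    dN: float
    ratio: Optional[float]  # None when dS == 0 (undefined)


@functools.lru_cache(maxsize=None)
def _site_fractions(codon: str) -> float:
    """Synonymous site count of one codon (sum of per-position fractions)."""
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn


@functools.lru_cache(maxsize=None)
def _pair_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over the
    minimal mutational pathways with equal weights.

    Implemented as a uniform recursion over which differing position is
    changed next (equivalent to enumerating position permutations)."""
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    for i in diff:
        step = codon1[:i] + codon2[i] + codon1[i + 1 :]
        aa1 = GENETIC_CODE.get(codon1)
        aa2 = GENETIC_CODE.get(step)
        if aa1 is not None and aa1 == aa2:
            s_here, n_here = 1.0, 0.0
        else:
            s_here, n_here = 0.0, 1.0
        s_rest, n_rest = _pair_diffs(step, codon2)
        syn += (s_here + s_rest) / len(diff)
        nonsyn += (n_here + n_rest) / len(diff)
    return syn, nonsyn


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion of differences {p:.3f} >= 3/4")
    if p == 0.0:
        return 0.0
    import math

    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(codons_a: list[str], codons_b: list[str]) -> Ng86Result:
    """NG86 dN/dS between two gap-free codon sequences of equal length."""
    pairs = [
        (a, b)
        for a, b in zip(codons_a, codons_b, strict=True)
        if "-" not in a and "-" not in b
    ]
    if not pairs:
        raise ValueError("no codon pair without gaps")
    syn_sites = nonsyn_sites = 0.0
    syn_d = nonsyn_d = 0.0
    for a, b in pairs:
        sa, sb = _site_fractions(a), _site_fractions(b)
        syn_sites += 0.5 * (sa + sb)
        nonsyn_sites += 3.0 - 0.5 * (sa + sb)
        ds, dn = _pair_diffs(a, b)
        syn_d += ds
        nonsyn_d += dn
    pS = syn_d / syn_sites if syn_sites else 0.0
    pN = nonsyn_d / nonsyn_sites if nonsyn_sites else 0.0
    dS, dN = _jc(pS), _jc(pN)
    ratio = dN / dS if dS > 0 else None
    return Ng86Result(syn_sites, nonsyn_sites, syn_d, nonsyn_d, dS, dN, ratio)


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError("sequence length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
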