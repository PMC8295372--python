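"""Orthology and paralogy: reciprocal best hits, duplication-mode calls.

Orthologs are assigned by reciprocal best hit (RBH) of Smith-Waterman
local alignment scores against a designated reference proteome.  Exact
Smith-Waterman (BLOSUM62, affine gaps) is used instead of a heuristic
seeded search: proteomes at this scale are small enough for exhaustive
all-vs-reference scoring.  Within-species paralog pairs are classified
tandem vs segmental from GFF coordinates.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

#: affine gap convention: a gap of length L costs GAP_OPEN + L * GAP_EXTEND
GAP_OPEN = 11
GAP_EXTEND = 1
SCORE_FLOOR = 40.0  # raw score below this counts as "no hit"
MIN_COVERAGE = 0.40  # paralog candidate coverage filter

_VALID = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    query_coverage: float
    identity: float


@dataclass
class ParalogPair:
    species: str
    gene_a: str
    gene_b: str
    mode: str = ""  # tandem | segmental
    chrom_a: str = ""
    chrom_b: str = ""
    relative_pos_a: float = 0.0
    relative_pos_b: float = 0.0


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _check_residues(seq: str, name: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)} in {name}")


def sw_score(a: str, b: str) -> float:
    """Smith-Waterman score only (no traceback; much faster than
    ``pairwise_align`` when coverage/identity are not needed)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return float(_aligner().score(a, b))


def pairwise_align(query_id: str, a: str, subject_id: str, b: str) -> AlignmentHit:
    """Best Smith-Waterman local alignment of two proteins.

    Coverage and identity are computed over the aligned region of the best
    alignment, relative to the query length.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    _check_residues(a, query_id)
    _check_residues(b, subject_id)
    try:
        aln = _aligner().align(a, b)[0]
    except IndexError:  # no positive-scoring local alignment at all
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, 0.0)
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        aligned_cols += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    q_span = aln.aligned[0][-1][1] - aln.aligned[0][0][0] if aligned_cols else 0
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(aln.score),
        query_coverage=q_span / len(a),
        identity=matches / aligned_cols if aligned_cols else 0.0,
    )


def _best_hits(queries: dict[str, str], subjects: dict[str, str],
               cache: dict) -> dict[str, AlignmentHit]:
    """Best subject per query; ties broken by identity then id."""
    best: dict[str, AlignmentHit] = {}
    for qid, qseq in queries.items():
        top: Optional[AlignmentHit] = None
        for sid, sseq in subjects.items():
            key = (qid, sid) if qid <= sid else (sid, qid)
            if key in cache:
                hit = cache[key]
                score, identity = hit.score, hit.identity
            else:
                hit = pairwise_align(qid, qseq, sid, sseq)
                cache[key] = hit
                score, identity = hit.score, hit.identity
            cand = AlignmentHit(qid, sid, score, hit.query_coverage, identity)
            if (
                top is None
                or cand.score > top.score
                or (cand.score == top.score and cand.identity > top.identity)
                or (
                    cand.score == top.score
                    and cand.identity == top.identity
                    and cand.subject_id < top.subject_id
                )
            ):
                top = cand
        if top is not None and top.score >= SCORE_FLOOR:
            best[qid] = top
    return best


def rbh_orthologs(
    proteome: dict[str, str], reference: dict[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Reciprocal-best-hit ortholog map gene -> reference gene.

    ``g`` maps to ``r`` iff r is g's best hit in the reference AND g is
    r's best hit in the species (score ranking; ties by identity then
    lexicographic id).  Returns (mapping, unmapped gene ids).
    """
    if not reference:
        raise ValueError("empty reference proteome")
    cache: dict = {}
    fwd = _best_hits(proteome, reference, cache)
    rev = _best_hits(reference, proteome, cache)
    mapping = {}
    for g, hit in fwd.items():
        back = rev.get(hit.subject_id)
        if back is not None and back.subject_id == g:
            mapping[g] = hit.subject_id
    unmapped = sorted(set(proteome) - set(mapping))
    return mapping, unmapped


#: a homolog link additionally needs this fraction of the query self-score,
#: so that the weak similarity shared by all WRKY domains (heptapeptide +
#: zinc finger) does not join unrelated families
SELF_SCORE_RATIO = 0.5


def best_reference_hit(seq: str, reference: dict[str, str]) -> Optional[str]:
    """Best-scoring reference gene (co-ortholog assignment for genes that
    fail the reciprocal test), or None below the score floor / self-score
    ratio."""
    floor = max(SCORE_FLOOR, SELF_SCORE_RATIO * sw_score(seq, seq))
    best_id, best_score = None, floor
    for rid in sorted(reference):
        s = sw_score(seq, reference[rid])
        if s > best_score:
            best_id, best_score = rid, s
    return best_id


def reference_self_groups(reference: dict[str, str]) -> dict[str, str]:
    """Cluster the reference proteome by best non-self hits (single
    linkage over the best-hit graph); group label = smallest member id.

    Gives the reference species its own paralog families, consistent with
    the co-ortholog assignment of the other species.
    """
    parent = {g: g for g in reference}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    for g in sorted(reference):
        floor = max(SCORE_FLOOR, SELF_SCORE_RATIO * sw_score(reference[g], reference[g]))
        best_id, best_score = None, floor
        for other in sorted(reference):
            if other == g:
                continue
            s = sw_score(reference[g], reference[other])
            if s > best_score:
                best_id, best_score = other, s
        if best_id is not None:
            hit = pairwise_align(g, reference[g], best_id, reference[best_id])
            if hit.query_coverage >= MIN_COVERAGE:
                union(g, best_id)
    return {g: find(g) for g in reference}


# ---------------------------------------------------------------------------
# paralogs
# ---------------------------------------------------------------------------


def find_paralogs(
    genes_by_species: dict[str, dict[str, str]],
    family_of: dict[str, str],
    proteins: Optional[dict[str, str]] = None,
) -> list[ParalogPair]:
    """All unordered same-species, same-family gene pairs.

    ``genes_by_species`` maps species -> {gene id -> family id is looked up
    in family_of}; when ``proteins`` is given, candidate pairs must align
    with query coverage >= MIN_COVERAGE (the HSP coverage filter).
    """
    pairs: list[ParalogPair] = []
    for species in sorted(genes_by_species):
        gene_ids = sorted(g for g in genes_by_species[species] if g in family_of)
        for a, b in itertools.combinations(gene_ids, 2):
            if family_of[a] != family_of[b]:
                continue
            if proteins is not None:
                hit = pairwise_align(a, proteins[a], b, proteins[b])
                if hit.query_coverage < MIN_COVERAGE:
                    continue
            pairs.append(ParalogPair(species=species, gene_a=a, gene_b=b))
    return pairs


def classify_duplication(
    pair: ParalogPair,
    coords: dict[str, tuple[str, int, int]],
    gene_order: dict[str, list[str]],
    max_intervening: int = 5,
    max_distance: int = 100_000,
) -> str:
    """Tandem iff same chromosome AND (<= K intervening genes OR <= D bp apart).

    ``coords`` maps gene -> (chromosome, start, end); ``gene_order`` maps
    chromosome -> gene ids sorted by position (for the intervening-gene
    count).
    """
    for g in (pair.gene_a, pair.gene_b):
        if g not in coords:
            raise ValueError(f"missing coordinates for {g}")
    ca, sa, ea = coords[pair.gene_a]
    cb, sb, eb = coords[pair.gene_b]
    if ca != cb:
        return "segmental"
    distance = max(sb, sa) - min(ea, eb)
    order = gene_order.get(ca, [])
    try:
        ia, ib = order.index(pair.gene_a), order.index(pair.gene_b)
        intervening = abs(ia - ib) - 1
    except ValueError:
        intervening = max_intervening + 1
    if intervening <= max_intervening or distance <= max_distance:
        return "tandem"
    return "segmental"


def normalize_positions(
    coords: dict[str, tuple[str, int, int]],
    chrom_lengths: dict[str, int],
) -> dict[str, float]:
    """Gene midpoint / chromosome length, in [0, 1] (0-1 scaled synteny)."""
    out = {}
    for gene, (chrom, start, end) in sorted(coords.items()):
        length = chrom_lengths[chrom]
        mid = 0.5 * (start + end)
        if mid > length:
            raise ValueError(f"{gene}: midpoint {mid} beyond chromosome {chrom}")
        out[gene] = mid / length
    return out


def tip_fraction(
    pairs: list[ParalogPair],
    positions: dict[str, float],
    coords: dict[str, tuple[str, int, int]],
    chromosomes: tuple[str, ...] = ("chr11", "chr12"),
    tip: float = 0.10,
) -> float:
    """Fraction of paralog-pair endpoints in the distal ``tip`` of the
    designated chromosomes (duplication hot-spot summary)."""
    endpoints = 0
    in_tip = 0
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            endpoints += 1
            if coords[g][0] in chromosomes and positions[g] <= tip:
                in_tip += 1
    return in_tip / endpoints if endpoints else 0.0
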