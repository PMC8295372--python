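"""Progressive multiple protein alignment (guide tree + profile-profile).

A deliberately small aligner for the highly similar within-family
sequences this pipeline aligns: k-mer guide distances, UPGMA guide tree,
and Needleman-Wunsch profile-profile merges with a BLOSUM62
expected-score column metric and a linear gap penalty.  External
alignments (e.g. from a dedicated MSA tool) can always be imported as
FASTA instead.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from .io import SequenceRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(_AA)}
GAP_PENALTY = -4.0

_B62 = substitution_matrices.load("BLOSUM62")
_SCORE = np.zeros((21, 21))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _SCORE[_i, _j] = _B62[_a][_b]
# gap column (index 20) scores 0 against everything


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(1, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(1, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / max(len(ka), len(kb))


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 21) frequency profile; column 20 is the gap."""
    L = len(rows[0])
    prof = np.zeros((L, 21))
    for row in rows:
        for i, aa in enumerate(row):
            prof[i, _AA_IDX.get(aa, 20) if aa != "-" else 20] += 1.0
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    pa, pb = _profile(rows_a), _profile(rows_b)
    col_score = pa @ _SCORE @ pb.T  # (La, Lb)
    La, Lb = len(pa), len(pb)
    score = np.zeros((La + 1, Lb + 1))
    back = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = np.arange(La + 1) * GAP_PENALTY
    score[0, :] = np.arange(Lb + 1) * GAP_PENALTY
    back[1:, 0] = 1
    back[0, 1:] = 2
    for i in range(1, La + 1):
        diag = score[i - 1, :-1] + col_score[i - 1]
        up = score[i - 1, 1:] + GAP_PENALTY
        prev = score[i, 0]
        row = score[i]
        brow = back[i]
        for j in range(1, Lb + 1):
            left = prev + GAP_PENALTY
            best = diag[j - 1]
            move = 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            if left > best:
                best, move = left, 2
            row[j] = prev = best
            brow[j] = move
    # traceback
    out_a = [""] * len(rows_a)
    out_b = [""] * len(rows_b)
    i, j = La, Lb
    cols_a: list[int] = []  # -1 for gap
    cols_b: list[int] = []
    while i > 0 or j > 0:
        move = back[i, j]
        if move == 0:
            i, j = i - 1, j - 1
            cols_a.append(i)
            cols_b.append(j)
        elif move == 1:
            i -= 1
            cols_a.append(i)
            cols_b.append(-1)
        else:
            j -= 1
            cols_a.append(-1)
            cols_b.append(j)
    cols_a.reverse()
    cols_b.reverse()
    out_a = ["".join(r[c] if c >= 0 else "-" for c in cols_a) for r in rows_a]
    out_b = ["".join(r[c] if c >= 0 else "-" for c in cols_b) for r in rows_b]
    return out_a, out_b


def progressive_align(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Align protein sequences; returns records in the input order."""
    if not records:
        return []
    if len(records) == 1:
        return [SequenceRecord(records[0].id, records[0].description,
                               records[0].residues)]
    ids = [r.id for r in records]
    seqs = {r.id: r.residues for r in records}
    # UPGMA guide from k-mer distances, deterministic ties by member ids
    clusters: dict[tuple[str, ...], list[str]] = {
        (rid,): [seqs[rid]] for rid in sorted(ids)
    }
    dist = {}
    sorted_ids = sorted(ids)
    for x in range(len(sorted_ids)):
        for y in range(x + 1, len(sorted_ids)):
            a, b = sorted_ids[x], sorted_ids[y]
            dist[frozenset(((a,), (b,)))] = _kmer_distance(seqs[a], seqs[b])
    members: dict[tuple[str, ...], list[str]] = {(rid,): [rid] for rid in sorted_ids}
    while len(clusters) > 1:
        best = None
        for ka in sorted(clusters):
            for kb in sorted(clusters):
                if ka >= kb:
                    continue
                dv = dist[frozenset((ka, kb))]
                if best is None or (dv, ka, kb) < best:
                    best = (dv, ka, kb)
        _, ka, kb = best
        rows_a, rows_b = _align_profiles(clusters[ka], clusters[kb])
        new_key = tuple(sorted(members[ka] + members[kb]))
        new_rows = rows_a + rows_b
        new_members = members[ka] + members[kb]
        na, nb = len(members[ka]), len(members[kb])
        for other in list(clusters):
            if other in (ka, kb):
                continue
            dist[frozenset((new_key, other))] = (
                na * dist[frozenset((ka, other))] + nb * dist[frozenset((kb, other))]
            ) / (na + nb)
        del clusters[ka], clusters[kb], members[ka], members[kb]
        clusters[new_key] = new_rows
        members[new_key] = new_members
    (final_key,) = clusters
    aligned = dict(zip(members[final_key], clusters[final_key]))
    return [SequenceRecord(r.id, r.description, aligned[r.id]) for r in records]
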