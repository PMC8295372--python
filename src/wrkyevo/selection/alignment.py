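"""Codon-alignment construction: occupancy filtering and codon threading."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import SequenceRecord
from .codon import CODON_INDEX, GENETIC_CODE, STOP_CODONS, split_codons


class AlignmentError(ValueError):
    pass


def occupancy_filter(
    records: list[SequenceRecord], min_fraction: float = 0.93
) -> tuple[list[SequenceRecord], list[int]]:
    """Drop alignment columns whose non-gap occupancy is below threshold.

    Returns the filtered records plus the map from kept column index to
    the original 0-based column index.
    """
    if not records:
        raise AlignmentError("empty alignment")
    rows = [rec.residues for rec in records]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("ragged alignment")
    n = len(rows)
    kept: list[int] = []
    for col in range(width):
        occ = sum(1 for r in rows if r[col] != "-") / n
        if occ >= min_fraction:
            kept.append(col)
    if not kept:
        raise AlignmentError("alignment too gappy: all columns removed")
    out = [
        SequenceRecord(rec.id, rec.description, "".join(rec.residues[c] for c in kept))
        for rec in records
    ]
    return out, kept


@dataclass
class CodonAlignment:
    taxa: list[str]
    codons: list[list[str]]  # rows of codons; "---" is a gap
    column_map: list[int] = field(default_factory=list)  # to protein columns

    @property
    def n_sites(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def to_matrix(self) -> np.ndarray:
        """Codon-index matrix (n_taxa, n_sites); -1 for gaps."""
        X = np.full((len(self.taxa), self.n_sites), -1, dtype=np.int64)
        for i, row in enumerate(self.codons):
            for j, codon in enumerate(row):
                if codon in CODON_INDEX:
                    X[i, j] = CODON_INDEX[codon]
        return X

    def pair(self, a: str, b: str) -> tuple[list[str], list[str]]:
        ia, ib = self.taxa.index(a), self.taxa.index(b)
        return self.codons[ia], self.codons[ib]


def thread_codons(
    protein_alignment: list[SequenceRecord], cds: dict[str, str]
) -> CodonAlignment:
    """Replace each aligned amino acid by its source codon.

    Per taxon the translation of the CDS must equal the ungapped protein
    row; protein gaps become codon gaps.
    """
    taxa = [rec.id for rec in protein_alignment]
    rows: list[list[str]] = []
    for rec in protein_alignment:
        if rec.id not in cds:
            raise AlignmentError(f"no CDS for taxon {rec.id}")
        codons = split_codons(cds[rec.id])
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        row: list[str] = []
        k = 0
        for pos, aa in enumerate(rec.residues):
            if aa == "-":
                row.append("---")
                continue
            if k >= len(codons):
                raise AlignmentError(f"{rec.id}: CDS shorter than protein row")
            codon = codons[k]
            if codon in STOP_CODONS:
                raise AlignmentError(f"{rec.id}: internal stop codon at codon {k + 1}")
            if GENETIC_CODE.get(codon) != aa:
                raise AlignmentError(
                    f"{rec.id}: codon {codon} does not translate to {aa!r} "
                    f"at alignment column {pos + 1}"
                )
            row.append(codon)
            k += 1
        if k != len(codons):
            raise AlignmentError(f"{rec.id}: CDS longer than protein row")
        rows.append(row)
    return CodonAlignment(taxa=taxa, codons=rows)
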