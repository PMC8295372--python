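"""Sequence and annotation I/O: validating FASTA and GFF3 readers/writers.

Coordinates follow the GFF3 convention everywhere: 1-based, inclusive.
Protein and CDS sequences are stored strand-resolved (5'->3' of the mRNA);
the GFF strand field is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SequenceRecord:
    id: str
    description: str = ""
    residues: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file, validating ids and residue alphabet.

    ``alphabet`` is "protein" (20 AA + X, stops allowed) or "nucleotide"
    (ACGTN).  Residues are uppercased; wrapped lines are joined.
    """
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    current: SequenceRecord | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                rid = parts[0]
                if rid in seen:
                    raise FormatError(
                        f"{path}: duplicate sequence id {rid!r} at line {lineno}"
                    )
                seen.add(rid)
                current = SequenceRecord(
                    id=rid, description=parts[1] if len(parts) > 1 else ""
                )
                records.append(current)
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunk = line.strip().upper()
                bad = set(chunk) - allowed
                if bad:
                    raise FormatError(
                        f"{path}: illegal {alphabet} character(s) "
                        f"{sorted(bad)} at line {lineno}"
                    )
                current.residues += chunk
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPES = {"gene", "mRNA", "CDS"}


@dataclass
class GffFeature:
    seqid: str
    type: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.attributes.get("ID", "")

    @property
    def parent(self) -> str:
        return self.attributes.get("Parent", "")


def read_gff3(path) -> list[GffFeature]:
    """Parse gene/mRNA/CDS features from a 9-column GFF3 file.

    Validates coordinates (1 <= start <= end) and that every mRNA/CDS
    Parent attribute resolves to a previously declared feature.
    """
    features: list[GffFeature] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: expected 9 tab-separated columns at line {lineno}, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype not in _GFF_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from None
            if not (1 <= start <= end):
                raise FormatError(
                    f"{path}: invalid interval {start}..{end} at line {lineno}"
                )
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}: bad strand {strand!r} at line {lineno}")
            attributes = {}
            for item in attrs_s.split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k] = v
            feat = GffFeature(seqid, ftype, start, end, strand, attributes)
            if ftype in {"gene", "mRNA"}:
                if not feat.id:
                    raise FormatError(f"{path}: {ftype} without ID at line {lineno}")
                ids.add(feat.id)
            if ftype in {"mRNA", "CDS"}:
                if not feat.parent:
                    raise FormatError(
                        f"{path}: {ftype} without Parent at line {lineno}"
                    )
                if feat.parent not in ids:
                    raise FormatError(
                        f"{path}: {ftype} Parent {feat.parent!r} unresolved "
                        f"at line {lineno}"
                    )
            features.append(feat)
    return features


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.seqid}\twrkyevo\t{f.type}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def gene_features(features) -> list[GffFeature]:
    return [f for f in features if f.type == "gene"]
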