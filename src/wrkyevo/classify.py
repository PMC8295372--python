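"""WRKY group assignment from domain calls, after isoform selection.

Rules (one label per gene):

* two complete domains, both C2H2 -> Ia; both C2HC -> Ib; mixed finger
  types are labeled by the C-terminal finger (the DNA-binding domain)
  with a ``mixed_zf`` flag;
* one complete C2H2 domain with a subgroup zinc-finger literal -> IIa,
  IIb, IId or IIe; bare core -> IIc;
* one complete C2HC domain -> III;
* no complete domain but at least one partial motif -> IV;
* three or more complete domains are labeled by the terminal pair with a
  ``multi_domain`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .scan import DomainCall
from .templates import expected_group

GROUP_ORDER = ["Ia", "Ib", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV"]


class NotWrkyError(ValueError):
    """No WRKY motif evidence at all; gene should be excluded upstream."""


@dataclass
class GeneRecord:
    gene_id: str
    species: str
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    isoforms: dict[str, str] = field(default_factory=dict)  # iso id -> protein
    calls: dict[str, list[DomainCall]] = field(default_factory=dict)
    representative_isoform: str = ""
    group: str = ""
    flags: list[str] = field(default_factory=list)


def select_isoform(calls_by_isoform: dict[str, list[DomainCall]],
                   lengths: dict[str, int]) -> str:
    """Representative isoform: the longest, unless only a shorter isoform
    carries a complete WRKY domain (heptapeptide + zinc finger), in which
    case the longest complete-domain isoform is chosen."""
    if not lengths:
        raise ValueError("empty isoform list")
    by_len = sorted(lengths, key=lambda i: (-lengths[i], i))
    longest = by_len[0]
    if any(c.complete for c in calls_by_isoform.get(longest, [])):
        return longest
    for iso in by_len:
        if any(c.complete for c in calls_by_isoform.get(iso, [])):
            return iso
    return longest


def classify_group(calls: list[DomainCall]) -> tuple[str, list[str]]:
    """Group label plus flags for one protein's domain calls.

    Pure function of the call list; call order is normalized internally so
    permutations cannot change the label.
    """
    if not calls:
        raise NotWrkyError("not a WRKY gene: no domain calls")
    ordered = sorted(calls, key=lambda c: c.hepta_start)
    return expected_group(ordered)


def classify_gene(gene: GeneRecord) -> GeneRecord:
    lengths = {iso: len(seq) for iso, seq in gene.isoforms.items()}
    gene.representative_isoform = select_isoform(gene.calls, lengths)
    label, flags = classify_group(gene.calls.get(gene.representative_isoform, []))
    gene.group = label
    gene.flags = flags
    return gene


def classification_table(
    genes: list[GeneRecord],
    genome_sizes_mb: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Per-species x per-group counts with totals and genes/Mb density."""
    rows = []
    species = sorted({g.species for g in genes})
    for sp in species:
        counts = {grp: 0 for grp in GROUP_ORDER}
        for g in genes:
            if g.species == sp:
                counts[g.group] += 1
        row = {"species": sp, **counts, "total": sum(counts.values())}
        if genome_sizes_mb and sp in genome_sizes_mb:
            row["wrky_per_mb"] = round(row["total"] / genome_sizes_mb[sp], 2)
        rows.append(row)
    return pd.DataFrame(rows)


def chromosome_table(genes: list[GeneRecord]) -> pd.DataFrame:
    """Per-species x per-chromosome WRKY counts (chromosome distribution)."""
    df = pd.DataFrame(
        [{"species": g.species, "chromosome": g.chromosome} for g in genes]
    )
    if df.empty:
        return pd.DataFrame(columns=["species", "chromosome", "n_genes"])
    out = (
        df.groupby(["species", "chromosome"]).size().reset_index(name="n_genes")
    )
    return out.sort_values(["species", "chromosome"]).reset_index(drop=True)
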