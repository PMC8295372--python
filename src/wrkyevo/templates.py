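"""WRKY domain templates: group-specific heptapeptide and zinc-finger signatures.

A WRKY domain is modeled as::

    heptapeptide(7) . spacer1 . C x{4,5} C [literal] . spacer2 . H x (H|C)

where the heptapeptide is canonically WRKYGQK, the C-pair is the zinc-finger
core (CX4C or CX5C), the optional literal is a subgroup-diagnostic motif
immediately after the second cysteine (e.g. PVKKK[LV]Q for subgroup IIa),
and the trailing pair distinguishes C2H2 (H-x-H) from C2HC (H-x-C) fingers.

Groups: Ia (two C2H2 domains), Ib (two C2HC domains), IIa/IIb/IId/IIe
(one C2H2 domain with a subgroup literal), IIc (one C2H2 domain, bare CX4C
core), III (one C2HC domain), IV (incomplete: heptapeptide without a
zinc finger).
"""

from __future__ import annotations

from dataclasses import dataclass

HEPTA_CANONICAL = ("WRKYGQK", "WRKYGEK", "WRKYGKK")
DEGENERATE_CORES = ("WKKY", "WRMC", "WSKY", "WVKY")

#: subgroup literals read immediately after the second core cysteine;
#: each entry is a tuple of per-position residue alternatives
SUBGROUP_LITERALS: dict[str, tuple[str, ...]] = {
    "IIa": ("P", "V", "K", "K", "K", "LV", "Q"),
    "IIb": ("P", "V", "R", "K", "Q", "V", "Q"),
    "IId": ("P", "A", "R", "K", "H", "V", "E"),
    "IIe": ("P", "A", "R", "K", "QM", "V", "ED"),
}

#: filler alphabet inside domains excludes C/H/W so that stochastic
#: evolution at non-signature sites cannot fabricate spurious cysteine
#: cores, histidine pairs, or tryptophan-anchored heptapeptides
DOMAIN_FILLER_AA = "ADEFGIKLMNPQRSTVY"
FREE_AA = "ACDEFGHIKLMNPQRSTVWY"

SPACER1 = 8  # heptapeptide end -> first cysteine
ZF_GAP = 21  # second cysteine -> first histidine (within the 18-28 window)
DOMAIN_WINDOW = 7 + SPACER1 + 1 + 5 + 1 + ZF_GAP + 3  # max domain span, 46


@dataclass(frozen=True)
class DomainTemplate:
    """Blueprint for one WRKY domain of a given group."""

    group: str  # classification group this domain belongs to
    hepta: str = "WRKYGQK"
    zf_type: str = "C2H2"  # C2H2 | C2HC | none
    core_len: int = 4  # x-count between the two core cysteines
    literal: str = ""  # subgroup literal (representative residues)

    @property
    def has_zf(self) -> bool:
        return self.zf_type != "none"

    def length(self) -> int:
        if not self.has_zf:
            return 7 + SPACER1
        return 7 + SPACER1 + 1 + self.core_len + 1 + ZF_GAP + 3

    def realize(self, rng) -> tuple[str, list[bool]]:
        """Emit a concrete domain string plus a per-residue frozen mask.

        Signature residues (heptapeptide, cysteines, literal, H/C pair)
        are frozen; spacer residues are drawn from the restricted domain
        filler alphabet.
        """
        seq: list[str] = []
        frozen: list[bool] = []

        def sig(s: str) -> None:
            seq.extend(s)
            frozen.extend([True] * len(s))

        def filler(n: int) -> None:
            for _ in range(n):
                seq.append(DOMAIN_FILLER_AA[rng.integers(len(DOMAIN_FILLER_AA))])
                frozen.append(False)

        sig(self.hepta)
        filler(SPACER1)
        if self.has_zf:
            sig("C")
            filler(self.core_len)
            sig("C")
            if self.literal:
                sig(self.literal)
            filler(ZF_GAP - len(self.literal))
            sig("H")
            filler(1)
            sig("H" if self.zf_type == "C2H2" else "C")
        return "".join(seq), frozen


def _lit(sub: str) -> str:
    return "".join(alt[0] for alt in SUBGROUP_LITERALS[sub])


#: per-group ordered (N->C) domain templates
GROUP_TEMPLATES: dict[str, tuple[DomainTemplate, ...]] = {
    "Ia": (
        DomainTemplate("Ia", zf_type="C2H2", core_len=4),
        DomainTemplate("Ia", zf_type="C2H2", core_len=4),
    ),
    "Ib": (
        DomainTemplate("Ib", zf_type="C2HC", core_len=5),
        DomainTemplate("Ib", zf_type="C2HC", core_len=5),
    ),
    "IIa": (DomainTemplate("IIa", zf_type="C2H2", core_len=5, literal=_lit("IIa")),),
    "IIb": (DomainTemplate("IIb", zf_type="C2H2", core_len=5, literal=_lit("IIb")),),
    "IIc": (DomainTemplate("IIc", zf_type="C2H2", core_len=4),),
    "IId": (DomainTemplate("IId", zf_type="C2H2", core_len=5, literal=_lit("IId")),),
    "IIe": (DomainTemplate("IIe", zf_type="C2H2", core_len=5, literal=_lit("IIe")),),
    "III": (DomainTemplate("III", zf_type="C2HC", core_len=5),),
    "IV": (DomainTemplate("IV", zf_type="none"),),
}


def expected_group(domains) -> tuple[str, list[str]]:
    """Group label implied by an ordered list of domain descriptors.

    ``domains`` is a sequence of objects with ``zf_type`` (C2H2/C2HC/none)
    and ``signature`` (subgroup label, "CX4C", "CX5C", or "none")
    attributes, ordered N->C.  Returns (label, flags).  This encodes the
    classification rules: two complete domains -> Ia (C2H2) / Ib (C2HC),
    one complete domain -> subgroup literal, IIc (bare C2H2 core) or III
    (C2HC), incomplete -> IV.
    """
    flags: list[str] = []
    complete = [d for d in domains if d.zf_type in ("C2H2", "C2HC")]
    if not complete:
        if not domains:
            raise ValueError("not a WRKY gene: no domain calls")
        return "IV", flags
    if len(complete) >= 3:
        flags.append("multi_domain")
    if len(complete) >= 2:
        n_type = complete[0].zf_type
        c_type = complete[-1].zf_type
        if n_type != c_type:
            flags.append("mixed_zf")
        return ("Ia" if c_type == "C2H2" else "Ib"), flags
    d = complete[0]
    if d.zf_type == "C2HC":
        return "III", flags
    if d.signature in SUBGROUP_LITERALS:
        return d.signature, flags
    return "IIc", flags
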