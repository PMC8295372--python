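"""WRKY domain detection in protein sequences.

The screen anchors on heptapeptide matches (WRKYGQK and its variants),
pairs each anchor with the nearest downstream zinc-finger motif, and
scores the spanned region against a position-specific scoring matrix
(PSSM) built from a packaged reference alignment of WRKY domains.  The
acceptance threshold is calibrated so that the false-positive rate on
shuffled sequences of realistic composition is ~1e-3 per sequence.

A structurally complete domain with an exact canonical heptapeptide is
always kept, even if its profile score is degraded; anchors without any
zinc finger are reported with ``zf_type == "none"`` (Group IV logic).
"""

from __future__ import annotations

import functools
import importlib.resources
import re
from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import templates as T
from .io import SequenceRecord, read_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

PSSM_WIDTH = T.DOMAIN_WINDOW  # 46 residues from the heptapeptide start
PAIR_WINDOW = 60  # max residues between heptapeptide end and core start
SPACER_MIN, SPACER_MAX = 18, 28  # residues between second C and first H

#: seed under which the packaged score threshold is calibrated
CALIBRATION_SEED = 777
CALIBRATION_N = 10_000
TARGET_FPR = 1e-3

_HEPTA_RE = re.compile(
    "(?=("
    + "|".join(T.HEPTA_CANONICAL)
    + "|"
    + "|".join(c + "..." for c in T.DEGENERATE_CORES)
    + "))"
)


@dataclass
class DomainCall:
    protein_id: str
    hepta_start: int  # 1-based; for zf-only calls this is the core start
    hepta_variant: str  # "" when the heptapeptide is absent
    zf_type: str  # C2H2 | C2HC | none
    signature: str  # subgroup label, CX4C, CX5C, or "none"
    zf_start: int  # 1-based; 0 when absent
    zf_end: int
    score: float
    terminal: str = ""  # N | internal | C | only

    @property
    def complete(self) -> bool:
        return bool(self.hepta_variant) and self.zf_type in ("C2H2", "C2HC")


# ---------------------------------------------------------------------------
# motif-level scans
# ---------------------------------------------------------------------------


def scan_heptapeptide(protein: str) -> list[tuple[int, str]]:
    """All heptapeptide-class matches as (1-based index, exact 7-mer)."""
    out = []
    for m in _HEPTA_RE.finditer(protein):
        out.append((m.start() + 1, m.group(1)))
    return out


def _match_literal(segment: str) -> Optional[str]:
    for sub, pattern in T.SUBGROUP_LITERALS.items():
        if len(segment) >= len(pattern) and all(
            segment[i] in alts for i, alts in enumerate(pattern)
        ):
            return sub
    return None


def scan_zinc_finger(
    protein: str, search_from: int, window: int = PAIR_WINDOW
) -> Optional[tuple[str, str, tuple[int, int]]]:
    """First zinc-finger motif at or after 1-based position ``search_from``.

    Looks for a C-x(4,5)-C core whose second cysteine is followed, after a
    spacer of 18-28 residues, by an H-x-H (C2H2) or H-x-C (C2HC) pair.
    Returns (zf_type, signature_label, (start, end)) with 1-based inclusive
    span, or None.
    """
    n = len(protein)
    lo = max(0, search_from - 1)
    hi = min(n, lo + window)
    for ci in range(lo, hi):
        if protein[ci] != "C":
            continue
        # prefer the CX5C reading when it carries a subgroup literal
        core_candidates = []
        for core in (5, 4):
            cj = ci + core + 1
            if cj < n and protein[cj] == "C":
                literal = _match_literal(protein[cj + 1 : cj + 8]) if core == 5 else None
                core_candidates.append((0 if literal else 1, core, cj, literal))
        for _, core, cj, literal in sorted(core_candidates):
            for gap in range(SPACER_MIN, SPACER_MAX + 1):
                hi_pos = cj + 1 + gap
                if hi_pos + 2 >= n:
                    break
                if protein[hi_pos] == "H" and protein[hi_pos + 2] in "HC":
                    zf_type = "C2H2" if protein[hi_pos + 2] == "H" else "C2HC"
                    label = literal if literal else f"CX{core}C"
                    return zf_type, label, (ci + 1, hi_pos + 3)
    return None


# ---------------------------------------------------------------------------
# profile
# ---------------------------------------------------------------------------


def build_reference_alignment(seed: int = 101, n_per_template: int = 4):
    """Synthetic reference WRKY-domain alignment used to train the PSSM.

    One block of ``n_per_template`` realizations per complete-domain
    template, each padded with domain-filler residues to the fixed scan
    window.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(T.GROUP_TEMPLATES):
        for di, tpl in enumerate(T.GROUP_TEMPLATES[group]):
            if not tpl.has_zf:
                continue
            for k in range(n_per_template):
                seq, _ = tpl.realize(rng)
                while len(seq) < PSSM_WIDTH:
                    seq += T.DOMAIN_FILLER_AA[rng.integers(len(T.DOMAIN_FILLER_AA))]
                records.append(
                    SequenceRecord(
                        id=f"{group}.d{di + 1}.r{k + 1}",
                        description="synthetic reference domain",
                        residues=seq[:PSSM_WIDTH],
                    )
                )
    return records


def _packaged_reference() -> list[SequenceRecord]:
    path = importlib.resources.files("wrkyevo.data") / "reference_domains.afa"
    with importlib.resources.as_file(path) as p:
        return read_fasta(p)


class ScanProfile:
    """Log-odds PSSM over the reference alignment plus a calibrated threshold."""

    def __init__(self, records, threshold: float = 0.0):
        counts = np.full((PSSM_WIDTH, 20), 0.5)  # pseudocount
        for rec in records:
            for i, aa in enumerate(rec.residues[:PSSM_WIDTH]):
                if aa in _AA_INDEX:
                    counts[i, _AA_INDEX[aa]] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        background = counts.sum(axis=0) / counts.sum()
        self.matrix = np.log2(freqs / background)
        self.threshold = threshold

    def score(self, window: str) -> float:
        total = 0.0
        for i, aa in enumerate(window[:PSSM_WIDTH]):
            if aa in _AA_INDEX:
                total += self.matrix[i, _AA_INDEX[aa]]
        return float(total)

    @classmethod
    def calibrated(
        cls, records=None, seed: int = CALIBRATION_SEED, n: int = CALIBRATION_N
    ) -> "ScanProfile":
        profile = cls(records if records is not None else _packaged_reference())
        profile.threshold = calibrate_threshold(profile, seed=seed, n=n)
        return profile


def _decoy_pool(rng, n: int) -> list[str]:
    """Shuffled versions of synthetic WRKY-like proteins (same composition)."""
    groups = [g for g in sorted(T.GROUP_TEMPLATES) if g != "IV"]
    pool = []
    for i in range(n):
        tpls = T.GROUP_TEMPLATES[groups[i % len(groups)]]
        parts = ["".join(T.FREE_AA[j] for j in rng.integers(len(T.FREE_AA), size=25))]
        for tpl in tpls:
            parts.append(tpl.realize(rng)[0])
            parts.append(
                "".join(T.FREE_AA[j] for j in rng.integers(len(T.FREE_AA), size=15))
            )
        residues = list("".join(parts))
        rng.shuffle(residues)
        pool.append("".join(residues))
    return pool


def _best_candidate_score(protein: str, profile: "ScanProfile") -> float:
    best = -np.inf
    for idx, _variant in scan_heptapeptide(protein):
        if scan_zinc_finger(protein, idx + 7) is None:
            continue
        best = max(best, profile.score(protein[idx - 1 : idx - 1 + PSSM_WIDTH]))
    return best


def calibrate_threshold(
    profile: ScanProfile, seed: int = CALIBRATION_SEED, n: int = CALIBRATION_N
) -> float:
    """Score threshold giving ~TARGET_FPR accepted calls per shuffled sequence.

    Deterministic in ``seed``; the packaged default is reproducible
    bit-exact from CALIBRATION_SEED.
    """
    rng = np.random.default_rng(seed)
    scores = sorted(
        (_best_candidate_score(p, profile) for p in _decoy_pool(rng, n)), reverse=True
    )
    k = max(1, round(n * TARGET_FPR))
    finite = [s for s in scores if np.isfinite(s)]
    if len(finite) <= k:
        return (min(finite) if finite else 0.0) - 1.0
    return 0.5 * (finite[k - 1] + finite[k])


@functools.lru_cache(maxsize=1)
def default_profile() -> ScanProfile:
    return ScanProfile.calibrated()


# ---------------------------------------------------------------------------
# domain calling
# ---------------------------------------------------------------------------


def call_domains(
    protein_id: str, residues: str, profile: Optional[ScanProfile] = None
) -> list[DomainCall]:
    """Detect WRKY domains in one protein.

    Anchors are resolved leftmost-first and calls never overlap; a call is
    kept when its PSSM score clears the calibrated threshold OR when it has
    an exact canonical heptapeptide (structurally complete domains with
    degraded profile scores survive).  Exact-heptapeptide anchors with no
    downstream zinc finger are emitted with ``zf_type == "none"``.
    """
    if profile is None:
        profile = default_profile()
    calls: list[DomainCall] = []
    cursor = 0  # 1-based end of the last accepted call
    for idx, variant in scan_heptapeptide(residues):
        if idx <= cursor:
            continue
        zf = scan_zinc_finger(residues, idx + 7)
        score = profile.score(residues[idx - 1 : idx - 1 + PSSM_WIDTH])
        exact = variant in T.HEPTA_CANONICAL
        if zf is not None:
            if score < profile.threshold and not exact:
                continue
            zf_type, label, (zs, ze) = zf
            calls.append(
                DomainCall(protein_id, idx, variant, zf_type, label, zs, ze, score)
            )
            cursor = ze
        else:
            if not exact:
                continue
            calls.append(
                DomainCall(protein_id, idx, variant, "none", "none", 0, 0, score)
            )
            cursor = idx + 6
    if not calls:
        # zinc finger without any heptapeptide: only trust subgroup literals
        zf = scan_zinc_finger(residues, 1, window=len(residues))
        if zf is not None and zf[1] in T.SUBGROUP_LITERALS:
            zf_type, label, (zs, ze) = zf
            calls.append(
                DomainCall(protein_id, zs, "", zf_type, label, zs, ze, 0.0)
            )
    if len(calls) == 1:
        calls[0] = replace(calls[0], terminal="only")
    else:
        for i, c in enumerate(calls):
            term = "N" if i == 0 else ("C" if i == len(calls) - 1 else "internal")
            calls[i] = replace(c, terminal=term)
    return calls


def scan_proteome(records, profile: Optional[ScanProfile] = None):
    """protein id -> list of DomainCall, for every record with >= 1 call."""
    if profile is None:
        profile = default_profile()
    out: dict[str, list[DomainCall]] = {}
    for rec in records:
        calls = call_domains(rec.id, rec.residues, profile)
        if calls:
            out[rec.id] = calls
    return out


def motif_census(calls_by_protein) -> dict[str, int]:
    """Exact counts per heptapeptide variant over a set of domain calls."""
    counter: Counter[str] = Counter()
    if isinstance(calls_by_protein, dict):
        calls_iter = (c for calls in calls_by_protein.values() for c in calls)
    else:
        calls_iter = iter(calls_by_protein)
    for call in calls_iter:
        if call.hepta_variant:
            counter[call.hepta_variant] += 1
    return dict(sorted(counter.items()))
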