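"""Protein-architecture features of linker-histone-like sequences.

* P-x-V-x-L motif scanning (the pentapeptide recognized by the HP1
  chromoshadow domain; positions 1, 3 and 5 fixed, overlaps allowed),
* per-region charge/hydrophobicity composition (basic = K/R -- histidine
  is excluded because it is mostly neutral at physiological pH; acidic =
  D/E; hydrophobic = A/V/L/I/M/F/W/C),
* maximal poly-D/E acidic-tract detection,
* pairwise identity/similarity over an aligned pair (similarity counts
  BLOSUM62-positive residue pairs, identities included).

All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "MotifHit",
    "RegionComposition",
    "AcidicTract",
    "scan_pxvxl",
    "composition_profile",
    "find_acidic_tract",
    "pairwise_identity",
    "BASIC",
    "ACIDIC",
    "HYDROPHOBIC",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")
HYDROPHOBIC = frozenset("AVLIMFWC")

_PXVXL = re.compile(r"(?=(P[A-Z]V[A-Z]L))")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class MotifHit:
    start: int            # 1-based inclusive
    end: int
    matched_sequence: str

    def __post_init__(self) -> None:
        if self.end != self.start + 4:
            raise ValueError("a P-x-V-x-L hit spans exactly 5 residues")


@dataclass(frozen=True)
class RegionComposition:
    name: str
    start: int
    end: int
    pct_basic: float
    pct_acidic: float
    pct_hydrophobic: float


@dataclass(frozen=True)
class AcidicTract:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = [i + 1 for i, c in enumerate(seq) if c not in _AA]
    if bad:
        raise ValueError(f"non-standard residues at positions {bad}")
    return seq


def scan_pxvxl(seq: str) -> list[MotifHit]:
    """All (possibly overlapping) P-x-V-x-L occurrences, 1-based."""
    seq = _validate(seq)
    hits = []
    for m in _PXVXL.finditer(seq):
        start = m.start() + 1
        hits.append(MotifHit(start=start, end=start + 4, matched_sequence=m.group(1)))
    return hits


def composition_profile(
    seq: str,
    regions: Sequence[tuple[str, int, int]],
    basic: frozenset = BASIC,
    acidic: frozenset = ACIDIC,
    hydrophobic: frozenset = HYDROPHOBIC,
) -> list[RegionComposition]:
    """Percent basic/acidic/hydrophobic residues per named 1-based span.

    Spans may overlap each other; each must lie within the sequence.
    """
    seq = _validate(seq)
    out = []
    for name, start, end in regions:
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"region {name!r} span ({start},{end}) out of bounds")
        sub = seq[start - 1: end]
        n = len(sub)
        out.append(RegionComposition(
            name=name, start=start, end=end,
            pct_basic=100.0 * sum(c in basic for c in sub) / n,
            pct_acidic=100.0 * sum(c in acidic for c in sub) / n,
            pct_hydrophobic=100.0 * sum(c in hydrophobic for c in sub) / n,
        ))
    return out


def find_acidic_tract(seq: str, min_len: int = 15) -> list[AcidicTract]:
    """Maximal runs of D/E residues at least ``min_len`` long, 1-based."""
    if min_len < 2:
        raise ValueError("min_len must be >=2")
    seq = _validate(seq)
    return [
        AcidicTract(start=m.start() + 1, end=m.end())
        for m in re.finditer(r"[DE]{%d,}" % min_len, seq)
    ]


def pairwise_identity(aligned_a: str, aligned_b: str) -> dict:
    """Identity and similarity percentages over an aligned sequence pair.

    Computed over columns where both rows are non-gap: identity is the
    percent of identical pairs; similarity the percent of pairs with a
    positive BLOSUM62 score (which includes all identities of standard
    residues).
    """
    a, b = aligned_a.upper(), aligned_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no comparable columns")
    for x, y in pairs:
        if x not in _AA or y not in _AA:
            raise ValueError(f"non-standard residue pair ({x},{y})")
    n = len(pairs)
    ident = sum(x == y for x, y in pairs)
    simil = sum(_BLOSUM62[x, y] > 0 for x, y in pairs)
    return {
        "identity_pct": 100.0 * ident / n,
        "similarity_pct": 100.0 * simil / n,
        "n_columns": n,
    }
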