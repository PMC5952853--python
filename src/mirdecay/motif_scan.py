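"""AU-, GU- and U-rich destabilizing-element motif scanning.

Nine degenerate patterns over {A,C,G,T,W} (W = A or T after the U->T
mapping) describe the AU-rich (ARE), GU-rich (GRE) and U-rich (URE)
elements bound by destabilizing RNA-binding proteins.  A transcript is
flagged as potentially unstable when at least one pattern literal occurs in
every one of its five region classes (5'UTR, exon, intron, CDS, 3'UTR) —
any pattern per region, not the same one throughout.

Scanning is on the forward (mRNA) strand only: the substrate is a
single-stranded transcript, so a reverse-complement occurrence is not a
binding element and is deliberately not counted.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping

from .io_formats import REGIONS, RegionSequences

MOTIF_PATTERNS = (
    "ATTTA",
    "AWTAAA",
    "GTTTG",
    "TTTGTTT",
    "WTTTW",
    "WWTTTWW",
    "WWWTTTWWW",
    "WWWWTTTWWWW",
    "WWWWWTTTWWWWW",
)

_ALPHABET = set("ACGTW")


@lru_cache(maxsize=None)
def expand_w(pattern: str) -> frozenset[str]:
    """All literals obtained by substituting each W with A or T.

    The result has exactly 2**(#W) members.
    """
    bad = set(pattern) - _ALPHABET
    if bad:
        raise ValueError(f"pattern {pattern!r}: illegal characters {sorted(bad)}")
    choices = [("A", "T") if c == "W" else (c,) for c in pattern]
    return frozenset("".join(p) for p in product(*choices))


def _all_literals() -> frozenset[str]:
    lits: set[str] = set()
    for pat in MOTIF_PATTERNS:
        lits |= expand_w(pat)
    return frozenset(lits)


def motif_hits(regions: RegionSequences) -> list[tuple[str, str, int]]:
    """(region, pattern, 0-based position) for every literal occurrence."""
    out = []
    for region in REGIONS:
        seq = regions.get(region)
        if not seq:
            continue
        for pat in MOTIF_PATTERNS:
            for lit in sorted(expand_w(pat)):
                p = seq.find(lit)
                while p != -1:
                    out.append((region, pat, p))
                    p = seq.find(lit, p + 1)
    out.sort(key=lambda t: (REGIONS.index(t[0]), t[2], t[1]))
    return out


def scan_region_motifs(regions: RegionSequences) -> dict[str, bool]:
    """Per region: does any pattern literal occur as a substring?"""
    lits = _all_literals()
    flags: dict[str, bool] = {}
    for region in REGIONS:
        seq = regions.get(region)
        flags[region] = bool(seq) and any(lit in seq for lit in lits)
    return flags


def flag_are_transcripts(
    records: Iterable[RegionSequences],
) -> set[str]:
    """Transcripts with a motif hit in all five regions simultaneously.

    A transcript missing any region class cannot qualify.
    """
    flagged: set[str] = set()
    for rec in records:
        flags = scan_region_motifs(rec)
        if all(flags[r] for r in REGIONS):
            flagged.add(rec.transcript_id)
    return flagged
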