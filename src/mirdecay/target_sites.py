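"""Canonical miRNA seed-match sites: construction, scanning, classification.

A mature miRNA represses transcripts whose 3'UTR (or CDS) contains a match
to its seed, nucleotides 2-8 of the mature sequence.  The three canonical
site types on the target (written 5'->3' in DNA letters) are:

* ``7mer-m8``  — reverse complement of miRNA nt 2-8;
* ``8mer-1a``  — the 7mer-m8 string followed by an ``A`` (the A faces miRNA
  position 1 regardless of what nt 1 actually is);
* ``7mer-1a``  — reverse complement of miRNA nt 2-7 followed by an ``A``
  (equivalently, the 8mer-1a string minus its first character).

miRNAs sharing nt 2-8 form one family; a site for any member counts for the
family.  Scanning collapses overlapping matches that share the same 7mer-m8
core into a single site labelled with the most specific type
(8mer-1a > 7mer-m8 > 7mer-1a).

Target calling is conservation-gated: a transcript is a target in region R
only if a family site is present in its focal R sequence and in the
corresponding R sequence of every required ortholog species (presence-based;
positions are not aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer-1a", "7mer-m8", "7mer-1a")
# specificity order used when overlapping matches collapse
_SPECIFICITY = {"8mer-1a": 0, "7mer-m8": 1, "7mer-1a": 2}

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class MiRNA:
    """A mature miRNA with derived seed fields.

    ``mature`` is stored 5'->3' in the RNA alphabet (T accepted on input and
    mapped to U).  ``seed2_7``/``seed2_8`` are the nt 2-7 / nt 2-8
    substrings (RNA letters); the family id is the shared seed2_8.
    """

    name: str
    mature: str
    expression_rank: int = 1
    seed2_7: str = field(init=False)
    seed2_8: str = field(init=False)
    family_id: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.mature.upper().replace("T", "U")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.name}: illegal characters {sorted(bad)}")
        if len(seq) < 8:
            raise ValueError(
                f"{self.name}: mature sequence must be >= 8 nt, got {len(seq)}"
            )
        self.mature = seq
        self.seed2_8 = seq[1:8]
        self.seed2_7 = seq[1:7]
        self.family_id = self.seed2_8


@dataclass(frozen=True)
class TargetSite:
    """One seed-match site on a region sequence (0-based, half-open)."""

    transcript_id: str
    region: str
    start: int
    end: int
    site_type: str
    family_id: str

    def __post_init__(self) -> None:
        expected = 8 if self.site_type == "8mer-1a" else 7
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class TargetClassification:
    """Per-transcript target status and the binary group labels."""

    transcript_id: str
    is_target_utr3: bool = False
    is_target_cds: bool = False
    n_sites_utr3: int = 0
    seed_group: str = "none"   # 8mer-1a | 7mer-m8 | 7mer-1a | multi | none
    apa_group: str = "noAPA"   # APA | noAPA
    cotarget_group: str = "low"  # high | low
    utr_len_group: str = "long"  # long | short


def seed_site_strings(mirna: MiRNA) -> dict[str, str]:
    """Site strings (target-strand DNA) for the three canonical types."""
    seed28_dna = mirna.seed2_8.replace("U", "T")
    seed27_dna = mirna.seed2_7.replace("U", "T")
    m8 = _revcomp_dna(seed28_dna)
    return {
        "7mer-m8": m8,
        "8mer-1a": m8 + "A",
        "7mer-1a": _revcomp_dna(seed27_dna) + "A",
    }


def family_site_strings(mirnas: Iterable[MiRNA]) -> dict[str, dict[str, str]]:
    """One site-string map per family (members share seed2_8)."""
    out: dict[str, dict[str, str]] = {}
    for m in mirnas:
        out.setdefault(m.family_id, seed_site_strings(m))
    return out


def scan_sites(
    region_seq: str,
    mirnas: Sequence[MiRNA],
    transcript_id: str = "",
    region: str = "UTR3",
) -> list[TargetSite]:
    """All canonical sites for the given miRNA families, left to right.

    Overlapping matches sharing a 7mer-m8 core report one site with the most
    specific type: an 8mer-1a occurrence is never double-counted as the
    7mer-m8 (same start) or 7mer-1a (start+1) it contains.
    """
    if not region_seq:
        return []
    seq = region_seq
    sites: list[TargetSite] = []
    for family_id, strings in family_site_strings(mirnas).items():
        s8, sm8, s1a = strings["8mer-1a"], strings["7mer-m8"], strings["7mer-1a"]
        starts8 = _find_all(seq, s8)
        starts8_set = set(starts8)
        for p in starts8:
            sites.append(TargetSite(transcript_id, region, p, p + 8,
                                    "8mer-1a", family_id))
        for p in _find_all(seq, sm8):
            if p in starts8_set:  # the m8 core of a counted 8mer
                continue
            sites.append(TargetSite(transcript_id, region, p, p + 7,
                                    "7mer-m8", family_id))
        for p in _find_all(seq, s1a):
            if (p - 1) in starts8_set:  # tail of a counted 8mer
                continue
            sites.append(TargetSite(transcript_id, region, p, p + 7,
                                    "7mer-1a", family_id))
    sites.sort(key=lambda s: (s.start, _SPECIFICITY[s.site_type], s.family_id))
    return sites


def _find_all(seq: str, sub: str) -> list[int]:
    out = []
    p = seq.find(sub)
    while p != -1:
        out.append(p)
        p = seq.find(sub, p + 1)
    return out


def conserved_targets(
    focal: Mapping[str, object],
    orthologs: Mapping[str, Mapping[str, object]],
    mirnas: Sequence[MiRNA],
    region: str = "UTR3",
) -> set[str]:
    """Transcripts with >= 1 family site in the focal region sequence and in
    every required ortholog's corresponding region sequence.

    ``focal`` maps transcript id -> RegionSequences; ``orthologs`` maps
    species -> {focal transcript id -> RegionSequences}.  Transcripts
    missing an ortholog record are excluded (logged), not an error.
    """
    targets: set[str] = set()
    for tx, rec in focal.items():
        if not scan_sites(rec.get(region), mirnas, tx, region):
            continue
        conserved = True
        for species, recs in orthologs.items():
            ortho = recs.get(tx)
            if ortho is None:
                logger.info("conserved_targets: %s has no %s record; excluded",
                            tx, species)
                conserved = False
                break
            if not scan_sites(ortho.get(region), mirnas, tx, region):
                conserved = False
                break
        if conserved:
            targets.add(tx)
    return targets


APA_HEXAMERS = ("AATAAA", "ATTAAA")


def classify_apa(utr3_seq: str, site: TargetSite) -> str:
    """APA iff a poly(A) hexamer ends strictly 5' of the site start.

    Alternative polyadenylation at an upstream signal truncates the 3'UTR and
    deletes everything downstream, including the miRNA site — hence only
    hexamers wholly before the site count.
    """
    if site.region != "UTR3":
        raise ValueError("APA classification applies to 3'UTR sites")
    window = utr3_seq[: max(site.start, 0)]
    return "APA" if any(h in window for h in APA_HEXAMERS) else "noAPA"


def classify_cotargeting(
    utr3_seq: str,
    high_mirnas: Sequence[MiRNA],
    focal_family: str,
) -> str:
    """'high' iff any highly expressed non-focal-family miRNA has a site."""
    others = [m for m in high_mirnas if m.family_id != focal_family]
    return "high" if scan_sites(utr3_seq, others) else "low"


def top_expressed_mirnas(mirnas: Sequence[MiRNA], k: int = 20) -> list[MiRNA]:
    """The k most highly expressed miRNAs (rank 1 = highest)."""
    return sorted(mirnas, key=lambda m: m.expression_rank)[:k]


def classify_utr_length(
    gene_isoforms: Mapping[str, Mapping[str, int]],
) -> dict[str, str]:
    """'long' iff the transcript's 3'UTR is the longest among its gene's
    isoforms (ties long; single-isoform genes long)."""
    out: dict[str, str] = {}
    for gene, isoforms in gene_isoforms.items():
        longest = max(isoforms.values())
        for tx, length in isoforms.items():
            out[tx] = "long" if length == longest else "short"
    return out


def classify_seed_group(sites: Sequence[TargetSite]) -> str:
    """Single-site transcripts take their site's type; several sites ->
    'multi' (excluded from the seed-type contrast); none -> 'none'."""
    utr3 = [s for s in sites if s.region == "UTR3"]
    if not utr3:
        return "none"
    if len(utr3) > 1:
        return "multi"
    return utr3[0].site_type


def classify_targets(
    focal: Mapping[str, object],
    orthologs: Mapping[str, Mapping[str, object]],
    mirnas: Sequence[MiRNA],
    focal_family: str,
    cds_ortholog_species: Sequence[str] | None = None,
    top_k: int = 20,
) -> dict[str, TargetClassification]:
    """Full per-transcript classification over a cohort.

    UTR3 targets use all ortholog species; CDS targets may use a subset
    (``cds_ortholog_species``) — by default the same set.  Group labels are
    computed only for UTR3 targets.
    """
    family = [m for m in mirnas if m.family_id == focal_family]
    if not family:
        raise ValueError(f"no miRNA with family id {focal_family!r}")
    high = top_expressed_mirnas(mirnas, top_k)

    utr3_targets = conserved_targets(focal, orthologs, family, "UTR3")
    cds_orthos = orthologs
    if cds_ortholog_species is not None:
        cds_orthos = {sp: orthologs[sp] for sp in cds_ortholog_species}
    cds_targets = conserved_targets(focal, cds_orthos, family, "CDS")

    gene_isoforms: dict[str, dict[str, int]] = {}
    for tx, rec in focal.items():
        gene_isoforms.setdefault(rec.gene_id, {})[tx] = len(rec.get("UTR3"))
    utr_len = classify_utr_length(gene_isoforms)

    out: dict[str, TargetClassification] = {}
    for tx, rec in focal.items():
        cls = TargetClassification(tx)
        cls.is_target_utr3 = tx in utr3_targets
        cls.is_target_cds = tx in cds_targets
        utr3_seq = rec.get("UTR3")
        sites = scan_sites(utr3_seq, family, tx, "UTR3")
        cls.n_sites_utr3 = len(sites)
        if cls.is_target_utr3:
            cls.seed_group = classify_seed_group(sites)
            cls.apa_group = classify_apa(utr3_seq, sites[0])
            cls.cotarget_group = classify_cotargeting(utr3_seq, high,
                                                      focal_family)
            cls.utr_len_group = utr_len[tx]
        out[tx] = cls
    return out
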