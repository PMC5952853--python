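"""Readers and writers for the pipeline's tabular and sequence inputs.

Expression matrices arrive as TSV (one ``transcript_id`` column plus one
numeric FPKM column per sample) together with a design table mapping sample
names to genotype, time point and replicate.  Region sequences (5'UTR, CDS,
exon, intron, 3'UTR) arrive as one FASTA file per region, with headers of
the form ``transcriptID|geneID`` (delimiter configurable).  Mature miRNA
sequences arrive as a three-column TSV (name, sequence, expression rank).

All sequences are normalized to an uppercase DNA alphabet on ingest (U is
mapped to T) so that miRNA-derived site strings and genomic regions live in
a single alphabet.  Coordinates used elsewhere in the package are 0-based,
half-open, on the stored region sequence in its 5'->3' orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .target_sites import MiRNA

GENOTYPES = ("WT", "KO")
REGIONS = ("UTR5", "CDS", "EXON", "INTRON", "UTR3")

_DNA_OK = set("ACGTN")


class FormatError(ValueError):
    """An input file violates the documented format contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Design annotation for one RNA-seq sample."""

    sample_id: str
    genotype: str
    time_h: float
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(
                f"sample {self.sample_id!r}: genotype must be one of "
                f"{GENOTYPES}, got {self.genotype!r}"
            )
        if self.time_h < 0:
            raise FormatError(f"sample {self.sample_id!r}: negative time_h")
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples FPKM values with the experimental design attached.

    ``values`` is a DataFrame indexed by transcript id with one column per
    sample, column order canonicalized to (genotype, time_h, replicate).
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate transcript ids: {dupes}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample_id in design")
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise FormatError(f"samples in design missing from table: {missing}")
        order = sorted(
            self.samples, key=lambda s: (s.genotype, s.time_h, s.replicate)
        )
        self.samples = order
        self.values = self.values[[s.sample_id for s in order]]
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative FPKM at transcript {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    # -- convenience views ------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self, genotype: str | None = None,
                   time_h: float | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if time_h is not None and s.time_h != time_h:
                continue
            out.append(s.sample_id)
        return out

    def times(self, genotype: str) -> np.ndarray:
        return np.array([s.time_h for s in self.samples if s.genotype == genotype])

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "genotype": [s.genotype for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [t for t in self.transcript_ids if t in set(transcript_ids)]
        return ExpressionMatrix(self.values.loc[ids].copy(), list(self.samples))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.samples))


@dataclass
class RegionSequences:
    """Per-transcript region sequences for one species (DNA, uppercase)."""

    transcript_id: str
    gene_id: str
    species: str
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, seq in self.regions.items():
            if region not in REGIONS:
                raise FormatError(
                    f"{self.transcript_id}: unknown region {region!r}"
                )
            bad = set(seq) - _DNA_OK
            if bad:
                raise FormatError(
                    f"{self.transcript_id}/{region}: illegal characters {sorted(bad)}"
                )

    def get(self, region: str) -> str:
        return self.regions.get(region, "")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T; reject anything outside A/C/G/T/N."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA_OK
    if bad:
        raise FormatError(f"illegal sequence characters: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# design + expression tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "time_h", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            genotype=row.genotype,
            time_h=float(row.time_h),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_design(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genotype": [s.genotype for s in samples],
            "time_h": [s.time_h for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_table(
    path: str | Path, design: Sequence[SampleMeta]
) -> ExpressionMatrix:
    """Read a TSV of FPKM values and attach the design.

    The first column must be ``transcript_id``; every sample in the design
    must appear as a column.  Non-numeric or negative cells raise
    :class:`FormatError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if df.columns[0] != "transcript_id":
        raise FormatError(
            f"{path}: first column must be 'transcript_id', got {df.columns[0]!r}"
        )
    df = df.set_index("transcript_id")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value at transcript {row!r}, sample {col!r}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: missing value at transcript {row!r}, sample {col!r}"
            )
        if (numeric < 0).any():
            row = df.index[(numeric < 0).to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: negative FPKM at transcript {row!r}, sample {col!r}"
            )
        df[col] = numeric.astype(float)
    return ExpressionMatrix(df, list(design))


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, precision: int = 9
) -> None:
    out = matrix.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format=f"%.{precision}g")


# ---------------------------------------------------------------------------
# region FASTA
# ---------------------------------------------------------------------------

def read_region_fasta(
    paths: Mapping[str, str | Path],
    species: str,
    header_delim: str = "|",
) -> dict[str, RegionSequences]:
    """Read one FASTA per region into RegionSequences keyed by transcript id.

    Headers are ``transcriptID<delim>geneID``.  Transcripts absent from a
    region's file get an empty string for that region; downstream scanners
    treat empty regions as having no sites.
    """
    records: dict[str, RegionSequences] = {}
    for region, path in paths.items():
        if region not in REGIONS:
            raise FormatError(f"unknown region {region!r}")
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split(header_delim)
            if len(parts) < 2:
                raise FormatError(
                    f"{path}: header {rec.id!r} lacks "
                    f"'transcript{header_delim}gene' structure"
                )
            tx, gene = parts[0], parts[1]
            if tx in seen:
                raise FormatError(f"{path}: duplicate transcript {tx!r}")
            seen.add(tx)
            seq = normalize_sequence(str(rec.seq))
            if tx not in records:
                records[tx] = RegionSequences(tx, gene, species, {})
            elif records[tx].gene_id != gene:
                raise FormatError(
                    f"{tx!r}: inconsistent gene id across region files"
                )
            records[tx].regions[region] = seq
    return records


def write_region_fasta(
    records: Iterable[RegionSequences],
    region: str,
    path: str | Path,
    header_delim: str = "|",
) -> None:
    out = []
    for rec in records:
        seq = rec.get(region)
        if not seq:
            continue
        out.append(
            SeqRecord(
                Seq(seq),
                id=f"{rec.transcript_id}{header_delim}{rec.gene_id}",
                description="",
            )
        )
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# miRNA table
# ---------------------------------------------------------------------------

def read_mirna_table(path: str | Path) -> list[MiRNA]:
    """Read (name, mature 5'->3' sequence, expression_rank) rows.

    T/U in the mature sequence are both accepted; seed fields are derived in
    the RNA alphabet.  Sequences shorter than 8 nt and duplicate names are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "sequence", "rank"}
    if not required <= set(df.columns):
        raise FormatError(f"miRNA table must have columns {sorted(required)}")
    if df["name"].duplicated().any():
        dupes = df["name"][df["name"].duplicated()].tolist()
        raise FormatError(f"duplicate miRNA names: {dupes}")
    out = []
    for row in df.itertuples():
        out.append(MiRNA(name=row.name, mature=row.sequence,
                         expression_rank=int(row.rank)))
    return out


def write_mirna_table(mirnas: Sequence[MiRNA], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [m.name for m in mirnas],
            "sequence": [m.mature for m in mirnas],
            "rank": [m.expression_rank for m in mirnas],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results / summaries
# ---------------------------------------------------------------------------

def write_json_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
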