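"""Ground-truthed synthetic inputs for the whole pipeline.

The generator draws per-transcript kinetics from the linearized birth-death
model dx/dt = B - D x (synthesis B, degradation D = d + m) and emits:

* WT and KO transcription-shutdown time courses: the noiseless value is
  X exp(-D t) with X = B/D the equilibrium abundance; observed FPKM adds
  multiplicative lognormal noise and a per-sample library scale factor;
* region sequences (5'UTR/CDS/exon/intron/3'UTR) for a focal species and
  ortholog species, with seed-match sites, poly(A) hexamers and AU-rich
  motifs planted according to per-transcript group labels;
* a truth table recording every parameter and label for recovery tests.

Effect model.  ``delta`` is the *apparent equilibrium* repression: the
KO/WT equilibrium ratio of a target is X_ko/X_wt = 1 + delta.  A
synthesis-degradation ``coupling_ratio`` c sets B_wt = c B_ko for targets,
which forces the true degradation ratio to D_wt/d = c (1 + delta).  With
c = 1 the decay-based and equilibrium-based effects coincide at delta; with
c = 2 and delta = 0.1 the equilibrium assay still reports 10% while the
true degradation increase is 120% — the bias the direct measurement is
designed to expose.

Basal decay d is gamma-distributed, rescaled so the density mode sits at
``d_mode`` (default 0.12/h) with a long right tail; the gamma shape (5)
reproduces a median/mode ratio of ~1.17 and keeps essentially all rates
below 0.4/h.  Normalization references are simulated as perfectly stable
transcripts (d = 0 by default, configurable).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, REGIONS, RegionSequences, SampleMeta
from .target_sites import MiRNA, TargetSite, seed_site_strings

SEED_GROUPS = ("8mer-1a", "7mer-m8", "7mer-1a")

TRUTH_COLUMNS = [
    "transcript_id", "gene_id", "species_focal", "is_reference",
    "d", "m", "B_wt", "B_ko", "X_wt", "X_ko",
    "is_target_utr3", "is_target_cds", "is_are",
    "seed_group", "apa_group", "cotarget_group", "utr_len_group",
    "utr3_length",
]


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the measured design: 2 genotypes x 4 time points
    (0/2/4/8 h) x 2 replicates, ~10% of transcripts targeted, a 10%
    apparent equilibrium effect, lognormal noise of sd 0.1 on the ln scale,
    and a right-skewed basal-decay distribution with mode 0.12/h.
    """

    n_transcripts: int = 2000
    n_references: int = 10
    target_fraction: float = 0.10
    cds_target_fraction: float = 0.05
    delta: float = 0.10                  # apparent equilibrium repression
    coupling_ratio: float = 1.0          # B_wt / B_ko for targets
    d_shape: float = 5.0
    d_mode: float = 0.12                 # per hour
    reference_decay: float = 0.0         # per hour
    reference_expression: tuple[float, float] = (100.0, 300.0)
    noise_sigma: float = 0.10            # lognormal sd on the ln scale
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    replicates: int = 2
    library_scale_range: tuple[float, float] = (0.5, 2.0)
    expression_log_mean: float = math.log(50.0)
    expression_log_sd: float = 0.8
    conservation_prob: float = 1.0
    focal_species: str = "dmel"
    ortholog_species: tuple[str, ...] = ("dsim", "dyak")
    cds_ortholog_species: tuple[str, ...] = ("dsim",)
    region_lengths: dict[str, int] = field(default_factory=lambda: {
        "UTR5": 200, "CDS": 900, "EXON": 300, "INTRON": 300, "UTR3": 500,
    })
    background_gc: float = 0.5
    multi_site_fraction: float = 0.10    # targets with > 1 site
    apa_fraction: float = 0.5
    cotarget_fraction: float = 0.5
    long_utr_fraction: float = 0.5
    are_fraction: float = 0.03
    n_background_mirnas: int = 25
    top_k_mirnas: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_fraction", "cds_target_fraction",
                     "conservation_prob", "multi_site_fraction",
                     "apa_fraction", "cotarget_fraction",
                     "long_utr_fraction", "are_fraction", "background_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if 0.0 not in self.times:
            raise ValueError("times must include 0 (the pre-shutdown sample)")
        if self.d_shape <= 1.0:
            raise ValueError("d_shape must exceed 1 so the gamma has a mode")
        if self.delta <= -1.0 or self.coupling_ratio <= 0:
            raise ValueError("invalid effect parameters")
        if self.n_transcripts < 1 or self.replicates < 1:
            raise ValueError("n_transcripts and replicates must be >= 1")

    @property
    def d_scale(self) -> float:
        # gamma mode = (shape - 1) * scale
        return self.d_mode / (self.d_shape - 1.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["times"] = list(self.times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for key in ("times", "ortholog_species", "cds_ortholog_species",
                    "library_scale_range", "reference_expression"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _rng(config: SimConfig, rng: np.random.Generator | None,
         offset: int) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.rng_seed + offset)


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def generate_mirnas(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[MiRNA], str]:
    """A focal 4-member cluster sharing a seed plus background miRNAs.

    Background miRNAs take expression ranks 1..n_background (the top-k of
    these drive the co-targeting label); the focal cluster is ranked below
    them, mirroring a moderately expressed family.  Returns the miRNA list
    and the focal family id.
    """
    rng = _rng(config, rng, 3)
    seeds: set[str] = set()

    def fresh_mature() -> str:
        while True:
            seq = "".join(rng.choice(list("ACGU"), size=22))
            if seq[1:8] not in seeds:
                seeds.add(seq[1:8])
                return seq

    focal_mature = fresh_mature()
    mirnas = []
    for i in range(4):
        tail = "".join(rng.choice(list("ACGU"), size=14))
        mirnas.append(MiRNA(
            name=f"mir-31{i}",
            mature=focal_mature[:8] + tail,
            expression_rank=config.n_background_mirnas + 1 + i,
        ))
    focal_family = mirnas[0].family_id
    for i in range(config.n_background_mirnas):
        mirnas.append(MiRNA(
            name=f"mir-bg{i + 1:02d}",
            mature=fresh_mature(),
            expression_rank=i + 1,
        ))
    return mirnas, focal_family


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def generate_truth(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-transcript kinetic parameters, flags and group labels."""
    rng = _rng(config, rng, 0)
    n = config.n_transcripts
    ids = [f"tx{i:05d}" for i in range(n)]
    genes = [f"g{i:05d}" for i in range(n)]

    d = rng.gamma(config.d_shape, config.d_scale, size=n)
    x_ko = rng.lognormal(config.expression_log_mean,
                         config.expression_log_sd, size=n)

    perm = rng.permutation(n)
    n_utr3 = int(round(n * config.target_fraction))
    n_cds = int(round(n * config.cds_target_fraction))
    utr3_idx = set(perm[:n_utr3].tolist())
    cds_idx = set(perm[n_utr3:n_utr3 + n_cds].tolist())

    is_target_utr3 = np.array([i in utr3_idx for i in range(n)])
    is_target_cds = np.array([i in cds_idx for i in range(n)])
    is_target = is_target_utr3 | is_target_cds

    # D_wt/d = c (1 + delta) for targets; B_wt = c B_ko for targets
    ratio = np.where(is_target,
                     config.coupling_ratio * (1.0 + config.delta), 1.0)
    m = d * (ratio - 1.0)
    b_ko = x_ko * d
    b_wt = np.where(is_target, config.coupling_ratio * b_ko, b_ko)
    x_wt = b_wt / (d + m)

    is_are = rng.random(n) < config.are_fraction

    seed_group = np.array(["none"] * n, dtype=object)
    apa_group = np.array(["noAPA"] * n, dtype=object)
    cotarget_group = np.array(["low"] * n, dtype=object)
    utr_len_group = np.array(["long"] * n, dtype=object)
    base_len = config.region_lengths["UTR3"]
    utr3_length = np.full(n, base_len)

    non_target_pool = [i for i in range(n) if not is_target[i]]
    pool_pos = 0
    for i in sorted(utr3_idx):
        if rng.random() < config.multi_site_fraction:
            seed_group[i] = "multi"
        else:
            seed_group[i] = SEED_GROUPS[rng.integers(len(SEED_GROUPS))]
        apa_group[i] = "APA" if rng.random() < config.apa_fraction else "noAPA"
        cotarget_group[i] = ("high" if rng.random() < config.cotarget_fraction
                             else "low")
        if rng.random() < config.long_utr_fraction:
            utr_len_group[i] = "long"
        elif pool_pos < len(non_target_pool):
            # a 'short' target shares a gene with a longer non-target isoform
            utr_len_group[i] = "short"
            partner = non_target_pool[pool_pos]
            pool_pos += 1
            genes[partner] = genes[i]
            utr3_length[i] = int(base_len * 0.6)
            utr3_length[partner] = base_len
        else:
            utr_len_group[i] = "long"

    df = pd.DataFrame({
        "transcript_id": ids,
        "gene_id": genes,
        "species_focal": config.focal_species,
        "is_reference": False,
        "d": d,
        "m": m,
        "B_wt": b_wt,
        "B_ko": b_ko,
        "X_wt": x_wt,
        "X_ko": x_ko,
        "is_target_utr3": is_target_utr3,
        "is_target_cds": is_target_cds,
        "is_are": is_are,
        "seed_group": seed_group,
        "apa_group": apa_group,
        "cotarget_group": cotarget_group,
        "utr_len_group": utr_len_group,
        "utr3_length": utr3_length,
    })

    # perfectly stable normalization references
    ref_x = rng.uniform(*config.reference_expression,
                        size=config.n_references)
    refs = pd.DataFrame({
        "transcript_id": [f"ref{i:03d}" for i in range(config.n_references)],
        "gene_id": [f"gref{i:03d}" for i in range(config.n_references)],
        "species_focal": config.focal_species,
        "is_reference": True,
        "d": config.reference_decay,
        "m": 0.0,
        "B_wt": ref_x * config.reference_decay,
        "B_ko": ref_x * config.reference_decay,
        "X_wt": ref_x,
        "X_ko": ref_x,
        "is_target_utr3": False,
        "is_target_cds": False,
        "is_are": False,
        "seed_group": "none",
        "apa_group": "noAPA",
        "cotarget_group": "low",
        "utr_len_group": "long",
        "utr3_length": base_len,
    })
    return pd.concat([df, refs], ignore_index=True)[TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# expression time courses
# ---------------------------------------------------------------------------

def simulate_timecourse(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Observed FPKM = X exp(-D t) x lognormal noise x library scale factor."""
    rng = _rng(config, rng, 1)
    samples = []
    for genotype in ("WT", "KO"):
        for t in config.times:
            for rep in range(1, config.replicates + 1):
                samples.append(SampleMeta(
                    sample_id=f"{genotype}_t{t:g}_r{rep}",
                    genotype=genotype, time_h=float(t), replicate=rep,
                ))
    lo, hi = config.library_scale_range
    if lo == hi:
        factors = np.full(len(samples), float(lo))
    else:
        factors = rng.uniform(lo, hi, size=len(samples))

    d = truth["d"].to_numpy()
    m = truth["m"].to_numpy()
    x_wt = truth["X_wt"].to_numpy()
    x_ko = truth["X_ko"].to_numpy()
    n = len(truth)

    cols = {}
    for j, s in enumerate(samples):
        if s.genotype == "WT":
            mean = x_wt * np.exp(-(d + m) * s.time_h)
        else:
            mean = x_ko * np.exp(-d * s.time_h)
        cols[s.sample_id] = mean * factors[j]
    values = pd.DataFrame(cols, index=pd.Index(truth["transcript_id"],
                                               name="transcript_id"))
    if config.noise_sigma > 0:
        noise = rng.lognormal(0.0, config.noise_sigma,
                              size=(n, len(samples)))
        values = values * noise
    return ExpressionMatrix(values, samples)


# ---------------------------------------------------------------------------
# sequences with planted features
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _plant(seq: str, insert: str, pos: int) -> str:
    return seq[:pos] + insert + seq[pos + len(insert):]


def _free_position(
    rng: np.random.Generator, lo: int, hi: int, length: int,
    occupied: list[tuple[int, int]], tries: int = 100,
) -> int:
    """A start in [lo, hi] whose [start, start+length) avoids occupied spans."""
    if hi < lo:
        raise ValueError("region too short for the requested plant")
    for _ in range(tries):
        p = int(rng.integers(lo, hi + 1))
        if all(p + length <= a or p >= b for a, b in occupied):
            occupied.append((p, p + length))
            return p
    raise ValueError("could not place a non-overlapping feature")


def generate_region_sequences(
    truth: pd.DataFrame,
    mirnas: Sequence[MiRNA],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, RegionSequences],
           dict[str, dict[str, RegionSequences]],
           list[TargetSite]]:
    """Focal and ortholog region sequences with planted features.

    Returns (focal records, {species: records}, planted focal sites).
    Backgrounds are i.i.d. nucleotides; planted features overwrite the
    background in place and accidental background matches are deliberately
    left alone (the truth table records planted labels only).
    """
    rng = _rng(config, rng, 2)
    focal_family = mirnas[0].family_id
    family_strings = seed_site_strings(mirnas[0])
    top_bg = sorted(
        (m for m in mirnas if m.family_id != focal_family),
        key=lambda m: m.expression_rank,
    )[: config.top_k_mirnas]
    if not top_bg:
        raise ValueError("need background miRNAs for co-targeting plants")

    species_list = [config.focal_species, *config.ortholog_species]
    focal: dict[str, RegionSequences] = {}
    orthologs: dict[str, dict[str, RegionSequences]] = {
        sp: {} for sp in config.ortholog_species
    }
    planted: list[TargetSite] = []

    for row in truth.itertuples(index=False):
        tx = row.transcript_id
        lengths = dict(config.region_lengths)
        lengths["UTR3"] = int(row.utr3_length)
        per_species = {}
        for sp in species_list:
            regions = {r: _random_seq(rng, lengths[r], config.background_gc)
                       for r in REGIONS}
            per_species[sp] = regions

        if row.is_target_utr3:
            site_types = ([row.seed_group] if row.seed_group != "multi"
                          else list(rng.choice(SEED_GROUPS, size=2)))
            occupied: list[tuple[int, int]] = []
            l3 = lengths["UTR3"]
            first_start = None
            for st in site_types:
                site = family_strings[st]
                pos = _free_position(rng, 150, l3 - len(site) - 1,
                                     len(site), occupied)
                per_species[config.focal_species]["UTR3"] = _plant(
                    per_species[config.focal_species]["UTR3"], site, pos)
                planted.append(TargetSite(tx, "UTR3", pos, pos + len(site),
                                          st, focal_family))
                if first_start is None or pos < first_start:
                    first_start = pos
                for sp in config.ortholog_species:
                    if rng.random() < config.conservation_prob:
                        opos = int(rng.integers(10, l3 - len(site)))
                        per_species[sp]["UTR3"] = _plant(
                            per_species[sp]["UTR3"], site, opos)
            if row.apa_group == "APA":
                hexamer = ("AATAAA", "ATTAAA")[int(rng.integers(2))]
                pos = _free_position(rng, 10, first_start - 26, 6, occupied)
                per_species[config.focal_species]["UTR3"] = _plant(
                    per_species[config.focal_species]["UTR3"], hexamer, pos)
            if row.cotarget_group == "high":
                bg = top_bg[int(rng.integers(len(top_bg)))]
                site = seed_site_strings(bg)["7mer-m8"]
                pos = _free_position(rng, 10, l3 - len(site) - 1,
                                     len(site), occupied)
                per_species[config.focal_species]["UTR3"] = _plant(
                    per_species[config.focal_species]["UTR3"], site, pos)

        if row.is_target_cds:
            st = SEED_GROUPS[int(rng.integers(len(SEED_GROUPS)))]
            site = family_strings[st]
            lc = lengths["CDS"]
            pos = int(rng.integers(10, lc - len(site)))
            per_species[config.focal_species]["CDS"] = _plant(
                per_species[config.focal_species]["CDS"], site, pos)
            planted.append(TargetSite(tx, "CDS", pos, pos + len(site),
                                      st, focal_family))
            for sp in config.ortholog_species:
                if rng.random() < config.conservation_prob:
                    opos = int(rng.integers(10, lc - len(site)))
                    per_species[sp]["CDS"] = _plant(
                        per_species[sp]["CDS"], site, opos)

        if row.is_are:
            for region in REGIONS:
                pos = int(rng.integers(0, lengths[region] - 5))
                per_species[config.focal_species][region] = _plant(
                    per_species[config.focal_species][region], "ATTTA", pos)

        focal[tx] = RegionSequences(tx, row.gene_id, config.focal_species,
                                    per_species[config.focal_species])
        for sp in config.ortholog_species:
            orthologs[sp][tx] = RegionSequences(tx, row.gene_id, sp,
                                                per_species[sp])
    return focal, orthologs, planted


# ---------------------------------------------------------------------------
# truth report / dataset bundle
# ---------------------------------------------------------------------------

def truth_report(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class SyntheticDataset:
    """Everything one simulator run produces."""

    config: SimConfig
    truth: pd.DataFrame
    matrix: ExpressionMatrix
    mirnas: list[MiRNA]
    focal_family: str
    focal: dict[str, RegionSequences]
    orthologs: dict[str, dict[str, RegionSequences]]
    planted_sites: list[TargetSite]


def simulate_dataset(
    config: SimConfig, sequences: bool = True
) -> SyntheticDataset:
    """One deterministic end-to-end draw under config.rng_seed."""
    truth = generate_truth(config)
    matrix = simulate_timecourse(truth, config)
    mirnas, focal_family = generate_mirnas(config)
    if sequences:
        focal, orthologs, planted = generate_region_sequences(
            truth, mirnas, config)
    else:
        focal, orthologs, planted = {}, {}, []
    return SyntheticDataset(config, truth, matrix, mirnas, focal_family,
                            focal, orthologs, planted)
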