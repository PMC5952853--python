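"""Decay-rate estimation from transcription-shutdown time courses.

After transcription is chemically shut down (synthesis B -> 0), transcript
abundance follows dx/dt = -D x, so x(t) = X exp(-D t) and

    ln x(t) = ln(B/D) - D t

with D = d + m in the wild type (basal decay d plus the miRNA contribution
m) and D = d in the miRNA-knockout background.  D is therefore the
sign-flipped slope of the ordinary least-squares regression of ln(FPKM) on
time, with every replicate entering as its own point.

Because the equilibrium abundance X = B/D couples synthesis into the usual
expression-level comparison, the equilibrium ratio X*/X understates the
degradation ratio whenever synthesis differs between backgrounds:
D/d = (X*/X) (B/B*).  ``implied_degradation_ratio`` evaluates that identity.

Supporting steps: reference-transcript cross-sample normalization
(geometric-mean scale factors anchored at each genotype's t = 0 samples),
half-life conversion, the FPKM >= 5 / half-life <= 15 h filters, and
normalization of decay rates by their genotype's kernel-density mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GENOTYPES


@dataclass(frozen=True)
class DecayFit:
    """Per-transcript, per-genotype log-linear fit."""

    transcript_id: str
    genotype: str
    D: float            # decay rate per hour (= -slope)
    intercept: float    # fitted ln(FPKM) at t = 0
    half_life_h: float
    n_points: int
    r2: float


@dataclass
class NormalizedDecayTable:
    """Mode-normalized decay rates for transcripts kept in both genotypes."""

    table: pd.DataFrame  # index transcript_id; D_wt, D_ko, D_wt_norm, D_ko_norm
    mode_wt: float
    mode_ko: float

    @property
    def kept_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class EquilibriumRecord:
    """Mean normalized FPKM at t = 0 per genotype (the equilibrium X)."""

    transcript_id: str
    X_wt: float
    X_ko: float


# ---------------------------------------------------------------------------
# reference selection and cross-sample normalization
# ---------------------------------------------------------------------------

def select_references(
    matrix: ExpressionMatrix, candidate_ids: Iterable[str], k: int
) -> list[str]:
    """The k candidates with the smallest coefficient of variation of FPKM
    across all samples (both genotypes pooled); ties break lexicographically.
    """
    candidates = sorted(set(candidate_ids))
    missing = [c for c in candidates if c not in matrix.values.index]
    if missing:
        raise ValueError(f"candidates not in matrix: {missing}")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    sub = matrix.values.loc[candidates]
    mean = sub.mean(axis=1)
    if (mean <= 0).any():
        raise ValueError("reference candidates must have positive mean FPKM")
    cv = sub.std(axis=1, ddof=1) / mean
    order = sorted(candidates, key=lambda c: (cv[c], c))
    return order[:k]


def normalize_samples(
    matrix: ExpressionMatrix, reference_ids: Sequence[str]
) -> ExpressionMatrix:
    """Divide each sample's column by its reference scale factor.

    The factor for sample s is geomean(refs in s) / anchor, where the anchor
    is the geometric mean over ALL t = 0 samples (both genotypes) of their
    per-sample reference geometric means.  A single anchor is what makes
    WT-vs-KO expression ratios meaningful: the references are assumed
    equally expressed in both genotypes, so after the operation their
    geometric mean is identical across every sample, and re-applying the
    operation is a no-op.
    """
    refs = list(reference_ids)
    vals = matrix.values
    missing = [r for r in refs if r not in vals.index]
    if missing:
        raise ValueError(f"references not in matrix: {missing}")
    ref_vals = vals.loc[refs]
    if (ref_vals.to_numpy() <= 0).any():
        bad = ref_vals.columns[(ref_vals <= 0).any(axis=0)][0]
        raise ValueError(
            f"reference FPKM must be strictly positive in every sample "
            f"(violated in sample {bad!r})"
        )
    log_gm = np.log(ref_vals).mean(axis=0)  # per-sample ln geomean
    for genotype in GENOTYPES:
        if matrix.sample_ids(genotype=genotype) and \
                not matrix.sample_ids(genotype=genotype, time_h=0.0):
            raise ValueError(f"no t=0 sample for genotype {genotype}")
    t0_cols = matrix.sample_ids(time_h=0.0)
    anchor = log_gm[t0_cols].mean()
    factors = np.exp(log_gm - anchor)
    out = vals / factors
    return ExpressionMatrix(out, list(matrix.samples))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_decay(
    matrix: ExpressionMatrix, transcript_id: str, genotype: str
) -> DecayFit:
    """OLS of ln(FPKM) on time for one transcript in one genotype.

    All replicate points enter individually.  Requires strictly positive
    FPKM (apply the expression filter first) and >= 3 points.
    """
    cols = matrix.sample_ids(genotype=genotype)
    if len(cols) < 3:
        raise ValueError(f"need >= 3 points, got {len(cols)}")
    x = matrix.values.loc[transcript_id, cols].to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError(
            f"{transcript_id}/{genotype}: non-positive FPKM; filter low-"
            f"expression transcripts before fitting"
        )
    t = matrix.times(genotype)
    y = np.log(x)
    slope, intercept, r2 = _ols_line(t, y)
    D = -slope
    return DecayFit(
        transcript_id=transcript_id,
        genotype=genotype,
        D=D,
        intercept=intercept,
        half_life_h=half_life(D),
        n_points=len(cols),
        r2=r2,
    )


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    tbar = t.mean()
    ybar = y.mean()
    stt = float(((t - tbar) ** 2).sum())
    if stt == 0:
        raise ValueError("time points are all identical")
    slope = float(((t - tbar) * (y - ybar)).sum() / stt)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0  # constant series fitted exactly by a flat line
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_all(
    matrix: ExpressionMatrix,
    genotype: str,
    transcript_ids: Iterable[str] | None = None,
) -> dict[str, DecayFit]:
    """fit_decay over a set of transcripts, skipping non-positive series."""
    ids = list(transcript_ids) if transcript_ids is not None \
        else matrix.transcript_ids
    cols = matrix.sample_ids(genotype=genotype)
    sub = matrix.values.loc[ids, cols]
    positive = (sub > 0).all(axis=1)
    out: dict[str, DecayFit] = {}
    for tx in sub.index[positive]:
        out[tx] = fit_decay(matrix, tx, genotype)
    return out


def half_life(D: float) -> float:
    """ln(2)/D in hours; +inf for non-decaying (D <= 0) transcripts."""
    if D <= 0:
        return math.inf
    return math.log(2) / D


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(
    matrix: ExpressionMatrix,
    fits: Mapping[str, DecayFit] | Iterable[DecayFit],
    min_fpkm: float = 5.0,
    max_halflife_h: float = 15.0,
) -> set[str]:
    """Transcripts with FPKM >= min_fpkm in every sample of the fit's
    genotype and half-life <= max_halflife_h.  Boundaries are inclusive.

    Long half-lives are poorly constrained over an 8 h chase and low-FPKM
    series are dominated by measurement noise, so both tails are dropped.
    """
    fit_list = list(fits.values()) if isinstance(fits, Mapping) else list(fits)
    kept: set[str] = set()
    cols_by_genotype = {g: matrix.sample_ids(genotype=g) for g in GENOTYPES}
    # inclusive boundaries, with a hair of float slack so that a series
    # sitting exactly on a threshold survives round-off in the regression
    fpkm_cut = min_fpkm * (1.0 - 1e-9)
    hl_cut = max_halflife_h * (1.0 + 1e-9)
    for fit in fit_list:
        cols = cols_by_genotype[fit.genotype]
        vals = matrix.values.loc[fit.transcript_id, cols]
        if (vals >= fpkm_cut).all() and fit.half_life_h <= hl_cut:
            kept.add(fit.transcript_id)
    return kept


# ---------------------------------------------------------------------------
# mode estimation and mode normalization
# ---------------------------------------------------------------------------

def mode_1d(values: Sequence[float] | np.ndarray) -> float:
    """Most frequent value: argmax of a Gaussian KDE (Silverman bandwidth)
    on a 512-point uniform grid over [min, max]."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("mode_1d needs >= 2 values")
    if not np.isfinite(v).all():
        raise ValueError("mode_1d requires finite values")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return float(lo)
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def normalize_by_mode(
    fits_by_genotype: Mapping[str, Mapping[str, DecayFit]],
    kept_ids: Iterable[str] | None = None,
) -> NormalizedDecayTable:
    """Divide each decay rate by its own genotype's background KDE mode.

    The mode is estimated from all kept transcripts of that genotype; the
    table is restricted to transcripts kept in both genotypes so that both
    D (WT) and d (KO) are estimable.
    """
    wt = fits_by_genotype["WT"]
    ko = fits_by_genotype["KO"]
    ids = sorted(set(wt) & set(ko))
    if kept_ids is not None:
        ids = [i for i in ids if i in set(kept_ids)]
    if not ids:
        raise ValueError("no transcripts kept in both genotypes")
    mode_wt = mode_1d([wt[i].D for i in ids])
    mode_ko = mode_1d([ko[i].D for i in ids])
    if mode_wt <= 0 or mode_ko <= 0:
        raise ValueError(
            f"non-positive background mode (WT {mode_wt:.4g}, KO {mode_ko:.4g})"
        )
    table = pd.DataFrame(
        {
            "D_wt": [wt[i].D for i in ids],
            "D_ko": [ko[i].D for i in ids],
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    table["D_wt_norm"] = table["D_wt"] / mode_wt
    table["D_ko_norm"] = table["D_ko"] / mode_ko
    return NormalizedDecayTable(table, mode_wt, mode_ko)


# ---------------------------------------------------------------------------
# equilibrium expression and the synthesis-coupling identity
# ---------------------------------------------------------------------------

def equilibrium_expression(
    matrix: ExpressionMatrix,
    transcript_ids: Iterable[str] | None = None,
) -> list[EquilibriumRecord]:
    """X per genotype = arithmetic mean of (normalized) FPKM over the t = 0
    replicates — the pre-shutdown sample is the equilibrium observation."""
    ids = list(transcript_ids) if transcript_ids is not None \
        else matrix.transcript_ids
    out = []
    t0 = {}
    for genotype in GENOTYPES:
        cols = matrix.sample_ids(genotype=genotype, time_h=0.0)
        if not cols:
            raise ValueError(f"no t=0 sample for genotype {genotype}")
        t0[genotype] = matrix.values[cols].mean(axis=1)
    for tx in ids:
        out.append(EquilibriumRecord(tx, float(t0["WT"][tx]), float(t0["KO"][tx])))
    return out


def implied_degradation_ratio(eq_ratio: float, synth_ratio: float) -> float:
    """D/d implied by the identity D/d = (X*/X) (B/B*).

    ``eq_ratio`` is the KO/WT equilibrium-expression ratio X*/X;
    ``synth_ratio`` is the WT/KO synthesis ratio B/B*.  With B/B* = 1 this
    reduces to the conventional equilibrium-only estimate; any synthesis
    coupling multiplies the true degradation ratio accordingly.
    """
    if eq_ratio <= 0 or synth_ratio <= 0:
        raise ValueError("ratios must be strictly positive")
    return eq_ratio * synth_ratio


def decay_table_frame(
    fits_by_genotype: Mapping[str, Mapping[str, DecayFit]],
    normalized: NormalizedDecayTable | None = None,
    kept: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Flat per-transcript/per-genotype table for the decay TSV output."""
    kept_set = set(kept) if kept is not None else None
    rows = []
    for genotype, fits in fits_by_genotype.items():
        for tx, fit in fits.items():
            row = {
                "transcript_id": tx,
                "genotype": genotype,
                "D": fit.D,
                "intercept": fit.intercept,
                "half_life_h": fit.half_life_h,
                "r2": fit.r2,
                "n_points": fit.n_points,
                "kept": kept_set is None or tx in kept_set,
            }
            if normalized is not None and tx in normalized.table.index:
                col = "D_wt_norm" if genotype == "WT" else "D_ko_norm"
                row["D_normalized"] = normalized.table.loc[tx, col]
            else:
                row["D_normalized"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["genotype", "transcript_id"]).reset_index(drop=True)
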