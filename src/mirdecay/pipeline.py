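"""Stage orchestration: simulate -> fit -> targets -> compare.

Each stage reads and writes plain files under one output directory so the
pipeline is re-runnable from intermediates; the in-memory helpers
(`run_decay_analysis`, `compare_targets`, `bias_demo`) carry the same logic
for library use.  The WT-vs-KO transcript universe is the intersection of
the per-genotype kept sets: both the WT decay rate D = d + m and the KO
rate d must be estimable for a transcript to enter a comparison.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import decay_model, group_compare, motif_scan, synthetic_data, target_sites
from .io_formats import (
    ExpressionMatrix,
    REGIONS,
    RegionSequences,
    read_design,
    read_expression_table,
    read_mirna_table,
    read_region_fasta,
    write_design,
    write_expression_table,
    write_json_summary,
    write_mirna_table,
    write_region_fasta,
)
from .synthetic_data import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds for the fit/compare stages (defaults = study values)."""

    min_fpkm: float = 5.0
    max_halflife_h: float = 15.0
    n_references: int = 10
    top_expressed_n: int | None = None
    n_extremes: int = 200
    top_k_mirnas: int = 20
    kde_grid_n: int = 100
    reference_candidates: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig.from_dict(raw.get("sim", {})) if "sim" in raw \
            else SimConfig()
        analysis = AnalysisConfig(**raw.get("analysis", {}))
        return cls(sim=sim, analysis=analysis)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "sim": self.sim.to_dict(),
            "analysis": {
                "min_fpkm": self.analysis.min_fpkm,
                "max_halflife_h": self.analysis.max_halflife_h,
                "n_references": self.analysis.n_references,
                "top_expressed_n": self.analysis.top_expressed_n,
                "n_extremes": self.analysis.n_extremes,
                "top_k_mirnas": self.analysis.top_k_mirnas,
                "kde_grid_n": self.analysis.kde_grid_n,
                "reference_candidates": list(self.analysis.reference_candidates),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------

@dataclass
class DecayAnalysis:
    """Everything the fit stage produces, in memory."""

    normalized_matrix: ExpressionMatrix
    reference_ids: list[str]
    fits_wt: dict[str, decay_model.DecayFit]
    fits_ko: dict[str, decay_model.DecayFit]
    kept_wt: set[str]
    kept_ko: set[str]
    kept: set[str]
    normalized: decay_model.NormalizedDecayTable
    equilibrium: pd.DataFrame  # index transcript_id; X_wt, X_ko


def run_decay_analysis(
    matrix: ExpressionMatrix,
    reference_candidates: Sequence[str],
    analysis: AnalysisConfig | None = None,
) -> DecayAnalysis:
    """normalize -> fit (both genotypes) -> filter -> mode-normalize."""
    analysis = analysis or AnalysisConfig()
    k = min(analysis.n_references, len(list(reference_candidates)))
    refs = decay_model.select_references(matrix, reference_candidates, k)
    norm = decay_model.normalize_samples(matrix, refs)
    fits_wt = decay_model.fit_all(norm, "WT")
    fits_ko = decay_model.fit_all(norm, "KO")
    kept_wt = decay_model.apply_filters(
        norm, fits_wt, analysis.min_fpkm, analysis.max_halflife_h)
    kept_ko = decay_model.apply_filters(
        norm, fits_ko, analysis.min_fpkm, analysis.max_halflife_h)
    kept = kept_wt & kept_ko
    if analysis.top_expressed_n is not None:
        n = min(analysis.top_expressed_n, len(norm.transcript_ids))
        kept &= group_compare.top_expressed(norm, n)
    normalized = decay_model.normalize_by_mode(
        {"WT": fits_wt, "KO": fits_ko}, kept)
    eq_records = decay_model.equilibrium_expression(norm)
    eq = pd.DataFrame(
        {"X_wt": [r.X_wt for r in eq_records],
         "X_ko": [r.X_ko for r in eq_records]},
        index=pd.Index([r.transcript_id for r in eq_records],
                       name="transcript_id"),
    )
    return DecayAnalysis(norm, refs, fits_wt, fits_ko, kept_wt, kept_ko,
                         kept, normalized, eq)


_GROUPINGS = {
    "seed": ("seed_group", ("8mer-1a", "7mer-m8", "7mer-1a")),
    "apa": ("apa_group", ("APA", "noAPA")),
    "cotarget": ("cotarget_group", ("high", "low")),
    "utr_len": ("utr_len_group", ("long", "short")),
}


def compare_targets(
    analysis: DecayAnalysis,
    classifications: Mapping[str, target_sites.TargetClassification],
    region: str = "UTR3",
    grid_n: int = 100,
) -> dict:
    """The full WT-vs-KO statistics block for one target region.

    Cohort level: change of medians for equilibrium expression and for
    mode-normalized decay rates, ECDF tables, and the densest point of the
    2D decay-rate KDE.  Group level (3'UTR targets only): median of
    per-target changes per binary group, with rank-sum p-values between
    groups.
    """
    flag = "is_target_utr3" if region == "UTR3" else "is_target_cds"
    targets = sorted(
        tx for tx, c in classifications.items()
        if getattr(c, flag) and tx in analysis.kept
    )
    if not targets:
        raise ValueError(f"no kept {region} targets to compare")
    tbl = analysis.normalized.table.loc[targets]
    eq = analysis.equilibrium.loc[targets]

    results = []
    results.append(group_compare.change_of_medians(
        eq["X_wt"], eq["X_ko"], "equilibrium",
        name=f"{region}:equilibrium_medians"))
    results.append(group_compare.change_of_medians(
        tbl["D_wt_norm"], tbl["D_ko_norm"], "degradation",
        name=f"{region}:degradation_medians"))
    results.append(group_compare.median_of_changes(
        eq["X_wt"], eq["X_ko"], "equilibrium",
        name=f"{region}:equilibrium_per_target"))
    results.append(group_compare.median_of_changes(
        tbl["D_wt_norm"], tbl["D_ko_norm"], "degradation",
        name=f"{region}:degradation_per_target"))

    mode2d = group_compare.kde2d_mode(
        np.column_stack([tbl["D_wt_norm"], tbl["D_ko_norm"]]), grid_n=grid_n)
    mode_change = group_compare.percent_change(mode2d.x, mode2d.y)

    ecdfs = {
        "equilibrium_change": group_compare.ecdf(
            group_compare.per_pair_changes(eq["X_wt"], eq["X_ko"],
                                           "equilibrium")),
        "degradation_change": group_compare.ecdf(
            group_compare.per_pair_changes(tbl["D_wt_norm"], tbl["D_ko_norm"],
                                           "degradation")),
    }

    group_results = []
    if region == "UTR3":
        eq_changes = pd.Series(
            group_compare.per_pair_changes(eq["X_wt"], eq["X_ko"],
                                           "equilibrium"), index=targets)
        deg_changes = pd.Series(
            group_compare.per_pair_changes(tbl["D_wt_norm"], tbl["D_ko_norm"],
                                           "degradation"), index=targets)
        for gname, (attr, levels) in _GROUPINGS.items():
            members = {
                lvl: [tx for tx in targets
                      if getattr(classifications[tx], attr) == lvl]
                for lvl in levels
            }
            for orientation, changes in (("equilibrium", eq_changes),
                                         ("degradation", deg_changes)):
                for lvl, txs in members.items():
                    if not txs:
                        continue
                    group_results.append(group_compare.ComparisonResult(
                        statistic_name=f"{region}:{gname}:{lvl}:{orientation}",
                        wt_value=float("nan"), ko_value=float("nan"),
                        percent_change=float(np.median(changes[txs])),
                        group_labels=(gname, lvl),
                        n_per_group=(len(txs), len(txs)),
                    ))
                for a, b in _pairs(levels):
                    if members[a] and members[b]:
                        p = group_compare.rank_sum_test(
                            changes[members[a]], changes[members[b]])
                        group_results.append(group_compare.ComparisonResult(
                            statistic_name=(f"{region}:{gname}:{a}-vs-{b}:"
                                            f"{orientation}:p"),
                            wt_value=float("nan"), ko_value=float("nan"),
                            percent_change=float("nan"), p_value=p,
                            group_labels=(a, b),
                            n_per_group=(len(members[a]), len(members[b])),
                        ))

    return {
        "region": region,
        "n_targets": len(targets),
        "target_ids": targets,
        "results": results,
        "group_results": group_results,
        "mode2d": mode2d,
        "mode_change": mode_change,
        "ecdfs": ecdfs,
    }


def _pairs(levels: Sequence[str]):
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            yield levels[i], levels[j]


def bias_demo(config: SimConfig,
              analysis: AnalysisConfig | None = None) -> dict:
    """Decay-based vs equilibrium-based repression on one simulated cohort.

    Simulates time courses under ``config``, fits decay in both genotypes
    after reference normalization, and summarizes the per-target effect two
    ways: the median WT/KO decay-rate change (direct) and the median KO/WT
    t = 0 expression change (the conventional equilibrium estimate).  With
    synthesis coupling the two diverge by the factor B_wt/B_ko.
    """
    dataset = synthetic_data.simulate_dataset(config, sequences=False)
    truth = dataset.truth
    refs = truth.loc[truth["is_reference"], "transcript_id"].tolist()
    analysis = analysis or AnalysisConfig()
    res = run_decay_analysis(dataset.matrix, refs, analysis)
    target_ids = truth.loc[
        (truth["is_target_utr3"] | truth["is_target_cds"]),
        "transcript_id"].tolist()
    usable = [tx for tx in target_ids
              if tx in res.fits_wt and tx in res.fits_ko and tx in res.kept]
    d_wt = np.array([res.fits_wt[tx].D for tx in usable])
    d_ko = np.array([res.fits_ko[tx].D for tx in usable])
    decay_change = float(np.median(d_wt / d_ko - 1.0))
    eq = res.equilibrium.loc[usable]
    eq_change = float(np.median(eq["X_ko"] / eq["X_wt"] - 1.0))
    return {
        "n_targets": len(usable),
        "decay_based_change": decay_change,
        "equilibrium_based_change": eq_change,
        "analysis": res,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Write all synthetic inputs (expression, design, sequences, miRNAs,
    truth) plus a manifest."""
    t0 = time.monotonic()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = synthetic_data.simulate_dataset(config.sim)
    write_expression_table(ds.matrix, out / "expression.tsv")
    write_design(ds.matrix.samples, out / "design.tsv")
    write_mirna_table(ds.mirnas, out / "mirnas.tsv")
    synthetic_data.truth_report(ds.truth, out / "truth.tsv")
    files = ["expression.tsv", "design.tsv", "mirnas.tsv", "truth.tsv"]
    for region in REGIONS:
        name = f"{config.sim.focal_species}_{region}.fa"
        write_region_fasta(ds.focal.values(), region, out / name)
        files.append(name)
        for sp, recs in ds.orthologs.items():
            name = f"{sp}_{region}.fa"
            write_region_fasta(recs.values(), region, out / name)
            files.append(name)
    planted = pd.DataFrame(
        [(s.transcript_id, s.region, s.start, s.end, s.site_type,
          s.family_id) for s in ds.planted_sites],
        columns=["transcript_id", "region", "start", "end", "site_type",
                 "family_id"],
    )
    planted.to_csv(out / "planted_sites.tsv", sep="\t", index=False)
    files.append("planted_sites.tsv")
    manifest = {
        "stage": "simulate",
        "seed": config.sim.rng_seed,
        "n_transcripts": int(len(ds.truth)),
        "focal_family": ds.focal_family,
        "files": sorted(files),
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    write_json_summary(manifest, out / "simulate_manifest.json")
    logger.info("simulate: wrote %d files to %s", len(files), out)
    return manifest


def _load_matrix(outdir: Path) -> ExpressionMatrix:
    design = read_design(outdir / "design.tsv")
    return read_expression_table(outdir / "expression.tsv", design)


def _reference_candidates(config: PipelineConfig, outdir: Path) -> list[str]:
    if config.analysis.reference_candidates:
        return list(config.analysis.reference_candidates)
    truth_path = outdir / "truth.tsv"
    if truth_path.exists():
        truth = synthetic_data.read_truth(truth_path)
        return truth.loc[truth["is_reference"], "transcript_id"].tolist()
    raise ValueError(
        "no reference candidates: set analysis.reference_candidates or "
        "provide a truth.tsv with is_reference flags"
    )


def cmd_fit(config: PipelineConfig, outdir: str | Path) -> dict:
    """Normalize, fit decay per genotype, filter, mode-normalize; write the
    decay tables and a summary."""
    t0 = time.monotonic()
    out = Path(outdir)
    matrix = _load_matrix(out)
    refs = _reference_candidates(config, out)
    res = run_decay_analysis(matrix, refs, config.analysis)
    table = decay_model.decay_table_frame(
        {"WT": res.fits_wt, "KO": res.fits_ko}, res.normalized, res.kept)
    table.to_csv(out / "decay_table.tsv", sep="\t", index=False,
                 float_format="%.9g")
    res.normalized.table.to_csv(out / "normalized_decay.tsv", sep="\t",
                                float_format="%.9g")
    res.equilibrium.to_csv(out / "equilibrium.tsv", sep="\t",
                           float_format="%.9g")
    summary = {
        "stage": "fit",
        "reference_ids": res.reference_ids,
        "min_fpkm": config.analysis.min_fpkm,
        "max_halflife_h": config.analysis.max_halflife_h,
        "mode_wt": res.normalized.mode_wt,
        "mode_ko": res.normalized.mode_ko,
        "n_fit_wt": len(res.fits_wt),
        "n_fit_ko": len(res.fits_ko),
        "n_kept_wt": len(res.kept_wt),
        "n_kept_ko": len(res.kept_ko),
        "n_kept_both": len(res.kept),
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    write_json_summary(summary, out / "fit_summary.json")
    logger.info("fit: %d/%d transcripts kept", len(res.kept),
                len(matrix.transcript_ids))
    return summary


def _load_regions(config: PipelineConfig, outdir: Path, species: str
                  ) -> dict[str, RegionSequences]:
    paths = {r: outdir / f"{species}_{r}.fa" for r in REGIONS
             if (outdir / f"{species}_{r}.fa").exists()}
    return read_region_fasta(paths, species)


def cmd_targets(config: PipelineConfig, outdir: str | Path) -> dict:
    """Scan sites, call conserved targets, classify groups, flag ARE
    transcripts; write site/classification tables."""
    t0 = time.monotonic()
    out = Path(outdir)
    mirnas = read_mirna_table(out / "mirnas.tsv")
    focal = _load_regions(config, out, config.sim.focal_species)
    orthologs = {sp: _load_regions(config, out, sp)
                 for sp in config.sim.ortholog_species}
    focal_family = [m for m in mirnas
                    if m.name in {"mir-310", "mir-311", "mir-312", "mir-313"}]
    family_id = focal_family[0].family_id if focal_family \
        else mirnas[0].family_id
    cls = target_sites.classify_targets(
        focal, orthologs, mirnas, family_id,
        cds_ortholog_species=list(config.sim.cds_ortholog_species),
        top_k=config.analysis.top_k_mirnas,
    )
    family = [m for m in mirnas if m.family_id == family_id]
    site_rows = []
    for tx, rec in focal.items():
        for region in ("UTR3", "CDS"):
            for s in target_sites.scan_sites(rec.get(region), family, tx,
                                             region):
                site_rows.append((s.transcript_id, s.start, s.end,
                                  s.site_type, s.family_id, s.region))
    pd.DataFrame(site_rows, columns=["transcript_id", "start", "end",
                                     "site_type", "family_id", "region"]
                 ).to_csv(out / "sites.tsv", sep="\t", index=False)
    cls_frame = pd.DataFrame([
        {"transcript_id": tx,
         "is_target_utr3": c.is_target_utr3,
         "is_target_cds": c.is_target_cds,
         "n_sites_utr3": c.n_sites_utr3,
         "seed_group": c.seed_group,
         "apa_group": c.apa_group,
         "cotarget_group": c.cotarget_group,
         "utr_len_group": c.utr_len_group}
        for tx, c in sorted(cls.items())
    ])
    cls_frame.to_csv(out / "classifications.tsv", sep="\t", index=False)
    are_flagged = motif_scan.flag_are_transcripts(focal.values())
    pd.DataFrame({"transcript_id": sorted(are_flagged)}).to_csv(
        out / "are_flags.tsv", sep="\t", index=False)
    summary = {
        "stage": "targets",
        "focal_family": family_id,
        "n_sites": len(site_rows),
        "n_targets_utr3": int(cls_frame["is_target_utr3"].sum()),
        "n_targets_cds": int(cls_frame["is_target_cds"].sum()),
        "n_are_flagged": len(are_flagged),
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    write_json_summary(summary, out / "targets_summary.json")
    logger.info("targets: %d 3'UTR, %d CDS targets",
                summary["n_targets_utr3"], summary["n_targets_cds"])
    return summary


def cmd_compare(config: PipelineConfig, outdir: str | Path) -> dict:
    """Compute the comparison statistics from the fit + targets outputs."""
    t0 = time.monotonic()
    out = Path(outdir)
    matrix = _load_matrix(out)
    refs = _reference_candidates(config, out)
    res = run_decay_analysis(matrix, refs, config.analysis)
    cls_frame = pd.read_csv(out / "classifications.tsv", sep="\t")
    cls = {
        row.transcript_id: target_sites.TargetClassification(
            transcript_id=row.transcript_id,
            is_target_utr3=bool(row.is_target_utr3),
            is_target_cds=bool(row.is_target_cds),
            n_sites_utr3=int(row.n_sites_utr3),
            seed_group=row.seed_group,
            apa_group=row.apa_group,
            cotarget_group=row.cotarget_group,
            utr_len_group=row.utr_len_group,
        )
        for row in cls_frame.itertuples(index=False)
    }
    report: dict = {
        "stage": "compare",
        "config": {"sim": config.sim.to_dict()},
        "modes": {"wt": res.normalized.mode_wt, "ko": res.normalized.mode_ko},
        "counts": {
            "transcripts": len(matrix.transcript_ids),
            "kept_both": len(res.kept),
        },
        "comparisons": {},
    }
    all_results = []
    for region in ("UTR3", "CDS"):
        try:
            block = compare_targets(res, cls, region,
                                    grid_n=config.analysis.kde_grid_n)
        except ValueError:
            logger.warning("compare: no kept %s targets", region)
            continue
        all_results.extend(block["results"])
        all_results.extend(block["group_results"])
        report["comparisons"][region] = {
            "n_targets": block["n_targets"],
            "mode2d": {"wt": block["mode2d"].x, "ko": block["mode2d"].y},
            "mode_change": block["mode_change"],
            "statistics": [
                {"name": r.statistic_name, "wt": r.wt_value,
                 "ko": r.ko_value, "percent_change": r.percent_change,
                 "p_value": r.p_value}
                for r in block["results"] + block["group_results"]
            ],
        }
        for key, steps in block["ecdfs"].items():
            pd.DataFrame(steps, columns=["value", "cumulative_fraction"]
                         ).to_csv(out / f"ecdf_{region}_{key}.tsv", sep="\t",
                                  index=False)
    group_compare.comparison_frame(all_results).to_csv(
        out / "comparisons.tsv", sep="\t", index=False, float_format="%.9g")
    report["elapsed_s"] = round(time.monotonic() - t0, 3)
    write_json_summary(report, out / "run_report.json")
    return report


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    cmd_simulate(config, outdir)
    cmd_fit(config, outdir)
    cmd_targets(config, outdir)
    return cmd_compare(config, outdir)
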