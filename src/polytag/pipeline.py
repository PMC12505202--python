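"""End-to-end pipeline: chained stages with config, logging and reports.

Every stage writes a TSV report plus one structured log line with its
input/output record counts, so removal/retention narratives can be diffed
between runs; identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dosage as dosage_mod
from . import hybrid as hybrid_mod
from . import madc as madc_mod
from . import ploidy as ploidy_mod
from . import qc as qc_mod

logger = logging.getLogger("polytag")


@dataclass
class PipelineConfig:
    """All thresholds and toggles of the standard pipeline run."""

    madc_path: str = ""
    sheet_path: str = ""
    out_dir: str = "polytag_out"
    seed: int = 0
    # stage toggles
    run_dedup: bool = True
    run_qc: bool = True
    run_ploidy: bool = True
    run_dosage: bool = True
    run_pca: bool = True
    # thresholds
    min_reads: int = 10
    dedup_window_bp: int = 15
    sample_missing_threshold: float = 0.95
    marker_missing_threshold: float = 0.95
    classify_threshold: int = 10
    dosage_ploidy: int = 2
    bias_bounds: tuple = (0.05, 2.0)
    max_prop_mis: float = 0.1
    max_od: float = 0.05
    ploidy_candidates: tuple = (2, 4)
    n_pc: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, path: Path, float_format="%.4f"):
    df.to_csv(path, sep="\t", float_format=float_format)


def _log_stage(name, n_in, n_out, **extra):
    logger.info("stage=%s in=%d out=%d %s", name, n_in, n_out,
                " ".join(f"{k}={v}" for k, v in extra.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order:
    read -> dedup -> missingness/filter -> ploidy -> dosage -> QC stats.

    Returns a result dict; every stage's TSV report and a machine-readable
    removal log land in config.out_dir.  Raises with the failing stage's
    name on any error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2,
                                                default=str))
    results = {"config": config.to_dict()}
    stage = "read"
    try:
        sheet = madc_mod.read_sample_sheet(config.sheet_path)
        markers, counts, report = madc_mod.read_madc(config.madc_path, sheet)
        _log_stage(stage, report.n_loci, len(counts.loci),
                   other_rows=report.n_other_rows)
        results["n_loci_raw"] = len(counts.loci)

        if config.run_dedup:
            stage = "dedup"
            kept, removed = madc_mod.dedup_window(markers,
                                                  config.dedup_window_bp)
            counts = counts.subset(loci=[m.locus_id for m in kept])
            markers = kept
            pd.Series([m.locus_id for m in removed], name="locus_id").to_csv(
                out / "dedup_removed.tsv", sep="\t", index=False)
            _log_stage(stage, len(kept) + len(removed), len(kept))
            results["n_dedup_removed"] = len(removed)

        if config.run_qc:
            stage = "missingness"
            _, rep = qc_mod.missingness(counts, config.min_reads)
            _write(rep.sample_rate.to_frame("missing_rate"),
                   out / "sample_missingness.tsv")
            _write(rep.marker_rate.to_frame("missing_rate"),
                   out / "marker_missingness.tsv")
            stage = "filter_missing"
            n0 = counts.shape
            counts, log = qc_mod.filter_by_missing(
                counts, config.sample_missing_threshold,
                config.marker_missing_threshold, config.min_reads)
            (out / "removal_log.json").write_text(json.dumps({
                "order": list(log.order),
                "removed_samples": log.removed_samples,
                "removed_markers": log.removed_markers}, indent=2))
            _log_stage(stage, n0[0] * n0[1],
                       counts.shape[0] * counts.shape[1],
                       samples_removed=len(log.removed_samples),
                       markers_removed=len(log.removed_markers))
            results["removed_samples"] = log.removed_samples
            results["removed_markers"] = len(log.removed_markers)
            stage = "maf"
            maf = qc_mod.maf_from_reads(counts)
            poly, thr = qc_mod.polymorphic_call(maf, sheet.loc[counts.samples])
            _write(pd.DataFrame({"maf": maf, "polymorphic": poly}),
                   out / "marker_maf.tsv")
            results["polymorphic_threshold"] = float(thr)
            results["n_polymorphic"] = int(poly.sum())

        if config.run_ploidy:
            stage = "ploidy"
            calls, _pass1 = ploidy_mod.estimate_ploidy(
                counts, candidates=config.ploidy_candidates,
                min_reads=config.min_reads, seed=config.seed)
            _write(calls, out / "ploidy_calls.tsv")
            results["ploidy_calls"] = calls["call"].to_dict()

        if config.run_dosage:
            stage = "dosage"
            fits, G = dosage_mod.fit_norm_model(
                counts, m=config.dosage_ploidy, min_reads=config.min_reads,
                seed=config.seed)
            kept_ids, filt = dosage_mod.filter_postdosage(
                fits, config.bias_bounds, config.max_prop_mis, config.max_od)
            info = dosage_mod.informative_markers(G)
            _write(G.dosage, out / "genotypes.tsv", float_format="%.0f")
            _write(dosage_mod.fits_to_frame(fits), out / "model_fits.tsv",
                   float_format="%.6g")
            _write(filt, out / "postdosage_filter.tsv")
            _log_stage(stage, len(G.dosage), len(kept_ids),
                       informative=len(info))
            results["n_markers_postdosage"] = len(kept_ids)
            results["n_informative"] = len(info)
            stage = "pic"
            pic_vals = qc_mod.pic_per_marker(G.dosage.loc[info],
                                             config.dosage_ploidy)
            _write(pic_vals.to_frame(), out / "pic.tsv")
            results["mean_pic"] = float(pic_vals.mean())

        if config.run_pca:
            stage = "pca"
            pca = qc_mod.allele_ratio_pca(counts, n_pc=config.n_pc,
                                          min_reads=config.min_reads)
            _write(pca.scores, out / "pca_scores.tsv")
            results["pca_variance_explained"] = [
                float(v) for v in pca.variance_explained[:2]]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 default=str))
    return results


# ---------------------------------------------------------------------------
# published-panel validation workflow


def reproduce_validation(madc_path, sheet_path, min_reads: int = 10,
                         missing_threshold: float = 0.95,
                         hybrid_marker_threshold: float = 0.95,
                         classify_threshold: int = 10) -> dict:
    """Recompute the panel-validation summary statistics from a MADC file.

    Given the validation MADC table and a sample sheet whose ``group``
    column distinguishes (at least) the diverse diploid cranberry
    accessions, the *V. oxycoccos* x *V. corymbosum* hybrids, and the
    hybrid parents (groups ``blue_parent`` / ``cran_parent``), this runs
    the <min_reads missingness rule, the >=95% sample and marker removals,
    per-group mean missing rates, and the parental-read sub-genome
    classification for the hybrid panel, returning the counts a validation
    report quotes: samples/markers removed and retained, overall and
    per-group mean missing rates, amplification rate, and the number of
    shared (both-genome) loci.
    """
    sheet = madc_mod.read_sample_sheet(sheet_path)
    _, counts, _ = madc_mod.read_madc(madc_path, sheet)
    _, rep = qc_mod.missingness(counts, min_reads)
    overall_mean_missing = float(rep.sample_rate.mean())
    group_of = sheet["group"]
    group_means = rep.sample_rate.groupby(group_of.loc[rep.sample_rate.index]
                                          ).mean()
    filtered, log = qc_mod.filter_by_missing(counts, missing_threshold,
                                             missing_threshold, min_reads)
    out = {
        "n_samples": counts.shape[1],
        "n_markers": counts.shape[0],
        "n_samples_removed": len(log.removed_samples),
        "n_markers_removed": len(log.removed_markers),
        "n_markers_retained": filtered.shape[0],
        "mean_sample_missing_pct": 100.0 * overall_mean_missing,
        "group_mean_missing_pct": (100.0 * group_means).to_dict(),
    }
    diverse = [g for g in group_means.index if "macrocarpon" in g.lower()
               and "diverse" in g.lower()]
    if diverse:
        out["macrocarpon_amplification_pct"] = float(
            100.0 - 100.0 * group_means[diverse[0]])
    blue = sheet.index[group_of == "blue_parent"].tolist()
    cran = sheet.index[group_of == "cran_parent"].tolist()
    hybrids = sheet.index[group_of.str.contains("hybrid", case=False)].tolist()
    if blue and cran and hybrids:
        hyb_counts = filtered.subset(
            samples=[s for s in filtered.samples
                     if s in set(blue) | set(cran) | set(hybrids)])
        _, hrep = qc_mod.missingness(hyb_counts, min_reads)
        bad = hrep.marker_rate[
            hrep.marker_rate >= hybrid_marker_threshold].index
        hyb_counts = hyb_counts.subset(
            loci=hyb_counts.loci[~hyb_counts.loci.isin(bad)])
        out["n_hybrid_markers_removed"] = int(len(bad))
        classes = hybrid_mod.classify_loci(hyb_counts, blue, cran,
                                           threshold=classify_threshold)
        vc = classes["label"].value_counts()
        out["n_shared_loci"] = int(vc.get("shared", 0))
        out["n_genome_specific_loci"] = int(vc.get("cran_specific", 0)
                                            + vc.get("blue_specific", 0))
        out["n_failed_loci"] = int(vc.get("failed", 0))
    return out
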