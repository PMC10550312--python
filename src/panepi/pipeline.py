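"""End-to-end orchestration: simulate -> call -> classify -> statistics -> report.

Each stage is a plain function over the library modules so stages can be
re-run individually; :func:`run_all` chains them and writes a report
directory.  The report reproduces the analysis surfaces of the study design:
per-genome epiallele count tables, structural-feature summaries by epiallele,
pangene class and duplicate-epiallele tables, and per-tissue
paired-difference and correlation summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import epialleles, features, metagene, pangenes, stats
from .annotations import cds_region_index, read_bed, read_gff3
from .epialleles import ThresholdConfig
from .expression import categorize_matrix, read_matrix, write_matrix
from .methylome import cds_methylation_table, read_cgmap_frame
from .simulate import SimConfig, SimResult, simulate

log = logging.getLogger("panepi")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "panepi_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    metagene_internal_bp: int = 1500
    min_copy_strata: tuple[int, ...] = (2, 4)
    metagene_genomes: int = 1   # profiles are heavy; compute for this many genomes
    from_files: bool = False    # re-read the emitted files instead of reusing memory

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        thr = ThresholdConfig(**raw.pop("thresholds", {}))
        return cls(sim=sim, thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            return obj

        data = dataclasses.asdict(self)
        data["sim"]["switch_rates"] = {
            f"{a}->{b}": v for (a, b), v in self.sim.switch_rates.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(clean(data), fh, default_flow_style=False)


def call_genome_products(
    sim: SimResult, genome: str, thresholds: ThresholdConfig
) -> tuple[pd.DataFrame, dict]:
    """Methylation summary + epiallele calls for one simulated genome."""
    models, _ = sim.structures(genome)
    cg = sim.methylome(genome)
    gm = cds_methylation_table(cg, models)
    return epialleles.call_genome(gm, thresholds)


def call_genome_from_files(
    cgmap_path, gff3_path, thresholds: ThresholdConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """File-based variant of :func:`call_genome_products`."""
    models = read_gff3(gff3_path)
    cg = read_cgmap_frame(cgmap_path)
    gm = cds_methylation_table(cg, models)
    return epialleles.call_genome(gm, thresholds)


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the report dictionary and writes files.

    Any stage failure propagates as an exception naming the stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    cfg.to_yaml(out / "config_used.yaml")
    report: dict = {}

    stage = "simulate"
    try:
        sim = simulate(cfg.sim, cfg.seed)
        inputs = out / "inputs"
        sim.write(inputs)
        log.info("simulate: %d pangenes x %d genomes", cfg.sim.n_pangenes, cfg.sim.n_genomes)

        stage = "methylation+call"
        call_tables: dict[str, pd.DataFrame] = {}
        summaries = {}
        for g in sim.genomes:
            if cfg.from_files:
                table, summary = call_genome_from_files(
                    inputs / g / "methylome.cgmap", inputs / g / "genes.gff3",
                    cfg.thresholds,
                )
            else:
                table, summary = call_genome_products(sim, g, cfg.thresholds)
            call_tables[g] = table
            summaries[g] = summary
            epialleles.write_calls(table, out / f"calls_{g}.tsv")
            models, _ = sim.structures(g)
            epialleles.tem_bed_track(table, models, out / f"teM_{g}.bed")
        report["epiallele_counts"] = {
            g: s["counts"] for g, s in summaries.items()
        }

        stage = "metagene"
        for g in sim.genomes[: cfg.metagene_genomes]:
            models, _ = sim.structures(g)
            profiles = metagene.metagene_profile(
                models, sim.methylome(g), internal_bp=cfg.metagene_internal_bp
            )
            metagene.write_profiles(profiles, out / f"metagene_{g}.tsv")

        stage = "features"
        labels_all: dict[str, str] = {}
        for g in sim.genomes:
            labels_all.update(epialleles.epiallele_map(call_tables[g]))
        g0 = sim.genomes[0]
        models, tes = sim.structures(g0)
        ft = features.feature_table(models, tes, sim.synteny_table(g0))
        ft.to_csv(out / f"features_{g0}.tsv", sep="\t")
        feat_summary = features.summarize_by_epiallele(ft, labels_all)
        feat_summary.to_csv(out / "features_by_epiallele.tsv", sep="\t")
        report["features_by_epiallele"] = feat_summary.to_dict()

        stage = "expression"
        cat_counts = {}
        for g in sim.genomes:
            cats = categorize_matrix(sim.tpm(g))
            cat_counts[g] = cats.value_counts().to_dict()
        report["expression_categories"] = cat_counts

        stage = "pangenes"
        table = sim.pangene_table
        core = pangenes.core_filter(table)
        filtered, filt_report = pangenes.intact_filter(table, sim.cds_lengths())
        classes = pangenes.classify_table(
            filtered, labels_all, core_mask=core, excluded=filt_report["excluded"]
        )
        classes.to_csv(out / "pangene_classes.tsv", sep="\t")
        report["pangene_classes"] = pangenes.class_counts(classes)
        report["n_core"] = int(core.sum())
        dup_counts = {}
        for mc in cfg.min_copy_strata:
            cnt = pangenes.count_duplicate_epialleles(filtered, classes, labels_all, mc)
            cnt.to_csv(out / f"duplicate_epialleles_min{mc}.tsv", sep="\t")
            dup_counts[mc] = cnt
        report["duplicate_epiallele_counts"] = {
            mc: c.to_dict() for mc, c in dup_counts.items()
        }
        stable_types = pangenes.stable_type_counts(filtered, classes, labels_all)
        one_types = report["pangene_classes"]["one_to_N_singleton_types"]
        report["relative_duplication"] = pangenes.relative_duplication_ratio(
            one_types, stable_types
        )

        stage = "stats"
        tpm_all: dict[str, pd.Series] = {}
        for g in sim.genomes:
            tpm_all.update({gid: row for gid, row in sim.tpm(g).iterrows()})
        de = stats.pangene_label_matrix(filtered, labels_all)
        unstable_ids = classes.index[
            (classes["class"] == "unstable_1to1") & (classes["subtype"] == "UM-gbM")
        ]
        dt_by_tissue = {
            t: stats.pangene_matrix(
                filtered, {gid: row[t] for gid, row in tpm_all.items()}
            )
            for t in cfg.sim.tissues
        }
        paired = stats.gbm_um_analysis(
            {t: m.loc[unstable_ids] for t, m in dt_by_tissue.items()},
            de.loc[unstable_ids],
        )
        paired_rows = []
        for t, r in paired.items():
            paired_rows.append(
                {
                    "tissue": t, "n": r.n, "n_pos": r.n_pos, "n_neg": r.n_neg,
                    "median_d": r.median_d, "mean_d": r.mean_d,
                    "normalized_median_pct": r.normalized_median_pct,
                    "sign_test_p": r.sign_test_p, "wilcoxon_p": r.wilcoxon_p,
                }
            )
        paired_df = pd.DataFrame(paired_rows).set_index("tissue")
        paired_df.to_csv(out / "gbm_um_differences.tsv", sep="\t")
        report["gbm_um"] = paired_df.to_dict(orient="index")

        # quantitative mCG-vs-TPM correlations
        mcg_vals, mchg_vals = {}, {}
        for g in sim.genomes:
            t = call_tables[g]
            okc = (t["n_sites_CG"] >= cfg.thresholds.min_sites_cg) & (
                t["n_sites_CHG"] >= cfg.thresholds.min_sites_chg
            )
            mcg_vals.update(dict(zip(t.index[okc], t.loc[okc, "mCG"])))
            mchg_vals.update(dict(zip(t.index[okc], t.loc[okc, "mCHG"])))
        mcg_m = stats.pangene_matrix(filtered, mcg_vals)
        mchg_m = stats.pangene_matrix(filtered, mchg_vals)
        mcg_masked = stats.mask_low_confidence(mcg_m, mchg_m, 0.05)
        corr_rows = []
        for t in cfg.sim.tissues:
            cs = stats.methylation_expression_correlation(
                mcg_masked, dt_by_tissue[t], tissue=t
            )
            corr_rows.append(
                {
                    "tissue": t, "variable": "mCG", "n": cs.n_pangenes,
                    "median_r": cs.median_r, "mean_r": cs.mean_r,
                    "pos_neg_ratio": cs.pos_neg_ratio,
                }
            )
            cs2 = stats.methylation_expression_correlation(
                mchg_m, dt_by_tissue[t], tissue=t
            )
            corr_rows.append(
                {
                    "tissue": t, "variable": "mCHG", "n": cs2.n_pangenes,
                    "median_r": cs2.median_r, "mean_r": cs2.mean_r,
                    "pos_neg_ratio": cs2.pos_neg_ratio,
                }
            )
        corr_df = pd.DataFrame(corr_rows)
        corr_df.to_csv(out / "meth_expression_correlation.tsv", sep="\t", index=False)
        report["correlations"] = corr_df.to_dict(orient="records")

        stage = "report"
        with open(out / "report.json", "w") as fhj:
            json.dump(_jsonable(report), fhj, indent=2)
        _write_summary(report, out / "summary.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    return obj


def _write_summary(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("panepi pipeline summary\n=======================\n\n")
        fh.write("[epiallele counts per genome]\n")
        for g, c in report["epiallele_counts"].items():
            fh.write(f"  {g}: " + ", ".join(f"{k}={v}" for k, v in c.items()) + "\n")
        fh.write("\n[pangene classes]\n")
        for k, v in report["pangene_classes"]["classes"].items():
            fh.write(f"  {k}: {v}\n")
        fh.write("\n[unstable subtypes]\n")
        for k, v in report["pangene_classes"]["unstable_subtypes"].items():
            fh.write(f"  {k}: {v}\n")
        rd = report["relative_duplication"]
        fh.write("\n[relative duplication UM:gbM fold] "
                 f"{rd['fold_UM_vs_gbM']:.3g}\n")
        fh.write("\n[gbM-UM differences per tissue]\n")
        for t, r in report["gbm_um"].items():
            fh.write(
                f"  {t}: n={r['n']} median_d={r['median_d']:.4g} "
                f"norm_median={r['normalized_median_pct']:.3g}% "
                f"sign_p={r['sign_test_p']:.3g} wilcoxon_p={r['wilcoxon_p']:.3g}\n"
            )
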