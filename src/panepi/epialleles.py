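"""Epiallele calling: assign each gene a UM / gbM / teM label from CDS methylation.

The three epiallele types are defined by joint mCG/mCHG thresholds over coding
sequence:

* **UM** — unmethylated: mCG and mCHG both at most 0.05;
* **gbM** — gene-body methylation: mCG at least 0.2, mCHG at most 0.05
  (CG-only methylation);
* **teM** — TE-like methylation: mCG and mCHG both at least 0.4
  (heterochromatin-like).

Genes with intermediate values are ``undetermined`` and genes with fewer than
40 covered CG or 40 covered CHG cytosines are ``low_coverage``; neither counts
as a defined epiallele downstream.  Boundary inclusivity is configurable
because the defining inequalities can be read as strict or inclusive; the
boundary carries negligible probability mass at realistic read depth, and the
inclusive reading is the default.  mCHH plays no role in calling but is
carried through for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotations import BedRecord, GeneModel, write_bed
from .methylome import GeneMethylation

LABELS = ("UM", "gbM", "teM", "undetermined", "low_coverage")
DEFINED = ("UM", "gbM", "teM")


@dataclass
class ThresholdConfig:
    """Coverage and methylation-level thresholds for epiallele calling."""

    min_sites_cg: int = 40
    min_sites_chg: int = 40
    um_max: float = 0.05
    gbm_min_mcg: float = 0.2
    tem_min: float = 0.4
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.um_max < self.gbm_min_mcg < self.tem_min <= 1):
            raise ValueError(
                "thresholds must satisfy 0 <= um_max < gbm_min_mcg < tem_min <= 1"
            )
        if self.min_sites_cg < 0 or self.min_sites_chg < 0:
            raise ValueError("minimum site counts must be non-negative")


@dataclass
class EpialleleCall:
    gene_id: str
    label: str
    mCG: float
    mCHG: float


def call_epiallele(gm: GeneMethylation, cfg: ThresholdConfig | None = None) -> EpialleleCall:
    """Label one gene from its CDS methylation summary.

    ``low_coverage`` overrides everything, including genes whose mCG or mCHG
    is undefined because no site was covered.
    """
    cfg = cfg or ThresholdConfig()
    mcg, mchg = gm.mCG, gm.mCHG
    if (
        gm.n_sites_CG < cfg.min_sites_cg
        or gm.n_sites_CHG < cfg.min_sites_chg
        or math.isnan(mcg)
        or math.isnan(mchg)
    ):
        return EpialleleCall(gm.gene_id, "low_coverage", mcg, mchg)
    if cfg.boundary_inclusive:
        low = lambda x, t: x <= t  # noqa: E731
        high = lambda x, t: x >= t  # noqa: E731
    else:
        low = lambda x, t: x < t  # noqa: E731
        high = lambda x, t: x > t  # noqa: E731
    if low(mcg, cfg.um_max) and low(mchg, cfg.um_max):
        label = "UM"
    elif high(mcg, cfg.gbm_min_mcg) and low(mchg, cfg.um_max):
        label = "gbM"
    elif high(mcg, cfg.tem_min) and high(mchg, cfg.tem_min):
        label = "teM"
    else:
        label = "undetermined"
    return EpialleleCall(gm.gene_id, label, mcg, mchg)


def call_table(gm_table: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Vectorized calling over a per-gene methylation table.

    ``gm_table`` is indexed by gene_id with columns ``mCG, mCHG, n_sites_CG,
    n_sites_CHG`` (as produced by
    :func:`panepi.methylome.cds_methylation_table`).  Returns the same index
    with an added ``label`` column.
    """
    cfg = cfg or ThresholdConfig()
    mcg = gm_table["mCG"].to_numpy(dtype=float)
    mchg = gm_table["mCHG"].to_numpy(dtype=float)
    covered = (
        (gm_table["n_sites_CG"].to_numpy() >= cfg.min_sites_cg)
        & (gm_table["n_sites_CHG"].to_numpy() >= cfg.min_sites_chg)
        & ~np.isnan(mcg)
        & ~np.isnan(mchg)
    )
    if cfg.boundary_inclusive:
        um = (mcg <= cfg.um_max) & (mchg <= cfg.um_max)
        gbm = (mcg >= cfg.gbm_min_mcg) & (mchg <= cfg.um_max)
        tem = (mcg >= cfg.tem_min) & (mchg >= cfg.tem_min)
    else:
        um = (mcg < cfg.um_max) & (mchg < cfg.um_max)
        gbm = (mcg > cfg.gbm_min_mcg) & (mchg < cfg.um_max)
        tem = (mcg > cfg.tem_min) & (mchg > cfg.tem_min)
    label = np.select(
        [~covered, um, gbm, tem],
        ["low_coverage", "UM", "gbM", "teM"],
        default="undetermined",
    )
    out = gm_table.copy()
    out["label"] = label
    return out


def call_genome(
    genes: Iterable[GeneMethylation] | pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Call every gene of a genome and summarize label counts.

    Fractions are computed over genes that pass the coverage rule (label not
    ``low_coverage``); with no such gene the fractions are absent.  Duplicate
    gene ids are an error.
    """
    if isinstance(genes, pd.DataFrame):
        table = call_table(genes, cfg)
    else:
        gms = list(genes)
        calls = [call_epiallele(g, cfg) for g in gms]
        table = pd.DataFrame(
            {
                "mCG": [g.mCG for g in gms],
                "mCHG": [g.mCHG for g in gms],
                "n_sites_CG": [g.n_sites_CG for g in gms],
                "n_sites_CHG": [g.n_sites_CHG for g in gms],
                "label": [c.label for c in calls],
            },
            index=pd.Index([g.gene_id for g in gms], name="gene_id"),
        )
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    counts = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    n_covered = len(table) - counts["low_coverage"]
    summary: dict = {"counts": counts, "n_genes": len(table), "n_covered": n_covered}
    if n_covered > 0:
        summary["fractions"] = {
            lab: counts[lab] / n_covered for lab in ("UM", "gbM", "teM", "undetermined")
        }
    return table, summary


def epiallele_map(call_table_df: pd.DataFrame) -> dict[str, str]:
    """gene_id -> label mapping from a call table."""
    return dict(zip(call_table_df.index, call_table_df["label"]))


def write_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def tem_bed_track(
    calls: pd.DataFrame, genes: Mapping[str, GeneModel] | Iterable[GeneModel], path: str | Path
) -> int:
    """Write teM-flagged genes as a BED track; returns the number written.

    Mirrors the deliverable of flagging TE-like-methylated genes for genome
    browsers so they can be deprioritized as likely pseudogenes or
    mis-annotations.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    recs = [
        BedRecord(genes[gid].chrom, genes[gid].start, genes[gid].end, gid)
        for gid in calls.index[calls["label"] == "teM"]
        if gid in genes
    ]
    recs.sort(key=lambda r: (r.chrom, r.start))
    write_bed(recs, path)
    return len(recs)
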