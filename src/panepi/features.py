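"""Per-gene structural features and TE-overlap quantities.

For every canonical gene model this module computes cumulative feature
lengths (UTR, CDS, exon, intron), exon counts, merged TE overlap with introns
and CDS, the set of TE superfamilies inserted in introns, UTR presence, and an
optional syntenic-homolog flag from an external table.  Lengths are cumulative:
individual elements within a gene are summed to a single value per gene.

Conventions that matter downstream:

* TE overlaps are merged before summing, so overlapping repeat annotations
  are never double counted.
* A TE superfamily is recorded at most once per gene, however many insertions
  it has.
* The CDS-TE flag requires an overlap strictly greater than 100 bp
  (``cds_te_min_bp``, switchable to inclusive).
* Genes absent from the synteny table get ``synteny = None`` (unknown), not
  False.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import BedRecord, GeneModel, derive_introns
from .intervals import intersect_and_merge, total_length


@dataclass
class FeatureRow:
    gene_id: str
    utr_len_total: int
    cds_len: int
    exon_len_total: int
    intron_len_total: int
    intron_te_len_total: int
    cds_te_overlap_len: int
    exon_count: int
    has_utr: bool
    has_cds_te: bool
    te_superfamilies_in_introns: set[str] = field(default_factory=set)
    synteny_sorghum: bool | None = None


def _te_by_chrom(
    te_records: Iterable[BedRecord],
) -> dict[str, list[tuple[int, int, str | None]]]:
    out: dict[str, list[tuple[int, int, str | None]]] = {}
    warned = False
    for r in te_records:
        if r.name is None and not warned:
            warnings.warn(
                "TE record(s) without a superfamily label: counted in overlap "
                "lengths but excluded from superfamily sets",
                stacklevel=3,
            )
            warned = True
        out.setdefault(r.chrom, []).append((r.start, r.end, r.name))
    for v in out.values():
        v.sort()
    return out


def gene_features(
    gene: GeneModel,
    te_intervals: Sequence[tuple[int, int, str | None]] = (),
    synteny: bool | None = None,
    cds_te_min_bp: int = 100,
    cds_te_inclusive: bool = False,
) -> FeatureRow:
    """Feature row for a single gene; ``te_intervals`` are on the gene's chromosome."""
    introns = derive_introns(gene)
    te_ivs = [(s, e) for s, e, _ in te_intervals]
    intron_te_len, _ = intersect_and_merge(introns, te_ivs)
    cds_te_len, _ = intersect_and_merge(gene.cds, te_ivs)
    superfams: set[str] = set()
    for s, e, name in te_intervals:
        if name is None:
            continue
        ov, _ = intersect_and_merge(introns, [(s, e)])
        if ov > 0:
            superfams.add(name)
    if cds_te_inclusive:
        has_cds_te = cds_te_len >= cds_te_min_bp
    else:
        has_cds_te = cds_te_len > cds_te_min_bp
    return FeatureRow(
        gene_id=gene.gene_id,
        utr_len_total=total_length(gene.utr5) + total_length(gene.utr3),
        cds_len=gene.cds_length(),
        exon_len_total=total_length(gene.exons),
        intron_len_total=sum(e - s for s, e in introns),
        intron_te_len_total=intron_te_len,
        cds_te_overlap_len=cds_te_len,
        exon_count=len(gene.exons),
        has_utr=bool(gene.utr5 or gene.utr3),
        has_cds_te=has_cds_te,
        te_superfamilies_in_introns=superfams,
        synteny_sorghum=synteny,
    )


def feature_table(
    genes: Sequence[GeneModel],
    te_records: Iterable[BedRecord] = (),
    synteny_table: Mapping[str, bool] | None = None,
    cds_te_min_bp: int = 100,
    cds_te_inclusive: bool = False,
) -> pd.DataFrame:
    """Feature rows for a gene set as a DataFrame indexed by gene_id.

    Only TE records overlapping a gene's span are considered for that gene.
    ``synteny_table`` maps gene_id to presence of a syntenic homolog; missing
    genes are reported as ``NA`` (unknown).
    """
    te_idx = _te_by_chrom(te_records)
    rows = []
    for g in genes:
        cands = [
            t for t in te_idx.get(g.chrom, []) if t[0] < g.end and t[1] > g.start
        ]
        syn = synteny_table.get(g.gene_id) if synteny_table is not None else None
        rows.append(
            gene_features(
                g,
                cands,
                synteny=syn,
                cds_te_min_bp=cds_te_min_bp,
                cds_te_inclusive=cds_te_inclusive,
            )
        )
    df = pd.DataFrame(
        {
            "utr_len_total": [r.utr_len_total for r in rows],
            "cds_len": [r.cds_len for r in rows],
            "exon_len_total": [r.exon_len_total for r in rows],
            "intron_len_total": [r.intron_len_total for r in rows],
            "intron_te_len_total": [r.intron_te_len_total for r in rows],
            "cds_te_overlap_len": [r.cds_te_overlap_len for r in rows],
            "exon_count": [r.exon_count for r in rows],
            "has_utr": [r.has_utr for r in rows],
            "has_cds_te": [r.has_cds_te for r in rows],
            "te_superfamilies_in_introns": [
                ",".join(sorted(r.te_superfamilies_in_introns)) for r in rows
            ],
            "synteny_sorghum": [r.synteny_sorghum for r in rows],
        },
        index=pd.Index([r.gene_id for r in rows], name="gene_id"),
    )
    return df


def read_synteny_table(path: str | Path) -> dict[str, bool]:
    """Read a delimited table (gene_id, has_homolog) into a mapping.

    ``has_homolog`` accepts 1/0, true/false, yes/no (case-insensitive).
    """
    df = pd.read_csv(path, sep="\t")
    truthy = {"1", "true", "yes", "t", "y"}
    return {
        str(g): str(v).strip().lower() in truthy
        for g, v in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def summarize_by_epiallele(
    features: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Group feature medians/proportions by epiallele label.

    Reproducible from the feature row table alone plus the label map; genes
    without a defined label are grouped under their literal label
    (``undetermined`` / ``low_coverage``).
    """
    df = features.copy()
    df["label"] = [labels.get(g, "low_coverage") for g in df.index]
    num_cols = [
        "utr_len_total",
        "cds_len",
        "exon_len_total",
        "intron_len_total",
        "intron_te_len_total",
        "cds_te_overlap_len",
        "exon_count",
    ]
    med = df.groupby("label")[num_cols].median()
    med["mean_exon_count"] = df.groupby("label")["exon_count"].mean()
    med["prop_has_utr"] = df.groupby("label")["has_utr"].mean()
    med["prop_has_cds_te"] = df.groupby("label")["has_cds_te"].mean()
    syn = df.dropna(subset=["synteny_sorghum"])
    if len(syn):
        med["prop_synteny"] = syn.groupby("label")["synteny_sorghum"].mean()
    med["n_genes"] = df.groupby("label").size()
    return med
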