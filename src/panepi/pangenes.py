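"""Pangene tables: core selection, intact-CDS filtering, and stability classes.

A *pangene* is the set of homologous genes occupying one syntenic position
across the genomes of a pan-genome.  The pangene table has one row per
pangene and one column per genome; a cell holds one gene id (singleton),
several gene ids (a tandem-duplicate array), a coordinate placeholder
(``chrom:start-end``: homologous DNA present but no annotated gene), or is
missing.

Analysis proceeds in three stages:

1. **Core selection** — a pangene is core when no genome cell is missing.
   Coordinate-only cells count as present for core status but contribute no
   genes to any analysis.
2. **Intact-CDS filter** — to exclude fragmented duplicates and annotation
   artifacts, each gene's cumulative CDS length must deviate from the median
   of the pangene's *singleton* genes by less than 10%.  Pangenes without any
   singleton are excluded from pangene analyses entirely.  Dropping genes
   never revokes core status.
3. **Stability classes** — after filtering, a pangene is classified as
   ``one_to_N`` (singleton in some genomes, intact tandem duplicates in at
   least one other, with a single singleton epiallele type), ``stable_1to1``
   (all singletons, one epiallele type), ``unstable_1to1`` (all singletons,
   at least two epiallele types, each represented by at least two genomes) or
   ``other``.  Undetermined and low-coverage calls are neutral: they neither
   qualify nor disqualify a type-uniformity requirement.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFINED_TYPES = ("UM", "gbM", "teM")
CLASSES = ("one_to_N", "stable_1to1", "unstable_1to1", "other")

COORD_RE = re.compile(r"^[^\s:]+:\d+-\d+$")

Cell = tuple[str, ...]  # gene ids; () is unusable; None = missing; str = coordinates


class PangeneTable:
    """Pangene x genome matrix of cells.

    Internally each cell is a tuple of gene ids, ``None`` for a missing gene,
    or the raw coordinate string for an unannotated homolog.
    """

    def __init__(self, cells: pd.DataFrame):
        self.cells = cells

    @property
    def pangene_ids(self) -> pd.Index:
        return self.cells.index

    @property
    def genomes(self) -> pd.Index:
        return self.cells.columns

    @property
    def n_genomes(self) -> int:
        return len(self.cells.columns)

    def row(self, pangene_id: str) -> pd.Series:
        return self.cells.loc[pangene_id]

    def genes(self) -> Iterable[str]:
        for row in self.cells.itertuples(index=False):
            for cell in row:
                if isinstance(cell, tuple):
                    yield from cell

    @staticmethod
    def parse_cell(text: str | float | None, subdelim: str = ";") -> Cell | None | str:
        if text is None or (isinstance(text, float) and np.isnan(text)):
            return None
        s = str(text).strip()
        if s == "" or s.upper() == "NA":
            return None
        if COORD_RE.match(s):
            return s
        return tuple(p.strip() for p in s.split(subdelim) if p.strip())

    @classmethod
    def read_csv(cls, path: str | Path, subdelim: str = ";") -> "PangeneTable":
        raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        cells = raw.map(lambda v: cls.parse_cell(v, subdelim))
        return cls(cells)

    def to_csv(self, path: str | Path, subdelim: str = ";") -> None:
        def fmt(cell):
            if cell is None:
                return "NA"
            if isinstance(cell, str):
                return cell
            return subdelim.join(cell)

        self.cells.map(fmt).to_csv(path)

    def subset(self, pangene_ids) -> "PangeneTable":
        return PangeneTable(self.cells.loc[pangene_ids])


def _is_genes(cell) -> bool:
    return isinstance(cell, tuple)


def core_filter(table: PangeneTable) -> pd.Series:
    """Boolean mask: pangene present in every genome (coordinate cells count)."""
    present = table.cells.map(lambda c: c is not None)
    return present.all(axis=1)


def intact_filter(
    table: PangeneTable,
    cds_lengths: Mapping[str, float],
    tol: float = 0.10,
) -> tuple[PangeneTable, pd.DataFrame]:
    """Apply the intact-CDS rule; returns the filtered table and a report.

    Per pangene the median is over singleton genes only (cells holding exactly
    one gene id); every gene, singleton or duplicate, is kept iff
    ``|L - median| / median < tol``.  The report has one row per pangene with
    ``n_singletons``, ``median_cds_len``, ``n_dropped`` and ``excluded`` (no
    singleton to define a median).  Genes without a known CDS length are an
    error.  Because kept singletons all lie within the tolerance band of the
    median, re-applying the filter to its own output leaves it unchanged for
    any realistically clustered singleton lengths.
    """
    new_cells = {}
    rows = []
    for pid, row in table.cells.iterrows():
        sing_lens = []
        for cell in row:
            if _is_genes(cell) and len(cell) == 1:
                g = cell[0]
                if g not in cds_lengths:
                    raise KeyError(f"no CDS length for gene {g!r}")
                sing_lens.append(float(cds_lengths[g]))
        if not sing_lens:
            med = np.nan
            excluded = True
        else:
            med = float(np.median(sing_lens))
            excluded = False
        dropped = 0
        new_row = []
        for cell in row:
            if not _is_genes(cell):
                new_row.append(cell)
                continue
            if excluded:
                new_row.append(())
                dropped += len(cell)
                continue
            kept = []
            for g in cell:
                if g not in cds_lengths:
                    raise KeyError(f"no CDS length for gene {g!r}")
                if med > 0 and abs(float(cds_lengths[g]) - med) / med < tol:
                    kept.append(g)
                else:
                    dropped += 1
            new_row.append(tuple(kept))
        new_cells[pid] = new_row
        rows.append(
            {
                "pangene_id": pid,
                "n_singletons": len(sing_lens),
                "median_cds_len": med,
                "n_dropped": dropped,
                "excluded": excluded,
            }
        )
    filtered = PangeneTable(
        pd.DataFrame.from_dict(new_cells, orient="index", columns=table.cells.columns).loc[
            table.cells.index
        ]
    )
    report = pd.DataFrame(rows).set_index("pangene_id")
    return filtered, report


@dataclass
class PangeneClass:
    pangene_id: str
    core: bool
    cls: str  # one of CLASSES
    subtype: str | None = None           # for unstable_1to1, e.g. "UM-gbM"
    singleton_epiallele: str | None = None  # for one_to_N
    type_counts: dict = field(default_factory=dict)


def classify_pangene(
    cells: Sequence,
    epialleles: Mapping[str, str],
    core: bool = True,
) -> PangeneClass:
    """Classify one (post-filter) pangene row.

    ``cells`` is the row's cell sequence; ``epialleles`` maps gene id to its
    label (labels outside UM/gbM/teM, and missing genes, count as undefined).
    """
    singles: list[str] = []
    has_dup = False
    for cell in cells:
        if not _is_genes(cell) or len(cell) == 0:
            continue
        if len(cell) == 1:
            singles.append(cell[0])
        else:
            has_dup = True
    labels = [epialleles.get(g) for g in singles]
    defined = [l for l in labels if l in DEFINED_TYPES]
    counts = Counter(defined)
    types = set(counts)

    if has_dup:
        if len(singles) >= 2 and len(defined) >= 2 and len(types) == 1:
            cls, sub, se = "one_to_N", None, next(iter(types))
        else:
            cls, sub, se = "other", None, None
    else:
        if len(types) == 1 and len(defined) >= 2:
            cls, sub, se = "stable_1to1", None, None
        elif len(types) >= 2 and all(c >= 2 for c in counts.values()):
            order = [t for t in DEFINED_TYPES if t in types]
            cls, sub, se = "unstable_1to1", "-".join(order), None
        else:
            cls, sub, se = "other", None, None
    return PangeneClass(
        pangene_id="",
        core=core,
        cls=cls,
        subtype=sub,
        singleton_epiallele=se,
        type_counts=dict(counts),
    )


def classify_table(
    table: PangeneTable,
    epialleles: Mapping[str, str],
    core_mask: pd.Series | None = None,
    excluded: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every core, non-excluded pangene of a filtered table.

    Returns a DataFrame indexed by pangene id with ``class``, ``subtype``,
    ``singleton_epiallele`` columns; excluded or non-core pangenes get class
    ``NA``.
    """
    if core_mask is None:
        core_mask = core_filter(table)
    recs = []
    for pid, row in table.cells.iterrows():
        if not core_mask.loc[pid] or (excluded is not None and excluded.loc[pid]):
            recs.append({"pangene_id": pid, "class": None, "subtype": None,
                         "singleton_epiallele": None})
            continue
        pc = classify_pangene(list(row), epialleles, core=True)
        recs.append(
            {
                "pangene_id": pid,
                "class": pc.cls,
                "subtype": pc.subtype,
                "singleton_epiallele": pc.singleton_epiallele,
            }
        )
    return pd.DataFrame(recs).set_index("pangene_id")


def count_duplicate_epialleles(
    table: PangeneTable,
    classes: pd.DataFrame,
    epialleles: Mapping[str, str],
    min_copy: int = 2,
) -> pd.DataFrame:
    """Pooled duplicate-gene epiallele counts per singleton type (1-to-N rows).

    For every 1-to-N pangene, genes in cells with at least ``min_copy`` intact
    copies are pooled; only duplicates with a defined epiallele are counted.
    Returns a singleton-type x duplicate-type count matrix.
    """
    out = pd.DataFrame(
        0, index=pd.Index(DEFINED_TYPES, name="singleton_type"), columns=list(DEFINED_TYPES)
    )
    sel = classes[classes["class"] == "one_to_N"]
    for pid, crow in sel.iterrows():
        stype = crow["singleton_epiallele"]
        for cell in table.cells.loc[pid]:
            if not _is_genes(cell) or len(cell) < max(2, min_copy):
                continue
            for g in cell:
                lab = epialleles.get(g)
                if lab in DEFINED_TYPES:
                    out.loc[stype, lab] += 1
    return out


def relative_duplication_ratio(
    n_one_to_n: Mapping[str, int], n_stable: Mapping[str, int]
) -> dict:
    """1-to-N / stable-1-to-1 ratios per epiallele type, and the UM:gbM fold.

    A zero stable count makes the ratio undefined (``nan``) with a warning.
    """
    import warnings

    ratios: dict = {}
    for t in DEFINED_TYPES:
        num = n_one_to_n.get(t, 0)
        den = n_stable.get(t, 0)
        if den == 0:
            warnings.warn(f"no stable 1-to-1 pangenes of type {t}; ratio undefined")
            ratios[t] = float("nan")
        else:
            ratios[t] = num / den
    fold = (
        ratios["UM"] / ratios["gbM"]
        if ratios.get("gbM") not in (0, None) and not np.isnan(ratios.get("gbM", np.nan))
        and ratios["gbM"] != 0
        else float("nan")
    )
    return {"ratios": ratios, "fold_UM_vs_gbM": fold}


def class_counts(classes: pd.DataFrame) -> dict:
    """Summary counts used for reporting: classes, subtypes, singleton types."""
    cc = classes["class"].value_counts(dropna=True).to_dict()
    sub = (
        classes.loc[classes["class"] == "unstable_1to1", "subtype"]
        .value_counts()
        .to_dict()
    )
    one = (
        classes.loc[classes["class"] == "one_to_N", "singleton_epiallele"]
        .value_counts()
        .to_dict()
    )
    return {"classes": cc, "unstable_subtypes": sub, "one_to_N_singleton_types": one}


def stable_type_counts(
    table: PangeneTable, classes: pd.DataFrame, epialleles: Mapping[str, str]
) -> dict[str, int]:
    """Counts of stable 1-to-1 pangenes per epiallele type."""
    out = {t: 0 for t in DEFINED_TYPES}
    for pid in classes.index[classes["class"] == "stable_1to1"]:
        for cell in table.cells.loc[pid]:
            if _is_genes(cell) and len(cell) == 1:
                lab = epialleles.get(cell[0])
                if lab in DEFINED_TYPES:
                    out[lab] += 1
                    break
    return out
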