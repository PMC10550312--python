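"""Per-site methylome records (CGmap dialect) and region methylation levels.

The CGmap dialect is an 8-column tab-delimited text format, one cytosine per
line::

    chrom  strand_base  pos(1-based)  context  subcontext  level  n_meth  n_total

``context`` is one of CG/CHG/CHH (H = A, T or C).  A cytosine counts as
*covered* when at least one read spans it (``n_total >= 1``); uncovered
cytosines are simply absent from the file.

Per-gene methylation is computed over coding sequence only.  UTRs are excluded
because their boundaries are often imprecisely annotated and can overlap
nearby transposons; introns are excluded because TE insertions give them
TE-like methylation unrelated to the exons around them.  The default level of
a region is read-weighted, ``sum(n_meth) / sum(n_total)`` over covered sites,
which is robust to uneven read depth; an unweighted mean of per-site levels is
available behind ``weighted=False`` for sensitivity checks.
"""

from __future__ import annotations

import gzip
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, merge_intervals

CONTEXTS = ("CG", "CHG", "CHH")

CGMAP_COLUMNS = (
    "chrom",
    "strand_base",
    "pos",
    "context",
    "subcontext",
    "level",
    "n_meth",
    "n_total",
)


@dataclass(frozen=True)
class SiteRecord:
    """One cytosine's methylation evidence on the reported strand."""

    chrom: str
    pos: int  # 1-based, as in the file
    strand_base: str
    context: str
    subcontext: str
    level: float
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context token {self.context!r}")
        if self.n_total <= 0 or self.n_meth < 0 or self.n_meth > self.n_total:
            raise ValueError(
                f"invalid counts n_meth={self.n_meth}, n_total={self.n_total} at "
                f"{self.chrom}:{self.pos}"
            )


class CGmapFormatError(ValueError):
    """A malformed CGmap line, carrying the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


RegionIndex = Mapping[str, Sequence[Interval]]


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _in_regions(regions: Sequence[Interval], starts: Sequence[int], pos0: int) -> bool:
    i = bisect_right(starts, pos0) - 1
    return i >= 0 and pos0 < regions[i][1]


def parse_cgmap_line(line: str, line_number: int) -> SiteRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 8:
        raise CGmapFormatError(f"expected 8 tab-separated fields, got {len(parts)}", line_number)
    chrom, base, pos_s, context, sub, level_s, meth_s, total_s = parts
    if context not in CONTEXTS:
        raise CGmapFormatError(f"unknown context token {context!r}", line_number)
    try:
        pos = int(pos_s)
        level = float(level_s)
        n_meth = int(meth_s)
        n_total = int(total_s)
    except ValueError as exc:
        raise CGmapFormatError(str(exc), line_number) from None
    try:
        return SiteRecord(chrom, pos, base, context, sub, level, n_meth, n_total)
    except ValueError as exc:
        raise CGmapFormatError(str(exc), line_number) from None


def read_cgmap(
    path: str | Path,
    regions: RegionIndex | None = None,
    error_handler: Callable[[CGmapFormatError], None] | None = None,
) -> Iterator[SiteRecord]:
    """Stream :class:`SiteRecord` objects from a CGmap file in file order.

    ``regions`` (per-chromosome 0-based half-open intervals) restricts the
    stream to positions inside a region — the coding-sequence selection step.
    Malformed lines raise :class:`CGmapFormatError` naming the line, unless an
    ``error_handler`` is given, in which case the error is passed to it and
    parsing continues with the next line.
    """
    merged = (
        {c: merge_intervals(iv) for c, iv in regions.items()} if regions is not None else None
    )
    starts = {c: [s for s, _ in iv] for c, iv in merged.items()} if merged is not None else None
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = parse_cgmap_line(line, ln)
            except CGmapFormatError as exc:
                if error_handler is None:
                    raise
                error_handler(exc)
                continue
            if merged is not None:
                ivs = merged.get(rec.chrom)
                if not ivs or not _in_regions(ivs, starts[rec.chrom], rec.pos - 1):
                    continue
            yield rec


def read_cgmap_frame(path: str | Path, regions: RegionIndex | None = None) -> pd.DataFrame:
    """Read a CGmap file into a DataFrame (vectorized path for whole genomes).

    Column names follow :data:`CGMAP_COLUMNS`.  Context tokens are validated;
    region restriction matches :func:`read_cgmap`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=list(CGMAP_COLUMNS),
        dtype={
            "chrom": str,
            "strand_base": str,
            "pos": np.int64,
            "context": str,
            "subcontext": str,
            "level": np.float64,
            "n_meth": np.int64,
            "n_total": np.int64,
        },
    )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        first = df.index[bad][0]
        raise CGmapFormatError(
            f"unknown context token {df.loc[first, 'context']!r}", int(first) + 1
        )
    if (df["n_total"] <= 0).any() or (df["n_meth"] > df["n_total"]).any():
        raise ValueError(f"{path}: invalid read counts (need 0 <= n_meth <= n_total, n_total > 0)")
    if regions is not None:
        df = filter_frame_to_regions(df, regions)
    return df


def filter_frame_to_regions(df: pd.DataFrame, regions: RegionIndex) -> pd.DataFrame:
    """Keep rows whose position falls inside a region (0-based half-open)."""
    keep = np.zeros(len(df), dtype=bool)
    pos0 = df["pos"].to_numpy() - 1
    chrom = df["chrom"].to_numpy()
    for c, ivs in regions.items():
        merged = merge_intervals(ivs)
        if not merged:
            continue
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        mask = chrom == c
        idx = np.searchsorted(starts, pos0[mask], side="right") - 1
        ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, len(ends) - 1)])
        keep[np.flatnonzero(mask)[ok]] = True
    return df[keep].reset_index(drop=True)


def write_cgmap(sites: Iterable[SiteRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write site records (or a CGmap-column DataFrame) as CGmap text."""
    if isinstance(sites, pd.DataFrame):
        df = sites.copy()
        df["level"] = df["level"].map(lambda x: format(x, ".6g"))
        df.to_csv(path, sep="\t", header=False, index=False, columns=list(CGMAP_COLUMNS))
        return
    with open(path, "w") as fh:
        for r in sites:
            fh.write(
                f"{r.chrom}\t{r.strand_base}\t{r.pos}\t{r.context}\t{r.subcontext}\t"
                f"{r.level:.6g}\t{r.n_meth}\t{r.n_total}\n"
            )


# ---------------------------------------------------------------------------
# Region methylation
# ---------------------------------------------------------------------------

@dataclass
class GeneMethylation:
    """Per-gene methylation levels over CDS, by context.

    A level with zero covered sites is ``nan`` (undefined), never silently 0.
    """

    gene_id: str
    mCG: float = math.nan
    mCHG: float = math.nan
    mCHH: float = math.nan
    n_sites_CG: int = 0
    n_sites_CHG: int = 0
    n_sites_CHH: int = 0

    def level(self, context: str) -> float:
        return {"CG": self.mCG, "CHG": self.mCHG, "CHH": self.mCHH}[context]

    def n_sites(self, context: str) -> int:
        return {
            "CG": self.n_sites_CG,
            "CHG": self.n_sites_CHG,
            "CHH": self.n_sites_CHH,
        }[context]


def region_methylation(
    sites: Iterable[SiteRecord],
    regions: RegionIndex,
    gene_id: str = "",
    weighted: bool = True,
) -> GeneMethylation:
    """Methylation level of one gene's (CDS) regions, per context.

    ``regions`` maps chromosome to 0-based half-open intervals; overlapping
    intervals are merged first so no cytosine is counted twice.  The weighted
    level is ``sum(n_meth) / sum(n_total)``; with ``weighted=False`` it is the
    unweighted mean of per-site levels instead.
    """
    merged = {c: merge_intervals(iv) for c, iv in regions.items()}
    if not any(merged.values()):
        raise ValueError(f"empty region set for gene {gene_id!r}")
    starts = {c: [s for s, _ in iv] for c, iv in merged.items()}
    meth = {c: 0 for c in CONTEXTS}
    total = {c: 0 for c in CONTEXTS}
    lvl_sum = {c: 0.0 for c in CONTEXTS}
    n = {c: 0 for c in CONTEXTS}
    for rec in sites:
        ivs = merged.get(rec.chrom)
        if not ivs or not _in_regions(ivs, starts[rec.chrom], rec.pos - 1):
            continue
        meth[rec.context] += rec.n_meth
        total[rec.context] += rec.n_total
        lvl_sum[rec.context] += rec.n_meth / rec.n_total
        n[rec.context] += 1

    def _level(c: str) -> float:
        if n[c] == 0:
            return math.nan
        if weighted:
            return meth[c] / total[c]
        return lvl_sum[c] / n[c]

    return GeneMethylation(
        gene_id=gene_id,
        mCG=_level("CG"),
        mCHG=_level("CHG"),
        mCHH=_level("CHH"),
        n_sites_CG=n["CG"],
        n_sites_CHG=n["CHG"],
        n_sites_CHH=n["CHH"],
    )


def cds_methylation_table(
    sites: pd.DataFrame,
    genes: Sequence,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-gene CDS methylation for a whole genome at once.

    ``sites`` is a CGmap-column DataFrame (see :func:`read_cgmap_frame`);
    ``genes`` is a sequence of :class:`~panepi.annotations.GeneModel`.  Returns
    a DataFrame indexed by ``gene_id`` with columns ``mCG, mCHG, mCHH,
    n_sites_CG, n_sites_CHG, n_sites_CHH``.  Exactly equivalent to calling
    :func:`region_methylation` per gene, but vectorized with prefix sums over
    position-sorted sites.
    """
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    out = {
        f"m{c}": np.full(n_genes, np.nan) for c in CONTEXTS
    }
    for c in CONTEXTS:
        out[f"n_sites_{c}"] = np.zeros(n_genes, dtype=np.int64)

    # flatten merged CDS intervals per chromosome with their gene index
    iv_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, g in enumerate(genes):
        for s, e in merge_intervals(g.cds):
            iv_by_chrom.setdefault(g.chrom, []).append((s, e, gi))

    for chrom, grp in sites.groupby("chrom", sort=False):
        ivs = iv_by_chrom.get(str(chrom))
        if not ivs:
            continue
        for context, sub in grp.groupby("context", sort=False):
            pos0 = np.sort(sub["pos"].to_numpy(), kind="stable") - 1
            order = np.argsort(sub["pos"].to_numpy(), kind="stable")
            meth = sub["n_meth"].to_numpy()[order]
            tot = sub["n_total"].to_numpy()[order]
            lvl = meth / tot
            cmeth = np.concatenate(([0], np.cumsum(meth)))
            ctot = np.concatenate(([0], np.cumsum(tot)))
            clvl = np.concatenate(([0.0], np.cumsum(lvl)))
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            gidx = np.array([gi for _, _, gi in ivs])
            lo = np.searchsorted(pos0, starts, side="left")
            hi = np.searchsorted(pos0, ends, side="left")
            seg_n = hi - lo
            seg_meth = cmeth[hi] - cmeth[lo]
            seg_tot = ctot[hi] - ctot[lo]
            seg_lvl = clvl[hi] - clvl[lo]
            n_acc = np.zeros(n_genes, dtype=np.int64)
            m_acc = np.zeros(n_genes, dtype=np.int64)
            t_acc = np.zeros(n_genes, dtype=np.int64)
            l_acc = np.zeros(n_genes)
            np.add.at(n_acc, gidx, seg_n)
            np.add.at(m_acc, gidx, seg_meth)
            np.add.at(t_acc, gidx, seg_tot)
            np.add.at(l_acc, gidx, seg_lvl)
            covered = n_acc > 0
            out[f"n_sites_{context}"] += n_acc
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = m_acc / t_acc if weighted else l_acc / np.maximum(n_acc, 1)
            out[f"m{context}"][covered] = vals[covered]
    return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene_id"))
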