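"""Strand-aware metagene methylation profiles.

Genes are aligned at their transcription start sites (TSS) and
polyadenylation sites (polyA) and methylation is averaged in fixed-width bins:
3 kb upstream of the TSS, an internal window just inside each end of the gene
(1.5 kb by default, configurable to 2 kb), and 3 kb downstream of the polyA.
Minus-strand genes are flipped so "upstream" is always 5' in transcript
orientation.

Within one gene and bin the level is read-weighted over cytosines covered by
at least one read; across genes each bin is the *unweighted* mean over genes
that have at least one covered site of that context in the bin, so deeply
sequenced genes do not dominate the profile.  Internal bins that extend past
the end of a short gene are skipped for that gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import GeneModel
from .methylome import CONTEXTS, SiteRecord

SEGMENTS = ("upstream", "genic5", "genic3", "downstream")


@dataclass
class MetageneProfile:
    """Binned mean methylation around aligned gene landmarks for one context."""

    context: str
    bin_width: int
    upstream: np.ndarray      # 5'-most bin first; last bin abuts the TSS
    genic5: np.ndarray        # first bin starts at the TSS
    genic3: np.ndarray        # last bin abuts the polyA site
    downstream: np.ndarray    # first bin starts just past the polyA
    n_genes: dict[str, np.ndarray]

    def segment(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in SEGMENTS:
            vals = self.segment(seg)
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "context": self.context,
                        "window": seg,
                        "bin_index": i,
                        "mean_level": v,
                        "n_genes": int(self.n_genes[seg][i]),
                    }
                )
        return pd.DataFrame(rows)


def _sites_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    recs = list(sites)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in recs],
            "pos": [r.pos for r in recs],
            "context": [r.context for r in recs],
            "n_meth": [r.n_meth for r in recs],
            "n_total": [r.n_total for r in recs],
        }
    )


def metagene_profile(
    genes: Sequence[GeneModel],
    sites: pd.DataFrame | Iterable[SiteRecord],
    upstream_bp: int = 3000,
    internal_bp: int = 1500,
    bin_width: int = 100,
) -> dict[str, MetageneProfile]:
    """Metagene profiles per context over a set of genes.

    ``sites`` may be a CGmap-column DataFrame or an iterable of
    :class:`SiteRecord`.  Returns ``{context: MetageneProfile}``; bins with no
    contributing gene are ``nan``.
    """
    if len(genes) == 0:
        raise ValueError("metagene_profile requires at least one gene")
    if upstream_bp % bin_width or internal_bp % bin_width:
        raise ValueError("window sizes must be multiples of the bin width")
    df = _sites_frame(sites)
    n_up = upstream_bp // bin_width
    n_in = internal_bp // bin_width

    sums: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, dict[str, np.ndarray]] = {}
    for c in CONTEXTS:
        sums[c] = {s: np.zeros(n_up if s in ("upstream", "downstream") else n_in) for s in SEGMENTS}
        counts[c] = {
            s: np.zeros(n_up if s in ("upstream", "downstream") else n_in, dtype=np.int64)
            for s in SEGMENTS
        }

    # position-sorted arrays per (chrom, context) with prefix sums
    indexed: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (chrom, context), grp in df.groupby(["chrom", "context"], sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos0 = grp["pos"].to_numpy()[order] - 1
        cmeth = np.concatenate(([0], np.cumsum(grp["n_meth"].to_numpy()[order])))
        ctot = np.concatenate(([0], np.cumsum(grp["n_total"].to_numpy()[order])))
        indexed[(str(chrom), str(context))] = (pos0, cmeth, ctot)

    def accumulate(context, segment, bins_lo, bins_hi, pos0, cmeth, ctot, offset=0):
        """bins_lo/bins_hi: genomic half-open span of each bin, in bin order.

        ``offset`` shifts the destination index: for genic3 on a short gene
        only the bins nearest the polyA exist, and they occupy the *last*
        slots of the segment.
        """
        lo = np.searchsorted(pos0, bins_lo, side="left")
        hi = np.searchsorted(pos0, bins_hi, side="left")
        tot = ctot[hi] - ctot[lo]
        meth = cmeth[hi] - cmeth[lo]
        has = tot > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(has, meth / np.maximum(tot, 1), np.nan)
        dest = np.flatnonzero(has) + offset
        sums[context][segment][dest] += lvl[has]
        counts[context][segment][dest] += 1

    for g in genes:
        L = g.length
        usable_in = min(n_in, L // bin_width)  # whole bins fully inside the gene
        for context in CONTEXTS:
            key = (g.chrom, context)
            if key not in indexed:
                continue
            pos0, cmeth, ctot = indexed[key]
            if g.strand == "+":
                t = g.start          # TSS
                p = g.end            # one past polyA
                up_lo = t - upstream_bp + bin_width * np.arange(n_up)
                up_hi = up_lo + bin_width
                g5_lo = t + bin_width * np.arange(usable_in)
                g5_hi = g5_lo + bin_width
                g3_hi = p - bin_width * np.arange(usable_in)[::-1]
                g3_lo = g3_hi - bin_width
                dn_lo = p + bin_width * np.arange(n_up)
                dn_hi = dn_lo + bin_width
            else:
                t = g.end            # one past TSS base, moving leftward
                p = g.start
                # upstream bin k (5'-most first) covers transcript offsets
                # [-(n_up-k)*bw, -(n_up-k-1)*bw) => genomic [t+(n_up-k-1)*bw, t+(n_up-k)*bw)
                up_lo = t + bin_width * np.arange(n_up)[::-1]
                up_hi = up_lo + bin_width
                g5_hi = t - bin_width * np.arange(usable_in)
                g5_lo = g5_hi - bin_width
                g3_lo = p + bin_width * np.arange(usable_in)[::-1]
                g3_hi = g3_lo + bin_width
                dn_hi = p - bin_width * np.arange(n_up)
                dn_lo = dn_hi - bin_width
            accumulate(context, "upstream", up_lo, up_hi, pos0, cmeth, ctot)
            if usable_in:
                accumulate(context, "genic5", g5_lo, g5_hi, pos0, cmeth, ctot)
                accumulate(
                    context, "genic3", g3_lo, g3_hi, pos0, cmeth, ctot, offset=n_in - usable_in
                )
            accumulate(context, "downstream", dn_lo, dn_hi, pos0, cmeth, ctot)

    out: dict[str, MetageneProfile] = {}
    for c in CONTEXTS:
        seg_means = {}
        for s in SEGMENTS:
            with np.errstate(invalid="ignore", divide="ignore"):
                seg_means[s] = np.where(
                    counts[c][s] > 0, sums[c][s] / np.maximum(counts[c][s], 1), np.nan
                )
        out[c] = MetageneProfile(
            context=c,
            bin_width=bin_width,
            upstream=seg_means["upstream"],
            genic5=seg_means["genic5"],
            genic3=seg_means["genic3"],
            downstream=seg_means["downstream"],
            n_genes={s: counts[c][s].copy() for s in SEGMENTS},
        )
    return out


def write_profiles(profiles: dict[str, MetageneProfile], path: str | Path) -> None:
    """Write all context profiles as one delimited table."""
    pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
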