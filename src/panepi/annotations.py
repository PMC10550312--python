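"""Gene models and annotation I/O (GFF3, BED).

A :class:`GeneModel` is the canonical transcript of one gene: stranded exon,
CDS, and UTR interval lists, all 0-based half-open.  Introns are not stored —
annotation files usually lack them — and are derived as the gaps between
exons.  GFF3 is read through :mod:`gffutils`; BED files are plain tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import Interval, gaps_between, merge_intervals


@dataclass
class GeneModel:
    """Canonical gene annotation with stranded structure.

    ``start``/``end`` span the transcribed region (TSS to polyA in genome
    coordinates).  The TSS is ``start`` on the plus strand and ``end - 1`` on
    the minus strand; the polyA site is the opposite terminus.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def polya(self) -> int:
        """0-based position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds_length(self) -> int:
        return sum(e - s for s, e in merge_intervals(self.cds))


def derive_introns(gene: GeneModel) -> list[Interval]:
    """Introns as the gaps between consecutive exons.

    Raises ``ValueError`` if exons overlap one another — a malformed model,
    since merging would silently change the exon count.
    """
    exons = sorted(gene.exons)
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping exons in {gene.gene_id}: {(s1, e1)} / {(s2, _)}")
    return gaps_between(exons)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, canonical_attr: str = "canonical_transcript") -> list[GeneModel]:
    """Read gene models from GFF3, one canonical transcript per gene.

    The canonical mRNA is the one whose attributes carry ``canonical_attr``
    (any value); if no mRNA of a gene is tagged, the first mRNA in file order
    is used.  GFF3 coordinates (1-based closed) are converted to the internal
    0-based half-open convention here and nowhere else.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        chosen = next((m for m in mrnas if canonical_attr in m.attributes), mrnas[0])
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(chosen, order_by="start"):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=sorted(exons),
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS/UTR)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.gene_id
            mid = f"{gid}_T001"
            fh.write(
                f"{g.chrom}\tpanepi\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chrom}\tpanepi\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid};canonical_transcript=1\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for k, (s, e) in enumerate(sorted(ivs), 1):
                    fh.write(
                        f"{g.chrom}\tpanepi\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mid}_{ftype}{k};Parent={mid}\n"
                    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    name: str | None = None


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a BED3/BED4+ file; column 4, when present, is the record name.

    For TE tracks the name column carries the superfamily label.
    """
    out: list[BedRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
            out.append(
                BedRecord(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 and parts[3] != "." else None,
                )
            )
    return out


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            name = r.name if r.name is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def cds_region_index(genes: Iterable[GeneModel]) -> dict[str, list[Interval]]:
    """Merged CDS intervals per chromosome, for restricting methylome reads."""
    by_chrom: dict[str, list[Interval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).extend(g.cds)
    return {c: merge_intervals(iv) for c, iv in by_chrom.items()}
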