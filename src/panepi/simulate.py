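"""Synthetic pan-genome generator with recorded ground truth.

Emulates the statistical structure of a 26-genome maize-like pan-genome
resource: per-genome site-level methylomes (CGmap dialect), canonical gene
annotations (GFF3), TE tracks (BED), a pangene table with tandem-duplicate
cells and coordinate placeholders, and per-tissue expression matrices — all
internally consistent with a :class:`TruthSet`.

The generative model, top down:

* Each pangene draws an ancestral epiallele type from the configured base
  frequencies.  A small fraction of pangenes is epiallelically unstable: their
  per-genome singleton states segregate between two (rarely three) types,
  with pair weights mirroring the observed predominance of UM-gbM
  instability.
* Each genome cell is missing with a small probability (breaking core
  status), is a coordinate-only placeholder with a small probability, or
  holds one gene; gene cells become tandem-duplicate arrays with a configured
  probability and geometric copy numbers.  Duplicate copies inherit the
  cell's singleton state and switch type with the configured per-transition
  rates; a fraction of duplicate copies is a partial (truncated) duplication.
* Methylation is simulated at two levels: a per-gene level drawn from a Beta
  distribution around the type mean, then per-cytosine levels around the gene
  level, with binomial read counts at Poisson depth.  Site-level simulation
  means the coverage rule, the read-weighted region mean, and the metagene
  machinery are genuinely exercised.  Flanking sequence follows the type:
  TE-like genes are methylated straight across their TSS, while UM/gbM genes
  get a modest upstream mCHH bump.
* Expression is log-normal: a per-pangene baseline, a per-tissue effect, and
  per-gene noise, times an epiallele multiplier — gbM epialleles are
  expressed ``(1 + delta_gbm)`` relative to UM (attenuated in endosperm), and
  teM epialleles are strongly silenced.

All randomness flows from one integer seed through named substreams, so any
product (a single genome's methylome, say) is reproducible regardless of the
order in which products are requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import BedRecord, GeneModel, write_bed, write_gff3
from .expression import DEFAULT_TISSUES, write_matrix
from .methylome import CGMAP_COLUMNS, write_cgmap
from .pangenes import DEFINED_TYPES, PangeneTable, classify_pangene

TE_SUPERFAMILIES = (
    "Gypsy", "Copia", "hAT", "CACTA", "Mutator", "PIF_Harbinger", "Tc1_Mariner",
    "LINE", "Helitron",
)

_STREAM = {"core": 1, "structure": 2, "methylome": 3, "expression": 4, "counts": 5}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study-like conditions."""

    n_genomes: int = 26
    n_pangenes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    # ancestral epiallele frequencies (must sum to 1)
    epiallele_freqs: dict = field(
        default_factory=lambda: {"UM": 0.57, "gbM": 0.31, "teM": 0.12}
    )
    # per-type gene-level methylation: mean and Beta concentration per context
    # Low-methylation contexts get a high Beta concentration: UM and gbM genes
    # have characteristically near-zero mCHG, so the per-type distributions are
    # well separated from the 0.05 boundary rather than leaking across it.
    meth_params: dict = field(
        default_factory=lambda: {
            "UM": {"CG": (0.01, 600.0), "CHG": (0.01, 600.0), "CHH": (0.015, 600.0)},
            "gbM": {"CG": (0.80, 50.0), "CHG": (0.02, 600.0), "CHH": (0.015, 600.0)},
            "teM": {"CG": (0.85, 50.0), "CHG": (0.85, 50.0), "CHH": (0.08, 100.0)},
        }
    )
    site_concentration: float = 2.0     # site-level Beta spread around the gene level
    mean_sites_cg: int = 90
    mean_sites_chg: int = 90
    mean_sites_chh: int = 60
    low_coverage_fraction: float = 0.05  # genes simulated with < 40 CG/CHG sites
    read_depth: float = 20.0             # Poisson mean per cytosine

    # pangene table structure
    p_missing: float = 0.005
    p_unannotated: float = 0.01
    p_duplicate: float = 0.012           # per gene cell
    copy_geom_p: float = 0.6             # copies = 2 + Geometric(p) - 1, capped
    max_copies: int = 47
    p_partial_duplicate: float = 0.10    # truncated duplicate copies
    p_partial_singleton: float = 0.01

    # epiallele instability
    p_unstable: float = 0.035            # pangenes with segregating singleton states
    unstable_pair_weights: dict = field(
        default_factory=lambda: {
            "UM-gbM": 0.930, "UM-teM": 0.028, "gbM-teM": 0.031, "UM-gbM-teM": 0.011
        }
    )
    # duplicate epiallele switch rates (from -> to), per duplicate copy
    switch_rates: dict = field(
        default_factory=lambda: {
            ("UM", "gbM"): 0.007, ("UM", "teM"): 0.015,
            ("gbM", "UM"): 0.069, ("gbM", "teM"): 0.036,
            ("teM", "UM"): 0.030, ("teM", "gbM"): 0.020,
        }
    )

    # gene structure
    median_cds_len: int = 1200
    cds_len_sigma: float = 0.35          # log-normal spread across pangenes
    mean_exons: dict = field(
        default_factory=lambda: {"UM": 3.2, "gbM": 9.8, "teM": 3.4}
    )
    mean_intron_total: dict = field(
        default_factory=lambda: {"UM": 1144.0, "gbM": 5481.0, "teM": 1200.0}
    )
    utr_absent_prob: dict = field(
        default_factory=lambda: {"UM": 0.063, "gbM": 0.0038, "teM": 0.591}
    )
    p_intron_te: dict = field(
        default_factory=lambda: {"UM": 0.15, "gbM": 0.45, "teM": 0.20}
    )
    p_cds_te: dict = field(
        default_factory=lambda: {"UM": 0.034, "gbM": 0.053, "teM": 0.346}
    )
    synteny_prob: dict = field(
        default_factory=lambda: {"UM": 0.70, "gbM": 0.75, "teM": 0.14}
    )
    intergenic_bp: int = 6500
    flank_sites_per_context: int = 15    # per 3-kb flank
    upstream_chh_bump: float = 0.08      # mCHH just upstream of UM/gbM TSSs

    # expression model (natural-log scale)
    log_tpm_mean: float = float(np.log(20.0))
    sigma_baseline: float = 0.3
    sigma_tissue: float = 0.2
    sigma_genome: float = 0.15
    delta_gbm: float = 0.03              # gbM multiplier is 1 + delta_gbm
    delta_gbm_endosperm: float = 0.005
    tem_multiplier: float = 0.02

    def validate(self) -> None:
        freqs = np.array([self.epiallele_freqs[t] for t in DEFINED_TYPES])
        if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError(
                f"epiallele frequencies must be non-negative and sum to 1, got {freqs}"
            )
        for name in (
            "p_missing", "p_unannotated", "p_duplicate", "p_unstable",
            "low_coverage_fraction", "p_partial_duplicate", "p_partial_singleton",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for k, v in self.switch_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"switch rate {k} must lie in [0, 1], got {v}")
        if self.n_genomes < 2 or self.n_pangenes < 1:
            raise ValueError("need at least 2 genomes and 1 pangene")


@dataclass
class TruthSet:
    """Ground truth recorded during simulation."""

    genes: pd.DataFrame            # one row per gene: genome, pangene, epiallele, ...
    pangenes: pd.DataFrame         # per-pangene: base type, unstable types, core
    delta_gbm: float
    switch_rates: dict

    def epiallele_map(self, genome: str | None = None) -> dict[str, str]:
        df = self.genes if genome is None else self.genes[self.genes["genome"] == genome]
        return dict(zip(df["gene_id"], df["epiallele"]))


def _genome_name(j: int) -> str:
    return f"G{j + 1:02d}"


class SimResult:
    """Handle to one simulated pan-genome; heavy products are built lazily."""

    def __init__(self, cfg: SimConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        self.seed = int(seed)
        self.genomes = [_genome_name(j) for j in range(cfg.n_genomes)]
        self._structures: dict[str, tuple[list[GeneModel], list[BedRecord]]] = {}
        self._methylomes: dict[str, pd.DataFrame] = {}
        self._tpm: dict[str, pd.DataFrame] = {}
        self._build_core()

    def _rng(self, stream: str, genome_idx: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream], genome_idx])

    # ------------------------------------------------------------------
    # core assignment: pangene structure, epialleles, CDS lengths
    # ------------------------------------------------------------------
    def _build_core(self) -> None:
        cfg = self.cfg
        rng = self._rng("core")
        nP, nG = cfg.n_pangenes, cfg.n_genomes
        types = np.array(DEFINED_TYPES)
        freqs = np.array([cfg.epiallele_freqs[t] for t in DEFINED_TYPES])
        base = rng.choice(types, size=nP, p=freqs)

        unstable = rng.random(nP) < cfg.p_unstable
        # only type combinations whose members all have non-zero base frequency
        supported = {t for t in DEFINED_TYPES if cfg.epiallele_freqs[t] > 0}
        pair_names = [
            k for k in cfg.unstable_pair_weights if set(k.split("-")) <= supported
        ]
        if not pair_names:
            unstable[:] = False
            pair_names = list(cfg.unstable_pair_weights)
        pair_w = np.array([cfg.unstable_pair_weights[k] for k in pair_names], dtype=float)
        pair_w = pair_w / pair_w.sum()
        pair_choice = rng.choice(len(pair_names), size=nP, p=pair_w)

        # per-genome singleton state
        state = np.tile(base[:, None], (1, nG))
        for i in np.flatnonzero(unstable):
            members = pair_names[pair_choice[i]].split("-")
            if len(members) == 2:
                f_minor = rng.uniform(0.2, 0.5)
                probs = [1 - f_minor, f_minor]
            else:
                probs = rng.dirichlet([4.0, 4.0, 4.0])
            state[i] = rng.choice(members, size=nG, p=np.asarray(probs) / np.sum(probs))

        missing = rng.random((nP, nG)) < cfg.p_missing
        unannot = (~missing) & (rng.random((nP, nG)) < cfg.p_unannotated)
        genecell = ~missing & ~unannot
        dup = genecell & (rng.random((nP, nG)) < cfg.p_duplicate)
        copies = np.ones((nP, nG), dtype=int)
        n_dup = int(dup.sum())
        copies[dup] = np.minimum(2 + rng.geometric(cfg.copy_geom_p, size=n_dup) - 1,
                                 cfg.max_copies)

        base_len = np.exp(rng.normal(np.log(cfg.median_cds_len), cfg.cds_len_sigma, nP))
        base_len = np.maximum(base_len, 300).astype(int)

        # per-gene records
        recs: dict[str, list] = {
            "gene_id": [], "genome": [], "pangene": [], "pangene_idx": [],
            "copy_idx": [], "epiallele": [], "cds_len": [], "partial": [],
            "is_duplicate": [],
        }
        pangene_ids = [f"pg{i:05d}" for i in range(nP)]
        cells: list[list] = []
        switch_to = {
            t: [u for u in DEFINED_TYPES if u != t] for t in DEFINED_TYPES
        }
        switch_p = {
            t: [cfg.switch_rates.get((t, u), 0.0) for u in switch_to[t]]
            for t in DEFINED_TYPES
        }
        for i in range(nP):
            row: list = []
            for j in range(nG):
                if missing[i, j]:
                    row.append(None)
                    continue
                if unannot[i, j]:
                    row.append(f"chr1:{1000 * i + 1}-{1000 * i + 900}")
                    continue
                k = copies[i, j]
                s = state[i, j]
                ids = []
                for c in range(k):
                    gid = f"{self.genomes[j]}g{i:05d}.{c + 1}"
                    ids.append(gid)
                    if k > 1:
                        # duplicate copy: may switch type, may be partial
                        u = rng.random()
                        ep = s
                        acc = 0.0
                        for t_to, p_sw in zip(switch_to[s], switch_p[s]):
                            acc += p_sw
                            if u < acc:
                                ep = t_to
                                break
                        partial = rng.random() < cfg.p_partial_duplicate
                    else:
                        ep = s
                        partial = rng.random() < cfg.p_partial_singleton
                    if partial:
                        length = int(base_len[i] * rng.uniform(0.40, 0.85))
                    else:
                        length = int(base_len[i] * rng.uniform(0.97, 1.03))
                    recs["gene_id"].append(gid)
                    recs["genome"].append(self.genomes[j])
                    recs["pangene"].append(pangene_ids[i])
                    recs["pangene_idx"].append(i)
                    recs["copy_idx"].append(c)
                    recs["epiallele"].append(ep)
                    recs["cds_len"].append(max(length, 150))
                    recs["partial"].append(partial)
                    recs["is_duplicate"].append(k > 1)
                row.append(tuple(ids))
            cells.append(row)

        self.genes = pd.DataFrame(recs)
        self.pangene_table = PangeneTable(
            pd.DataFrame(cells, index=pd.Index(pangene_ids, name="pangene_id"),
                         columns=self.genomes)
        )
        # gene-level methylation
        rng_m = self._rng("core", 999)
        n_genes = len(self.genes)
        lev = {}
        for ctx in ("CG", "CHG", "CHH"):
            mean = np.array(
                [cfg.meth_params[t][ctx][0] for t in self.genes["epiallele"]]
            )
            conc = np.array(
                [cfg.meth_params[t][ctx][1] for t in self.genes["epiallele"]]
            )
            lev[ctx] = rng_m.beta(mean * conc, (1 - mean) * conc, n_genes)
        self.genes["mCG_true"] = lev["CG"]
        self.genes["mCHG_true"] = lev["CHG"]
        self.genes["mCHH_true"] = lev["CHH"]
        self.genes["low_coverage_sim"] = rng_m.random(n_genes) < cfg.low_coverage_fraction

        pangene_truth = pd.DataFrame(
            {
                "base_type": base,
                "unstable": unstable,
                "unstable_types": [
                    pair_names[pair_choice[i]] if unstable[i] else ""
                    for i in range(nP)
                ],
                "base_cds_len": base_len,
                "core": ~missing.any(axis=1),
            },
            index=pd.Index(pangene_ids, name="pangene_id"),
        )
        self.truth = TruthSet(
            genes=self.genes[
                ["gene_id", "genome", "pangene", "epiallele", "cds_len", "partial",
                 "is_duplicate", "low_coverage_sim"]
            ].copy(),
            pangenes=pangene_truth,
            delta_gbm=cfg.delta_gbm,
            switch_rates=dict(cfg.switch_rates),
        )

    # ------------------------------------------------------------------
    def cds_lengths(self) -> dict[str, int]:
        return dict(zip(self.genes["gene_id"], self.genes["cds_len"]))

    def true_classes(self) -> pd.DataFrame:
        """Pangene classes implied by the latent truth (intact genes, true labels)."""
        labels = dict(zip(self.genes["gene_id"], self.genes["epiallele"]))
        partial = dict(zip(self.genes["gene_id"], self.genes["partial"]))
        recs = []
        for pid, row in self.pangene_table.cells.iterrows():
            if not self.truth.pangenes.loc[pid, "core"]:
                recs.append({"pangene_id": pid, "class": None, "subtype": None,
                             "singleton_epiallele": None})
                continue
            cells = [
                tuple(g for g in c if not partial[g]) if isinstance(c, tuple) else c
                for c in row
            ]
            pc = classify_pangene(cells, labels)
            recs.append({"pangene_id": pid, "class": pc.cls, "subtype": pc.subtype,
                         "singleton_epiallele": pc.singleton_epiallele})
        return pd.DataFrame(recs).set_index("pangene_id")

    # ------------------------------------------------------------------
    # gene structures and TE tracks
    # ------------------------------------------------------------------
    def structures(self, genome: str) -> tuple[list[GeneModel], list[BedRecord]]:
        if genome in self._structures:
            return self._structures[genome]
        cfg = self.cfg
        j = self.genomes.index(genome)
        rng = self._rng("structure", j)
        sub = self.genes[self.genes["genome"] == genome]
        models: list[GeneModel] = []
        tes: list[BedRecord] = []
        cursor = cfg.intergenic_bp
        for row in sub.itertuples():
            ep = row.epiallele
            cds_len = int(row.cds_len)
            n_ex = 1 + rng.poisson(max(cfg.mean_exons[ep] - 1, 0.0))
            if n_ex > 1:
                intron_total = int(
                    np.exp(rng.normal(np.log(cfg.mean_intron_total[ep]), 0.6))
                )
                intron_total = max(intron_total, 20 * (n_ex - 1))
                w = rng.dirichlet(np.ones(n_ex - 1))
                introns = np.maximum((w * intron_total).astype(int), 20)
            else:
                introns = np.array([], dtype=int)
            w = rng.dirichlet(np.ones(n_ex))
            cds_parts = np.maximum((w * cds_len).astype(int), 30)
            cds_parts[-1] += cds_len - cds_parts.sum()  # keep total exact
            if cds_parts[-1] < 30:
                cds_parts = np.array([cds_len])
                introns = np.array([], dtype=int)
                n_ex = 1
            has_utr = rng.random() >= cfg.utr_absent_prob[ep]
            u5 = int(rng.uniform(80, 350)) if has_utr else 0
            u3 = int(rng.uniform(100, 450)) if has_utr else 0
            strand = "+" if rng.random() < 0.5 else "-"

            # lay out in transcript order, then map to genome coordinates
            parts = list(cds_parts)
            start = cursor
            exons, cds_ivs = [], []
            if strand == "+":
                pos = start
                first_ex_start = pos
                pos += u5
                for k, c in enumerate(parts):
                    ex_start = pos if k > 0 else first_ex_start
                    cds_ivs.append((pos, pos + c))
                    pos += c
                    ex_end = pos + (u3 if k == n_ex - 1 else 0)
                    exons.append((ex_start, ex_end))
                    if k < n_ex - 1:
                        pos += introns[k]
                end = exons[-1][1]
                utr5 = [(start, start + u5)] if u5 else []
                utr3 = [(end - u3, end)] if u3 else []
            else:
                # transcript runs right-to-left: 5' UTR at the high end
                pos = start
                # walk 3' -> 5' left to right
                rev_parts = parts[::-1]
                rev_introns = introns[::-1] if n_ex > 1 else introns
                first_ex_start = pos
                pos += u3
                for k, c in enumerate(rev_parts):
                    ex_start = pos if k > 0 else first_ex_start
                    cds_ivs.append((pos, pos + c))
                    pos += c
                    ex_end = pos + (u5 if k == n_ex - 1 else 0)
                    exons.append((ex_start, ex_end))
                    if k < n_ex - 1:
                        pos += rev_introns[k]
                end = exons[-1][1]
                utr3 = [(start, start + u3)] if u3 else []
                utr5 = [(end - u5, end)] if u5 else []
            g = GeneModel(
                gene_id=row.gene_id, chrom="chr1", strand=strand, start=start, end=end,
                exons=sorted(exons), cds=sorted(cds_ivs), utr5=utr5, utr3=utr3,
            )
            models.append(g)

            from .annotations import derive_introns as _derive

            gene_introns = _derive(g)
            if gene_introns and rng.random() < cfg.p_intron_te[ep]:
                s, e = gene_introns[rng.integers(len(gene_introns))]
                if e - s > 60:
                    te_len = int(rng.uniform(50, min(e - s, 3000)))
                    te_s = int(rng.integers(s, e - te_len + 1))
                    fam = TE_SUPERFAMILIES[rng.integers(len(TE_SUPERFAMILIES))]
                    tes.append(BedRecord("chr1", te_s, te_s + te_len, fam))
            if rng.random() < cfg.p_cds_te[ep]:
                cs, ce = cds_ivs[rng.integers(len(cds_ivs))]
                ov = int(rng.uniform(110, 500))
                te_s = max(cs, ce - ov)
                fam = TE_SUPERFAMILIES[rng.integers(len(TE_SUPERFAMILIES))]
                tes.append(BedRecord("chr1", te_s, te_s + ov + 200, fam))
            cursor = end + cfg.intergenic_bp
        tes.sort(key=lambda r: (r.start, r.end))
        self._structures[genome] = (models, tes)
        return models, tes

    def synteny_table(self, genome: str) -> dict[str, bool]:
        j = self.genomes.index(genome)
        rng = self._rng("structure", 1000 + j)
        sub = self.genes[self.genes["genome"] == genome]
        p = np.array([self.cfg.synteny_prob[t] for t in sub["epiallele"]])
        flags = rng.random(len(sub)) < p
        return dict(zip(sub["gene_id"], (bool(f) for f in flags)))

    # ------------------------------------------------------------------
    # methylomes
    # ------------------------------------------------------------------
    def methylome(self, genome: str, include_flanks: bool = True) -> pd.DataFrame:
        """CGmap-column DataFrame for one genome (genic CDS sites + flanks)."""
        if genome in self._methylomes:
            return self._methylomes[genome]
        cfg = self.cfg
        j = self.genomes.index(genome)
        rng = self._rng("methylome", j)
        models, _ = self.structures(genome)
        sub = self.genes[self.genes["genome"] == genome].set_index("gene_id")

        pos_list, ctx_list, lvl_gene, sub_ctx = [], [], [], []
        mean_sites = {"CG": cfg.mean_sites_cg, "CHG": cfg.mean_sites_chg,
                      "CHH": cfg.mean_sites_chh}
        for g in models:
            row = sub.loc[g.gene_id]
            glev = {"CG": row["mCG_true"], "CHG": row["mCHG_true"],
                    "CHH": row["mCHH_true"]}
            # genic sites: evenly spaced within CDS with a random phase,
            # contexts interleaved on distinct residue classes (no collisions)
            cds = sorted(g.cds)
            lens = np.array([e - s for s, e in cds])
            starts = np.array([s for s, _ in cds])
            cum = np.concatenate(([0], np.cumsum(lens)))
            total = int(cum[-1])
            for ci, ctx in enumerate(("CG", "CHG", "CHH")):
                slots = total // 3
                if row["low_coverage_sim"] and ctx in ("CG", "CHG"):
                    n = int(rng.integers(5, 40))
                else:
                    n = int(rng.poisson(mean_sites[ctx]))
                n = min(max(n, 1), max(slots, 1))
                stride = slots / n
                phase = rng.uniform(0, stride)
                offs = (np.floor(phase + stride * np.arange(n)).astype(int)) * 3 + ci
                offs = offs[offs < total]
                seg = np.searchsorted(cum, offs, side="right") - 1
                gpos = starts[seg] + (offs - cum[seg])
                pos_list.append(gpos)
                ctx_list.append(np.full(len(gpos), ctx))
                lvl_gene.append(np.full(len(gpos), glev[ctx]))
            if include_flanks:
                for ctx in ("CG", "CHG", "CHH"):
                    nf = cfg.flank_sites_per_context
                    up = g.tss - rng.integers(1, 3000, nf) if g.strand == "+" else (
                        g.tss + rng.integers(1, 3000, nf)
                    )
                    dn = g.polya + rng.integers(1, 3000, nf) if g.strand == "+" else (
                        g.polya - rng.integers(1, 3000, nf)
                    )
                    if row["epiallele"] == "teM":
                        lev_up = lev_dn = 0.85 if ctx in ("CG", "CHG") else 0.05
                    else:
                        if ctx == "CHH":
                            # upstream mCHH bump within 500 bp of the TSS
                            near = (
                                np.abs(up - g.tss) <= 500
                            )
                            lev_up = np.where(near, cfg.upstream_chh_bump, 0.02)
                            lev_dn = 0.02
                        else:
                            lev_up = lev_dn = 0.02
                    for posv, levv in ((up, lev_up), (dn, lev_dn)):
                        posv = posv[posv >= 0]
                        pos_list.append(posv)
                        ctx_list.append(np.full(len(posv), ctx))
                        lvl_gene.append(np.broadcast_to(levv, (nf,))[: len(posv)].astype(float))

        pos = np.concatenate(pos_list)
        ctx = np.concatenate(ctx_list)
        gl = np.clip(np.concatenate(lvl_gene), 1e-4, 1 - 1e-4)
        n_sites = len(pos)
        depth = rng.poisson(cfg.read_depth, n_sites)
        keep = depth > 0
        pos, ctx, gl, depth = pos[keep], ctx[keep], gl[keep], depth[keep]
        sc = cfg.site_concentration
        p_site = rng.beta(gl * sc, (1 - gl) * sc)
        n_meth = rng.binomial(depth, p_site)
        order = np.argsort(pos, kind="stable")
        subctx = np.where(ctx == "CG", "CG",
                          np.array(["CA", "CT", "CC"])[rng.integers(0, 3, len(pos))])
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "strand_base": np.where(rng.random(len(pos)) < 0.5, "C", "G"),
                "pos": pos + 1,  # CGmap positions are 1-based
                "context": ctx,
                "subcontext": subctx,
                "level": n_meth / depth,
                "n_meth": n_meth,
                "n_total": depth,
            }
        )[list(CGMAP_COLUMNS)].iloc[order].reset_index(drop=True)
        self._methylomes[genome] = df
        return df

    # ------------------------------------------------------------------
    # expression
    # ------------------------------------------------------------------
    def tpm(self, genome: str) -> pd.DataFrame:
        """Genes x tissues TPM matrix for one genome."""
        if genome in self._tpm:
            return self._tpm[genome]
        cfg = self.cfg
        j = self.genomes.index(genome)
        sub = self.genes[self.genes["genome"] == genome]
        nT = len(cfg.tissues)
        # pangene baseline and tissue effects are shared across genomes
        rng_shared = self._rng("expression", 10_000)
        b = rng_shared.normal(cfg.log_tpm_mean, cfg.sigma_baseline, cfg.n_pangenes)
        e = rng_shared.normal(0.0, cfg.sigma_tissue, (cfg.n_pangenes, nT))
        rng = self._rng("expression", j)
        pi = sub["pangene_idx"].to_numpy()
        noise = rng.normal(0.0, cfg.sigma_genome, (len(sub), nT))
        log_tpm = b[pi][:, None] + e[pi] + noise
        tpm = np.exp(log_tpm)
        mult = np.ones((len(sub), nT))
        ep = sub["epiallele"].to_numpy()
        gbm_mult = np.full(nT, 1.0 + cfg.delta_gbm)
        if "endosperm" in cfg.tissues:
            gbm_mult[cfg.tissues.index("endosperm")] = 1.0 + cfg.delta_gbm_endosperm
        mult[ep == "gbM"] = gbm_mult
        mult[ep == "teM"] = cfg.tem_multiplier
        df = pd.DataFrame(
            tpm * mult, index=pd.Index(sub["gene_id"], name="gene_id"),
            columns=list(cfg.tissues)
        )
        self._tpm[genome] = df
        return df

    def counts(self, genome: str, library_size: int = 5_000_000) -> pd.DataFrame:
        """Poisson read counts consistent with the genome's TPM and CDS lengths."""
        j = self.genomes.index(genome)
        rng = self._rng("counts", j)
        tpm = self.tpm(genome)
        sub = self.genes[self.genes["genome"] == genome].set_index("gene_id")
        lens = sub.loc[tpm.index, "cds_len"].to_numpy(dtype=float)
        lam = tpm.to_numpy() * lens[:, None]
        lam = lam / lam.sum(axis=0, keepdims=True) * library_size
        return pd.DataFrame(rng.poisson(lam), index=tpm.index, columns=tpm.columns)

    # ------------------------------------------------------------------
    def write(
        self,
        outdir: str | Path,
        genomes: Sequence[str] | None = None,
        gzip_cgmap: bool = False,
    ) -> None:
        """Emit every dialect consumed by the analysis modules."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pangene_table.to_csv(out / "pangene_table.csv")
        self.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.truth.pangenes.to_csv(out / "truth_pangenes.tsv", sep="\t")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "delta_gbm": self.truth.delta_gbm,
                    "switch_rates": {f"{a}->{b}": v for (a, b), v
                                     in self.truth.switch_rates.items()},
                    "seed": self.seed,
                },
                fh, indent=2,
            )
        for g in genomes if genomes is not None else self.genomes:
            gdir = out / g
            gdir.mkdir(exist_ok=True)
            models, tes = self.structures(g)
            write_gff3(models, gdir / "genes.gff3")
            write_bed(tes, gdir / "te.bed")
            suffix = ".gz" if gzip_cgmap else ""
            cg = self.methylome(g)
            if gzip_cgmap:
                import gzip as _gz

                with _gz.open(gdir / f"methylome.cgmap.gz", "wt") as fh:
                    cg.to_csv(fh, sep="\t", header=False, index=False)
            else:
                write_cgmap(cg, gdir / "methylome.cgmap")
            write_matrix(self.tpm(g), gdir / "tpm.tsv")
            syn = self.synteny_table(g)
            pd.DataFrame(
                {"gene_id": list(syn), "synteny_sorghum": [int(v) for v in syn.values()]}
            ).to_csv(gdir / "synteny.tsv", sep="\t", index=False)


def simulate(cfg: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Generate a synthetic pan-genome; see :class:`SimResult` for products."""
    return SimResult(cfg or SimConfig(), seed)


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------

def truth_compare(calls: Mapping[str, pd.DataFrame], sim: SimResult) -> dict:
    """Compare pipeline epiallele calls against generator truth.

    ``calls`` maps genome name to a call table (gene_id index, ``label``
    column).  Returns the pooled confusion matrix over genes passing coverage
    and the overall agreement fraction.
    """
    rows = []
    for genome, table in calls.items():
        truth = sim.truth.epiallele_map(genome)
        unknown = set(table.index) - set(truth)
        if unknown:
            raise ValueError(f"calls contain gene ids not in truth: {sorted(unknown)[:3]}")
        for gid, lab in zip(table.index, table["label"]):
            rows.append((truth[gid], lab))
    df = pd.DataFrame(rows, columns=["truth", "call"])
    covered = df[df["call"] != "low_coverage"]
    confusion = pd.crosstab(covered["truth"], covered["call"])
    agree = float((covered["truth"] == covered["call"]).mean()) if len(covered) else np.nan
    return {"confusion": confusion, "agreement": agree, "n_covered": len(covered)}
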