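"""CGmap parsing and region methylation levels."""

import math

import numpy as np
import pandas as pd
import pytest

from panepi.annotations import GeneModel
from panepi.methylome import (
    CGmapFormatError,
    GeneMethylation,
    SiteRecord,
    cds_methylation_table,
    parse_cgmap_line,
    read_cgmap,
    read_cgmap_frame,
    region_methylation,
    write_cgmap,
)


def make_site(pos, context="CG", n_meth=1, n_total=2, chrom="chr1"):
    return SiteRecord(chrom, pos, "C", context, "CG", n_meth / n_total, n_meth, n_total)


class TestReadCgmap:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.cgmap"
        p.write_text("chr1\tC\t101\tCG\tCG\t0.8\t8\t10\n")
        (rec,) = read_cgmap(p)
        assert (rec.pos, rec.context, rec.n_meth, rec.n_total) == (101, "CG", 8, 10)

    def test_region_filter_excludes_outside_positions(self, tmp_path):
        p = tmp_path / "a.cgmap"
        p.write_text("chr1\tC\t101\tCG\tCG\t0.8\t8\t10\n")
        assert list(read_cgmap(p, regions={"chr1": [(200, 300)]})) == []
        # 1-based position 101 is inside the 0-based half-open region [100, 101)
        assert len(list(read_cgmap(p, regions={"chr1": [(100, 101)]}))) == 1

    def test_malformed_line_reported_with_number(self, tmp_path):
        p = tmp_path / "a.cgmap"
        p.write_text(
            "chr1\tC\t1\tCG\tCG\t0.5\t1\t2\n"
            "chr1\tC\tnotanumber\tCG\tCG\t0.5\t1\t2\n"
            "chr1\tC\t3\tCHH\tCA\t0\t0\t5\n"
        )
        with pytest.raises(CGmapFormatError):
            list(read_cgmap(p))
        errors = []
        recs = list(read_cgmap(p, error_handler=errors.append))
        assert len(recs) == 2 and len(errors) == 1
        assert errors[0].line_number == 2

    def test_unknown_context_token_named(self):
        with pytest.raises(CGmapFormatError, match="XYZ"):
            parse_cgmap_line("chr1\tC\t1\tXYZ\tCG\t0.5\t1\t2", 1)

    def test_gzip_and_frame_agree(self, tmp_path):
        import gzip

        lines = "chr1\tC\t5\tCHG\tCA\t0.25\t1\t4\nchr2\tG\t9\tCG\tCG\t1\t3\t3\n"
        (tmp_path / "a.cgmap").write_text(lines)
        with gzip.open(tmp_path / "a.cgmap.gz", "wt") as fh:
            fh.write(lines)
        recs = list(read_cgmap(tmp_path / "a.cgmap.gz"))
        frame = read_cgmap_frame(tmp_path / "a.cgmap")
        assert len(recs) == len(frame) == 2
        assert list(frame["pos"]) == [r.pos for r in recs]

    def test_write_round_trip(self, tmp_path):
        recs = [make_site(3, "CG", 2, 4), make_site(9, "CHH", 0, 7)]
        write_cgmap(recs, tmp_path / "w.cgmap")
        back = list(read_cgmap(tmp_path / "w.cgmap"))
        assert back == recs


def region_oracle(sites, regions):
    """Per-site accumulation oracle for region methylation (weighted)."""
    sums = {c: [0, 0, 0] for c in ("CG", "CHG", "CHH")}
    for s in sites:
        for rs, re_ in regions.get(s.chrom, []):
            if rs <= s.pos - 1 < re_:
                sums[s.context][0] += s.n_meth
                sums[s.context][1] += s.n_total
                sums[s.context][2] += 1
                break
    return sums


class TestRegionMethylation:
    def test_weighted_mean_forced_by_definition(self):
        sites = [make_site(10, "CG", 2, 10), make_site(20, "CG", 3, 10)]
        gm = region_methylation(sites, {"chr1": [(0, 100)]})
        assert gm.mCG == pytest.approx(5 / 20)
        assert gm.n_sites_CG == 2

    def test_uncovered_context_is_undefined_not_zero(self):
        gm = region_methylation([make_site(10, "CG", 0, 5)], {"chr1": [(0, 100)]})
        assert math.isnan(gm.mCHG) and gm.n_sites_CHG == 0
        assert gm.mCG == 0.0  # covered but unmethylated is a true zero

    def test_all_unmethylated_sites(self):
        sites = [make_site(i, "CG", 0, 5) for i in range(1, 61)]
        gm = region_methylation(sites, {"chr1": [(0, 100)]})
        assert gm.mCG == 0.0 and gm.n_sites_CG == 60

    def test_empty_region_set_is_error(self):
        with pytest.raises(ValueError):
            region_methylation([], {})

    def test_site_mean_variant(self):
        sites = [make_site(10, "CG", 1, 10), make_site(20, "CG", 9, 10)]
        gm = region_methylation(sites, {"chr1": [(0, 100)]}, weighted=False)
        assert gm.mCG == pytest.approx((0.1 + 0.9) / 2)

    def test_matches_accumulation_oracle_randomized(self, rng):
        from panepi.intervals import merge_intervals

        for _ in range(200):
            sites = []
            for _ in range(int(rng.integers(1, 30))):
                m = int(rng.integers(0, 11))
                t = int(rng.integers(m + 1, 21))
                ctx = ["CG", "CHG", "CHH"][rng.integers(3)]
                sites.append(
                    SiteRecord("chr1", int(rng.integers(1, 500)), "C", ctx, "CG",
                               m / t, m, t)
                )
            regions = {
                "chr1": [
                    (int(a := rng.integers(0, 400)), int(a + rng.integers(1, 120)))
                    for _ in range(rng.integers(1, 4))
                ]
            }
            gm = region_methylation(sites, regions)
            oracle = region_oracle(sites, {"chr1": merge_intervals(regions["chr1"])})
            for c in ("CG", "CHG", "CHH"):
                m_, t_, n_ = oracle[c]
                if n_ == 0:
                    assert math.isnan(gm.level(c))
                else:
                    assert gm.level(c) == pytest.approx(m_ / t_)
                assert gm.n_sites(c) == n_

    def test_disjoint_region_additivity(self):
        sites = [make_site(i, "CG", 1, 4) for i in (5, 50, 150)]
        a = region_methylation(sites, {"chr1": [(0, 100)]})
        b = region_methylation(sites, {"chr1": [(100, 200)]})
        both = region_methylation(sites, {"chr1": [(0, 100), (100, 200)]})
        assert both.n_sites_CG == a.n_sites_CG + b.n_sites_CG
        # weighted means pool numerators and denominators additively
        assert both.mCG == pytest.approx(
            (a.mCG * a.n_sites_CG * 4 + b.mCG * b.n_sites_CG * 4)
            / (4 * (a.n_sites_CG + b.n_sites_CG))
        )


class TestVectorizedTable:
    def test_matches_streaming_per_gene(self, rng):
        genes = []
        sites = []
        for gi in range(25):
            start = gi * 1000
            cds = [(start, start + 150), (start + 300, start + 500)]
            genes.append(
                GeneModel(f"g{gi}", "chr1", "+", start, start + 600, cds=cds,
                          exons=[(start, start + 600)])
            )
            for _ in range(rng.integers(5, 40)):
                pos = int(rng.integers(start, start + 620))
                m = int(rng.integers(0, 9))
                t = int(rng.integers(m + 1, 15))
                ctx = ["CG", "CHG", "CHH"][rng.integers(3)]
                sites.append(SiteRecord("chr1", pos + 1, "C", ctx, "CG", m / t, m, t))
        frame = pd.DataFrame(
            {
                "chrom": [s.chrom for s in sites],
                "strand_base": "C",
                "pos": [s.pos for s in sites],
                "context": [s.context for s in sites],
                "subcontext": "CG",
                "level": [s.level for s in sites],
                "n_meth": [s.n_meth for s in sites],
                "n_total": [s.n_total for s in sites],
            }
        )
        table = cds_methylation_table(frame, genes)
        for g in genes:
            gm = region_methylation(sites, {g.chrom: g.cds}, gene_id=g.gene_id)
            row = table.loc[g.gene_id]
            for c in ("CG", "CHG", "CHH"):
                if math.isnan(gm.level(c)):
                    assert math.isnan(row[f"m{c}"])
                else:
                    assert row[f"m{c}"] == pytest.approx(gm.level(c))
                assert row[f"n_sites_{c}"] == gm.n_sites(c)
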