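"""Pangene table parsing, core/intact filters, and stability classification."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from panepi.pangenes import (
    PangeneTable,
    classify_pangene,
    classify_table,
    core_filter,
    count_duplicate_epialleles,
    intact_filter,
    relative_duplication_ratio,
    stable_type_counts,
)


def table_from_rows(rows, genomes=None):
    genomes = genomes or [f"G{j}" for j in range(len(rows[0]))]
    return PangeneTable(
        pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))], columns=genomes)
    )


class TestParsing:
    def test_cell_kinds(self):
        assert PangeneTable.parse_cell("NA") is None
        assert PangeneTable.parse_cell("") is None
        assert PangeneTable.parse_cell("chr3:100-900") == "chr3:100-900"
        assert PangeneTable.parse_cell("geneA") == ("geneA",)
        assert PangeneTable.parse_cell("a;b;c") == ("a", "b", "c")

    def test_csv_round_trip(self, tmp_path):
        t = table_from_rows([[("a",), ("b1", "b2"), None], [("c",), "chr1:5-50", ("d",)]])
        t.to_csv(tmp_path / "t.csv")
        back = PangeneTable.read_csv(tmp_path / "t.csv")
        assert back.cells.equals(t.cells)


class TestCoreFilter:
    def test_all_present_is_core(self):
        t = table_from_rows([[("a",)] * 26])
        assert core_filter(t).all()

    def test_one_missing_breaks_core(self):
        t = table_from_rows([[("a",)] * 25 + [None]])
        assert not core_filter(t).any()

    def test_coordinate_cell_counts_as_present(self):
        t = table_from_rows([[("a",)] * 25 + ["chr1:10-500"]])
        assert core_filter(t).all()


class TestIntactFilter:
    def test_strict_ten_percent_boundary(self):
        t = table_from_rows([[("a",), ("b",), ("c",), ("d1", "d2")]])
        lens = {"a": 1000, "b": 1000, "c": 1020, "d1": 1099, "d2": 1100}
        filtered, report = intact_filter(t, lens)
        assert report.loc["p0", "median_cds_len"] == 1000
        assert filtered.cells.loc["p0"].iloc[3] == ("d1",)  # 1099 kept, 1100 dropped

    def test_singleton_outside_band_dropped(self):
        t = table_from_rows([[("a",), ("b",), ("c",)]])
        lens = {"a": 1000, "b": 1000, "c": 899}  # |899-1000|/1000 = 0.101
        filtered, _ = intact_filter(t, lens)
        assert filtered.cells.loc["p0"].iloc[2] == ()

    def test_identical_lengths_all_kept(self):
        t = table_from_rows([[("a",), ("b", "c")]])
        filtered, report = intact_filter(t, {g: 500 for g in "abc"})
        assert report.loc["p0", "n_dropped"] == 0

    def test_zero_singletons_excludes_pangene(self):
        t = table_from_rows([[("a1", "a2"), ("b1", "b2")]])
        filtered, report = intact_filter(t, {g: 100 for g in ("a1", "a2", "b1", "b2")})
        assert report.loc["p0", "excluded"]
        assert all(c == () for c in filtered.cells.loc["p0"])

    def test_missing_length_is_error(self):
        t = table_from_rows([[("a",), ("b",)]])
        with pytest.raises(KeyError):
            intact_filter(t, {"a": 100})

    def test_idempotent_on_simulated_table(self, tiny_sim):
        lens = tiny_sim.cds_lengths()
        f1, _ = intact_filter(tiny_sim.pangene_table, lens)
        f2, _ = intact_filter(f1, lens)
        assert f1.cells.equals(f2.cells)


def classify_oracle(cells, labels):
    """Independent restatement of the classification rules from raw counts."""
    gene_cells = [c for c in cells if isinstance(c, tuple) and len(c) > 0]
    singles = [c[0] for c in gene_cells if len(c) == 1]
    has_dup = any(len(c) >= 2 for c in gene_cells)
    defined = [labels[g] for g in singles if labels.get(g) in ("UM", "gbM", "teM")]
    cnt = Counter(defined)
    if has_dup:
        if len(singles) >= 2 and len(defined) >= 2 and len(cnt) == 1:
            return "one_to_N", next(iter(cnt)), None
        return "other", None, None
    if len(cnt) == 1 and len(defined) >= 2:
        return "stable_1to1", None, None
    if len(cnt) >= 2 and min(cnt.values()) >= 2:
        sub = "-".join(t for t in ("UM", "gbM", "teM") if t in cnt)
        return "unstable_1to1", None, sub
    return "other", None, None


class TestClassify:
    def test_one_to_n(self):
        cells = [("s%d" % i,) for i in range(24)] + [("d1", "d2", "d3"), ("e1", "e2", "e3")]
        labels = {f"s{i}": "UM" for i in range(24)}
        labels.update({g: "UM" for g in ("d1", "d2", "d3", "e1", "e2", "e3")})
        pc = classify_pangene(cells, labels)
        assert pc.cls == "one_to_N" and pc.singleton_epiallele == "UM"

    def test_unstable_split(self):
        cells = [(f"g{i}",) for i in range(26)]
        labels = {f"g{i}": "UM" if i < 13 else "gbM" for i in range(26)}
        pc = classify_pangene(cells, labels)
        assert (pc.cls, pc.subtype) == ("unstable_1to1", "UM-gbM")

    def test_minor_type_needs_two_genomes(self):
        cells = [(f"g{i}",) for i in range(26)]
        labels = {f"g{i}": "gbM" for i in range(25)}
        labels["g25"] = "teM"
        assert classify_pangene(cells, labels).cls == "other"

    def test_undefined_singletons_are_neutral(self):
        cells = [(f"g{i}",) for i in range(5)]
        labels = {"g0": "gbM", "g1": "gbM", "g2": "undetermined",
                  "g3": "low_coverage"}
        assert classify_pangene(cells, labels).cls == "stable_1to1"

    def test_exhaustive_six_genome_enumeration(self):
        """All label assignments of a 6-genome singleton table match the oracle."""
        cells = [(f"g{i}",) for i in range(6)]
        alphabet = ["UM", "gbM", "teM", "undetermined"]
        n_checked = 0
        for combo in itertools.product(alphabet, repeat=6):
            labels = {f"g{i}": combo[i] for i in range(6)}
            pc = classify_pangene(cells, labels)
            cls, se, sub = classify_oracle(cells, labels)
            assert (pc.cls, pc.singleton_epiallele, pc.subtype) == (cls, se, sub), combo
            n_checked += 1
        assert n_checked == 4 ** 6

    def test_randomized_tables_with_duplicates_match_oracle(self, rng):
        alphabet = ["UM", "gbM", "teM", "undetermined", "low_coverage"]
        for _ in range(1000):
            n_genomes = int(rng.integers(2, 7))
            cells, labels = [], {}
            gid = 0
            for j in range(n_genomes):
                kind = rng.random()
                if kind < 0.1:
                    cells.append(None)
                elif kind < 0.15:
                    cells.append("chr1:1-2")
                elif kind < 0.25:
                    cells.append(())
                else:
                    k = 1 if rng.random() < 0.7 else int(rng.integers(2, 5))
                    ids = tuple(f"x{gid + i}" for i in range(k))
                    gid += k
                    for g in ids:
                        labels[g] = alphabet[rng.integers(len(alphabet))]
                    cells.append(ids)
            pc = classify_pangene(cells, labels)
            assert (pc.cls, pc.singleton_epiallele, pc.subtype) == classify_oracle(
                cells, labels
            )

    def test_classes_partition_core_pangenes(self, tiny_sim, tiny_calls):
        from panepi.epialleles import epiallele_map

        labels = {}
        for t in tiny_calls.values():
            labels.update(epiallele_map(t))
        core = core_filter(tiny_sim.pangene_table)
        filtered, rep = intact_filter(tiny_sim.pangene_table, tiny_sim.cds_lengths())
        classes = classify_table(filtered, labels, core, rep["excluded"])
        classified = classes["class"].notna().sum()
        assert classified == (core & ~rep["excluded"]).sum()
        assert set(classes["class"].dropna()) <= {
            "one_to_N", "stable_1to1", "unstable_1to1", "other"
        }


class TestDuplicateCounts:
    def make_setup(self):
        cells = [("s1",), ("s2",), ("d1", "d2", "d3")]
        labels = {"s1": "UM", "s2": "UM", "d1": "UM", "d2": "UM", "d3": "teM"}
        t = table_from_rows([cells])
        classes = pd.DataFrame(
            {"class": ["one_to_N"], "subtype": [None], "singleton_epiallele": ["UM"]},
            index=pd.Index(["p0"], name="pangene_id"),
        )
        return t, classes, labels

    def test_three_copy_cell_in_min2_not_min4(self):
        t, classes, labels = self.make_setup()
        c2 = count_duplicate_epialleles(t, classes, labels, min_copy=2)
        assert c2.loc["UM", "UM"] == 2 and c2.loc["UM", "teM"] == 1
        c4 = count_duplicate_epialleles(t, classes, labels, min_copy=4)
        assert c4.to_numpy().sum() == 0

    def test_four_copy_cell_in_both_strata(self):
        cells = [("s1",), ("s2",), ("d1", "d2", "d3", "d4")]
        labels = {g: "gbM" for g in ("s1", "s2", "d1", "d2", "d3", "d4")}
        t = table_from_rows([cells])
        classes = pd.DataFrame(
            {"class": ["one_to_N"], "subtype": [None], "singleton_epiallele": ["gbM"]},
            index=pd.Index(["p0"], name="pangene_id"),
        )
        for mc in (2, 4):
            c = count_duplicate_epialleles(t, classes, labels, min_copy=mc)
            assert c.loc["gbM", "gbM"] == 4


class TestRelativeDuplication:
    def test_published_style_worked_example(self):
        out = relative_duplication_ratio(
            {"UM": 4149, "gbM": 1589, "teM": 232},
            {"UM": 7001, "gbM": 5992, "teM": 277},
        )
        assert round(out["fold_UM_vs_gbM"], 1) == 2.2

    def test_equal_counts_fold_one(self):
        out = relative_duplication_ratio({"UM": 5, "gbM": 5, "teM": 5},
                                         {"UM": 5, "gbM": 5, "teM": 5})
        assert out["fold_UM_vs_gbM"] == 1.0

    def test_zero_denominator_warns_and_is_nan(self):
        with pytest.warns(UserWarning):
            out = relative_duplication_ratio({"UM": 1, "gbM": 1, "teM": 0},
                                             {"UM": 1, "gbM": 0, "teM": 1})
        assert np.isnan(out["fold_UM_vs_gbM"])
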