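"""Epiallele-expression statistics over pangene matrices.

Inputs are pangene x genome matrices: ``DT`` of TPM values (one per tissue)
and ``DE`` of epiallele labels.  With ``I_e(DE)`` the 0/1 indicator of
epiallele type ``e``, the mean TPM of type ``e`` in pangene ``i`` is

    mean_i(e) = sum_j DT[i,j] * I_e[i,j] / sum_j I_e[i,j]

undefined when no genome of that type exists.  Per-pangene gbM-UM differences
``d_i = mean_i(gbM) - mean_i(UM)`` feed an exact two-sided binomial sign test
(ties excluded from n) and a two-sided Wilcoxon signed-rank test (zeros
dropped).  The median difference is also reported as a percentage of the mean
UM TPM over the same pangene set and tissue; medians are preferred because a
few highly expressed epialleles skew the means.

A separate analysis treats methylation as a quantitative variable: per-pangene
Pearson correlation of mCG (or mCHG) with TPM across genomes, restricted to
pangenes whose methylation range is at least 0.2 with at least three usable
genes and non-zero spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pangenes import DEFINED_TYPES, PangeneTable, _is_genes


def pangene_matrix(
    table: PangeneTable, values: Mapping[str, float], singletons_only: bool = True
) -> pd.DataFrame:
    """Build a pangene x genome matrix from per-gene values.

    Singleton cells contribute their gene's value; missing, coordinate-only,
    empty, and (by default) tandem-duplicate cells are ``NaN``.
    """
    def cell_value(cell):
        if not _is_genes(cell):
            return np.nan
        if len(cell) == 1:
            return values.get(cell[0], np.nan)
        if singletons_only:
            return np.nan
        vals = [values[g] for g in cell if g in values]
        return float(np.mean(vals)) if vals else np.nan

    return table.cells.map(cell_value).astype(float)


def pangene_label_matrix(table: PangeneTable, labels: Mapping[str, str]) -> pd.DataFrame:
    """Pangene x genome matrix of epiallele labels (singleton cells only)."""
    def cell_label(cell):
        if _is_genes(cell) and len(cell) == 1:
            return labels.get(cell[0])
        return None

    return table.cells.map(cell_label)


def indicator(de: pd.DataFrame, etype: str) -> pd.DataFrame:
    """0/1 indicator matrix I_e(DE); indicators over types sum to at most 1."""
    if etype not in DEFINED_TYPES:
        raise ValueError(f"unknown epiallele type {etype!r}")
    return (de == etype).astype(int)


def mean_tpm_per_epiallele(dt: pd.DataFrame, de: pd.DataFrame, etype: str) -> pd.Series:
    """Per-pangene mean TPM over genomes carrying epiallele ``etype``.

    ``NaN`` TPM cells are excluded from both numerator and denominator;
    pangenes with no genome of the type are ``NaN``.
    """
    if dt.shape != de.shape:
        raise ValueError(f"shape mismatch: DT {dt.shape} vs DE {de.shape}")
    ind = indicator(de, etype).to_numpy()
    vals = dt.to_numpy(dtype=float)
    ok = ind.astype(bool) & ~np.isnan(vals)
    num = np.where(ok, vals, 0.0).sum(axis=1)
    den = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return pd.Series(out, index=dt.index, name=f"mean_tpm_{etype}")


@dataclass
class PairedDifferenceResult:
    tissue: str
    n: int                      # pangenes with both means defined
    n_pos: int
    n_neg: int
    n_tie: int
    median_d: float
    mean_d: float
    mean_um: float
    normalized_median_pct: float
    sign_test_p: float
    sign_test_p_with_ties: float
    wilcoxon_p: float
    differences: pd.Series = field(repr=False, default=None)


def paired_difference_tests(
    d: pd.Series | Sequence[float],
    mean_um: pd.Series | Sequence[float] | None = None,
    tissue: str = "",
) -> PairedDifferenceResult:
    """Sign and signed-rank tests on per-pangene TPM differences.

    ``d`` should contain only pangenes where both epiallele means are defined
    (NaNs are dropped here as a convenience).  The sign test is the exact
    two-sided binomial test of ``n_pos`` successes out of the non-tied pairs
    at p = 0.5; a variant counting ties in ``n`` is reported alongside.  The
    Wilcoxon test drops zero differences and uses the exact distribution for
    small samples, the tie-corrected normal approximation otherwise.
    """
    d = pd.Series(d).dropna().astype(float)
    n = len(d)
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    n_tie = n - n_pos - n_neg
    if n == 0:
        return PairedDifferenceResult(
            tissue, 0, 0, 0, 0, math.nan, math.nan, math.nan, math.nan,
            math.nan, math.nan, math.nan, d
        )
    sign_p = (
        sps.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue
        if n_pos + n_neg > 0
        else math.nan
    )
    sign_p_ties = sps.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    nz = d[d != 0]
    if len(nz) > 0:
        method = "exact" if (len(nz) <= 25 and not nz.abs().duplicated().any()) else "approx"
        wil_p = float(sps.wilcoxon(nz, alternative="two-sided", method=method).pvalue)
    else:
        wil_p = math.nan
    mu = math.nan
    if mean_um is not None:
        mu = float(pd.Series(mean_um).dropna().astype(float).mean())
    norm_pct = 100.0 * float(d.median()) / mu if mu and not math.isnan(mu) and mu != 0 else math.nan
    return PairedDifferenceResult(
        tissue=tissue,
        n=n,
        n_pos=n_pos,
        n_neg=n_neg,
        n_tie=n_tie,
        median_d=float(d.median()),
        mean_d=float(d.mean()),
        mean_um=mu,
        normalized_median_pct=norm_pct,
        sign_test_p=float(sign_p),
        sign_test_p_with_ties=float(sign_p_ties),
        wilcoxon_p=wil_p,
        differences=d,
    )


def gbm_um_analysis(
    dt_by_tissue: Mapping[str, pd.DataFrame],
    de: pd.DataFrame,
    type_a: str = "gbM",
    type_b: str = "UM",
) -> dict[str, PairedDifferenceResult]:
    """Per-tissue paired-difference analysis d = mean(type_a) - mean(type_b)."""
    out = {}
    for tissue, dt in dt_by_tissue.items():
        ma = mean_tpm_per_epiallele(dt, de, type_a)
        mb = mean_tpm_per_epiallele(dt, de, type_b)
        both = ma.notna() & mb.notna()
        d = (ma - mb)[both]
        out[tissue] = paired_difference_tests(d, mean_um=mb[both], tissue=tissue)
    return out


def duplicate_proportion_test(counts: pd.DataFrame | np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on a 2 x k count table.

    Used to compare duplicate epiallele proportions between copy-number
    strata.  Returns ``(chi2, p, dof)``; a zero expected cell is an error.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a 2-D contingency table with at least 2 rows and columns")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell count in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), float(p), int(dof)


@dataclass
class CorrelationSummary:
    tissue: str
    n_pangenes: int             # pangenes with a defined correlation
    median_r: float
    mean_r: float
    n_pos: int
    n_neg: int
    pos_neg_ratio: float
    r_values: pd.Series = field(repr=False, default=None)


def methylation_expression_correlation(
    meth: pd.DataFrame,
    tpm: pd.DataFrame,
    min_range: float = 0.2,
    min_genes: int = 3,
    tissue: str = "",
) -> CorrelationSummary:
    """Per-pangene Pearson correlation between methylation level and TPM.

    ``meth`` and ``tpm`` are aligned pangene x genome matrices with low
    confidence genes already masked to ``NaN`` (CDS-length deviation, coverage,
    and any mCHG exclusion are upstream concerns).  A pangene is included iff
    its methylation range (max - min over genomes) is at least ``min_range``,
    it has at least ``min_genes`` genomes where both values are defined, and
    both variables have non-zero spread; otherwise its r is ``NaN``.
    """
    if meth.shape != tpm.shape:
        raise ValueError(f"shape mismatch: meth {meth.shape} vs tpm {tpm.shape}")
    m = meth.to_numpy(dtype=float)
    t = tpm.to_numpy(dtype=float)
    ok = ~np.isnan(m) & ~np.isnan(t)
    r = np.full(m.shape[0], np.nan)
    for i in range(m.shape[0]):
        sel = ok[i]
        if sel.sum() < min_genes:
            continue
        mi, ti = m[i, sel], t[i, sel]
        if mi.max() - mi.min() < min_range:
            continue
        if mi.std() == 0 or ti.std() == 0:
            continue
        r[i] = float(np.corrcoef(mi, ti)[0, 1])
    rs = pd.Series(r, index=meth.index, name="pearson_r")
    defined = rs.dropna()
    n_pos = int((defined > 0).sum())
    n_neg = int((defined < 0).sum())
    return CorrelationSummary(
        tissue=tissue,
        n_pangenes=len(defined),
        median_r=float(defined.median()) if len(defined) else math.nan,
        mean_r=float(defined.mean()) if len(defined) else math.nan,
        n_pos=n_pos,
        n_neg=n_neg,
        pos_neg_ratio=n_pos / n_neg if n_neg else math.inf if n_pos else math.nan,
        r_values=rs,
    )


def mask_low_confidence(
    meth: pd.DataFrame,
    mchg: pd.DataFrame | None = None,
    mchg_max: float | None = 0.05,
) -> pd.DataFrame:
    """Mask cells whose gene fails the mCHG exclusion (TE-like confound).

    Coverage and CDS-length masking happen when the matrices are built; this
    helper applies the additional mCHG <= 0.05 requirement for the mCG-vs-TPM
    analysis.  Pass ``mchg_max=None`` (the mCHG variant) to skip it.
    """
    out = meth.copy()
    if mchg is not None and mchg_max is not None:
        out[mchg > mchg_max] = np.nan
    return out
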