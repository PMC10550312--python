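"""Gene x tissue expression matrices: TPM normalization and expression categories.

The study tissues are ten maize organs/sections; a gene is *constitutive* when
its TPM is at least 1 in every tissue, *silent* when below 1 in every tissue,
and *tissue-specific* otherwise (at least one tissue on each side of the
threshold).  The threshold comparison is inclusive (TPM = 1.0 counts as
expressed).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_TISSUES = (
    "leaf_tip",
    "leaf_middle",
    "leaf_base",
    "root",
    "shoot",
    "ear",
    "anther",
    "tassel",
    "endosperm",
    "embryo",
)

CATEGORIES = ("tissue_specific", "constitutive", "silent", "undefined")


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series | dict) -> pd.DataFrame:
    """Transcripts-per-million from read counts and effective gene lengths (bp).

    ``tpm = 1e6 * (count / length) / sum_genes(count / length)`` per column.
    Replicate columns that share a tissue name are summed as raw counts before
    normalization (summing counts approximates merging replicate reads).
    Columns with zero total signal are an error.
    """
    if not isinstance(lengths, pd.Series):
        lengths = pd.Series(lengths)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:3]
        raise ValueError(f"missing gene length for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if counts.columns.duplicated().any():
        counts = counts.T.groupby(level=0, sort=False).sum().T
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise ValueError(f"zero total expression in tissue(s) {bad}")
    return rate.div(denom, axis=1) * 1e6


def categorize_expression(row: Sequence[float] | pd.Series, threshold: float = 1.0) -> str:
    """Expression category of one gene from its per-tissue TPM vector."""
    vals = np.asarray(row, dtype=float)
    if vals.size == 0:
        raise ValueError("empty TPM vector")
    if np.isnan(vals).any():
        return "undefined"
    expressed = vals >= threshold
    if expressed.all():
        return "constitutive"
    if not expressed.any():
        return "silent"
    return "tissue_specific"


def categorize_matrix(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Vectorized :func:`categorize_expression` over a genes x tissues matrix."""
    vals = tpm.to_numpy(dtype=float)
    expressed = vals >= threshold
    n_exp = expressed.sum(axis=1)
    cat = np.select(
        [np.isnan(vals).any(axis=1), n_exp == vals.shape[1], n_exp == 0],
        ["undefined", "constitutive", "silent"],
        default="tissue_specific",
    )
    return pd.Series(cat, index=tpm.index, name="category")


def log_tpm(values, pseudocount: float = 1.0):
    """log10(TPM + pseudocount), for reporting; raises on negative TPM."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative TPM values")
    out = np.log10(arr + pseudocount)
    if np.isscalar(values) or arr.ndim == 0:
        return float(out)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a delimited genes-by-tissues matrix (header required, 'NA'-aware)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
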