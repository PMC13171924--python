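"""Count normalization: cumulative sum scaling (CSS), proportions, logs.

CSS divides each sample's counts by the cumulative sum of its counts up
to a chosen quantile of the sample's nonzero count distribution, which
dampens the influence of a few dominant taxa on library-size correction.
The quantile is the "nearest-rank <=" empirical quantile of the sample's
NONZERO counts: the value at 1-based index ceil(q * m) of the sorted
nonzero vector of length m.  Scaling factors are then rescaled by a
global constant (median factor by default) so normalized magnitudes stay
comparable to counts.

The exact quantile level used by any particular reference implementation
is not standardized; the fixed-quantile form here (default q = 0.5) is
deterministic and fully specified, and an adaptive mode that picks the
smallest stable quantile is provided as an option.  Results may differ
from other CSS implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import CountTable

__all__ = [
    "NormalizedTable",
    "css_scaling_factors",
    "css_normalize",
    "adaptive_css_quantile",
    "relative_abundance",
    "log10_shift",
]


@dataclass
class NormalizedTable:
    """Real-valued taxa-by-samples table produced by a normalization."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scaling_factor: np.ndarray | None = None
    css_quantile: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("normalized values must be nonnegative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)


def _nonzero_quantile(col: np.ndarray, quantile: float) -> float:
    """Nearest-rank (<=) empirical quantile of a column's nonzero counts."""
    nz = np.sort(col[col > 0])
    m = nz.size
    idx = max(1, math.ceil(quantile * m))  # 1-based
    return float(nz[idx - 1])


def css_scaling_factors(table: CountTable, quantile: float = 0.5) -> np.ndarray:
    """Per-sample CSS scaling factors.

    For sample j the factor is the sum of counts over taxa whose (nonzero)
    count is <= the sample's empirical ``quantile`` of nonzero counts.

    Raises
    ------
    ValueError
        If ``quantile`` is outside (0, 1) or a sample has no nonzero count.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    counts = table.counts
    factors = np.empty(table.n_samples, dtype=float)
    for j in range(table.n_samples):
        col = counts[:, j]
        if not (col > 0).any():
            raise ValueError(f"sample {table.sample_ids[j]!r} has only zero counts")
        q = _nonzero_quantile(col, quantile)
        factors[j] = float(col[(col > 0) & (col <= q)].sum())
    return factors


def adaptive_css_quantile(
    table: CountTable,
    candidates: np.ndarray | None = None,
    instability_threshold: float = 0.1,
) -> float:
    """Pick the smallest quantile at which scaling factors turn unstable.

    Scans a grid of quantile levels and returns the smallest level where
    the median relative change of the scaling factors between successive
    levels exceeds ``instability_threshold``; falls back to 0.5 if the
    factors stay stable over the whole grid.
    """
    if candidates is None:
        candidates = np.arange(0.05, 1.0, 0.05)
    prev = css_scaling_factors(table, float(candidates[0]))
    for q in candidates[1:]:
        cur = css_scaling_factors(table, float(q))
        rel = np.abs(cur - prev) / np.where(prev > 0, prev, 1.0)
        if np.median(rel) > instability_threshold:
            return float(q)
        prev = cur
    return 0.5


def css_normalize(
    table: CountTable, quantile: float = 0.5, rescale: str = "median"
) -> NormalizedTable:
    """CSS-normalize a count table.

    normalized[i, j] = counts[i, j] / s_j * R, with s_j the CSS scaling
    factor and R either the median of the s_j (``rescale="median"``) or
    1000 (``rescale="fixed_1000"``).
    """
    if rescale not in ("median", "fixed_1000"):
        raise ValueError(f"rescale must be 'median' or 'fixed_1000', got {rescale!r}")
    s = css_scaling_factors(table, quantile)
    R = float(np.median(s)) if rescale == "median" else 1000.0
    values = table.counts / s[np.newaxis, :] * R
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values,
        scaling_factor=s, css_quantile=quantile,
    )


def relative_abundance(table: CountTable | NormalizedTable) -> NormalizedTable:
    """Per-sample proportions (each column sums to 1)."""
    values = table.counts if isinstance(table, CountTable) else table.values
    values = np.asarray(values, dtype=float)
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has only zero counts"
        )
    return NormalizedTable(
        list(table.taxon_ids), list(table.sample_ids), values / colsums
    )


def log10_shift(values, pseudocount: float = 1e-6) -> np.ndarray:
    """Elementwise log10(value + pseudocount); the default pseudocount
    1e-6 maps an absence (0) to -6 on relative-abundance data."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log10_shift requires nonnegative values")
    return np.log10(arr + pseudocount)
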