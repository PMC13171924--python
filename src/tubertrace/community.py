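"""Community-level statistics: alpha diversity, Bray-Curtis, PERMANOVA,
Kruskal-Wallis and Dunn post hoc comparisons.

PERMANOVA follows the distance-based ANOVA partitioning: the squared
dissimilarity matrix is Gower-centred and its total sum of squares
split sequentially (Type-I, model-formula order) among the requested
terms via projection (hat) matrices, with pseudo-F significance from
raw-data permutations of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .data_model import CountTable
from .normalize import NormalizedTable
from .transfer_stats import bh_adjust

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _values_of(table) -> np.ndarray:
    if isinstance(table, CountTable):
        return table.counts.astype(float)
    if isinstance(table, NormalizedTable):
        return table.values
    return np.asarray(table, dtype=float)


def alpha_diversity(table, metric: str = "shannon") -> pd.Series:
    """Per-sample richness, Shannon entropy (natural log) or Pielou
    evenness (H / ln richness; NA for single-taxon samples)."""
    values = _values_of(table)
    sample_ids = getattr(table, "sample_ids", list(range(values.shape[1])))
    if metric not in ("richness", "shannon", "pielou"):
        raise ValueError(f"unknown metric {metric!r}")
    out = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        nz = col[col > 0]
        if metric == "richness":
            out[j] = nz.size
            continue
        if nz.size == 0:
            raise ValueError(
                f"sample {sample_ids[j]!r} has no nonzero counts; "
                f"{metric} is undefined"
            )
        p = nz / nz.sum()
        H = float(-(p * np.log(p)).sum())
        if metric == "shannon":
            out[j] = H
        else:
            out[j] = H / np.log(nz.size) if nz.size > 1 else np.nan
    return pd.Series(out, index=sample_ids, name=metric)


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples:
    d_jk = sum |x_ij - x_ik| / sum (x_ij + x_ik)."""
    values = _values_of(table)
    sample_ids = getattr(table, "sample_ids", [str(j) for j in range(values.shape[1])])
    if values.shape[1] < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    zero = values.sum(axis=0) == 0
    with np.errstate(invalid="ignore"):
        mat = squareform(pdist(values.T, metric="braycurtis"))
    if zero.sum() >= 2:
        warnings.warn("sample pairs with all-zero counts yield NA dissimilarity")
        zz = np.flatnonzero(zero)
        for a in zz:
            for b in zz:
                if a != b:
                    mat[a, b] = np.nan
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(list(sample_ids), mat)


@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table."""

    table: pd.DataFrame  # term, ss, df, pseudo_f, r2, p
    ss_total: float
    ss_residual: float
    df_residual: int
    n_permutations: int


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _term_design(factors: pd.DataFrame, term: str) -> np.ndarray:
    """One-hot columns for a main effect or ':'-joined interaction."""
    parts = term.split(":")
    for pcol in parts:
        if pcol not in factors.columns:
            raise ValueError(f"unknown factor {pcol!r}")
    combo = factors[parts[0]].astype(str)
    for pcol in parts[1:]:
        combo = combo + "|" + factors[pcol].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def permanova(
    d: DistanceMatrix,
    factors: pd.DataFrame,
    terms: Sequence[str],
    B: int | None = 999,
    rng_seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with permutation p-values.

    ``terms`` are metadata columns or ``a:b`` interactions, partitioned
    sequentially in the given order.  p-values come from ``B`` raw-data
    permutations of the samples: p = (1 + #{F_perm >= F_obs}) / (1 + B).
    ``B=None`` enumerates all N! permutations (small N only), giving the
    exact null proportion #{F_perm >= F_obs} / N! with the identity
    permutation included.
    """
    N = d.n
    if N < 3:
        raise ValueError("PERMANOVA needs at least 3 samples")
    if len(factors) != N:
        raise ValueError("factors table does not match the distance matrix")
    if np.isnan(d.matrix).any():
        raise ValueError("distance matrix contains NA entries")
    for t in terms:
        for pcol in t.split(":"):
            if factors[pcol].astype(str).nunique() < 2:
                raise ValueError(f"factor {pcol!r} has a single level")
    A = -0.5 * d.matrix**2
    J = np.eye(N) - np.ones((N, N)) / N
    G = J @ A @ J
    ss_total = float(np.trace(G))

    # nested sequence of hat matrices: intercept, +term1, +term2, ...
    X = np.ones((N, 1))
    hats = [_hat(X)]
    dfs = []
    rank_prev = 1
    for t in terms:
        X = np.hstack([X, _term_design(factors, t)])
        H = _hat(X)
        rank = int(np.round(np.trace(H)))
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(H)
    df_res = N - rank_prev
    if df_res < 1:
        raise ValueError("saturated design: no residual degrees of freedom")

    def stats_for(Gm: np.ndarray):
        # tr(H G) = sum(H * G) for symmetric H, G
        ss_terms = []
        prev = float(np.sum(hats[0] * Gm))
        for H in hats[1:]:
            cur = float(np.sum(H * Gm))
            ss_terms.append(cur - prev)
            prev = cur
        ss_resid = float(np.trace(Gm)) - prev
        fstats = [
            (ss_t / df_t) / (ss_resid / df_res) if df_t > 0 else np.nan
            for ss_t, df_t in zip(ss_terms, dfs)
        ]
        return ss_terms, ss_resid, fstats

    ss_terms, ss_resid, f_obs = stats_for(G)

    if B is None:
        import itertools
        import math

        if N > 8:
            raise ValueError("exhaustive enumeration supported for N <= 8 only")
        perms = [np.asarray(p) for p in itertools.permutations(range(N))]
        n_perms = math.factorial(N)
    else:
        rng = (
            rng_seed
            if isinstance(rng_seed, np.random.Generator)
            else np.random.default_rng(rng_seed)
        )
        perms = [rng.permutation(N) for _ in range(B)]
        n_perms = B
    extreme = np.zeros(len(terms))
    f_obs_arr = np.asarray(f_obs)
    # tie tolerance: permutations equivalent to the observed labelling
    # must count as extreme despite floating-point noise
    f_tol = f_obs_arr - (1e-8 * np.abs(f_obs_arr) + 1e-12)
    for perm in perms:
        Gp = G[np.ix_(perm, perm)]
        _, _, f_perm = stats_for(Gp)
        extreme += np.asarray(f_perm) >= f_tol
    if B is None:
        pvals = extreme / n_perms
    else:
        pvals = (1 + extreme) / (1 + n_perms)

    table = pd.DataFrame(
        {
            "term": list(terms),
            "ss": ss_terms,
            "df": dfs,
            "pseudo_f": f_obs,
            "r2": [s / ss_total for s in ss_terms],
            "p": pvals,
        }
    )
    return PermanovaResult(
        table=table,
        ss_total=ss_total,
        ss_residual=ss_resid,
        df_residual=df_res,
        n_permutations=n_perms,
    )


def kruskal_wallis(values, group_labels) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns (H, df, p) with p from the chi-square approximation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least 1 observation")
    res = stats.kruskal(*groups)
    return float(res.statistic), len(groups) - 1, float(res.pvalue)


def dunn_posthoc(values, group_labels, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's pairwise z comparisons from pooled ranks with tie
    correction; two-sided p per pair, BH-adjusted across pairs."""
    if adjust != "bh":
        raise ValueError("only Benjamini-Hochberg adjustment is supported")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("Dunn post hoc needs at least 2 groups")
    N = values.size
    ranks = stats.rankdata(values)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    ties = float(np.sum(tie_counts**3 - tie_counts))
    tie_term = ties / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in levels}
    n_of = {g: int((labels == g).sum()) for g in levels}
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            se = np.sqrt(var_base * (1.0 / n_of[a] + 1.0 / n_of[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    return df
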