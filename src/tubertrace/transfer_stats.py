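"""Model-based transfer-probability estimation and paired comparisons.

The probability that a baseline-generation taxon is detected again in
the next generation is modelled at the context level: one observation
per (compartment x cultivar x field x transition) with
``successes`` = retained taxa and ``trials`` = taxa present at the
baseline generation.  A binomial logit GLM with fixed effects is fitted
by iteratively reweighted least squares; field-level dependence can be
absorbed with cluster-robust (sandwich) standard errors, and a
Firth-type bias-reduced fit handles separation.  Term significance uses
Wald chi-square tests with Type-III style sum-to-zero contrasts, and
marginal transfer probabilities are reported on the response scale with
delta-method confidence intervals computed on the logit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "TransferModelResult",
    "build_trials",
    "fit_binomial_glm",
    "bias_reduced_fit",
    "paired_wilcoxon",
    "bh_adjust",
]


class SeparationError(ValueError):
    """Raised when ML fitted probabilities are pinned at 0/1."""


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is not full rank after coding."""


# ---------------------------------------------------------------------------
# Trials construction
# ---------------------------------------------------------------------------

def build_trials(classifications: Sequence) -> pd.DataFrame:
    """One successes/trials row per context and generation transition.

    ``classifications`` are :class:`~tubertrace.transfer.TransferClassification`
    objects (one per compartment/cultivar/field context).  Retention is
    chained: the entering set of each transition is the set retained at
    the previous stage, starting from the seed set.  Contexts with an
    empty baseline are excluded with a warning.
    """
    rows = []
    for cls in classifications:
        core = cls.seed_set
        prev_gen = "seed"
        if not core:
            warnings.warn(
                f"context ({cls.compartment}, {cls.cultivar}, {cls.field}) "
                "has an empty baseline; excluded"
            )
            continue
        for g, gt in cls.per_generation.items():
            retained = core & gt.present
            rows.append(
                {
                    "compartment": cls.compartment,
                    "cultivar": cls.cultivar,
                    "field": cls.field if cls.field is not None else "(none)",
                    "transition": f"{prev_gen}_to_{g}",
                    "successes": len(retained),
                    "trials": len(core),
                }
            )
            core = retained
            prev_gen = g
            if not core:
                break
    if not rows:
        warnings.warn("no usable contexts; returning empty trials table")
    return pd.DataFrame(
        rows,
        columns=["compartment", "cultivar", "field", "transition", "successes", "trials"],
    )


# ---------------------------------------------------------------------------
# Design coding
# ---------------------------------------------------------------------------

def _encode(data: pd.DataFrame, terms: Sequence[str], coding: str):
    """Intercept + factor columns, sum-to-zero or treatment coded."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    term_slices: dict[str, list[int]] = {}
    levels_of: dict[str, list[str]] = {}
    for t in terms:
        if t not in data.columns:
            raise ValueError(f"term {t!r} not found in trials columns")
        levels = sorted(map(str, pd.unique(data[t].astype(str))))
        levels_of[t] = levels
        if len(levels) < 2:
            raise ValueError(f"term {t!r} has a single level {levels}; cannot fit")
        idxs = []
        vals = data[t].astype(str).to_numpy()
        for lev in levels[:-1]:
            col = (vals == lev).astype(float)
            if coding == "sum":
                col = col - (vals == levels[-1]).astype(float)
            idxs.append(len(cols))
            cols.append(col)
            names.append(f"{t}[{'S' if coding == 'sum' else 'T'}.{lev}]")
        term_slices[t] = idxs
    X = np.column_stack(cols)
    return X, names, term_slices, levels_of


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * X.shape[0] * np.finfo(float).eps * 10
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise RankDeficiencyError(f"design matrix is rank deficient; aliased terms: {bad}")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class TransferModelResult:
    """Fitted binomial transfer-probability model."""

    method: str
    coding: str
    coef: pd.Series
    cov: pd.DataFrame
    se: pd.Series
    wald: pd.DataFrame  # term, chi2, df, p
    marginal: pd.DataFrame  # factor, level, prob, ci_low, ci_high
    converged: bool
    dispersion: float = 1.0
    robust_cluster: Optional[str] = None


def _irls(X, y, m, firth: bool, tol: float = 1e-8, max_iter: int = 100):
    p_obs = (y + 0.5) / (m + 1.0)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(p_obs.mean() / (1 - p_obs.mean()))
    converged = False
    for _ in range(max_iter if not firth else 2 * max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = m * p * (1.0 - p)
        W = np.maximum(W, 1e-12)
        XtWX = X.T @ (X * W[:, None])
        if firth:
            # leverages of W^(1/2) X; Jeffreys-prior score adjustment
            L = np.linalg.cholesky(XtWX)
            half = np.linalg.solve(L, (X * np.sqrt(W)[:, None]).T)
            h = np.sum(half**2, axis=0)
            score = X.T @ (y - m * p + h * (0.5 - p))
        else:
            score = X.T @ (y - m * p)
        step = np.linalg.solve(XtWX, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = np.maximum(m * p * (1.0 - p), 1e-12)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, cov, p, converged


def _wald_tests(beta, cov, term_slices):
    rows = []
    for term, idxs in term_slices.items():
        b = beta[idxs]
        V = cov[np.ix_(idxs, idxs)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idxs)
        rows.append(
            {"term": term, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


def _marginals(beta, cov, names, term_slices, levels_of, coding):
    """Marginal probabilities per factor level (and overall), averaging
    linear predictors over the levels of the other factors."""
    p_dim = len(beta)

    def avg_row(fix_factor=None, fix_level=None):
        x = np.zeros(p_dim)
        x[0] = 1.0
        for t, idxs in term_slices.items():
            levels = levels_of[t]
            if t == fix_factor:
                lev_set = [fix_level]
            else:
                lev_set = levels
            for lev in lev_set:
                for j, ref_lev in zip(idxs, levels[:-1]):
                    v = 1.0 if lev == ref_lev else 0.0
                    if coding == "sum" and lev == levels[-1]:
                        v = -1.0
                    x[j] += v / len(lev_set)
        return x

    rows = []
    combos = [("(overall)", "(overall)", avg_row())]
    for t, levels in levels_of.items():
        for lev in levels:
            combos.append((t, lev, avg_row(t, lev)))
    for factor, level, x in combos:
        eta = float(x @ beta)
        var = float(x @ cov @ x)
        se = np.sqrt(max(var, 0.0))
        lo, hi = eta - 1.959963984540054 * se, eta + 1.959963984540054 * se
        inv = lambda v: 1.0 / (1.0 + np.exp(-v))
        rows.append(
            {
                "factor": factor,
                "level": level,
                "prob": inv(eta),
                "ci_low": inv(lo),
                "ci_high": inv(hi),
            }
        )
    return pd.DataFrame(rows, columns=["factor", "level", "prob", "ci_low", "ci_high"])


def _prepare(data: pd.DataFrame, terms: Sequence[str], coding: str):
    if coding not in ("sum", "treatment"):
        raise ValueError(f"coding must be 'sum' or 'treatment', got {coding!r}")
    df = pd.DataFrame(data).reset_index(drop=True)
    y = df["successes"].to_numpy(dtype=float)
    m = df["trials"].to_numpy(dtype=float)
    if (m < 1).any():
        raise ValueError("every observation needs trials >= 1")
    if ((y < 0) | (y > m)).any():
        raise ValueError("successes must satisfy 0 <= successes <= trials")
    X, names, term_slices, levels_of = _encode(df, terms, coding)
    _check_rank(X, names)
    return df, y, m, X, names, term_slices, levels_of


def fit_binomial_glm(
    data: pd.DataFrame,
    terms: Sequence[str] = (),
    robust_cluster: Optional[str] = None,
    coding: str = "sum",
    quasi: bool = False,
) -> TransferModelResult:
    """Maximum-likelihood binomial logit fit of successes/trials data.

    Parameters
    ----------
    data
        Table with ``successes`` and ``trials`` columns plus factor
        covariates (compartment, cultivar, transition, field, ...).
    terms
        Factor names entering as fixed effects (main effects).
    robust_cluster
        Optional column name; switches the covariance to the
        cluster-robust sandwich over that grouping.
    coding
        ``"sum"`` (Type-III friendly, default) or ``"treatment"``.
    quasi
        Inflate the covariance by the Pearson dispersion (quasi-binomial),
        a closed-form stand-in for observation-level overdispersion.
    """
    df, y, m, X, names, term_slices, levels_of = _prepare(data, terms, coding)
    beta, cov, p, converged = _irls(X, y, m, firth=False)
    pinned = (p < 1e-6) | (p > 1 - 1e-6)
    if pinned.any():
        raise SeparationError(
            "fitted probabilities pinned at 0/1 (complete or quasi-complete "
            "separation); use bias_reduced_fit for a finite Firth-type fit"
        )
    if not converged:
        raise RuntimeError("IRLS failed to converge in 100 iterations")
    dispersion = 1.0
    if quasi:
        resid2 = (y - m * p) ** 2 / np.maximum(m * p * (1 - p), 1e-12)
        dof = max(len(y) - X.shape[1], 1)
        dispersion = float(resid2.sum() / dof)
        cov = cov * dispersion
    if robust_cluster is not None:
        if robust_cluster not in df.columns:
            raise ValueError(f"cluster column {robust_cluster!r} not in data")
        scores = X * (y - m * p)[:, None]
        meat = np.zeros((X.shape[1], X.shape[1]))
        for _, idx in df.groupby(robust_cluster).groups.items():
            g = scores[np.asarray(idx)].sum(axis=0)
            meat += np.outer(g, g)
        bread = np.linalg.inv(X.T @ (X * np.maximum(m * p * (1 - p), 1e-12)[:, None]))
        cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    return TransferModelResult(
        method="ml",
        coding=coding,
        coef=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        se=pd.Series(se, index=names),
        wald=_wald_tests(beta, cov, term_slices),
        marginal=_marginals(beta, cov, names, term_slices, levels_of, coding),
        converged=converged,
        dispersion=dispersion,
        robust_cluster=robust_cluster,
    )


def bias_reduced_fit(
    data: pd.DataFrame, terms: Sequence[str] = (), coding: str = "sum"
) -> TransferModelResult:
    """Firth-type penalized-likelihood fit (Jeffreys-prior score
    adjustment); coefficients stay finite under separation."""
    df, y, m, X, names, term_slices, levels_of = _prepare(data, terms, coding)
    beta, cov, p, converged = _irls(X, y, m, firth=True)
    se = np.sqrt(np.diag(cov))
    return TransferModelResult(
        method="firth",
        coding=coding,
        coef=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        se=pd.Series(se, index=names),
        wald=_wald_tests(beta, cov, term_slices),
        marginal=_marginals(beta, cov, names, term_slices, levels_of, coding),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------

def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The p-value is exact (full sign
    enumeration) when the effective n is <= 12 and the absolute
    differences are tie-free; otherwise the normal approximation with
    tie and continuity corrections is used.  All-zero differences give
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("paired samples must have equal length >= 1")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 12 and not has_ties) else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided",
        correction=True, method=method,
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
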