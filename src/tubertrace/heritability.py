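"""Broad-sense heritability (H2) of taxon abundance across generations.

For each taxon the transformed abundance y_ijk is modelled with a
one-way random-effects layout,

    y_ijk = mu + G_i + eps_ijk,   G_i ~ N(0, VG),  eps_ijk ~ N(0, VE),

where i indexes the host generation.  Broad-sense heritability is the
intraclass correlation H2 = VG / (VG + VE): the fraction of abundance
variance attributable to generation, a measure of how *consistent* a
taxon's abundance is across generations — not a claim about genetic
inheritance.

Variance components are estimated by REML, profiled down to a 1-D
problem in the ratio lambda = VG/VE on [0, 1e6], solved by bisection on
the analytic derivative of the profiled criterion (absolute tolerance
well below 1e-10) and truncated at the boundary VG = 0.  On balanced layouts
with an interior optimum the REML solution coincides with the classical
ANOVA method-of-moments estimator VG = (MSB - MSW) / n0, VE = MSW, which
serves as an independent oracle in the test-suite.

Significance is assessed by permuting the generation-label vector B
times (default 999) and recomputing H2; the empirical p-value is
(1 + #{H2_perm >= H2_obs}) / (1 + B), with ties counted as extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Dataset
from .normalize import css_normalize, log10_shift

__all__ = [
    "VarianceComponents",
    "fit_variance_components",
    "heritability",
    "permutation_test",
    "heritability_screen",
]

_LAMBDA_MAX = 1e6
_GOLD_TOL = 1e-10


@dataclass
class VarianceComponents:
    """REML variance decomposition of one taxon's transformed abundance."""

    mu: float
    vg: float
    ve: float
    h2: float
    n_groups: int
    group_sizes: tuple[int, ...]


def _group_stats(values: np.ndarray, labels: np.ndarray):
    """Sufficient statistics: group sizes, group means, within-group SS."""
    levels, inv = np.unique(labels, return_inverse=True)
    k = levels.size
    n = np.bincount(inv, minlength=k).astype(float)
    sums = np.bincount(inv, weights=values, minlength=k)
    means = sums / n
    ssw = float(np.sum(values**2) - np.sum(n * means**2))
    return n, means, max(ssw, 0.0)


def _reml_criterion(lam, n, means, ssw, N):
    """Profiled -2 REML log-likelihood (up to a constant) at ratio lam.

    ``lam`` may be a scalar or an array of candidate ratios per problem;
    ``means``/``ssw`` may carry a leading problem axis for vectorized use.
    """
    w = n / (1.0 + lam[..., None] * n)  # (..., k)
    sw = w.sum(axis=-1)
    mu = (w * means).sum(axis=-1) / sw
    q = ssw + (w * (means - mu[..., None]) ** 2).sum(axis=-1)
    q = np.maximum(q, 1e-300)
    return (N - 1) * np.log(q) + np.log1p(lam[..., None] * n).sum(axis=-1) + np.log(sw)


def _reml_dcriterion(lam, n, means, ssw, N):
    """Derivative of the profiled criterion in the ratio lambda.

    Uses dw_i/dlam = -w_i^2 and the fact that sum w_i (ybar_i - mu) = 0,
    giving dQ/dlam = -sum w_i^2 (ybar_i - mu)^2.
    """
    w = n / (1.0 + lam[..., None] * n)
    sw = w.sum(axis=-1)
    mu = (w * means).sum(axis=-1) / sw
    dev2 = (means - mu[..., None]) ** 2
    q = np.maximum(ssw + (w * dev2).sum(axis=-1), 1e-300)
    return (
        -(N - 1) * (w**2 * dev2).sum(axis=-1) / q
        + w.sum(axis=-1)
        - (w**2).sum(axis=-1) / sw
    )


def _solve_lambda(n, means, ssw, N):
    """Vectorized solve for the REML ratio lambda on [0, _LAMBDA_MAX].

    ``means`` has shape (B, k) and ``ssw`` shape (B,): B independent
    problems sharing the group-size vector are solved simultaneously.
    The profiled criterion is unimodal in lambda, so its interior
    optimum is bracketed by the sign of the derivative at the interval
    ends and pinned down by bisection (beyond the sqrt(eps) accuracy a
    value-based search could give); a derivative that never changes
    sign puts the solution at the corresponding boundary.
    """
    B = means.shape[0]
    g0 = _reml_dcriterion(np.zeros(B), n, means, ssw, N)
    gcap = _reml_dcriterion(np.full(B, _LAMBDA_MAX), n, means, ssw, N)
    at_zero = g0 >= 0.0  # criterion already increasing: boundary vg = 0
    at_cap = (~at_zero) & (gcap <= 0.0)  # still decreasing at the cap
    lo = np.zeros(B)
    hi = np.full(B, _LAMBDA_MAX)
    interior = ~(at_zero | at_cap)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        gm = _reml_dcriterion(mid, n, means, ssw, N)
        go_right = gm < 0.0
        lo = np.where(interior & go_right, mid, lo)
        hi = np.where(interior & ~go_right, mid, hi)
        if np.max(hi - lo) <= _GOLD_TOL * 1e-4:
            break
    lam = 0.5 * (lo + hi)
    lam = np.where(at_zero, 0.0, lam)
    lam = np.where(at_cap, _LAMBDA_MAX, lam)
    return lam


def _h2_from_stats(n, means, ssw, N):
    """H2, vg, ve, mu for B stacked problems sharing group sizes."""
    lam = _solve_lambda(n, means, ssw, N)
    w = n / (1.0 + lam[:, None] * n)
    sw = w.sum(axis=1)
    mu = (w * means).sum(axis=1) / sw
    q = ssw + (w * (means - mu[:, None]) ** 2).sum(axis=1)
    ve = q / (N - 1)
    vg = lam * ve
    tot = vg + ve
    h2 = np.where(tot > 0, vg / np.maximum(tot, 1e-300), 0.0)
    # ratio pinned at the upper search bound => residual variance is
    # numerically zero and H2 is 1 by the boundary convention
    h2 = np.where(lam >= 0.9 * _LAMBDA_MAX, 1.0, h2)
    return h2, vg, ve, mu


def _check_layout(values: np.ndarray, labels: np.ndarray):
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.size != labels.size:
        raise ValueError("values and generation labels differ in length")
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValueError("heritability requires at least 2 generations")
    if counts.min() < 2:
        raise ValueError(
            "every generation needs at least 2 observations "
            f"(smallest group has {counts.min()})"
        )
    return values, labels


def fit_variance_components(values, generation_labels) -> VarianceComponents:
    """REML fit of the one-way random-effects model for one taxon.

    Degenerate data with zero total variance returns vg = ve = 0 and
    h2 = 0 with a warning.
    """
    values, labels = _check_layout(values, generation_labels)
    n, means, ssw = _group_stats(values, labels)
    N = values.size
    grand = float(values.mean())
    total_ss = float(np.sum((values - grand) ** 2))
    if total_ss <= 1e-14 * max(1.0, grand**2) * N:
        warnings.warn("zero total variance; returning vg = ve = 0, h2 = 0")
        return VarianceComponents(grand, 0.0, 0.0, 0.0, n.size, tuple(int(x) for x in n))
    if ssw <= 1e-12 * total_ss:
        # zero residual variance: VE = 0, H2 = 1 by the boundary convention
        vg_b = float(np.sum((means - means.mean()) ** 2) / (n.size - 1))
        return VarianceComponents(
            grand, vg_b, 0.0, 1.0, n.size, tuple(int(x) for x in n)
        )
    h2, vg, ve, mu = _h2_from_stats(n, means[None, :], np.array([ssw]), N)
    return VarianceComponents(
        mu=float(mu[0]),
        vg=float(vg[0]),
        ve=float(ve[0]),
        h2=float(h2[0]),
        n_groups=n.size,
        group_sizes=tuple(int(x) for x in n),
    )


def heritability(vc: VarianceComponents) -> float:
    """H2 = vg / (vg + ve); defined as 0 when both components are 0."""
    tot = vc.vg + vc.ve
    return vc.vg / tot if tot > 0 else 0.0


def permutation_test(
    values,
    generation_labels,
    B: int = 999,
    rng_seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Permutation null for H2 of one taxon.

    Returns ``(h2_observed, p_empirical, permuted_h2)`` where the null
    distribution comes from ``B`` uniform random permutations of the
    generation-label vector and
    p = (1 + #{H2_perm >= H2_obs}) / (1 + B).

    With ``exhaustive=True`` all N! label orders are enumerated instead
    (small layouts only) and p is the exact null proportion
    #{H2_perm >= H2_obs} / N!, the identity permutation included.
    """
    values, labels = _check_layout(values, generation_labels)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    obs = fit_variance_components(values, labels).h2
    N = values.size
    levels, inv = np.unique(labels, return_inverse=True)
    k = levels.size
    n = np.bincount(inv, minlength=k).astype(float)
    # permuting values against fixed labels == permuting labels
    if exhaustive:
        import itertools
        import math as _math

        if N > 8:
            raise ValueError("exhaustive enumeration supported for N <= 8 only")
        order = np.array(list(itertools.permutations(range(N))))
        B = _math.factorial(N)
    else:
        order = np.argsort(rng.random((B, N)), axis=1)
    vperm = values[order]  # (B, N)
    M = np.zeros((N, k))
    M[np.arange(N), inv] = 1.0
    sums = vperm @ M
    means = sums / n
    ssw = np.maximum(np.sum(vperm**2, axis=1) - np.sum(n * means**2, axis=1), 0.0)
    if np.allclose(values, values[0]):
        perm_h2 = np.zeros(B)
    else:
        perm_h2, _, _, _ = _h2_from_stats(n, means, ssw, N)
    # count ties as extreme, with a tolerance so permutations equivalent
    # to the observed labelling are not lost to floating-point noise
    n_extreme = int(np.sum(perm_h2 >= obs - 1e-9))
    if exhaustive:
        p = n_extreme / B
    else:
        p = (1 + n_extreme) / (1 + B)
    return float(obs), float(p), perm_h2


def heritability_screen(
    ds: Dataset,
    taxa: list[str],
    context: tuple[str, str],
    transform: str = "css",
    css_quantile: float = 0.5,
    pseudocount: float = 1e-6,
    B: int = 999,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """H2 screen over a taxon subset within one cultivar-compartment cell.

    Pipeline per taxon: CSS-normalize the full table (or skip, with
    ``transform="proportion"``), renormalize the context's samples to
    proportions, log10(x + pseudocount) transform, REML fit, permutation
    test, then Benjamini-Hochberg adjustment across the screened taxa.
    Replicates within a generation pool over fields (generation is the
    only grouping factor of the model).  Taxa absent from every sample
    of the context are skipped with a warning.
    """
    from .transfer_stats import bh_adjust

    cultivar, compartment = context
    if transform not in ("css", "proportion"):
        raise ValueError(f"transform must be 'css' or 'proportion', got {transform!r}")
    cols = [
        j
        for j, m in enumerate(ds.metadata)
        if m.cultivar == cultivar and m.compartment == compartment
    ]
    if not cols:
        raise ValueError(f"no samples for context {context!r}")
    base = css_normalize(ds.table, quantile=css_quantile) if transform == "css" else ds.table
    values_full = base.values if transform == "css" else ds.table.counts.astype(float)
    sub = values_full[:, cols]
    colsum = sub.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("context contains an all-zero sample")
    rel = sub / colsum
    labels = np.array([ds.metadata[j].generation_level for j in cols])
    row_of = {t: i for i, t in enumerate(ds.table.taxon_ids)}
    rng = np.random.default_rng(rng_seed)

    rows = []
    for taxon in taxa:
        i = row_of.get(taxon)
        if i is None or not (rel[i] > 0).any():
            warnings.warn(f"taxon {taxon!r} absent from context {context!r}; skipped")
            continue
        y = log10_shift(rel[i], pseudocount)
        vc = fit_variance_components(y, labels)
        obs, p, perm = permutation_test(y, labels, B=B, rng_seed=rng)
        rows.append(
            {
                "taxon_id": taxon,
                "mu": vc.mu,
                "vg": vc.vg,
                "ve": vc.ve,
                "h2": obs,
                "B": B,
                "n_extreme": int(round(p * (1 + B) - 1)),
                "p_empirical": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "taxon_id", "mu", "vg", "ve", "h2", "B", "n_extreme", "p_empirical",
        ],
    )
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p_empirical"].to_numpy())
        result["significant"] = result["p_adjusted"] < alpha
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
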