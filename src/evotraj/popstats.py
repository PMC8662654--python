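"""Diversity trajectories and environment-enrichment classification.

Alpha diversity treats the detected mutation frequencies at one timepoint
as community abundances, normalized to proportions p_i = f_i / Σf:
Shannon H = −Σ p ln p (nats), Simpson 1 − Σ p² and inverse Simpson
1 / Σ p².  All three are scale-invariant in the input frequencies.

Environment enrichment compares a mutation's frequency after parallel
selection in two conditions (planktonic vs biofilm): an ordinary
least-squares regression of biofilm frequency (y) on planktonic frequency
(x) captures the population-wide trend, Cook's distance flags mutations
with outsized influence on that fit, and the classification rule calls a
mutation enriched when its distance reaches ``factor`` (default 4) times
the mean distance, with the residual sign giving the direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from evotraj.variants import TrajectoryTable

__all__ = [
    "alpha_diversity",
    "diversity_trajectory",
    "two_sample_ttest",
    "enrichment_fit",
    "classify_enrichment",
]

_MODES = ("shannon", "simpson", "invsimpson")


def alpha_diversity(frequencies, mode: str = "shannon") -> float:
    """Alpha diversity of a nonnegative abundance vector.

    Zero entries are ignored; the remainder is normalized to proportions.
    Raises on an all-zero vector.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    f = np.asarray(frequencies, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    f = f[f > 0]
    if f.size == 0:
        raise ValueError("no positive frequencies")
    p = f / f.sum()
    if mode == "shannon":
        return float(-(p * np.log(p)).sum())
    sum_sq = float((p**2).sum())
    if mode == "simpson":
        return 1.0 - sum_sq
    return 1.0 / sum_sq


def diversity_trajectory(table: TrajectoryTable) -> pd.DataFrame:
    """One row per sampled day with all three alpha-diversity modes,
    computed over that day's detected (nonzero) mutation frequencies.
    Days with no detected mutation get NaN."""
    rows = []
    for day in table.days:
        f = table.freq[day].to_numpy()
        f = f[f > 0]
        row = {"population": table.population, "day": day}
        if f.size:
            for mode in _MODES:
                row[mode] = alpha_diversity(f, mode)
        else:
            row.update({m: float("nan") for m in _MODES})
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_ttest(a, b, pooled: bool = True) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test; pooled-variance Student's by default
    (df = n_a + n_b − 2), Welch otherwise.  Returns (t, df, p)."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if pooled:
        na, nb = a.size, b.size
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        if se == 0:
            t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
            p = 1.0 if t == 0 else 0.0
            return float(t), float(df), float(p)
        t = (a.mean() - b.mean()) / se
        p = 2 * stats.t.sf(abs(t), df)
        return float(t), float(df), float(p)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite df
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t), float(df), float(p)


@dataclass
class EnrichmentFit:
    """OLS fit of biofilm (y) on planktonic (x) frequency with per-point
    Cook's distances."""

    intercept: float
    slope: float
    residuals: np.ndarray
    cooks_d: np.ndarray
    leverage: np.ndarray
    s2: float  # residual mean square


def enrichment_fit(x, y) -> EnrichmentFit:
    """Fit y = a + b·x by OLS and compute Cook's distance per point:
    D_i = (e_i² / (p·s²)) · (h_ii / (1−h_ii)²) with p = 2 coefficients.
    Requires ≥ 3 points and non-degenerate x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points for a regression with diagnostics")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    e = fit.resid
    h = fit.get_influence().hat_matrix_diag
    p = 2
    s2 = float(fit.mse_resid)
    scale = max(1.0, float(np.abs(y).max()))
    if np.allclose(e, 0.0, atol=1e-12 * scale):
        # exact fit: distances are identically zero, not 0/0 noise
        d = np.zeros(x.size)
        s2 = 0.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (e**2 / (p * s2)) * (h / (1 - h) ** 2)
        d = np.where(np.isfinite(d), d, np.inf)
    return EnrichmentFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        residuals=np.asarray(e),
        cooks_d=np.asarray(d),
        leverage=np.asarray(h),
        s2=s2,
    )


def classify_enrichment(
    x,
    y,
    factor: float = 4.0,
    mutation_ids=None,
) -> pd.DataFrame:
    """Flag environment-enriched mutations.

    A mutation is enriched when its Cook's distance is at least ``factor``
    times the mean distance across all points; the direction is ``biofilm``
    for a positive residual (observed biofilm frequency above the trend)
    and ``planktonic`` for a negative one.  Returns one row per mutation
    with x, y, Cook's D, the flag and the direction; invariant to point
    ordering.
    """
    fit = enrichment_fit(x, y)
    d = fit.cooks_d
    mean_d = float(np.mean(d[np.isfinite(d)])) if np.isfinite(d).any() else 0.0
    enriched = (d >= factor * mean_d) & (d > 0) if mean_d > 0 else np.zeros(d.size, bool)
    direction = np.where(
        ~enriched, "none", np.where(fit.residuals > 0, "biofilm", "planktonic")
    )
    idx = mutation_ids if mutation_ids is not None else np.arange(d.size)
    return pd.DataFrame(
        {
            "mutation": idx,
            "freq_planktonic": np.asarray(x, dtype=float),
            "freq_biofilm": np.asarray(y, dtype=float),
            "cooks_d": d,
            "enriched": enriched,
            "direction": direction,
        }
    )
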