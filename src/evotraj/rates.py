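"""Fitness, growth-rate and fluctuation-assay mutation-rate estimators.

Three independent wet-lab readouts get their estimators here:

* **Selective rate constant** ``r`` from one-day head-to-head competition
  colony counts: ``r = [ln(E1/E0) − ln(A1/A0)] / divisor``.  The default
  divisor of 2 follows the printed form of the statistic this package
  reproduces and is exposed as a parameter; see the methods note.
* **Maximum growth rate** (Vmax) as the steepest sliding-window slope of
  ln(OD600) against time.
* **Luria–Delbrück fluctuation analysis**: the Ma–Sandri–Sarkar (MSS)
  probability recursion for the number of resistant colonies per culture,
  its maximum-likelihood estimate of ``m`` (expected mutations per
  culture), mutation rate ``m/Nt`` and fold changes between strains, plus
  a simulator of mutant counts for estimator validation.

The MSS recursion: p₀ = e^(−m), p_r = (m/r) · Σ_{i=0}^{r−1} p_i/(r−i+1),
whose jackpot-heavy tail is what distinguishes fluctuation data from a
Poisson and what the MLE is robust to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "selection_rate",
    "vmax",
    "luria_delbruck_pmf",
    "mss_mle",
    "mutation_rate",
    "rate_fold_change",
    "simulate_fluctuation",
    "FluctuationExperiment",
]


def selection_rate(
    evolved_d0: float,
    evolved_d1: float,
    ancestor_d0: float,
    ancestor_d1: float,
    divisor: float = 2.0,
) -> float:
    """Selective rate constant from day-0/day-1 CFU counts of the two
    competitors.  Any non-positive count marks the replicate invalid
    (e.g. a competitor that became undetectable) and raises ValueError."""
    counts = (evolved_d0, evolved_d1, ancestor_d0, ancestor_d1)
    if any(c <= 0 for c in counts):
        raise ValueError("invalid replicate: all CFU counts must be positive")
    return (math.log(evolved_d1 / evolved_d0) - math.log(ancestor_d1 / ancestor_d0)) / divisor


def vmax(times, od, window: int = 4) -> float:
    """Maximum growth rate: the steepest least-squares slope of ln(OD)
    over any ``window`` consecutive readings (log-OD units per hour).

    Windows containing OD ≤ 0 are skipped; raises if no window is valid.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("times and od must have equal length >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not 2 <= window <= t.size:
        raise ValueError("window must satisfy 2 <= window <= len(times)")
    best = -np.inf
    for i in range(t.size - window + 1):
        yy = y[i : i + window]
        if np.any(yy <= 0):
            continue
        slope = np.polyfit(t[i : i + window], np.log(yy), 1)[0]
        best = max(best, float(slope))
    if not np.isfinite(best):
        raise ValueError("no window with strictly positive OD readings")
    return best


def luria_delbruck_pmf(m: float, r_max: int) -> np.ndarray:
    """MSS probabilities p_0..p_{r_max} of observing r resistant colonies
    in a culture with ``m`` expected mutations."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if r_max < 0:
        raise ValueError("r_max must be >= 0")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    for r in range(1, r_max + 1):
        i = np.arange(r)
        p[r] = (m / r) * float((p[:r] / (r - i + 1)).sum())
    return p


def _loglik(m: float, counts: np.ndarray, cap: int) -> float:
    if m <= 0:
        return -np.inf
    r_max = int(min(counts.max(), cap))
    p = luria_delbruck_pmf(m, r_max)
    ll = 0.0
    below = counts[counts < cap]
    with np.errstate(divide="ignore"):
        ll += float(np.log(p[below]).sum())
    n_cens = int((counts >= cap).sum())
    if n_cens:
        tail = max(1.0 - float(p[: cap].sum()), 1e-300)
        ll += n_cens * math.log(tail)
    return ll


def mss_mle(mutant_counts, tol: float = 1e-6, censor_at: int = 512) -> float:
    """Maximum-likelihood ``m`` (expected mutations per culture) from
    per-culture resistant-colony counts, by bracketed 1-D optimization on
    ln m.  All-zero counts return the boundary estimate 0.

    Jackpot cultures with ≥ ``censor_at`` colonies enter the likelihood as
    right-censored observations (through the distribution's upper tail),
    which keeps the quadratic-cost probability recursion tractable without
    discarding the jackpots' information.
    """
    counts = np.asarray(mutant_counts, dtype=int)
    if counts.size < 2:
        raise ValueError("need >= 2 cultures")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if counts.max() == 0:
        return 0.0
    # bracket: p0-method and mean-based bounds, padded generously
    frac_zero = float((counts == 0).mean())
    lo = max(-math.log(frac_zero) / 10 if frac_zero > 0 else 1e-4, 1e-6)
    hi = max(float(counts.mean()) * 10, lo * 1e4)
    res = minimize_scalar(
        lambda lm: -_loglik(math.exp(lm), counts, censor_at),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": tol},
    )
    return float(math.exp(res.x))


def mutation_rate(m: float, Nt: float) -> float:
    """Per-cell-per-division mutation rate m/Nt."""
    if Nt <= 0:
        raise ValueError("Nt must be positive")
    return m / Nt


def rate_fold_change(m_mut: float, Nt_mut: float, m_anc: float, Nt_anc: float) -> float:
    """Fold change in mutation rate between mutant and ancestor strains.
    Returns NaN when the ancestral estimate is 0 (undefined fold)."""
    if min(Nt_mut, Nt_anc) <= 0 or min(m_mut, m_anc) < 0:
        raise ValueError("need positive Nt and nonnegative m")
    if m_anc == 0:
        return float("nan")
    return (m_mut / Nt_mut) / (m_anc / Nt_anc)


def simulate_fluctuation(
    m: float, n_cultures: int, seed: int | np.random.Generator = 0, size_cap: int = 10**7
) -> np.ndarray:
    """Simulate per-culture resistant-colony counts under the
    Luria–Delbrück model.

    Mutation events per culture are Poisson(``m``); each event founds a
    clone whose final size follows the classic LD tail
    P(size ≥ k) = 1/k, sampled by inversion as floor(1/U) and capped at
    ``size_cap`` to keep jackpots finite.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    events = rng.poisson(m, size=n_cultures)
    for j in np.flatnonzero(events):
        u = rng.random(events[j])
        counts[j] = int(np.minimum(np.floor(1.0 / u), size_cap).sum())
    return counts


@dataclass
class FluctuationExperiment:
    """One strain's fluctuation assay: counts, final census and estimates."""

    mutant_counts: np.ndarray
    Nt: float
    m_hat: float = float("nan")

    def __post_init__(self) -> None:
        self.mutant_counts = np.asarray(self.mutant_counts, dtype=int)
        if self.mutant_counts.size < 2:
            raise ValueError("need >= 2 cultures")
        if self.Nt <= 0:
            raise ValueError("Nt must be positive")
        if math.isnan(self.m_hat):
            self.m_hat = mss_mle(self.mutant_counts)

    @property
    def rate(self) -> float:
        return mutation_rate(self.m_hat, self.Nt)

    def fold_change_vs(self, other: "FluctuationExperiment") -> float:
        return rate_fold_change(self.m_hat, self.Nt, other.m_hat, other.Nt)
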