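"""Circular statistics for peak-phase populations on the 24 h clock.

Phases enter in ZT hours (0 = lights-on) and are mapped to angles
θ = 2πφ/24.  Provided: the mean vector (direction and resultant length
R), the Rayleigh uniformity test, a dispersion-based large-sample 95%
confidence interval for the mean direction, half-open binned phase
histograms, and the rhythmic-gene enrichment test against a fixed
background expectation (16% of genes rhythmic by default, after the
mouse-liver circadian database convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PhaseSample",
    "mean_vector",
    "rayleigh_test",
    "mean_direction_ci95",
    "phase_histogram",
    "enrichment_test",
    "polar_phase_plot",
]

CYCLE_H = 24.0


@dataclass(frozen=True)
class PhaseSample:
    """Peak phases in hours (reduced mod 24), optionally weighted."""

    phases_h: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        p = np.mod(np.asarray(self.phases_h, dtype=float), CYCLE_H)
        if p.size == 0:
            raise ValueError("empty phase sample")
        if not np.all(np.isfinite(p)):
            raise ValueError("phases must be finite")
        object.__setattr__(self, "phases_h", p)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != p.shape or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be non-negative, same length, not all zero")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return int(self.phases_h.size)

    @property
    def _theta(self) -> np.ndarray:
        return 2 * np.pi * self.phases_h / CYCLE_H

    @property
    def _w(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self), 1.0 / len(self))
        return self.weights / self.weights.sum()


def mean_vector(sample: PhaseSample) -> tuple[float, float]:
    """Circular mean direction (ZT hours) and resultant length R ∈ [0, 1].

    The direction is NaN when R = 0 (perfectly balanced sample).
    """
    w = sample._w
    c = float(np.sum(w * np.cos(sample._theta)))
    s = float(np.sum(w * np.sin(sample._theta)))
    r = math.hypot(c, s)
    if r < 1e-12:
        return math.nan, 0.0
    mean_h = (CYCLE_H / (2 * np.pi)) * math.atan2(s, c)
    return float(np.mod(mean_h, CYCLE_H)), float(min(r, 1.0))


def rayleigh_test(sample: PhaseSample) -> float:
    """Rayleigh test of circular uniformity (unweighted n).

    Uses the classical series-corrected tail
    p = e^{−Z}[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
    Z = nR², clipped to (0, 1].
    """
    n = len(sample)
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    _, r = mean_vector(sample)
    z = n * r * r
    p = math.exp(-z) * (
        1
        + (2 * z - z * z) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n)
    )
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def mean_direction_ci95(sample: PhaseSample) -> tuple[float, float]:
    """Large-sample 95% CI for the mean direction, in ZT hours.

    Half-width = asin(z₀.₉₇₅·√(δ̂/n)) with circular dispersion
    δ̂ = (1 − ρ̂₂)/(2R²) (Fisher's dispersion-based interval).  Returns
    (lower, upper) mod 24; raises when R is too small for the
    approximation (the interval would be unbounded).
    """
    n = len(sample)
    if n < 3:
        raise ValueError("CI needs n >= 3")
    mean_h, r = mean_vector(sample)
    if r < 1e-12:
        raise ValueError("resultant length ~0: mean direction undefined")
    theta = sample._theta
    mu = 2 * np.pi * mean_h / CYCLE_H
    rho2 = float(np.mean(np.cos(2 * (theta - mu))))
    disp = (1 - rho2) / (2 * r * r)
    arg = sps.norm.ppf(0.975) * math.sqrt(disp / n)
    if arg >= 1:
        raise ValueError("dispersion too large: unbounded confidence interval")
    half_h = (CYCLE_H / (2 * np.pi)) * math.asin(arg)
    return float(np.mod(mean_h - half_h, CYCLE_H)), float(np.mod(mean_h + half_h, CYCLE_H))


def phase_histogram(sample: PhaseSample, bin_h: float = 3.0) -> np.ndarray:
    """Counts in half-open bins [0, b), [b, 2b), …; Σ counts = n."""
    if bin_h <= 0 or abs(CYCLE_H / bin_h - round(CYCLE_H / bin_h)) > 1e-9:
        raise ValueError("bin width must divide 24 h")
    n_bins = int(round(CYCLE_H / bin_h))
    idx = np.floor(sample.phases_h / bin_h).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def enrichment_test(
    k_hits: int,
    n_total: int,
    background_rate: float = 0.16,
    background_counts: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Fold enrichment and exact p of rhythmic-gene overrepresentation.

    Default: two-sided exact binomial test of k/n against the fixed
    background rate (minimum-likelihood two-sided convention).  When an
    explicit background gene set is given as ``background_counts=(K, N)``
    a 2×2 Fisher exact test is used instead.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= k_hits <= n_total):
        raise ValueError("k_hits must lie in [0, n_total]")
    if not (0 < background_rate < 1):
        raise ValueError("background rate must lie in (0, 1)")
    fold = (k_hits / n_total) / background_rate
    if background_counts is not None:
        bk, bn = background_counts
        table = [[k_hits, n_total - k_hits], [bk, bn - bk]]
        _, p = sps.fisher_exact(table, alternative="two-sided")
    else:
        p = sps.binomtest(k_hits, n_total, background_rate).pvalue
    return float(fold), float(min(max(p, 0.0), 1.0))


def polar_phase_plot(sample: PhaseSample, bin_h: float = 3.0, ax=None, **bar_kw):
    """Circular (Raleigh-style) histogram of peak phases; returns the axes."""
    import matplotlib.pyplot as plt

    counts = phase_histogram(sample, bin_h)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (np.arange(counts.size) + 0.5) * bin_h / CYCLE_H * 2 * np.pi
    ax.bar(centers, counts, width=2 * np.pi * bin_h / CYCLE_H, **bar_kw)
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"ZT{int(h)}" for h in np.arange(0, 24, 3)])
    mean_h, r = mean_vector(sample)
    if np.isfinite(mean_h):
        ax.plot([2 * np.pi * mean_h / CYCLE_H] * 2, [0, r * max(counts.max(), 1)], "r-")
    return ax
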