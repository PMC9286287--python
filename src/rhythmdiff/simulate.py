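"""Synthetic circadian expression datasets with known ground truth.

The generator emulates a pooled around-the-clock liver RNA-seq design:
8 timepoints at 3 h intervals across one 12:12 LD cycle, one pooled
sample per group and timepoint where each pool averages ``animals_per_pool``
(default 3) independent noisy animal profiles, and two compared
conditions (a reference group A, e.g. wild type, and a test group B,
e.g. a knockout).  Gene truth categories carry the reported effect
structure: wild-type-rhythmic genes peak at night (von Mises around
ZT20.5), genes that gain a rhythm in the test condition cluster at
mid-day (ZT6), and phase-shifted genes flip by 12 h from night to day.

Waveform: single-harmonic cosine with multiplicative relative amplitude,
expected abundance m·(1 + A·cos(2π(t − φ)/cycle)); peak/trough ratio is
(1+A)/(1−A), so A ≤ 1 keeps abundances non-negative.  Noise is either
multiplicative log-normal with fixed CV (mean-preserving) or negative
binomial with a dispersion parameter (integer counts).  One master seed
drives deterministic per-gene substreams, so extending a simulation with
more genes never perturbs the earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationDesign",
    "GeneTruth",
    "SyntheticDataset",
    "CATEGORY_CHOICES",
    "DEFAULT_FRACTIONS",
    "DEFAULT_PHASE_MODEL",
    "generate_truth",
    "expression_profile",
    "simulate_dataset",
    "write_dataset",
    "read_truth",
    "largest_remainder_counts",
]

CATEGORY_CHOICES = (
    "arrhythmic_both",
    "rhythmic_unchanged",
    "phase_shifted",
    "other_changed",
    "gained_in_B",
    "lost_in_B",
)

# Study-condition defaults: mostly arrhythmic background, a solidly
# rhythmic shared core, and the gain/flip/loss effect structure.
DEFAULT_FRACTIONS: dict[str, float] = {
    "arrhythmic_both": 0.60,
    "rhythmic_unchanged": 0.20,
    "phase_shifted": 0.10,
    "gained_in_B": 0.07,
    "lost_in_B": 0.03,
}

# (mean ZT hour, von Mises concentration κ) of the group-A (or defining-group)
# peak phase per category.  Night-peaking wild-type population ~ZT20.5;
# gains in the test condition strongly clustered at mid-day (ZT6).
DEFAULT_PHASE_MODEL: dict[str, tuple[float, float]] = {
    "rhythmic_unchanged": (20.5, 2.0),
    "phase_shifted": (20.5, 2.0),
    "other_changed": (20.5, 2.0),
    "lost_in_B": (20.5, 2.0),
    "gained_in_B": (6.0, 4.0),
}

_DEFAULT_REL_AMPLITUDE = 0.5
_DEFAULT_NOISE_CV = 0.10
_OTHER_CHANGED_AMP_B = 0.2
_PHASE_SHIFT_H = 12.0
_MESOR_LOG10_RANGE = (1.0, 3.0)  # FPKM-like abundances 10–1000


@dataclass(frozen=True)
class SimulationDesign:
    """Sampling design: timepoints within one cycle, groups, pooling, seed."""

    timepoints_h: tuple[float, ...] = tuple(float(t) for t in range(0, 24, 3))
    cycle_h: float = 24.0
    groups: tuple[str, ...] = ("WT", "KO")
    animals_per_pool: int = 3
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.timepoints_h, dtype=float)
        if self.cycle_h <= 0:
            raise ValueError("cycle_h must be positive")
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(t < 0) or np.any(t >= self.cycle_h):
            raise ValueError("timepoints must lie in [0, cycle_h)")
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise ValueError("groups must be non-empty and unique")
        if self.animals_per_pool < 1:
            raise ValueError("animals_per_pool must be >= 1")


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth cosinor parameters of one gene, per group."""

    gene_id: str
    category: str
    mesor: Mapping[str, float]
    rel_amplitude: Mapping[str, float]
    phase_h: Mapping[str, float]
    noise_cv: float
    cycle_h: float = 24.0

    def __post_init__(self):
        if self.category not in CATEGORY_CHOICES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for g in self.mesor:
            if self.mesor[g] <= 0:
                raise ValueError("mesor must be positive")
            a = self.rel_amplitude[g]
            if not (0 <= a <= 1):
                raise ValueError("relative amplitude must lie in [0, 1]")
            if not (0 <= self.phase_h[g] < self.cycle_h):
                raise ValueError("phase must lie in [0, cycle_h)")


@dataclass(frozen=True)
class SyntheticDataset:
    """Expression matrix (genes × group/timepoint samples) plus its truth."""

    expression: pd.DataFrame  # index gene_id, columns '<GROUP>_ZT<hh>'
    truth: tuple[GeneTruth, ...]
    design: SimulationDesign

    def __post_init__(self):
        if len(self.truth) != self.expression.shape[0]:
            raise ValueError("one truth record per gene required")
        expected = len(self.design.groups) * len(self.design.timepoints_h)
        if self.expression.shape[1] != expected:
            raise ValueError("sample count must be |groups| × |timepoints|")


def largest_remainder_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Exact integer per-category counts by largest-remainder rounding."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {total})")
    for c in fractions:
        if c not in CATEGORY_CHOICES:
            raise ValueError(f"unknown category {c!r}")
    quotas = {c: n * f for c, f in fractions.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(
        fractions, key=lambda c: (-(quotas[c] - counts[c]), list(fractions).index(c))
    )
    for c in by_remainder[:leftover]:
        counts[c] += 1
    return counts


def _gene_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, stream, index))))


def _von_mises_hours(rng: np.random.Generator, mu_h: float, kappa: float, cycle_h: float) -> float:
    theta = rng.vonmises(2 * np.pi * mu_h / cycle_h - np.pi, kappa) + np.pi
    return float(np.mod(theta * cycle_h / (2 * np.pi), cycle_h))


def generate_truth(
    n_genes: int,
    category_fractions: Mapping[str, float] | None = None,
    phase_model: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    groups: Sequence[str] = ("WT", "KO"),
    rel_amplitude: float = _DEFAULT_REL_AMPLITUDE,
    noise_cv: float = _DEFAULT_NOISE_CV,
    cycle_h: float = 24.0,
) -> tuple[GeneTruth, ...]:
    """Draw per-gene ground truth with exact category counts.

    The first group label takes the reference (A) role, the second the
    test (B) role; any further groups inherit the reference parameters.
    Phases are von Mises draws per the category's ``(mean ZT, κ)`` model;
    phase-shifted genes place group B exactly 12 h from group A.
    """
    fractions = dict(category_fractions or DEFAULT_FRACTIONS)
    phases = {**DEFAULT_PHASE_MODEL, **(phase_model or {})}
    if len(groups) < 2:
        raise ValueError("need a reference and a test group")
    counts = largest_remainder_counts(n_genes, fractions)
    ga, gb = groups[0], groups[1]
    others = list(groups[2:])
    categories: list[str] = []
    for c in fractions:  # insertion order: deterministic category layout
        categories.extend([c] * counts[c])

    width = len(str(max(n_genes - 1, 1)))
    truths: list[GeneTruth] = []
    for idx, cat in enumerate(categories):
        rng = _gene_rng(seed, 0, idx)
        mesor = float(10 ** rng.uniform(*_MESOR_LOG10_RANGE))
        mu_kappa = phases.get(cat, (20.5, 2.0))
        phi_a = _von_mises_hours(rng, *mu_kappa, cycle_h)
        amp = {ga: 0.0, gb: 0.0}
        phase = {ga: phi_a, gb: phi_a}
        if cat == "rhythmic_unchanged":
            amp = {ga: rel_amplitude, gb: rel_amplitude}
        elif cat == "phase_shifted":
            amp = {ga: rel_amplitude, gb: rel_amplitude}
            phase[gb] = float(np.mod(phi_a + _PHASE_SHIFT_H, cycle_h))
        elif cat == "other_changed":
            amp = {ga: rel_amplitude, gb: _OTHER_CHANGED_AMP_B}
        elif cat == "gained_in_B":
            amp = {ga: 0.0, gb: rel_amplitude}
        elif cat == "lost_in_B":
            amp = {ga: rel_amplitude, gb: 0.0}
        for g in others:
            amp[g] = amp[ga]
            phase[g] = phase[ga]
        truths.append(
            GeneTruth(
                gene_id=f"gene_{idx:0{width}d}",
                category=cat,
                mesor={g: mesor for g in groups},
                rel_amplitude=amp,
                phase_h=phase,
                noise_cv=noise_cv,
                cycle_h=cycle_h,
            )
        )
    return tuple(truths)


def expression_profile(truth: GeneTruth, group: str, t_h: float | np.ndarray) -> np.ndarray:
    """Noiseless expected abundance m·(1 + A·cos(2π(t − φ)/cycle)); peak at t ≡ φ."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    m = truth.mesor[group]
    a = truth.rel_amplitude[group]
    if a > 1:
        raise ValueError("relative amplitude > 1 implies negative abundance")
    phi = truth.phase_h[group]
    return m * (1.0 + a * np.cos(2 * np.pi * (t - phi) / truth.cycle_h))


def _pooled_noisy(
    rng: np.random.Generator,
    expected: np.ndarray,
    n_pool: int,
    noise_model: str,
    noise_param: float,
) -> np.ndarray:
    if noise_model == "lognormal_cv":
        if noise_param == 0:
            return expected.copy()
        sigma2 = math.log1p(noise_param**2)
        draws = expected[None, :] * rng.lognormal(
            mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=(n_pool,) + expected.shape
        )
    elif noise_model == "negative_binomial_dispersion":
        # pooled library drawn directly: pooling n animals divides the
        # extra-Poisson dispersion by n, keeping the mean at the profile
        # and the output integer-valued
        r = n_pool / noise_param
        p = r / (r + np.maximum(expected, 1e-12))
        return rng.negative_binomial(r, p, size=expected.shape).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return draws.mean(axis=0)


def simulate_dataset(
    design: SimulationDesign,
    truth: Sequence[GeneTruth],
    noise_model: str = "lognormal_cv",
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate the pooled expression matrix for a truth collection.

    Each gene × group × timepoint value is the arithmetic mean of
    ``animals_per_pool`` independent noisy draws around the expected
    profile (equal-mass RNA pooling ≈ averaging).  For the log-normal
    model the per-animal CV is the gene's ``noise_cv``; for the
    negative-binomial model ``noise_cv``² is used as the dispersion and
    pooled values are means of integer counts.
    """
    if not truth:
        raise ValueError("truth collection is empty")
    seed = design.seed if seed is None else seed
    t = np.asarray(design.timepoints_h, dtype=float)
    columns = [_sample_name(g, tp) for g in design.groups for tp in t]
    mat = np.empty((len(truth), len(columns)))
    for idx, tr in enumerate(truth):
        rng = _gene_rng(seed, 1, idx)
        row = []
        for g in design.groups:
            expected = expression_profile(tr, g, t)
            param = tr.noise_cv if noise_model == "lognormal_cv" else max(tr.noise_cv**2, 1e-12)
            row.append(_pooled_noisy(rng, expected, design.animals_per_pool, noise_model, param))
        mat[idx] = np.concatenate(row)
    expr = pd.DataFrame(mat, index=[tr.gene_id for tr in truth], columns=columns)
    expr.index.name = "gene_id"
    return SyntheticDataset(expression=expr, truth=tuple(truth), design=design)


def _sample_name(group: str, t_h: float) -> str:
    if float(t_h).is_integer():
        return f"{group}_ZT{int(t_h):02d}"
    return f"{group}_ZT{t_h:g}"


def truth_frame(truth: Sequence[GeneTruth], groups: Sequence[str]) -> pd.DataFrame:
    rows = []
    for tr in truth:
        row: dict[str, object] = {"gene_id": tr.gene_id, "category": tr.category}
        for g in groups:
            row[f"mesor_{g}"] = tr.mesor[g]
            row[f"rel_amplitude_{g}"] = tr.rel_amplitude[g]
            row[f"phase_h_{g}"] = tr.phase_h[g]
        row["noise_cv"] = tr.noise_cv
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(ds: SyntheticDataset, path: str | Path) -> tuple[Path, Path]:
    """Write expression and truth TSVs; returns their paths.

    ``path`` is a directory; files are ``expression.tsv`` and
    ``truth.tsv``.  Floats are written with enough digits for an exact
    round-trip within text-float precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    expr_path = path / "expression.tsv"
    truth_path = path / "truth.tsv"
    ds.expression.to_csv(expr_path, sep="\t", float_format="%.10g")
    truth_frame(ds.truth, ds.design.groups).to_csv(
        truth_path, sep="\t", index=False, float_format="%.10g"
    )
    return expr_path, truth_path


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
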