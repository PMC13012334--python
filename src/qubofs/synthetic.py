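"""Synthetic benchmark with planted ground truth.

The generator produces a controlled recovery problem: ``n`` correlated
Gaussian features (correlation matrix derived from C = BᵀB with B a random
normal matrix), ``p`` observations, five *source* features driving a highly
nonlinear target, and five *planted-correlate* features that are noisy copies
of the sources (X[:, t_m] = X[:, s_m] + ρ·ε with ρ = 0.1, giving a pair
correlation of 1/√(1+ρ²) ≈ 0.995).  The target is

    y_i = 0.5·cos(7·X[i,s4]) + sin(X[i,s3]·X[i,s2])
          + 0.1·exp(X[i,s5])·log2(|10·X[i,s1]| + g) + ρ·ε'_i

with a small guard ``g`` inside the logarithm (the raw expression is
undefined for non-positive arguments, which half of the Gaussian draws would
produce).  Features are z-scored and the target min-max scaled to [0, 1].

Source/planted indices in :class:`SyntheticSpec` are **1-based** (the
user-facing convention); conversion to 0-based column indices is centralized
in the spec's ``sources0`` / ``targets0`` properties.  A selection method is
scored by :func:`recovery_accuracy`, the fraction of the planted source set
it recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ContinuousDataset

LOG_GUARD = 1e-8


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe: sizes, planted indices (1-based), noise level, seed."""

    n: int = 50
    p: int = 10_000
    s: tuple[int, ...] = (5, 11, 7, 1, 14)
    t: tuple[int, ...] = (16, 17, 18, 19, 20)
    rho: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.s) != len(self.t):
            raise ValueError("s and t must have equal length")
        if set(self.s) & set(self.t):
            raise ValueError("s and t must be disjoint")
        for idx in (*self.s, *self.t):
            if not (1 <= idx <= self.n):
                raise ValueError(f"planted index {idx} outside [1, {self.n}]")

    @property
    def sources0(self) -> np.ndarray:
        """Source feature columns, 0-based."""
        return np.asarray(self.s, dtype=np.int64) - 1

    @property
    def targets0(self) -> np.ndarray:
        """Planted-correlate columns, 0-based."""
        return np.asarray(self.t, dtype=np.int64) - 1


@dataclass
class SyntheticDataset:
    """Standardized benchmark data: z-scored ``X_std``, min-max target
    ``y_norm`` in [0, 1] and the generating :class:`SyntheticSpec`."""

    X_std: np.ndarray
    y_norm: np.ndarray
    truth: SyntheticSpec | None = None

    def to_continuous(self) -> ContinuousDataset:
        names = [f"f{j + 1}" for j in range(self.X_std.shape[1])]
        return ContinuousDataset(self.X_std, self.y_norm, feature_names=names)


def correlation_structure(n: int, seed) -> np.ndarray:
    """Random correlation matrix: B ~ N(0,1) n×n, C = BᵀB, normalized to unit
    diagonal.  Symmetric positive semidefinite by construction."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = rng.standard_normal((n, n))
    C = B.T @ B
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_observations(R: np.ndarray, p: int, s: np.ndarray, t: np.ndarray,
                          rho: float, seed) -> np.ndarray:
    """Draw X ~ MVN(0, R), then overwrite each planted column t_m with its
    source column plus ρ-scaled Gaussian noise.  ``s``/``t`` are 0-based."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = np.asarray(R, dtype=np.float64)
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {evals.min():.3g})")
    try:
        X = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=p, method="cholesky")
    except np.linalg.LinAlgError:
        X = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=p, method="eigh")
    s = np.asarray(s, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    for sm, tm in zip(s, t):
        X[:, tm] = X[:, sm] + rho * rng.standard_normal(p)
    return X


def nonlinear_target(X: np.ndarray, s: np.ndarray, rho: float, seed,
                     guard: float = LOG_GUARD) -> np.ndarray:
    """Nonlinear response built from the five source columns (``s`` 0-based,
    in recipe order s1..s5), plus ρ-scaled Gaussian noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(s, dtype=np.int64)
    if s.size != 5:
        raise ValueError("the target recipe uses exactly five source columns")
    s1, s2, s3, s4, s5 = (X[:, j] for j in s)
    y = (0.5 * np.cos(7.0 * s4)
         + np.sin(s3 * s2)
         + 0.1 * np.exp(s5) * np.log2(np.abs(10.0 * s1) + guard))
    return y + rho * rng.standard_normal(X.shape[0])


def standardize(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score every column of X; min-max scale y to [0, 1].

    Idempotent up to floating point: standardizing a standardized pair
    changes nothing.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    span = y.max() - y.min()
    if span == 0.0:
        raise ValueError("target is constant; cannot min-max scale")
    sd = X.std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("constant feature column; cannot z-score")
    return (X - X.mean(axis=0)) / sd, (y - y.min()) / span


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Run the full recipe for a spec (default spec if none given)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    R = correlation_structure(spec.n, rng)
    X = simulate_observations(R, spec.p, spec.sources0, spec.targets0, spec.rho, rng)
    y = nonlinear_target(X, spec.sources0, spec.rho, rng)
    X_std, y_norm = standardize(X, y)
    return SyntheticDataset(X_std=X_std, y_norm=y_norm, truth=spec)


def recovery_accuracy(selected, truth_s) -> float:
    """|selected ∩ truth| / |truth|, order-insensitive.

    Both arguments must use the same index base; selections from
    ``select_features`` are 0-based, so compare against ``spec.sources0``.
    """
    truth = set(int(i) for i in np.asarray(truth_s).ravel())
    if not truth:
        raise ValueError("truth set is empty")
    sel = set(int(i) for i in np.asarray(selected).ravel())
    return len(sel & truth) / len(truth)
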