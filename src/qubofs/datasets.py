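"""Container for a regression problem: observations × features plus a continuous target."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContinuousDataset:
    """A feature matrix ``X`` (p observations × n features) and target vector ``T``.

    The target is any continuous per-observation quantity to be regressed on the
    features — for single-cell data, typically a pseudotime value per cell.

    Raises
    ------
    ValueError
        on NaN/Inf entries, fewer than 2 observations or features, mismatched
        shapes, or duplicated feature names.
    """

    X: np.ndarray
    T: np.ndarray
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.T = np.asarray(self.T, dtype=np.float64).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (observations x features)")
        p, n = self.X.shape
        if p < 2 or n < 2:
            raise ValueError(f"need at least 2 observations and 2 features, got {p}x{n}")
        if self.T.shape[0] != p:
            raise ValueError(f"target length {self.T.shape[0]} != {p} observations")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf")
        if not np.all(np.isfinite(self.T)):
            raise ValueError("T contains NaN or Inf")
        if self.feature_names is not None:
            self.feature_names = [str(s) for s in self.feature_names]
            if len(self.feature_names) != n:
                raise ValueError("feature_names length does not match feature count")
            if len(set(self.feature_names)) != n:
                raise ValueError("feature_names must be unique")

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_observations(self, idx: np.ndarray) -> "ContinuousDataset":
        """New dataset restricted to the given observation indices."""
        return ContinuousDataset(self.X[idx], self.T[idx], self.feature_names)

    def name_of(self, i: int) -> str:
        return self.feature_names[i] if self.feature_names else f"feature_{i}"
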