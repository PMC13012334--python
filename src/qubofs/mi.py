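"""Quantile binning and plug-in mutual information.

Continuous features and the continuous target are discretized into ``B``
quantile bins per variable; mutual information is then estimated by the
plug-in estimator on the empirical joint bin frequencies,

    I(a; b) = sum_{u,v} p(u,v) * log[ p(u,v) / (p(u) p(v)) ],

in nats (natural log).  Only ratios of MI values matter downstream, so the
log base is a free convention.  Feature importance ``I`` is the MI of each
feature with the target; redundancy ``R`` is the pairwise feature MI with a
zero diagonal (a feature is never redundant with itself).

Quantile bins with ties: heavily tied columns (e.g. sparse expression with
many zeros) produce duplicate quantile edges; duplicates are merged so the
effective number of bins may be < B, keeping the partition valid with no
empty interior structure.  Bins are left-closed/right-open, the last bin
closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ContinuousDataset

DEFAULT_BINS = 15


@dataclass(frozen=True)
class BinSpec:
    """Bin boundaries for one variable: ``edges`` strictly increasing, first/last
    spanning the data range; ``effective_bins = len(edges) - 1`` (>= 1)."""

    edges: np.ndarray
    effective_bins: int

    def __post_init__(self) -> None:
        if self.effective_bins < 1:
            raise ValueError("effective_bins must be >= 1")


@dataclass
class BinnedDataset:
    """Discretized dataset: per-feature integer labels (p × n), target labels and
    the per-variable :class:`BinSpec` objects."""

    labels: np.ndarray
    target_labels: np.ndarray
    bin_specs: list[BinSpec]
    target_spec: BinSpec

    @property
    def n_features(self) -> int:
        return self.labels.shape[1]

    @property
    def n_observations(self) -> int:
        return self.labels.shape[0]


def quantile_bin(values: np.ndarray, B: int) -> tuple[np.ndarray, BinSpec]:
    """Assign each value to one of up to ``B`` quantile bins.

    Duplicate quantile edges (ties in the data) are merged, so the returned
    spec may have ``effective_bins < B``; a constant input yields one bin.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 1:
        raise ValueError("values must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    edges = np.unique(np.quantile(v, np.linspace(0.0, 1.0, B + 1)))
    if edges.size < 2:  # constant input
        spec = BinSpec(edges=edges, effective_bins=1)
        return np.zeros(v.size, dtype=np.int64), spec
    # left-closed/right-open intervals; values equal to an interior edge go up
    labels = np.searchsorted(edges[1:-1], v, side="right").astype(np.int64)
    return labels, BinSpec(edges=edges, effective_bins=edges.size - 1)


def bin_dataset(data: ContinuousDataset, B: int = DEFAULT_BINS) -> BinnedDataset:
    """Discretize every feature column and the target with the same ``B``."""
    p, n = data.X.shape
    labels = np.empty((p, n), dtype=np.int64)
    specs: list[BinSpec] = []
    for j in range(n):
        labels[:, j], spec = quantile_bin(data.X[:, j], B)
        specs.append(spec)
    t_labels, t_spec = quantile_bin(data.T, B)
    return BinnedDataset(labels=labels, target_labels=t_labels, bin_specs=specs, target_spec=t_spec)


def plug_in_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two integer label vectors.

    Empty joint cells contribute zero (0·log 0 := 0); the result is clamped
    at 0 against negative floating-point residue.
    """
    a = np.asarray(a, dtype=np.int64).ravel()
    b = np.asarray(b, dtype=np.int64).ravel()
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    p = a.size
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(np.float64)
    joint /= p
    pa = joint.reshape(na, nb).sum(axis=1)
    pb = joint.reshape(na, nb).sum(axis=0)
    outer = np.outer(pa, pb).ravel()
    nz = joint > 0
    terms = joint[nz] * np.log(joint[nz] / outer[nz])
    # summing in sorted order makes the result exactly symmetric in (a, b):
    # the term multiset is invariant under transposing the joint table
    mi = float(np.sort(terms).sum())
    return max(mi, 0.0)


def entropy(a: np.ndarray) -> float:
    """Empirical Shannon entropy (nats) of a label vector."""
    a = np.asarray(a, dtype=np.int64).ravel()
    counts = np.bincount(a).astype(np.float64)
    pr = counts[counts > 0] / a.size
    return float(-np.sum(pr * np.log(pr)))


def importance_vector(binned: BinnedDataset) -> np.ndarray:
    """MI of each feature with the target: ``I[i] = MI(x_i, T)``, length n, nats."""
    n = binned.n_features
    I = np.empty(n, dtype=np.float64)
    for i in range(n):
        I[i] = plug_in_mi(binned.labels[:, i], binned.target_labels)
    return I


def redundancy_matrix(binned: BinnedDataset) -> np.ndarray:
    """Pairwise feature MI matrix ``R`` with ``R[i,i] = 0``.

    Symmetric by construction (the upper triangle is computed and mirrored).
    """
    n = binned.n_features
    if n < 2:
        raise ValueError("need at least 2 features")
    R = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            R[i, j] = R[j, i] = plug_in_mi(binned.labels[:, i], binned.labels[:, j])
    return R
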