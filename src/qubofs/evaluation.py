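"""Selection diagnostics: landscape enumeration, energy paths, stability.

Three complementary views of a fitted QUBO feature-selection model:

* *Landscape enumeration* — evaluate the model energy of every m-subset of a
  shortlist of features, giving an exhaustive picture of the low-order
  combinatorial landscape.
* *Energy paths* — the cumulative model energy as a ranked feature list is
  selected prefix by prefix, comparable across selection methods because all
  rankings are scored against the same QUBO.
* *k-fold stability* — resolve the selection on observation subsets with a
  locally rebuilt cost function and measure agreement with the global
  selection, by set overlap and by energy ratio under the global model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .datasets import ContinuousDataset
from .mi import DEFAULT_BINS, bin_dataset, importance_vector, redundancy_matrix
from .qubo import QuboModel, build_qubo, energy
from .solvers import select_features


@dataclass(frozen=True)
class LandscapePoint:
    """One enumerated subset: strictly increasing index tuple and its model
    energy (base energy of the induced mask)."""

    combo: tuple[int, ...]
    energy: float


@dataclass
class FoldResult:
    """One cross-validation fold: the locally solved selection, its overlap
    accuracy against the global selection, and its energy under the global
    model (both the fold selection and the global selection, for the ratio)."""

    fold: int
    selected: list[int]
    accuracy: float
    energy_fold_global: float
    energy_global_global: float

    @property
    def energy_ratio(self) -> float:
        """E_global(x_fold) / E_global(x_global); 1.0 means the fold solution
        is as good as the global one under the global cost."""
        if self.energy_global_global == 0.0:
            return float("nan")
        return self.energy_fold_global / self.energy_global_global


@dataclass
class StabilityReport:
    """Global selection plus per-fold results and min/mean summaries."""

    global_selected: list[int]
    per_fold: list[FoldResult]

    @property
    def min_accuracy(self) -> float:
        return min(f.accuracy for f in self.per_fold)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.per_fold]))

    @property
    def mean_energy_ratio(self) -> float:
        return float(np.mean([f.energy_ratio for f in self.per_fold]))


_MAX_COMBOS = 10**6


def enumerate_landscape(model: QuboModel, top_indices, m: int) -> list[LandscapePoint]:
    """Evaluate every m-subset of ``top_indices``; ascending by energy.

    The count is exactly C(|top_indices|, m); enumeration refuses budgets
    above 10^6 subsets.
    """
    top = [int(i) for i in top_indices]
    if len(set(top)) != len(top):
        raise ValueError("top_indices must be unique")
    n = model.Q.shape[0]
    if any(i < 0 or i >= n for i in top):
        raise ValueError("top_indices out of range for the model")
    if not 0 <= m <= len(top):
        raise ValueError(f"m={m} invalid for {len(top)} indices")
    total = comb(len(top), m)
    if total > _MAX_COMBOS:
        raise ValueError(f"C({len(top)}, {m}) = {total} exceeds the "
                         f"{_MAX_COMBOS} enumeration budget")
    points = []
    x = np.zeros(n, dtype=np.int8)
    for combo in itertools.combinations(sorted(top), m):
        x[:] = 0
        x[list(combo)] = 1
        points.append(LandscapePoint(combo=combo, energy=energy(model, x)))
    points.sort(key=lambda pt: (pt.energy, pt.combo))
    return points


def energy_path(model: QuboModel, ranked) -> np.ndarray:
    """Cumulative energies of the prefixes of a ranking.

    Entry j is the model energy of the mask selecting the first j ranked
    features; entry 0 is the empty-mask energy (the model offset).
    """
    ranked = [int(i) for i in ranked]
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked indices must be unique")
    n = model.Q.shape[0]
    if any(i < 0 or i >= n for i in ranked):
        raise ValueError("ranked indices out of range for the model")
    path = np.empty(len(ranked) + 1)
    path[0] = model.offset
    e = model.offset
    x = np.zeros(n, dtype=np.float64)
    for j, i in enumerate(ranked, start=1):
        # incremental single-flip update: dE = Q_ii + 2 Q[i]·x
        e += model.Q[i, i] + 2.0 * float(model.Q[i] @ x)
        x[i] = 1.0
        path[j] = e
    return path


def _stratified_folds(T: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint covering observation folds, stratified by target quantile.

    Observations are sorted by target value and dealt round-robin (with a
    seeded shuffle inside each quantile block) so every fold spans the
    target's range — a requirement for per-fold quantile binning.
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(T, kind="stable")
    assign = np.empty(T.size, dtype=np.int64)
    for start in range(0, T.size, folds):
        block = order[start:start + folds]
        labels = rng.permutation(folds)[:block.size]
        assign[block] = labels
    return [np.flatnonzero(assign == f) for f in range(folds)]


def kfold_stability(data: ContinuousDataset, k: int, folds: int = 10,
                    alpha: float = 0.9, B: int = DEFAULT_BINS,
                    solver: str = "sa", seed: int = 0,
                    freeze_bin_edges: bool = False) -> StabilityReport:
    """Stability of the selection under observation subsampling.

    The global selection S is computed on the full data.  Observations are
    partitioned into ``folds`` disjoint held-out sets (stratified by target
    quantile); for each fold, the cost function is rebuilt from the
    *training* portion — the observations outside that fold, the standard
    cross-validation subset — and solved for S_fold.  The local data are
    re-binned on the subset; ``freeze_bin_edges`` is reserved for a variant
    reusing the full-data quantile edges and is not implemented.  Each fold
    reports the set-overlap accuracy |S_fold ∩ S| / k and the energies of
    x_fold and x_global under the *global* model.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    p = data.X.shape[0]
    if p < folds * 10:
        raise ValueError(f"{p} observations is too few for {folds} folds "
                         "(need >= 10 per fold)")
    if freeze_bin_edges:
        raise NotImplementedError(
            "freeze_bin_edges: quantile edges are data-driven; per-fold "
            "re-binning is the supported behaviour")
    sel_global = select_features(data, k=k, alpha=alpha, B=B,
                                 solver=solver, seed=seed)
    binned = bin_dataset(data, B)
    model_global = build_qubo(importance_vector(binned),
                              redundancy_matrix(binned), alpha)
    n = data.X.shape[1]
    xg = np.zeros(n, dtype=np.int8)
    xg[sel_global.indices] = 1
    e_gg = energy(model_global, xg)
    S = set(sel_global.indices)
    results: list[FoldResult] = []
    all_idx = np.arange(p)
    for f, idx in enumerate(_stratified_folds(data.T, folds, seed)):
        fold_data = data.subset_observations(np.setdiff1d(all_idx, idx))
        sel_fold = select_features(fold_data, k=k, alpha=alpha, B=B,
                                   solver=solver, seed=seed + 1 + f)
        xf = np.zeros(n, dtype=np.int8)
        xf[sel_fold.indices] = 1
        results.append(FoldResult(
            fold=f, selected=list(sel_fold.indices),
            accuracy=len(S & set(sel_fold.indices)) / k,
            energy_fold_global=energy(model_global, xf),
            energy_global_global=e_gg))
    return StabilityReport(global_selected=list(sel_global.indices),
                           per_fold=results)


def overlap_report(list_a, list_b, list_c=None) -> dict:
    """Set algebra over two or three name lists, deterministically ordered.

    Returns counts and sorted memberships: the common core, each pairwise
    intersection (three-list case) and each list's exclusive names.
    """
    a, b = set(list_a), set(list_b)
    out: dict = {}
    if list_c is None:
        core = a & b
        out["overlap"] = sorted(core)
        out["only_a"] = sorted(a - b)
        out["only_b"] = sorted(b - a)
    else:
        c = set(list_c)
        core = a & b & c
        out["overlap"] = sorted(core)
        out["ab"] = sorted((a & b) - c)
        out["ac"] = sorted((a & c) - b)
        out["bc"] = sorted((b & c) - a)
        out["only_a"] = sorted(a - b - c)
        out["only_b"] = sorted(b - a - c)
        out["only_c"] = sorted(c - a - b)
    out["counts"] = {key: len(val) for key, val in out.items()}
    return out
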