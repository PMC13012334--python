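"""Comparison feature selectors run under a uniform top-k contract.

Six classical selectors — LASSO, elastic net, random-forest importance,
RReliefF, greedy mRMR and sequential forward selection — are each reduced to
"return k feature indices", so that every method can be scored against the
synthetic benchmark's planted sources with the same set-overlap metric and
timed on the identical standardized dataset.

Scoring subtlety for the regularization-path methods: the k features are the
top-|coefficient| entries at the sparsest solution on the path having at
least k nonzero coefficients; any of the k whose coefficient is exactly zero
is *flagged* and not credited by the accuracy score (a selector that pads
its answer with dead features should not score for them).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ContinuousDataset
from .mi import DEFAULT_BINS, bin_dataset, importance_vector, redundancy_matrix
from .solvers import select_features
from .synthetic import SyntheticDataset, SyntheticSpec, generate_dataset, recovery_accuracy

METHODS = ("lasso", "elastic_net", "rrelieff", "rfr", "mrmr", "sffs", "qubo")


@dataclass
class BenchmarkRow:
    """Result of one selector on one dataset: the k selected indices
    (0-based), the recovery accuracy, wall time and any zero-coefficient
    flags raised by path-based methods."""

    method: str
    accuracy: float
    wall_seconds: float
    seed: int
    selected: list[int]
    flagged_zero: list[int] = field(default_factory=list)


def _topk(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken toward the lowest index."""
    order = np.argsort(-values, kind="stable")
    return order[:k]


def _path_select(X, y, k, l1_ratio: float, seed: int):
    from sklearn.linear_model import enet_path, lasso_path

    if l1_ratio == 1.0:
        alphas, coefs, _ = lasso_path(X, y, alphas=100)
    else:
        alphas, coefs, _ = enet_path(X, y, l1_ratio=l1_ratio, alphas=100)
    nnz = (coefs != 0).sum(axis=0)          # alphas run sparse -> dense
    ok = np.flatnonzero(nnz >= k)
    col = int(ok[0]) if ok.size else coefs.shape[1] - 1
    w = np.abs(coefs[:, col])
    sel = _topk(w, k)
    flagged = [int(i) for i in sel if coefs[i, col] == 0.0]
    return [int(i) for i in sel], flagged


def _rfr_select(X, y, k, seed, n_estimators: int = 100):
    from sklearn.ensemble import RandomForestRegressor

    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return [int(i) for i in _topk(rf.feature_importances_, k)], []


def rrelieff_weights(X: np.ndarray, y: np.ndarray, n_samples: int = 200,
                     n_neighbors: int = 10, seed: int = 0) -> np.ndarray:
    """RReliefF attribute weights for a regression target.

    Regression variant of ReliefF: for ``n_samples`` randomly drawn
    instances, the ``n_neighbors`` nearest neighbours (Manhattan distance on
    range-normalized attributes) contribute probability-weighted accumulators
    for target change, attribute change, and their co-occurrence; the weight
    of attribute a is

        W[a] = N_dC&dA[a] / N_dC  -  (N_dA[a] - N_dC&dA[a]) / (m - N_dC).

    Positive weights indicate attributes whose variation tracks target
    variation among close neighbours.
    """
    rng = np.random.default_rng(seed)
    p, n = X.shape
    rngs = X.max(axis=0) - X.min(axis=0)
    rngs[rngs == 0] = 1.0
    y_rng = y.max() - y.min()
    if y_rng == 0:
        raise ValueError("constant target")
    Xn = X / rngs
    m = min(n_samples, p)
    picks = rng.choice(p, size=m, replace=False)
    ndc = 0.0
    nda = np.zeros(n)
    ndcda = np.zeros(n)
    for r in picks:
        d = np.abs(Xn - Xn[r]).sum(axis=1)
        d[r] = np.inf
        nb = np.argsort(d, kind="stable")[:n_neighbors]
        # rank-exponential neighbour influence, normalized
        w = np.exp(-((np.arange(n_neighbors) / (n_neighbors / 3.0)) ** 2))
        w /= w.sum()
        dy = np.abs(y[nb] - y[r]) / y_rng
        da = np.abs(Xn[nb] - Xn[r])          # (n_neighbors, n) already normalized
        ndc += float(dy @ w)
        nda += w @ da
        ndcda += (w * dy) @ da
    denom = m - ndc if m - ndc > 0 else 1.0
    return ndcda / max(ndc, 1e-12) - (nda - ndcda) / denom


def _rrelieff_select(X, y, k, seed):
    return [int(i) for i in _topk(rrelieff_weights(X, y, seed=seed), k)], []


def _mrmr_select(X, y, k, seed, B: int = DEFAULT_BINS):
    """Greedy MI-quotient mRMR: start from the most important feature, then
    repeatedly add argmax I_i / mean(R_i,selected)."""
    data = ContinuousDataset(X, y)
    binned = bin_dataset(data, B)
    I = importance_vector(binned)
    R = redundancy_matrix(binned)
    selected = [int(np.argmax(I))]
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            red = float(np.mean(R[j, selected]))
            score = I[j] / max(red, 1e-12)
            if score > best_score + 1e-15:
                best, best_score = j, score
        selected.append(best)
    return selected, []


def _sffs_select(X, y, k, seed, cv: int = 5):
    """Greedy forward selection minimizing cross-validated squared error of a
    regression-tree fit (a criterion able to see the nonlinear response)."""
    from sklearn.feature_selection import SequentialFeatureSelector
    from sklearn.model_selection import KFold
    from sklearn.tree import DecisionTreeRegressor

    est = DecisionTreeRegressor(random_state=seed, min_samples_leaf=20)
    sfs = SequentialFeatureSelector(
        est, n_features_to_select=k, direction="forward",
        scoring="neg_mean_squared_error",
        cv=KFold(n_splits=cv, shuffle=True, random_state=seed))
    sfs.fit(X, y)
    return [int(i) for i in np.flatnonzero(sfs.get_support())], []


def _qubo_select(X, y, k, seed, alpha=0.9, B=15, solver="sa"):
    sel = select_features(ContinuousDataset(X, y), k=k, alpha=alpha, B=B,
                          solver=solver, seed=seed)
    return sel.indices, []


_DISPATCH = {
    "lasso": lambda X, y, k, seed: _path_select(X, y, k, 1.0, seed),
    "elastic_net": lambda X, y, k, seed: _path_select(X, y, k, 0.5, seed),
    "rfr": _rfr_select,
    "rrelieff": _rrelieff_select,
    "mrmr": _mrmr_select,
    "sffs": _sffs_select,
    "qubo": _qubo_select,
}


def run_baseline(method: str, data: SyntheticDataset | ContinuousDataset,
                 k: int, seed: int = 0, **kwargs) -> BenchmarkRow:
    """Run one selector on a dataset and score it against the planted truth.

    For a :class:`SyntheticDataset` the accuracy is the planted-source
    recovery (zero-coefficient selections are not credited); for a plain
    :class:`ContinuousDataset` accuracy is reported as NaN.
    """
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if isinstance(data, SyntheticDataset):
        X, y = data.X_std, data.y_norm
        truth = data.truth.sources0 if data.truth is not None else None
    else:
        X, y = data.X, data.T
        truth = None
    if k > X.shape[1]:
        raise ValueError("k exceeds feature count")
    t0 = time.perf_counter()
    selected, flagged = _DISPATCH[method](X, y, k, seed, **kwargs)
    wall = time.perf_counter() - t0
    if truth is not None:
        credited = [i for i in selected if i not in flagged]
        acc = len(set(credited) & set(int(i) for i in truth)) / len(truth)
    else:
        acc = float("nan")
    return BenchmarkRow(method=method, accuracy=acc, wall_seconds=wall,
                        seed=seed, selected=selected, flagged_zero=flagged)


def benchmark_table(spec: SyntheticSpec | None = None,
                    methods: tuple[str, ...] = METHODS,
                    seeds: tuple[int, ...] = (1,),
                    k: int = 5, **method_kwargs) -> tuple[list[BenchmarkRow], pd.DataFrame]:
    """One row per (method, seed), all methods sharing the identical dataset
    per seed; plus an aggregate of mean accuracy and mean wall time."""
    if not seeds:
        raise ValueError("need at least one seed")
    spec = spec or SyntheticSpec()
    rows: list[BenchmarkRow] = []
    for seed in seeds:
        ds = generate_dataset(SyntheticSpec(n=spec.n, p=spec.p, s=spec.s,
                                            t=spec.t, rho=spec.rho, seed=seed))
        for method in methods:
            rows.append(run_baseline(method, ds, k=k, seed=seed,
                                     **method_kwargs.get(method, {})))
    df = pd.DataFrame([{"method": r.method, "seed": r.seed,
                        "accuracy": r.accuracy, "wall_seconds": r.wall_seconds}
                       for r in rows])
    agg = (df.groupby("method", sort=False)
             .agg(mean_accuracy=("accuracy", "mean"),
                  mean_wall_seconds=("wall_seconds", "mean"),
                  n_runs=("seed", "count"))
             .reset_index())
    return rows, agg


def format_table(agg: pd.DataFrame) -> str:
    """Human-readable benchmark summary (Method, Accuracy %, Time s)."""
    lines = [f"{'Method':<28}{'Accuracy (%)':>14}{'Time (s)':>12}"]
    for _, row in agg.iterrows():
        lines.append(f"{row['method']:<28}{100 * row['mean_accuracy']:>14.1f}"
                     f"{row['mean_wall_seconds']:>12.2f}")
    return "\n".join(lines)
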