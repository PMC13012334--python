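"""Classical minimizers for the QUBO cost function.

Three routes are provided:

* :func:`solve_exhaustive` — exact enumeration, feasible for small n (or small
  C(n, k) when a cardinality is fixed); serves as the ground-truth oracle.
* :func:`solve_sa` — multi-read single-flip Metropolis simulated annealing
  with a geometric inverse-temperature schedule.
* :func:`solve_tabu` — iterated tabu search: best-admissible single-flip moves
  with a recency tabu list, aspiration on improving the incumbent, and
  random-perturbation restarts.

All solvers are deterministic under a fixed seed.  :func:`select_features`
wires the full pipeline: quantile binning → importance/redundancy →
balanced QUBO → cardinality penalty → solve → greedy repair → ranking by
marginal energy contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, islice
from math import comb

import numpy as np

from .datasets import ContinuousDataset
from .mi import DEFAULT_BINS, bin_dataset, importance_vector, redundancy_matrix
from .qubo import (QuboModel, add_cardinality_penalty, auto_penalty, build_qubo,
                   energy, marginal_contribution)

_EXHAUSTIVE_MAX_N = 25
_EXHAUSTIVE_MAX_COMB = 5_000_000


@dataclass
class SolveResult:
    """Best mask found, its energy, the evaluation count and (optionally) a
    (step, best-energy) trace; ``best_energy`` always equals the recomputed
    energy of ``best_mask``."""

    best_mask: np.ndarray
    best_energy: float
    n_evaluations: int
    seed: int | None = None
    trace: list[tuple[int, float]] | None = None

    @property
    def selected(self) -> np.ndarray:
        """Indices of the selected features (0-based, ascending)."""
        return np.flatnonzero(self.best_mask)


@dataclass
class RankedSelection:
    """k selected features ordered by ascending marginal contribution (most
    energy-lowering first), with the contribution values and optional names."""

    indices: list[int]
    contributions: list[float]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("ranked indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


def _chunked_masks(n: int, chunk: int = 1 << 18):
    """Yield all 2^n binary masks as float arrays in deterministic chunks."""
    total = 1 << n
    bits = np.arange(n, dtype=np.uint64)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        yield ((codes[:, None] >> bits) & 1).astype(np.float64)


def solve_exhaustive(model: QuboModel, cardinality: int | None = None) -> SolveResult:
    """Globally optimal mask by enumeration.

    With ``cardinality`` given, the optimum is taken over masks of exactly
    that weight (the model's own penalty, if any, still contributes to the
    reported energy).  Ties break toward the earliest mask in enumeration
    order, i.e. the lexicographically smallest selected-index set.
    """
    n = model.n
    if cardinality is None:
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"n={n} too large for unconstrained enumeration "
                f"(max {_EXHAUSTIVE_MAX_N}); use solve_sa or solve_tabu")
        best_e = np.inf
        best_mask = np.zeros(n)
        n_eval = 0
        for X in _chunked_masks(n):
            E = np.einsum("ij,jk,ik->i", X, model.Q, X)
            i = int(np.argmin(E))
            if E[i] < best_e:
                best_e = float(E[i])
                best_mask = X[i].copy()
            n_eval += X.shape[0]
        return SolveResult(best_mask=best_mask.astype(np.int8),
                           best_energy=energy(model, best_mask),
                           n_evaluations=n_eval)
    if not (0 <= cardinality <= n):
        raise ValueError("cardinality out of range")
    n_comb = comb(n, cardinality)
    if n_comb > _EXHAUSTIVE_MAX_COMB:
        raise ValueError(
            f"C({n},{cardinality})={n_comb} exceeds the enumeration budget; "
            "use solve_sa or solve_tabu")
    it = combinations(range(n), cardinality)
    best_e = np.inf
    best_combo: tuple[int, ...] | None = None
    while True:
        batch = np.array(list(islice(it, 100_000)), dtype=np.int64)
        if batch.size == 0 and batch.shape[0] == 0:
            break
        E = model.Q[batch[:, :, None], batch[:, None, :]].sum(axis=(1, 2))
        i = int(np.argmin(E))
        if E[i] < best_e:
            best_e = float(E[i])
            best_combo = tuple(batch[i])
    mask = np.zeros(n, dtype=np.int8)
    if best_combo is not None:
        mask[list(best_combo)] = 1
    return SolveResult(best_mask=mask, best_energy=energy(model, mask),
                       n_evaluations=n_comb)


def _beta_schedule(model: QuboModel, n_sweeps: int,
                   beta_range: tuple[float, float] | None) -> np.ndarray:
    """Geometric inverse-temperature ladder spanning the model's energy scales.

    Hot end: the largest single-flip energy bound is accepted with
    probability 1/2.  Cold end: the smallest nonzero coupling magnitude is
    resolved (uphill acceptance ~1e-4), so near-degenerate masks can still be
    distinguished late in the anneal; the ratio is clipped at 1e8.
    """
    if beta_range is None:
        absQ = np.abs(model.Q)
        diag = np.diag(absQ)
        flip_bound = float(np.max(diag + 2.0 * (absQ.sum(axis=1) - diag)))
        flip_bound = max(flip_bound, 1e-12)
        nz = absQ[absQ > 0]
        small = float(nz.min()) if nz.size else flip_bound
        beta_min = np.log(2.0) / flip_bound
        beta_max = min(np.log(1e4) / small, beta_min * 1e8)
        beta_range = (beta_min, max(beta_max, beta_min * 10.0))
    return np.geomspace(beta_range[0], beta_range[1], n_sweeps)


def solve_sa(model: QuboModel, n_reads: int = 100, n_sweeps: int = 1000,
             beta_schedule: tuple[float, float] | None = None,
             seed: int = 0, record_trace: bool = False) -> SolveResult:
    """Simulated annealing: ``n_reads`` independent chains of single-flip
    Metropolis sweeps under a geometric inverse-temperature ladder spanning
    the model's own energy scales (see :func:`_beta_schedule`).  Identical
    (seed, inputs) give identical output.
    """
    if n_reads < 1 or n_sweeps < 1:
        raise ValueError("n_reads and n_sweeps must be >= 1")
    n = model.n
    rng = np.random.default_rng(seed)
    betas = _beta_schedule(model, n_sweeps, beta_schedule)
    Q = model.Q
    qd = np.diag(Q).copy()
    S = (rng.random((n_reads, n)) < 0.5).astype(np.float64)
    F = S @ Q                      # field F[r, j] = sum_i S[r, i] Q[i, j]
    E = np.einsum("rj,rj->r", S, F)
    best_e = np.inf
    best_mask = np.zeros(n)
    trace: list[tuple[int, float]] = []
    for step, beta in enumerate(betas):
        U = rng.random((n_reads, n))
        for i in range(n):
            xi = S[:, i]
            dE = (1.0 - 2.0 * xi) * (qd[i] + 2.0 * (F[:, i] - qd[i] * xi))
            acc = (dE <= 0.0) | (U[:, i] < np.exp(-beta * np.maximum(dE, 0.0)))
            if acc.any():
                delta = 1.0 - 2.0 * S[acc, i]
                S[acc, i] += delta
                F[acc] += delta[:, None] * Q[i]
                E[acc] += dE[acc]
        r = int(np.argmin(E))
        if E[r] < best_e - 1e-15:
            best_e = float(E[r])
            best_mask = S[r].copy()
        if record_trace:
            trace.append((step, best_e + model.offset))
    return SolveResult(best_mask=best_mask.astype(np.int8),
                       best_energy=energy(model, best_mask),
                       n_evaluations=n_reads * n_sweeps * n, seed=seed,
                       trace=trace if record_trace else None)


def solve_tabu(model: QuboModel, tenure: int | None = None,
               max_iters: int | None = None, restarts: int = 10,
               seed: int = 0, record_trace: bool = False) -> SolveResult:
    """Iterated tabu search with a single-flip neighborhood.

    Each iteration flips the best admissible bit (not tabu, or passing the
    aspiration test of improving the incumbent); after ``max_iters``
    iterations the search restarts from the incumbent perturbed by random
    flips.  Ties break toward the lowest feature index.
    """
    n = model.n
    if tenure is None:
        tenure = max(1, min(20, n // 4))
    if tenure < 1:
        raise ValueError("tenure must be >= 1")
    if max_iters is None:
        max_iters = 10 * n
    rng = np.random.default_rng(seed)
    Q = model.Q
    qd = np.diag(Q).copy()
    best_mask = (rng.random(n) < 0.5).astype(np.float64)
    best_e = float(best_mask @ Q @ best_mask)
    n_eval = 0
    trace: list[tuple[int, float]] = []
    x = best_mask.copy()
    for restart in range(restarts):
        if restart > 0:
            x = best_mask.copy()
            n_pert = max(1, n // 5)
            flip = rng.choice(n, size=n_pert, replace=False)
            x[flip] = 1.0 - x[flip]
        g = Q @ x
        e = float(x @ g)
        tabu_until = np.full(n, -1, dtype=np.int64)
        for it in range(max_iters):
            dE = (1.0 - 2.0 * x) * (qd + 2.0 * (g - qd * x))
            n_eval += n
            admissible = (tabu_until < it) | (e + dE < best_e - 1e-15)
            if not admissible.any():
                admissible[:] = True
            dE_adm = np.where(admissible, dE, np.inf)
            i = int(np.argmin(dE_adm))      # first occurrence = lowest index
            delta = 1.0 - 2.0 * x[i]
            x[i] += delta
            g += delta * Q[i]
            e += float(dE[i])
            tabu_until[i] = it + tenure
            if e < best_e - 1e-15:
                best_e = e
                best_mask = x.copy()
            if record_trace:
                trace.append((restart * max_iters + it, best_e + model.offset))
    return SolveResult(best_mask=best_mask.astype(np.int8),
                       best_energy=energy(model, best_mask),
                       n_evaluations=n_eval, seed=seed,
                       trace=trace if record_trace else None)


_SOLVERS = {"sa": solve_sa, "tabu": solve_tabu, "exhaustive": solve_exhaustive}


def _repair_cardinality(base: QuboModel, mask: np.ndarray, k: int) -> np.ndarray:
    """Greedy add/remove to weight k, then steepest-descent swaps at fixed k.

    Removal drops the selected feature with the largest (least favorable)
    marginal contribution; addition inserts the feature lowering the energy
    most.  The final swap pass guarantees no single exchange of a selected
    for an unselected feature can lower the base energy further.
    """
    x = mask.astype(np.float64).copy()
    Q = base.Q
    qd = np.diag(Q)
    while int(x.sum()) > k:
        sel = np.flatnonzero(x == 1.0)
        contrib = np.array([qd[i] + 2.0 * (Q[i] @ x - qd[i]) for i in sel])
        x[sel[int(np.argmax(contrib))]] = 0.0
    while int(x.sum()) < k:
        out = np.flatnonzero(x == 0.0)
        gain = np.array([qd[j] + 2.0 * (Q[j] @ x) for j in out])
        x[out[int(np.argmin(gain))]] = 1.0
    # swap descent at fixed cardinality
    improved = True
    while improved:
        improved = False
        sel = np.flatnonzero(x == 1.0)
        out = np.flatnonzero(x == 0.0)
        if out.size == 0:
            break
        rem = np.array([qd[i] + 2.0 * (Q[i] @ x - qd[i]) for i in sel])
        best = (0.0, None, None)
        for a_pos, a in enumerate(sel):
            x[a] = 0.0
            add = qd[out] + 2.0 * (Q[out] @ x)
            b_pos = int(np.argmin(add))
            d = float(add[b_pos] - rem[a_pos])
            if d < best[0] - 1e-12:
                best = (d, a, out[b_pos])
            x[a] = 1.0
        if best[1] is not None:
            x[best[1]] = 0.0
            x[best[2]] = 1.0
            improved = True
    return x.astype(np.int8)


def select_features(data: ContinuousDataset, k: int, alpha: float = 0.9,
                    B: int = DEFAULT_BINS, solver: str = "sa", seed: int = 0,
                    **solver_kwargs) -> RankedSelection:
    """End-to-end selection of exactly ``k`` features from a regression dataset.

    Pipeline: quantile-bin features and target → importance vector I and
    redundancy matrix R → balanced QUBO(alpha) → cardinality penalty with an
    automatic weight → minimize with the chosen solver → greedy repair if the
    returned weight differs from k → rank the k features by ascending
    marginal contribution in the unpenalized model.
    """
    n = data.n_features
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; choose from {sorted(_SOLVERS)}")
    binned = bin_dataset(data, B)
    I = importance_vector(binned)
    R = redundancy_matrix(binned)
    base = build_qubo(I, R, alpha)
    if solver == "exhaustive":
        result = solve_exhaustive(base, cardinality=k)
    else:
        M = auto_penalty(base, k)
        penalized = add_cardinality_penalty(base, k, M)
        result = _SOLVERS[solver](penalized, seed=seed, **solver_kwargs)
    mask = _repair_cardinality(base, result.best_mask, k)
    sel = np.flatnonzero(mask == 1)
    contribs = np.array([marginal_contribution(base, mask, i) for i in sel])
    order = np.argsort(contribs, kind="stable")
    names = [data.name_of(int(i)) for i in sel[order]] if data.feature_names else None
    return RankedSelection(indices=[int(i) for i in sel[order]],
                           contributions=[float(c) for c in contribs[order]],
                           names=names)
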