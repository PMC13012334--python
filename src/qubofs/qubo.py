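"""Balanced QUBO cost function for feature selection.

The cost of a binary selection vector ``x`` is

    E(x) = -alpha * sum_i I_i x_i + (1 - alpha) * sum_{i,j} R_ij x_i x_j

where ``I`` is the importance vector (feature–target MI), ``R`` the redundancy
matrix (pairwise feature MI, zero diagonal) and ``alpha`` in [0, 1] trades
importance (alpha → 1) against redundancy (alpha → 0).  The double sum runs
over all ordered pairs, which the symmetric canonical matrix reproduces
directly: energies are evaluated as ``xᵀQx + offset`` with

    Q[i,i] = -alpha * I[i]      Q[i,j] = (1 - alpha) * R[i,j]   (i != j).

A cardinality constraint |x| = k is imposed, when wanted, by adding the
penalty ``M (sum_i x_i - k)²`` expanded into the same canonical form.  An
Ising mapping (x = (1+σ)/2) and a coordinate text export are provided for
interoperability with binary-quadratic-model tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

_SYM_TOL = 1e-12


@dataclass
class QuboModel:
    """Symmetric canonical QUBO: energy of a mask x is ``xᵀQx + offset``.

    Off-diagonal couplings are counted twice by the quadratic form; the
    upper-triangular export doubles them accordingly.
    """

    Q: np.ndarray
    alpha: float
    penalty_M: float | None = None
    k: int | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=np.float64)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError("Q must be square")
        if not np.allclose(self.Q, self.Q.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("Q must be symmetric")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass
class IsingModel:
    """Spin form of a QUBO under x = (1+σ)/2: fields ``h``, upper-triangular
    couplings ``J`` and a constant ``offset`` such that the energy of every
    spin configuration equals the QUBO energy of the mapped binary one."""

    h: np.ndarray
    J: np.ndarray
    offset: float = 0.0

    def energy(self, sigma: np.ndarray) -> float:
        s = np.asarray(sigma, dtype=np.float64)
        if not np.all(np.isin(s, (-1.0, 1.0))):
            raise ValueError("sigma entries must be in {-1, +1}")
        return float(self.offset + self.h @ s + s @ self.J @ s)


def build_qubo(I: np.ndarray, R: np.ndarray, alpha: float) -> QuboModel:
    """Assemble the balanced cost matrix from importance ``I`` and redundancy ``R``."""
    I = np.asarray(I, dtype=np.float64).ravel()
    R = np.asarray(R, dtype=np.float64)
    n = I.size
    if R.shape != (n, n):
        raise ValueError(f"R shape {R.shape} does not match importance length {n}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    Q = (1.0 - alpha) * 0.5 * (R + R.T)
    np.fill_diagonal(Q, -alpha * I)
    return QuboModel(Q=Q, alpha=float(alpha))


def auto_penalty(model: QuboModel, k: int) -> float:
    """Penalty weight guaranteeing that minimum-energy solutions satisfy |x| = k.

    Returns ``M = 1 + max_i(|Q_ii| + 2 Σ_{j≠i} |Q_ij|)``, an upper bound on the
    magnitude of any single-flip energy change of the base model: moving one
    flip closer to the constraint then always lowers the penalized energy.
    """
    if model.penalty_M is not None:
        raise ValueError("model already carries a penalty")
    absQ = np.abs(model.Q)
    diag = np.diag(absQ)
    row_off = absQ.sum(axis=1) - diag
    return float(1.0 + np.max(diag + 2.0 * row_off))


def add_cardinality_penalty(model: QuboModel, k: int, M: float) -> QuboModel:
    """Return a new model with ``M (Σx_i − k)²`` folded into Q and the offset."""
    n = model.n
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if M <= 0:
        raise ValueError("M must be positive")
    Q = model.Q.copy()
    Q += M  # off-diagonal cells: each unordered pair gains 2M through xᵀQx
    Q[np.diag_indices(n)] += M * (1.0 - 2.0 * k) - M  # diag previously got +M above
    return replace(model, Q=Q, penalty_M=float(M), k=int(k),
                   offset=model.offset + M * k * k)


def _check_mask(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape != (n,):
        raise ValueError(f"mask length {x.shape} != model size {n}")
    xf = x.astype(np.float64)
    if not np.all((xf == 0.0) | (xf == 1.0)):
        raise ValueError("mask entries must be binary")
    return xf


def energy(model: QuboModel, x: np.ndarray) -> float:
    """Energy ``xᵀQx + offset`` of a binary selection mask."""
    xf = _check_mask(x, model.n)
    return float(xf @ model.Q @ xf + model.offset)


def marginal_contribution(model: QuboModel, x: np.ndarray, i: int) -> float:
    """Energy attributable to selected feature ``i`` within mask ``x``:
    ``energy(x) − energy(x with bit i cleared)``."""
    xf = _check_mask(x, model.n)
    if xf[i] != 1.0:
        raise ValueError(f"feature {i} is not selected in the mask")
    qii = model.Q[i, i]
    return float(qii + 2.0 * (model.Q[i] @ xf - qii))


def to_ising(model: QuboModel) -> IsingModel:
    """Map the QUBO to spin variables via x = (1+σ)/2.

    The returned Hamiltonian uses the binary-quadratic-model sign convention
    ``E(σ) = offset + Σ h_i σ_i + Σ_{i<j} J_ij σ_i σ_j`` and matches the QUBO
    energy configuration-by-configuration.
    """
    Q = model.Q
    h = 0.5 * Q.sum(axis=1)
    J = np.triu(0.5 * (Q + Q.T), k=1) * 0.5  # (1/2) Q_ij per unordered pair
    off = model.offset + 0.25 * Q.sum() + 0.25 * np.trace(Q)
    return IsingModel(h=h, J=J, offset=float(off))


def to_triu_dict(model: QuboModel) -> dict[tuple[int, int], float]:
    """Upper-triangular coefficient dialect: diagonal as-is, couplings doubled,
    so ``f(x) = Σ c_ii x_i + Σ_{i<j} c_ij x_i x_j`` equals ``xᵀQx``."""
    out: dict[tuple[int, int], float] = {}
    n = model.n
    for i in range(n):
        if model.Q[i, i] != 0.0:
            out[(i, i)] = float(model.Q[i, i])
        for j in range(i + 1, n):
            c = 2.0 * model.Q[i, j]
            if c != 0.0:
                out[(i, j)] = float(c)
    return out


def save_qubo(model: QuboModel, path: str | Path) -> None:
    """Write the model as three-column coordinate text (i, j, value; 0-based,
    upper-triangular dialect with doubled couplings)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# qubofs qubo export n={model.n} alpha={model.alpha} "
                 f"offset={model.offset!r}\n")
        for (i, j), v in sorted(to_triu_dict(model).items()):
            fh.write(f"{i} {j} {v!r}\n")


def load_qubo(path: str | Path) -> QuboModel:
    """Read a coordinate text file written by :func:`save_qubo`."""
    path = Path(path)
    header = None
    triples: list[tuple[int, int, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = line
                continue
            i, j, v = line.split()
            triples.append((int(i), int(j), float(v)))
    meta = {}
    if header:
        for tok in header.split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
    n = int(meta.get("n", max((max(i, j) for i, j, _ in triples), default=-1) + 1))
    Q = np.zeros((n, n))
    for i, j, v in triples:
        if i == j:
            Q[i, i] = v
        else:
            Q[i, j] = Q[j, i] = v / 2.0
    return QuboModel(Q=Q, alpha=float(meta.get("alpha", 0.5)),
                     offset=float(meta.get("offset", 0.0)))
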