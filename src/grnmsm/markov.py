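"""Lagtime transition matrix, stationary distribution, spectrum, landscape.

The row-stochastic transition matrix ``T(tau) = expm(tau Q)`` is never formed
densely for large spaces; its action on vectors is evaluated with
Krylov/scaling-squaring matrix-exponential products (``expm_multiply``), and
the dominant spectrum is obtained by Arnoldi iteration on that action.  A
dense path is used below ``dense_cutoff`` states, where it is both faster and
gives the full spectrum.

Implied timescales follow t_i = -tau / ln|lambda_i(tau)|, with the Perron
process (lambda_1 = 1) assigned an infinite timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import LinearOperator, eigs, expm_multiply

from .statespace import Generator, StateSpace

__all__ = [
    "LagTransitionMatrix",
    "SpectralDecomposition",
    "StationaryDistribution",
    "QuasipotentialSurface",
    "transition_matrix",
    "propagate",
    "stationary",
    "spectrum",
    "quasipotential",
]

DENSE_CUTOFF = 3000


class ReducibleChainError(RuntimeError):
    """The reaction graph is not strongly connected."""


@dataclass
class LagTransitionMatrix:
    """T(tau) = expm(tau Q), exposed through its action on vectors.

    ``dot`` applies T to columns (right action, used for committor-style
    quantities and memberships); ``propagate_dist`` advances a probability
    distribution one lagtime, i.e. computes ``T^T p``.
    """

    generator: Generator
    tau: float
    dense_cutoff: int = DENSE_CUTOFF
    _dense: np.ndarray | None = field(default=None, repr=False)
    _Qs: sp.csr_matrix | None = field(default=None, repr=False)
    _QTs: sp.csr_matrix | None = field(default=None, repr=False)
    _traceA: float | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("lagtime tau must be positive")
        self._Qs = (self.generator.Q * self.tau).tocsr()
        self._QTs = self._Qs.T.tocsr()
        self._traceA = self._Qs.diagonal().sum()

    @property
    def n_states(self) -> int:
        return self.generator.size

    @property
    def is_dense(self) -> bool:
        return self.n_states <= self.dense_cutoff

    def dense(self) -> np.ndarray:
        """Materialize T; only allowed for small state spaces."""
        if not self.is_dense:
            raise MemoryError(
                f"refusing to densify T for N={self.n_states} "
                f"(> cutoff {self.dense_cutoff})"
            )
        if self._dense is None:
            self._dense = sla.expm(self.tau * self.generator.Q.toarray())
        return self._dense

    def dot(self, X: np.ndarray) -> np.ndarray:
        """T @ X for a vector or column-stack X."""
        if self.is_dense:
            return self.dense() @ X
        return expm_multiply(self._Qs, X, traceA=self._traceA)

    def propagate_dist(self, p: np.ndarray) -> np.ndarray:
        """One Chapman-Kolmogorov step T^T p; p may be (N,) or (N, m)."""
        if self.is_dense:
            return self.dense().T @ p
        return expm_multiply(self._QTs, p, traceA=self._traceA)


def transition_matrix(generator: Generator, tau: float, **kw) -> LagTransitionMatrix:
    return LagTransitionMatrix(generator=generator, tau=tau, **kw)


def propagate(p0: np.ndarray, T: LagTransitionMatrix, k: int) -> np.ndarray:
    """Probability trajectory p(0), p(tau), ..., p(k tau); rows are times."""
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0, atol=1e-8):
        raise ValueError("p0 must be normalized")
    out = np.empty((k + 1, p0.size))
    out[0] = p0
    p = p0
    for i in range(1, k + 1):
        p = T.propagate_dist(p)
        out[i] = p
    return out


@dataclass(frozen=True)
class StationaryDistribution:
    """Normalized stationary probability over microstates."""

    pi: np.ndarray

    @property
    def D(self) -> sp.dia_matrix:
        return sp.diags(self.pi)

    def total_variation(self, other: np.ndarray) -> float:
        return 0.5 * float(np.abs(self.pi - np.asarray(other)).sum())


def check_ergodic(generator: Generator, *, error: bool = True) -> bool:
    """Verify strong connectivity of the jump graph."""
    Q = generator.Q
    n_comp, labels = connected_components(Q, directed=True, connection="strong")
    if n_comp > 1:
        sizes = np.bincount(labels)
        msg = (f"chain is reducible: {n_comp} strongly connected components "
               f"(sizes {sorted(sizes, reverse=True)[:5]}...)")
        if error:
            raise ReducibleChainError(msg)
        warnings.warn(msg, stacklevel=2)
        return False
    return True


def stationary(source, *, check: bool = True) -> StationaryDistribution:
    """Stationary distribution from the generator null space (Q^T pi = 0).

    Also accepts a :class:`LagTransitionMatrix`, in which case pi is the
    Perron left eigenvector of T(tau); both routes agree for an ergodic
    chain since Q and T share invariant distributions.
    """
    if isinstance(source, LagTransitionMatrix):
        gen = source.generator
    elif isinstance(source, Generator):
        gen = source
    else:
        raise TypeError("stationary() expects a Generator or LagTransitionMatrix")
    if check:
        check_ergodic(gen, error=True)
    N = gen.size
    A = gen.Q.T.tocsc()
    if N <= 1:
        return StationaryDistribution(pi=np.ones(max(N, 1)))
    if N < 50:
        # dense null space for tiny chains
        w, V = sla.eig(A.toarray())
        pi = V[:, int(np.argmin(np.abs(w)))].real
    else:
        # shift-invert Arnoldi around the zero eigenvalue of Q^T
        scale = np.abs(gen.Q.diagonal()).max()
        sigma = -1e-10 * scale
        w, V = eigs(A, k=1, sigma=sigma, which="LM",
                    v0=np.full(N, 1.0 / N), maxiter=5000)
        pi = V[:, 0].real
    pi = np.abs(pi)
    pi /= pi.sum()
    return StationaryDistribution(pi=pi)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Dominant eigen-structure of T(tau).

    ``eigenvalues`` are sorted by descending modulus (complex pairs kept).
    ``psi`` is a real basis of the corresponding right invariant subspace:
    eigenvectors for real eigenvalues, (Re, Im) column pairs for complex
    ones, with the first column normalized to the constant vector 1.  ``M``
    is the small real block matrix satisfying ``T psi = psi M`` exactly, so
    downstream projections of T onto this subspace need no further matrix
    exponentials.
    """

    tau: float
    eigenvalues: np.ndarray  # complex, |.| descending
    psi: np.ndarray  # (N, m) real invariant-subspace basis
    M: np.ndarray  # (m, m) real, T psi = psi M
    left_vectors: np.ndarray | None = None  # optional matched left eigenvectors

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales t_i = -tau/ln|lambda_i| (t_1 = inf)."""
        mod = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            t = -self.tau / np.log(mod)
        t[np.isclose(mod, 1.0, atol=1e-12)] = np.inf
        return t

    def to_table(self) -> list[tuple]:
        t = self.timescales
        return [
            (i + 1, lam.real, lam.imag, abs(lam), t[i])
            for i, lam in enumerate(self.eigenvalues)
        ]


def _real_basis(eigenvalues: np.ndarray, vectors: np.ndarray):
    """Real invariant-subspace basis and block matrix from eigenpairs.

    Complex-conjugate pairs contribute (Re v, Im v) columns and a 2x2
    rotation-scaling block; only one member of each pair is consumed.
    """
    cols, blocks = [], []
    used = np.zeros(len(eigenvalues), dtype=bool)
    order = []
    for i, lam in enumerate(eigenvalues):
        if used[i]:
            continue
        v = vectors[:, i]
        if abs(lam.imag) < 1e-12 * max(1.0, abs(lam.real)):
            # realign a numerically complex vector for a real eigenvalue
            w = v.real if np.linalg.norm(v.real) >= np.linalg.norm(v.imag) else v.imag
            cols.append(w)
            blocks.append(np.array([[lam.real]]))
            used[i] = True
            order.append(lam)
        else:
            j = None
            for cand in range(i + 1, len(eigenvalues)):
                if not used[cand] and np.isclose(eigenvalues[cand], lam.conjugate(), rtol=1e-8, atol=1e-12):
                    j = cand
                    break
            a, b = lam.real, lam.imag
            cols.append(v.real)
            cols.append(v.imag)
            blocks.append(np.array([[a, b], [-b, a]]))
            used[i] = True
            order += [lam, lam.conjugate()]
            if j is not None:
                used[j] = True
            else:
                warnings.warn(
                    "complex eigenvalue at the subspace boundary lacks its "
                    "conjugate partner; basis extended by its pair",
                    stacklevel=2,
                )
    psi = np.column_stack(cols)
    M = sla.block_diag(*blocks)
    return np.array(order), psi, M


def spectrum(
    T: LagTransitionMatrix,
    m: int,
    *,
    compute_left: bool = False,
    tol: float = 0.0,
) -> SpectralDecomposition:
    """Leading ``m`` eigenvalues/eigenvectors of T(tau), modulus-sorted.

    Dense solve below the cutoff, otherwise Arnoldi on the exponential
    action with a deterministic start vector.
    """
    N = T.n_states
    if m > N:
        raise ValueError(f"m={m} exceeds the state count N={N}")
    if not T.is_dense and m >= N - 1:
        raise ValueError(f"m={m} must be well below N={N} for the "
                         "matrix-free eigensolver")
    if T.is_dense and N <= 400:
        Td = T.dense()
        lam, V = sla.eig(Td)
        lamL, W = None, None
        if compute_left:
            lamL, W = sla.eig(Td.T)
    elif T.is_dense:
        # dense T available but full eig is wasteful for m << N
        Td = T.dense()
        v0 = np.full(N, 1.0 / N)
        k = min(m + 4, N - 2)
        lam, V = eigs(Td, k=k, which="LM", v0=v0, tol=tol)
        lamL, W = None, None
        if compute_left:
            lamL, W = eigs(Td.T, k=k, which="LM", v0=v0, tol=tol)
    else:
        op = LinearOperator((N, N), matvec=lambda v: T.dot(v), dtype=float)
        v0 = np.full(N, 1.0 / N)
        k = min(m + 4, N - 2)
        try:
            lam, V = eigs(op, k=k, which="LM", v0=v0, tol=tol,
                          maxiter=N * 20)
        except Exception as err:  # pragma: no cover - solver failure path
            raise RuntimeError(
                "Arnoldi iteration failed to converge; retry with a larger "
                "Krylov subspace (ncv), looser tol, or a longer lagtime"
            ) from err
        if compute_left:
            opT = LinearOperator((N, N), matvec=lambda v: T.propagate_dist(v),
                                 dtype=float)
            lamL, W = eigs(opT, k=k, which="LM", v0=v0, tol=tol, maxiter=N * 20)
    idx = np.argsort(-np.abs(lam), kind="stable")
    mm = m
    # never cut a complex-conjugate pair at the subspace boundary
    if mm < len(idx) and abs(lam[idx[mm - 1]].imag) > 1e-12 and np.isclose(
        lam[idx[mm]], lam[idx[mm - 1]].conjugate(), rtol=1e-8, atol=1e-12
    ):
        mm += 1
    idx = idx[:mm]
    lam, V = lam[idx], V[:, idx]
    lam, psi, M = _real_basis(lam, V)
    # Perron right eigenvector of a row-stochastic matrix is constant
    if np.isclose(abs(lam[0]), 1.0, atol=1e-6):
        psi[:, 0] = 1.0
        M[0, :] = 0.0
        M[:, 0] = 0.0
        M[0, 0] = 1.0
    left = None
    if compute_left and lamL is not None:
        idxL = np.argsort(-np.abs(lamL), kind="stable")[:m]
        W = W[:, idxL]
        # sign convention: largest-magnitude entry positive
        left = np.empty((N, m))
        for j in range(m):
            w = W[:, j]
            w = w.real if np.linalg.norm(w.real) >= np.linalg.norm(w.imag) else w.imag
            w = w / (np.linalg.norm(w) or 1.0)
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            left[:, j] = w
    return SpectralDecomposition(tau=T.tau, eigenvalues=lam, psi=psi, M=M,
                                 left_vectors=left)


@dataclass(frozen=True)
class QuasipotentialSurface:
    """Boltzmann-style landscape U = -ln(pi)."""

    U: np.ndarray  # per microstate; +inf where pi == 0
    U_proj: np.ndarray | None = None  # optional copy-number projection
    pi_proj: np.ndarray | None = None

    @property
    def argmin(self) -> int:
        return int(np.argmin(self.U))


def quasipotential(
    pi: np.ndarray | StationaryDistribution,
    space: StateSpace | None = None,
) -> QuasipotentialSurface:
    """U(x) = -ln pi(x), optionally with a 2-D copy-number projection.

    Zero-probability microstates map to +inf.  When ``space`` is given the
    stationary density is also marginalized over the promoter axes onto the
    protein copy-number grid.
    """
    p = pi.pi if isinstance(pi, StationaryDistribution) else np.asarray(pi, float)
    with np.errstate(divide="ignore"):
        U = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.inf)
    U_proj = pi_proj = None
    if space is not None:
        pi_proj = space.marginal_grid(p)
        with np.errstate(divide="ignore"):
            U_proj = np.where(pi_proj > 0, -np.log(np.where(pi_proj > 0, pi_proj, 1.0)), np.inf)
    return QuasipotentialSurface(U=U, U_proj=U_proj, pi_proj=pi_proj)


def count_local_minima(grid: np.ndarray, *, strict_margin: float = 0.0) -> int:
    """Local minima of a 2-D surface over 3x3 neighborhoods (inf-safe)."""
    g = np.asarray(grid, dtype=float)
    padded = np.pad(g, 1, mode="constant", constant_values=np.inf)
    count = 0
    rows, cols = g.shape
    for i in range(rows):
        for j in range(cols):
            v = g[i, j]
            if not np.isfinite(v):
                continue
            nb = padded[i:i + 3, j:j + 3].copy()
            nb[1, 1] = np.inf
            if v + strict_margin < nb.min():
                count += 1
    return count
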