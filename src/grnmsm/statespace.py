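"""Truncated CME state-space enumeration and sparse rate-matrix assembly.

Microstates are the tuples ``(n_1..n_S, axis_1..axis_P)`` with protein copy
numbers capped at ``n_max`` per species (inclusive).  Enumeration is
lexicographic with promoter axes outermost, then the protein counts in species
order, so e.g. the MISA space with ``n_max = 30`` enumerates
4 x 4 x 31 x 31 = 15,376 microstates deterministically.

The generator ``Q`` follows the standard row-as-source convention:
``Q[i, j]`` (i != j) is the rate of the microstate-i -> microstate-j jump and
diagonals make rows sum to zero, so the master equation reads
``dp/dt = Q^T p`` and ``T(tau) = expm(tau Q)`` is row-stochastic.
Production events that would exceed the cap are dropped (reflecting
truncation); :func:`truncation_error` quantifies the resulting bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .models import ReactionNetwork, Reaction

__all__ = ["StateSpace", "Generator", "enumerate_states", "build_generator",
           "truncation_error", "SizeLimitError"]


class SizeLimitError(RuntimeError):
    """The requested enumeration exceeds the configured size guard."""


@dataclass(frozen=True)
class StateSpace:
    """Enumerated, truncated microstate space for a reaction network."""

    network: ReactionNetwork
    n_max: tuple[int, ...]  # per-protein copy-number cap (inclusive)
    counts: np.ndarray  # (N, S) int
    axis_states: np.ndarray  # (N, P) int

    @property
    def size(self) -> int:
        return self.counts.shape[0]

    @property
    def dims(self) -> tuple[int, ...]:
        """Mixed-radix dimensions, outermost first: axes then counts."""
        return self.network.axis_sizes + tuple(m + 1 for m in self.n_max)

    def index_of(self, state) -> int:
        """Integer index of a flat microstate (counts..., axes...)."""
        S = self.network.n_species
        coords = tuple(state[S:]) + tuple(state[:S])
        return int(np.ravel_multi_index(coords, self.dims))

    def state_of(self, index: int) -> tuple[int, ...]:
        coords = np.unravel_index(index, self.dims)
        P = self.network.n_axes
        return tuple(int(c) for c in coords[P:]) + tuple(int(c) for c in coords[:P])

    def indices_of(self, counts: np.ndarray, axis_states: np.ndarray) -> np.ndarray:
        coords = tuple(axis_states.T) + tuple(counts.T)
        return np.ravel_multi_index(coords, self.dims)

    def marginal_grid(self, weights: np.ndarray) -> np.ndarray:
        """Sum a microstate vector over promoter axes onto the copy-number grid."""
        S = self.network.n_species
        shape = tuple(m + 1 for m in self.n_max)
        grid = np.zeros(shape)
        np.add.at(grid, tuple(self.counts.T), weights)
        return grid

    def to_table(self) -> list[tuple]:
        """(index, n_1.., labels..) rows for TSV export."""
        rows = []
        for i in range(self.size):
            labels = self.network.axis_labels(self.axis_states[i])
            rows.append((i, *map(int, self.counts[i]), *labels))
        return rows


def enumerate_states(
    network: ReactionNetwork,
    n_max: int | tuple[int, ...],
    *,
    size_limit: int = 500_000,
) -> StateSpace:
    """Enumerate all microstates with copy numbers in [0, n_max].

    ``n_max`` should be at least ceil(g1/k); a warning is emitted otherwise
    since the cap would then cut into the bulk of the stationary density.
    """
    S = network.n_species
    if np.isscalar(n_max):
        n_max = (int(n_max),) * S
    n_max = tuple(int(m) for m in n_max)
    if len(n_max) != S:
        raise ValueError(f"n_max must be scalar or length {S}")
    rec = math.ceil(network.params.g1 / network.params.k)
    if n_max and min(n_max) < rec:
        warnings.warn(
            f"n_max={n_max} is below g1/k={rec}; truncation will clip the "
            "stationary distribution", stacklevel=2,
        )
    dims = network.axis_sizes + tuple(m + 1 for m in n_max)
    N = int(np.prod(dims))
    if N > size_limit:
        raise SizeLimitError(
            f"state space has {N} microstates (> limit {size_limit}); "
            "reduce n_max or raise size_limit"
        )
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    flat = [g.ravel() for g in grids]
    P = network.n_axes
    axis_states = (np.stack(flat[:P], axis=1).astype(np.int64)
                   if P else np.zeros((N, 0), dtype=np.int64))
    counts = (np.stack(flat[P:], axis=1).astype(np.int64)
              if S else np.zeros((N, 0), dtype=np.int64))
    return StateSpace(network=network, n_max=n_max, counts=counts, axis_states=axis_states)


@dataclass(frozen=True)
class Generator:
    """Sparse CME rate matrix Q (rows = source states, row sums = 0)."""

    space: StateSpace
    Q: sp.csr_matrix
    leak_rates: np.ndarray  # per-state rate of dropped (out-of-box) events

    @property
    def size(self) -> int:
        return self.Q.shape[0]

    def with_sink(self) -> sp.csr_matrix:
        """FSP variant: (N+1) x (N+1) generator with an absorbing sink that
        collects all flux the reflecting truncation drops."""
        N = self.size
        Q = self.Q.tocoo()
        rows = np.concatenate([Q.row, np.arange(N)])
        cols = np.concatenate([Q.col, np.full(N, N)])
        data = np.concatenate([Q.data, self.leak_rates])
        # restore row sums to zero including the sink channel
        diag_fix = np.concatenate([-self.leak_rates, np.zeros(1)])
        A = sp.coo_matrix((data, (rows, cols)), shape=(N + 1, N + 1)).tocsr()
        A += sp.diags(diag_fix)
        return A


def _reaction_terms(space: StateSpace, rx: Reaction):
    """Vectorized (source_idx, dest_idx, propensity, leak) for one reaction."""
    net = space.network
    counts, axes = space.counts, space.axis_states
    prop = np.full(space.size, rx.rate)
    if rx.order >= 1:
        n = counts[:, rx.species].astype(float)
        prop = prop * (n if rx.order == 1 else
                       n * (n - 1) * (1.0 if rx.ordered_pairs else 0.5))
    if rx.axis >= 0 and rx.enabled_states:
        mask = np.isin(axes[:, rx.axis], rx.enabled_states)
        prop = np.where(mask, prop, 0.0)
    src = prop > 0
    if not np.any(src):
        z = np.zeros(0)
        return z.astype(int), z.astype(int), z, np.zeros(space.size)
    new_counts = counts[src] + np.asarray(rx.delta, dtype=np.int64)
    new_axes = axes[src].copy()
    if rx.axis >= 0 and rx.axis_to >= 0:
        new_axes[:, rx.axis] = rx.axis_to
    caps = np.asarray(space.n_max)
    inside = np.all((new_counts >= 0) & (new_counts <= caps), axis=1)
    below = np.any(new_counts < 0, axis=1)
    if np.any(below):
        # enabled reaction driving a count negative breaks the model invariants
        raise ValueError(f"reaction {rx.name!r} yields a negative copy number")
    src_idx = np.flatnonzero(src)
    leak = np.zeros(space.size)
    leak[src_idx[~inside]] = prop[src][~inside]
    dest_idx = space.indices_of(new_counts[inside], new_axes[inside])
    return src_idx[inside], dest_idx, prop[src][inside], leak


def build_generator(space: StateSpace) -> Generator:
    """Assemble the sparse generator from the network's reaction propensities.

    Jumps whose destination lies outside the truncation are dropped
    (reflecting boundary) and their total rate per state is retained in
    ``leak_rates`` for the FSP-style error estimate.
    """
    rows, cols, data = [], [], []
    leak = np.zeros(space.size)
    for rx in space.network.reactions:
        r, c, p, lk = _reaction_terms(space, rx)
        rows.append(r)
        cols.append(c)
        data.append(p)
        leak += lk
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    keep = rows != cols  # self-loops (no-op transitions) do not enter Q
    Q = sp.coo_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(space.size,) * 2
    ).tocsr()
    Q = Q + sp.diags(-np.asarray(Q.sum(axis=1)).ravel())
    return Generator(space=space, Q=Q.tocsr(), leak_rates=leak)


def truncation_error(
    network: ReactionNetwork,
    n_max: int | tuple[int, ...],
    reference_factor: float = 2.0,
    *,
    mode: str = "stationary",
    p0: np.ndarray | None = None,
    horizon: float | None = None,
    size_limit: int = 500_000,
) -> float:
    """Probability mass lost to the copy-number truncation.

    ``mode="stationary"`` computes the stationary distribution on a box
    enlarged by ``reference_factor`` and returns the mass outside the
    original box.  ``mode="fsp"`` augments the original generator with an
    absorbing sink and returns the sink mass accumulated from ``p0`` by time
    ``horizon`` (an upper-bound style transient estimate).
    """
    from . import markov  # local import to avoid a cycle

    S = network.n_species
    if np.isscalar(n_max):
        n_max = (int(n_max),) * S
    if mode == "stationary":
        if reference_factor <= 1:
            raise ValueError("reference_factor must exceed 1")
        big = tuple(int(math.ceil(m * reference_factor)) for m in n_max)
        space_big = enumerate_states(network, big, size_limit=size_limit)
        gen_big = build_generator(space_big)
        pi = markov.stationary(gen_big).pi
        outside = np.any(space_big.counts > np.asarray(n_max), axis=1)
        return float(pi[outside].sum())
    if mode == "fsp":
        if horizon is None or horizon <= 0:
            raise ValueError("fsp mode requires a positive horizon")
        space = enumerate_states(network, n_max, size_limit=size_limit)
        gen = build_generator(space)
        A = gen.with_sink()
        if p0 is None:
            pi = markov.stationary(gen).pi
            p0 = pi
        p = np.concatenate([np.asarray(p0, dtype=float), [0.0]])
        from scipy.sparse.linalg import expm_multiply

        pt = expm_multiply(A.T * horizon, p)
        return float(pt[-1])
    raise ValueError(f"unknown mode {mode!r}")
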