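"""Transition path theory on the coarse-grained MSM.

Committors are solved as linear boundary-value problems on the C-state
transition matrix; the backward committor uses the time-reversed chain
built from the coarse stationary distribution.  The reactive flux

    f_ij = pi~_i q-_i T~_ij q+_j   (i != j)

is antisymmetrized to the net flux F+_ij = max(f_ij - f_ji, 0), and the path
ensemble is decomposed by repeatedly removing the strongest (max-bottleneck)
source->target path, following the pathway-decomposition strategy used for
protein-folding MSMs.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .pcca import MarkovStateModel

__all__ = [
    "CommittorPair",
    "TransitionPath",
    "TransitionPathEnsemble",
    "committors",
    "net_flux",
    "decompose_paths",
    "forward_backward_paths",
]


@dataclass(frozen=True)
class CommittorPair:
    """Forward and backward committors over macrostates."""

    q_plus: np.ndarray  # P(hit target before source)
    q_minus: np.ndarray  # P(came from source rather than target)
    source: tuple[int, ...]
    target: tuple[int, ...]


@dataclass(frozen=True)
class TransitionPath:
    nodes: tuple[int, ...]
    flux: float
    relative_probability: float


@dataclass(frozen=True)
class TransitionPathEnsemble:
    committor: CommittorPair
    flux: np.ndarray  # gross reactive flux f_ij
    net_flux: np.ndarray  # F+_ij
    total_flux: float
    paths: tuple[TransitionPath, ...] = ()

    def path_table(self) -> list[tuple]:
        """(rank, node sequence, flux, relative %) rows."""
        return [
            (r + 1, "->".join(map(str, p.nodes)), p.flux, 100 * p.relative_probability)
            for r, p in enumerate(self.paths)
        ]


def _solve_committor(T: np.ndarray, source: np.ndarray, target: np.ndarray) -> np.ndarray:
    C = T.shape[0]
    q = np.zeros(C)
    q[target] = 1.0
    inter = np.flatnonzero(~(source | target))
    if inter.size:
        A = np.eye(inter.size) - T[np.ix_(inter, inter)]
        b = T[np.ix_(inter, np.flatnonzero(target))].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                "singular committor system (absorbing intermediate state?)"
            ) from err
    return q


def _as_mask(idx, C) -> np.ndarray:
    mask = np.zeros(C, dtype=bool)
    mask[np.atleast_1d(np.asarray(idx, dtype=int))] = True
    return mask


def committors(msm: MarkovStateModel, source, target) -> CommittorPair:
    """Forward/backward committors between two disjoint macrostate sets."""
    C = msm.n_macrostates
    A = _as_mask(source, C)
    B = _as_mask(target, C)
    if not A.any() or not B.any():
        raise ValueError("source and target must be non-empty")
    if (A & B).any():
        raise ValueError("source and target must be disjoint")
    q_plus = _solve_committor(msm.T_c, A, B)
    # time-reversed chain: R_ij = pi_j T_ji / pi_i
    R = (msm.T_c.T * msm.pi_c[None, :]) / msm.pi_c[:, None]
    q_minus = _solve_committor(R, B, A)  # reach source "backwards" before target
    return CommittorPair(
        q_plus=q_plus,
        q_minus=q_minus,
        source=tuple(np.flatnonzero(A)),
        target=tuple(np.flatnonzero(B)),
    )


def net_flux(msm: MarkovStateModel, source, target) -> TransitionPathEnsemble:
    """Reactive flux field and net (positive) flux between two sets."""
    q = committors(msm, source, target)
    f = (msm.pi_c * q.q_minus)[:, None] * msm.T_c * q.q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    F = np.clip(f - f.T, 0.0, None)
    src = list(q.source)
    total = float(F[src, :].sum())
    return TransitionPathEnsemble(committor=q, flux=f, net_flux=F, total_flux=total)


def _widest_path(F: np.ndarray, source, target) -> tuple[tuple[int, ...], float] | None:
    """Max-bottleneck simple path; ties broken by fewer hops then lexicographic."""
    C = F.shape[0]
    best: dict[int, tuple] = {}
    heap = []
    for s in source:
        heapq.heappush(heap, (-np.inf, 0, (s,)))
    target = set(target)
    src_set = set(source)
    while heap:
        neg_w, hops, path = heapq.heappop(heap)
        node = path[-1]
        width = -neg_w
        key = best.get(node)
        if key is not None and key < (neg_w, hops, path):
            continue
        if node in target:
            return path, width
        for nxt in range(C):
            w_edge = F[node, nxt]
            if w_edge <= 0 or nxt in path or (nxt in src_set):
                continue
            new_w = min(width, w_edge)
            cand = (-new_w, hops + 1, path + (nxt,))
            known = best.get(nxt)
            if known is None or cand < known:
                best[nxt] = cand
                heapq.heappush(heap, cand)
    return None


def decompose_paths(
    ensemble: TransitionPathEnsemble,
    tolerance: float = 1e-4,
    max_paths: int = 1000,
) -> TransitionPathEnsemble:
    """Rank transition paths by iterative max-bottleneck removal.

    Each iteration finds the strongest source->target path in the net-flux
    graph, records it with its bottleneck flux, subtracts that flux along
    the path, and repeats until the residual drops below
    ``tolerance * total_flux``.
    """
    if ensemble.total_flux <= 0:
        warnings.warn("no positive source->target flux; empty decomposition",
                      stacklevel=2)
        return ensemble
    F = ensemble.net_flux.copy()
    total = ensemble.total_flux
    src, tgt = ensemble.committor.source, ensemble.committor.target
    paths: list[TransitionPath] = []
    residual = total
    while residual > tolerance * total and len(paths) < max_paths:
        found = _widest_path(F, src, tgt)
        if found is None:
            break
        path, width = found
        if width <= 0:
            break
        for a, b in zip(path[:-1], path[1:]):
            F[a, b] -= width
        residual -= width
        paths.append(TransitionPath(nodes=path, flux=width,
                                    relative_probability=width / total))
    return TransitionPathEnsemble(
        committor=ensemble.committor,
        flux=ensemble.flux,
        net_flux=ensemble.net_flux,
        total_flux=total,
        paths=tuple(paths),
    )


@dataclass(frozen=True)
class ForwardBackwardPaths:
    forward: TransitionPathEnsemble
    backward: TransitionPathEnsemble
    shared_intermediates: tuple[int, ...]
    irreversible: bool

    @property
    def top_forward(self) -> TransitionPath:
        return self.forward.paths[0]

    @property
    def top_backward(self) -> TransitionPath:
        return self.backward.paths[0]


def forward_backward_paths(msm: MarkovStateModel, a, b,
                           tolerance: float = 1e-4) -> ForwardBackwardPaths:
    """Decompose a->b and b->a separately and compare the top paths.

    The chain is irreversible (in the pathway sense) when the most probable
    forward path reversed differs from the most probable backward path.
    """
    fa = decompose_paths(net_flux(msm, a, b), tolerance)
    fb = decompose_paths(net_flux(msm, b, a), tolerance)
    if not fa.paths or not fb.paths:
        raise RuntimeError("no transition paths found in at least one direction")
    top_f = fa.paths[0].nodes
    top_b = fb.paths[0].nodes
    inter_f = set(top_f[1:-1])
    inter_b = set(top_b[1:-1])
    shared = tuple(sorted(inter_f & inter_b))
    irreversible = tuple(reversed(top_b)) != top_f
    return ForwardBackwardPaths(
        forward=fa, backward=fb, shared_intermediates=shared,
        irreversible=irreversible,
    )
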