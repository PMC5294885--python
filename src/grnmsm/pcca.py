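"""Robust Perron Cluster Analysis (PCCA+) and MSM coarse-graining.

PCCA+ searches for a non-singular linear transform B of the dominant right
invariant-subspace basis psi of T(tau) such that chi = psi B is a valid fuzzy
partition (entries in [0, 1], rows summing to one) that maximizes the
metastability of the projected model, trace of

    T~(tau) = D~^{-1} chi^T D T(tau) chi,   D = diag(pi),  D~ = diag(chi^T pi).

Because psi spans an invariant subspace (T psi = psi M for a small real block
matrix M), the objective reduces to a C x C computation and the optimization
never touches the full transition matrix.  For chains without detailed
balance the basis mixes real eigenvectors with (Re, Im) pairs of complex
ones, which keeps chi real and reduces to plain eigenvectors in the
reversible case.

The optimization follows the standard feasible parametrization: the first
row and column of B are determined by the partition-of-unity and positivity
constraints, leaving (C-1)^2 free parameters refined from an inner-simplex
vertex initialization (the C rows of psi spanning the largest simplex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .markov import LagTransitionMatrix, SpectralDecomposition, StationaryDistribution
from .statespace import StateSpace

__all__ = [
    "Membership",
    "CrispPartition",
    "MarkovStateModel",
    "pcca_plus",
    "crispify",
    "coarse_grain",
    "macrostate_summary",
]


class EmptyMacrostateError(RuntimeError):
    """A macrostate received no microstates; choose a smaller C."""


@dataclass(frozen=True)
class Membership:
    """Fuzzy macrostate memberships chi = psi B."""

    chi: np.ndarray  # (N, C), rows sum to 1
    B: np.ndarray  # (C, C) transformation applied to the subspace basis
    spectral: SpectralDecomposition
    metastability: float  # trace of the fuzzy coarse-grained T~

    @property
    def n_macrostates(self) -> int:
        return self.chi.shape[1]


@dataclass(frozen=True)
class CrispPartition:
    """Hard assignment of microstates to macrostates (argmax of chi)."""

    labels: np.ndarray  # (N,) ints in [0, C)
    n_macrostates: int

    def indicator(self) -> np.ndarray:
        chi = np.zeros((self.labels.size, self.n_macrostates))
        chi[np.arange(self.labels.size), self.labels] = 1.0
        return chi

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


@dataclass(frozen=True)
class MarkovStateModel:
    """Coarse-grained MSM: C x C transition matrix and stationary weights."""

    T_c: np.ndarray  # (C, C) row-stochastic
    pi_c: np.ndarray  # (C,)
    tau: float
    chi: np.ndarray  # (N, C) membership used for the projection
    partition: CrispPartition | None = None

    @property
    def n_macrostates(self) -> int:
        return self.T_c.shape[0]

    @property
    def metastability(self) -> float:
        return float(np.trace(self.T_c))

    def stationary_check(self, atol: float = 1e-8) -> float:
        """Residual || pi~^T T~ - pi~^T ||_1."""
        return float(np.abs(self.pi_c @ self.T_c - self.pi_c).sum())


# ---------------------------------------------------------------------------
# PCCA+ internals
# ---------------------------------------------------------------------------

def _index_search(psi: np.ndarray) -> np.ndarray:
    """Inner-simplex vertex search: C rows of psi spanning the largest simplex."""
    N, C = psi.shape
    ortho = psi.copy()
    index = np.zeros(C, dtype=int)
    # first vertex: row with the largest norm
    norms = np.einsum("ij,ij->i", ortho, ortho)
    index[0] = int(np.argmax(norms))
    ortho -= ortho[index[0]]
    for j in range(1, C):
        norms = np.einsum("ij,ij->i", ortho, ortho)
        index[j] = int(np.argmax(norms))
        pivot = ortho[index[j]].copy()
        nrm = np.linalg.norm(pivot)
        if nrm == 0:
            raise RuntimeError("degenerate eigenvector basis in index search")
        pivot /= nrm
        ortho -= np.outer(ortho @ pivot, pivot)
    return index


def _fill_B(free: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Complete B from its free (C-1)^2 block so chi = psi B is feasible.

    Rows 1..C-1 are closed to zero sum; row 0 takes the tightest value
    keeping chi nonnegative; a global rescale restores row sums of one.
    """
    C = free.shape[0] + 1
    B = np.empty((C, C))
    B[1:, 1:] = free
    B[1:, 0] = -free.sum(axis=1)
    # positivity: chi_ij = B[0, j] + (psi[:, 1:] @ B[1:, j]) >= 0
    body = psi[:, 1:] @ B[1:, :]
    B[0, :] = -body.min(axis=0)
    total = B[0, :].sum()
    if total <= 0:
        raise FloatingPointError("infeasible transformation matrix")
    return B / total


def _metastability(B: np.ndarray, WM: np.ndarray, w_pi: np.ndarray) -> float:
    """trace(D~^{-1} B^T (psi^T D T psi) B) with precomputed WM = psi^T D T psi."""
    pi_c = B.T @ w_pi
    if np.any(pi_c <= 0):
        return -np.inf
    return float(np.trace((B.T @ WM @ B) / pi_c[:, None]))


def pcca_plus(
    spectral: SpectralDecomposition,
    pi: np.ndarray | StationaryDistribution,
    C: int,
    *,
    refine: bool = True,
    maxiter: int | None = None,
) -> Membership:
    """Fuzzy metastable memberships from the dominant spectral subspace.

    Parameters
    ----------
    spectral : SpectralDecomposition
        Must carry at least C basis vectors (psi), the first being constant.
    pi : array or StationaryDistribution
        Stationary distribution of the full chain.
    C : int
        Number of macrostates (user-specified, never auto-selected).
    refine : bool
        Run the derivative-free refinement of the vertex initialization.
    """
    if C < 2:
        raise ValueError("C must be at least 2")
    if spectral.psi.shape[1] < C:
        raise ValueError(
            f"spectral decomposition carries {spectral.psi.shape[1]} basis "
            f"vectors; need at least C={C}"
        )
    lam = spectral.eigenvalues
    if len(lam) > C and abs(abs(lam[C - 1]) - abs(lam[C])) < 1e-10:
        warnings.warn(
            f"|lambda_{C}| and |lambda_{C + 1}| are nearly degenerate; the "
            "C-macrostate split is not uniquely determined by a spectral gap",
            stacklevel=2,
        )
    if len(lam) > C - 1 and abs(lam[C - 1].imag) > 1e-12:
        # a complex pair straddling the subspace boundary has no C-dimensional
        # real invariant subspace; fall back to the real part of the pair
        # (approximate basis) rather than refusing a user-specified C
        pair_inside = C >= 2 and np.isclose(lam[C - 2], lam[C - 1].conjugate(),
                                            rtol=1e-8, atol=1e-12)
        if not pair_inside:
            warnings.warn(
                f"eigenvalue {C} is complex and its conjugate partner falls "
                "outside the C-state subspace; using the real part of the "
                "pair (approximate invariant subspace)",
                stacklevel=2,
            )
    p = pi.pi if isinstance(pi, StationaryDistribution) else np.asarray(pi, float)
    psi = spectral.psi[:, :C]
    M = spectral.M[:C, :C]
    # psi^T D T psi = (psi^T D psi) M, exact on the invariant subspace
    W = psi.T @ (p[:, None] * psi)
    WM = W @ M
    w_pi = psi.T @ p

    index = _index_search(psi)
    vertex = psi[index, :]
    try:
        B0 = np.linalg.inv(vertex)
    except np.linalg.LinAlgError:
        raise RuntimeError("inner-simplex vertices are linearly dependent")
    # project the vertex solution into the feasible set
    try:
        B = _fill_B(B0[1:, 1:], psi)
    except FloatingPointError:
        B = B0 / B0.sum()
    best = _metastability(B, WM, w_pi)

    if refine and C > 1:
        x0 = B[1:, 1:].ravel()

        def objective(x):
            try:
                Bx = _fill_B(x.reshape(C - 1, C - 1), psi)
            except FloatingPointError:
                return 1e3
            val = _metastability(Bx, WM, w_pi)
            return -val if np.isfinite(val) else 1e3

        n_free = (C - 1) ** 2
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={
                "maxfev": maxiter or min(200 * n_free, 8000),
                "xatol": 1e-8, "fatol": 1e-8,
            },
        )
        if np.isfinite(res.fun) and -res.fun > best:
            try:
                B_ref = _fill_B(res.x.reshape(C - 1, C - 1), psi)
            except FloatingPointError:
                B_ref = None
            if B_ref is not None:
                # accept the refinement only if it does not empty a macrostate
                # that the vertex solution kept populated
                counts_ref = np.bincount(np.argmax(psi @ B_ref, axis=1), minlength=C)
                counts_0 = np.bincount(np.argmax(psi @ B, axis=1), minlength=C)
                if counts_ref.min() > 0 or counts_0.min() == 0:
                    B = B_ref
                    best = -res.fun

    chi = psi @ B
    chi = np.clip(chi, 0.0, 1.0)
    rows = chi.sum(axis=1, keepdims=True)
    chi /= rows
    return Membership(chi=chi, B=B, spectral=spectral, metastability=best)


def crispify(membership: Membership | np.ndarray) -> CrispPartition:
    """Hard labels by row-argmax of chi (lowest index wins ties)."""
    chi = membership.chi if isinstance(membership, Membership) else np.asarray(membership)
    labels = np.argmax(chi, axis=1)
    C = chi.shape[1]
    counts = np.bincount(labels, minlength=C)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise EmptyMacrostateError(
            f"macrostate(s) {empty} received no microstates; reduce C"
        )
    return CrispPartition(labels=labels, n_macrostates=C)


def coarse_grain(
    T: LagTransitionMatrix,
    pi: np.ndarray | StationaryDistribution,
    chi: Membership | CrispPartition | np.ndarray,
) -> MarkovStateModel:
    """Project T(tau) onto macrostates: T~ = D~^{-1} chi^T D T chi.

    Accepts fuzzy memberships or a crisp partition (indicator chi); the
    coarse stationary distribution is pi~ = chi^T pi.
    """
    p = pi.pi if isinstance(pi, StationaryDistribution) else np.asarray(pi, float)
    partition = None
    if isinstance(chi, Membership):
        partition = crispify(chi)
        X = chi.chi
    elif isinstance(chi, CrispPartition):
        partition = chi
        X = chi.indicator()
    else:
        X = np.asarray(chi, float)
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("chi rows must sum to one")
    pi_c = X.T @ p
    if np.any(pi_c <= 0):
        raise ValueError("zero-probability macrostate in coarse-graining")
    Y = T.dot(X)  # T chi, via the exponential action
    T_c = (X.T @ (p[:, None] * Y)) / pi_c[:, None]
    # clip tiny negative round-off and renormalize rows
    T_c = np.clip(T_c, 0.0, None)
    T_c /= T_c.sum(axis=1, keepdims=True)
    return MarkovStateModel(T_c=T_c, pi_c=pi_c, tau=T.tau, chi=X, partition=partition)


@dataclass(frozen=True)
class MacrostateSummary:
    label: int
    probability: float
    mean_counts: tuple[float, ...]
    dominant_configuration: tuple[str, ...]
    contour_states: np.ndarray  # microstate indices holding 50% of the mass


def macrostate_summary(
    msm: MarkovStateModel,
    space: StateSpace,
    pi: np.ndarray | StationaryDistribution,
    *,
    contour: float = 0.5,
) -> list[MacrostateSummary]:
    """Per-macrostate phenotype summaries.

    Mean copy numbers are pi-weighted over the crisp members; the dominant
    promoter configuration is the one contributing the most stationary
    density; the contour set collects rank-ordered members until the given
    fraction of the macrostate mass is covered.
    """
    if msm.partition is None:
        raise ValueError("macrostate_summary requires a crisp partition")
    p = pi.pi if isinstance(pi, StationaryDistribution) else np.asarray(pi, float)
    out = []
    for j in range(msm.n_macrostates):
        members = msm.partition.members(j)
        w = p[members]
        mass = w.sum()
        mean_counts = tuple((space.counts[members] * w[:, None]).sum(axis=0) / mass)
        # promoter configuration with the largest share of the density
        cfg = space.axis_states[members]
        cfg_idx = np.ravel_multi_index(tuple(cfg.T), space.network.axis_sizes)
        cfg_mass = np.bincount(cfg_idx, weights=w,
                               minlength=int(np.prod(space.network.axis_sizes)))
        dom = np.unravel_index(int(np.argmax(cfg_mass)), space.network.axis_sizes)
        dom_labels = space.network.axis_labels(dom)
        order = members[np.argsort(-w, kind="stable")]
        csum = np.cumsum(p[order])
        n_keep = int(np.searchsorted(csum, contour * mass) + 1)
        out.append(
            MacrostateSummary(
                label=j,
                probability=float(mass),
                mean_counts=tuple(float(x) for x in mean_counts),
                dominant_configuration=dom_labels,
                contour_states=order[:n_keep],
            )
        )
    return out
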