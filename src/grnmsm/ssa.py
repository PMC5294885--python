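"""Exact stochastic simulation (Gillespie direct method) and validation aids.

The direct method draws two uniforms per event: an exponential waiting time
from the total propensity and a categorical reaction choice.  The inner loop
operates on flat reaction tables (rates, orders, promoter gates, state
changes) and is JIT-compiled with numba when available; a pure-Python loop
with identical semantics and random stream is kept as a fallback and for
reference in tests.

Histograms are time-weighted (occupancy), not event-weighted.  Simulations
are not constrained by the copy-number truncation, so the empirical mass
outside the box doubles as an independent truncation-leak estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import ReactionNetwork
from .statespace import StateSpace

__all__ = [
    "Trajectory",
    "simulate",
    "empirical_stationary",
    "macrostate_trace",
    "relaxation_curves",
    "autocorrelation",
    "autocorrelation_relaxation",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class Trajectory:
    """One SSA realization: event times and post-event states."""

    times: np.ndarray  # (E,), strictly increasing event times
    states: np.ndarray  # (E+1, S+P): states[0] = x0, states[i] after times[i-1]
    t_end: float
    seed: int
    exhausted: bool  # True if total propensity hit zero before t_end

    @property
    def n_events(self) -> int:
        return self.times.size

    def state_at(self, t: float) -> np.ndarray:
        """State occupied at time t (piecewise-constant interpolation)."""
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.states[i]

    def states_at(self, grid: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, grid, side="right")
        return self.states[idx]


def _reaction_tables(network: ReactionNetwork):
    """Flatten the reaction list into numba-friendly arrays."""
    S, P = network.n_species, network.n_axes
    R = len(network.reactions)
    max_axis_states = max(a.size for a in network.axes) if P else 1
    rate = np.zeros(R)
    order = np.zeros(R, dtype=np.int64)
    species = np.full(R, -1, dtype=np.int64)
    axis = np.full(R, -1, dtype=np.int64)
    axis_to = np.full(R, -1, dtype=np.int64)
    ordered = np.zeros(R, dtype=np.bool_)
    enabled = np.ones((R, max_axis_states), dtype=np.bool_)
    delta = np.zeros((R, S), dtype=np.int64)
    for r, rx in enumerate(network.reactions):
        rate[r] = rx.rate
        order[r] = rx.order
        species[r] = rx.species
        axis[r] = rx.axis
        axis_to[r] = rx.axis_to
        ordered[r] = rx.ordered_pairs
        if rx.axis >= 0 and rx.enabled_states:
            enabled[r, :] = False
            for s in rx.enabled_states:
                enabled[r, s] = True
        if rx.delta:
            delta[r, :] = rx.delta
    return rate, order, species, axis, axis_to, ordered, enabled, delta


def _ssa_loop(x0, t_end, rate, order, species, axis, axis_to, ordered, enabled,
              delta, S, uniforms, max_events):
    """Direct-method loop; identical in compiled and interpreted form."""
    R = rate.shape[0]
    x = x0.copy()
    t = 0.0
    times = np.empty(max_events)
    states = np.empty((max_events, x0.shape[0]), dtype=np.int64)
    props = np.empty(R)
    n = 0
    exhausted = False
    while n < max_events:
        a0 = 0.0
        for r in range(R):
            a = rate[r]
            ax = axis[r]
            if ax >= 0 and not enabled[r, x[S + ax]]:
                a = 0.0
            elif order[r] == 1:
                a *= x[species[r]]
            elif order[r] == 2:
                c = x[species[r]] * (x[species[r]] - 1)
                a *= c if ordered[r] else 0.5 * c
            props[r] = a
            a0 += a
        if a0 <= 0.0:
            exhausted = True
            break
        u1 = uniforms[2 * n]
        u2 = uniforms[2 * n + 1]
        t += -np.log(u1) / a0
        if t > t_end:
            break
        thresh = u2 * a0
        acc = 0.0
        chosen = R - 1
        for r in range(R):
            acc += props[r]
            if acc >= thresh:
                chosen = r
                break
        for s in range(S):
            x[s] += delta[chosen, s]
        ax = axis[chosen]
        if ax >= 0 and axis_to[chosen] >= 0:
            x[S + ax] = axis_to[chosen]
        times[n] = t
        states[n] = x
        n += 1
    return times[:n], states[:n], exhausted


_ssa_loop_jit = njit(cache=False)(_ssa_loop) if _HAVE_NUMBA else _ssa_loop


def simulate(
    network: ReactionNetwork,
    x0,
    t_end: float,
    seed: int,
    *,
    max_events: int = 20_000_000,
    use_numba: bool = True,
) -> Trajectory:
    """Statistically exact CME sample from initial microstate ``x0``.

    ``x0`` is the flat state (counts..., axis indices...).  The trajectory is
    reproducible given the seed (two uniform draws per event from a PCG64
    stream, regardless of the execution backend).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    S = network.n_species
    x0 = np.asarray(x0, dtype=np.int64)
    if x0.size != S + network.n_axes:
        raise ValueError("x0 has the wrong length for this network")
    if np.any(x0[:S] < 0):
        raise ValueError("negative initial copy number")
    tables = _reaction_tables(network)
    rng = np.random.default_rng(seed)
    loop = _ssa_loop_jit if (use_numba and _HAVE_NUMBA) else _ssa_loop
    # draw uniforms in chunks so short runs stay cheap
    chunk = 1 << 16
    all_times, all_states = [], []
    x = x0.copy()
    t_off = 0.0
    exhausted = False
    remaining = max_events
    while True:
        n_ev = min(chunk, remaining)
        uniforms = rng.random(2 * n_ev)
        times, states, exhausted = loop(
            x, t_end - t_off, *tables, S, uniforms, n_ev
        )
        if times.size:
            all_times.append(times + t_off)
            all_states.append(states)
            x = states[-1].copy()
            t_off = all_times[-1][-1]
        remaining -= n_ev
        if exhausted or times.size < n_ev or remaining <= 0:
            break
    if remaining <= 0 and not exhausted:
        warnings.warn("max_events reached before t_end", stacklevel=2)
    times = np.concatenate(all_times) if all_times else np.empty(0)
    states = (np.vstack([x0[None, :]] + all_states)
              if all_states else x0[None, :].copy())
    return Trajectory(times=times, states=states, t_end=t_end, seed=seed,
                      exhausted=exhausted)


def empirical_stationary(
    trajectories,
    space: StateSpace,
) -> tuple[np.ndarray, float]:
    """Time-weighted occupancy histogram over the truncated state space.

    Returns ``(histogram, outside_mass)``: the normalized occupancy of
    in-box microstates and the fraction of simulated time spent outside the
    truncation (an independent estimate of the truncation leak).
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    hist = np.zeros(space.size)
    outside = 0.0
    total = 0.0
    caps = np.asarray(space.n_max)
    S = space.network.n_species
    for traj in trajectories:
        edges = np.concatenate([[0.0], traj.times, [traj.t_end]])
        dt = np.diff(edges)
        states = traj.states
        inside = np.all((states[:, :S] >= 0) & (states[:, :S] <= caps), axis=1)
        total += dt.sum()
        outside += dt[~inside].sum()
        if np.any(inside):
            idx = space.indices_of(states[inside][:, :S], states[inside][:, S:])
            np.add.at(hist, idx, dt[inside])
    hist /= total
    return hist, outside / total


def macrostate_trace(trajectory: Trajectory, partition, space: StateSpace) -> np.ndarray:
    """Macrostate label after each event (-1 outside the truncation)."""
    labels = partition.labels if hasattr(partition, "labels") else np.asarray(partition)
    S = space.network.n_species
    caps = np.asarray(space.n_max)
    states = trajectory.states
    inside = np.all((states[:, :S] >= 0) & (states[:, :S] <= caps), axis=1)
    out = np.full(states.shape[0], -1, dtype=np.int64)
    if np.any(inside):
        idx = space.indices_of(states[inside][:, :S], states[inside][:, S:])
        out[inside] = labels[idx]
    return out


def relaxation_curves(
    network: ReactionNetwork,
    x0,
    n_runs: int,
    partition,
    space: StateSpace,
    grid: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Ensemble macrostate occupancy versus time from ``n_runs`` SSA runs.

    Returns an array (len(grid), C) of occupancy fractions; runs use seeds
    ``seed, seed+1, ...`` for reproducibility.
    """
    labels = partition.labels if hasattr(partition, "labels") else np.asarray(partition)
    C = int(labels.max()) + 1
    grid = np.asarray(grid, dtype=float)
    occ = np.zeros((grid.size, C))
    S = space.network.n_species
    caps = np.asarray(space.n_max)
    for r in range(n_runs):
        traj = simulate(network, x0, float(grid.max()), seed + r)
        states = traj.states_at(grid)
        inside = np.all((states[:, :S] >= 0) & (states[:, :S] <= caps), axis=1)
        idx = np.full(grid.size, -1, dtype=np.int64)
        if np.any(inside):
            idx[inside] = labels[space.indices_of(states[inside][:, :S],
                                                  states[inside][:, S:])]
        for c in range(C):
            occ[:, c] += idx == c
    return occ / n_runs


def autocorrelation(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Normalized autocorrelation of a regularly sampled series (FFT-based)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f))[: n_lags + 1]
    acf /= np.arange(n, n - n_lags - 1, -1)  # unbiased normalization
    if acf[0] <= 0:
        return np.zeros(n_lags + 1)
    return acf / acf[0]


def _fit_relaxation(lags: np.ndarray, acf: np.ndarray) -> float | None:
    """Relaxation constant from a single-exponential fit to the acf tail."""
    mask = acf > 0.05
    # use the decaying head above the noise floor, excluding lag 0
    mask[0] = False
    if mask.sum() < 3:
        return None
    t = lags[mask]
    y = np.log(acf[mask])
    slope, _ = np.polyfit(t, y, 1)
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def autocorrelation_relaxation(
    source,
    grid: np.ndarray,
    *,
    observable: np.ndarray | None = None,
    partition=None,
    space: StateSpace | None = None,
    initial_macrostate: int | None = None,
):
    """Autocorrelation function and fitted relaxation constant tau_r.

    ``source`` is either a coarse MSM (analytic acf from the spectrum of the
    coarse transition matrix) or a long SSA :class:`Trajectory` (empirical
    acf of the sampled observable).  The default observable is the indicator
    of one macrostate.  Returns ``(lag times, acf, tau_r)``; ``tau_r`` is
    None when the exponential fit fails.
    """
    from .pcca import MarkovStateModel  # local import, avoids cycle

    grid = np.asarray(grid, dtype=float)
    if isinstance(source, MarkovStateModel):
        msm = source
        C = msm.n_macrostates
        g = np.zeros(C)
        g[initial_macrostate if initial_macrostate is not None else 0] = 1.0
        if observable is not None:
            g = np.asarray(observable, dtype=float)
        # stationary autocovariance of g under the coarse chain:
        # C(k tau) = g^T D (T~^k) g - (pi~ g)^2
        mu = float(msm.pi_c @ g)
        var = float(msm.pi_c @ (g * g)) - mu**2
        ks = np.unique(np.round(grid / msm.tau).astype(int))
        ks = ks[ks >= 0]
        acf = np.empty(ks.size)
        v = g.copy()
        k_prev = 0
        for i, k in enumerate(ks):
            for _ in range(k - k_prev):
                v = msm.T_c @ v
            k_prev = k
            acf[i] = (float(msm.pi_c @ (g * v)) - mu**2) / var
        lags = ks * msm.tau
        return lags, acf, _fit_relaxation(lags, acf)
    if isinstance(source, Trajectory):
        dt = grid[1] - grid[0]
        sample_times = np.arange(0.0, source.t_end, dt)
        if observable is not None:
            raise ValueError("for trajectories pass partition/space instead")
        if partition is None or space is None:
            raise ValueError("trajectory acf needs a partition and state space")
        labels = partition.labels if hasattr(partition, "labels") else np.asarray(partition)
        states = source.states_at(sample_times)
        S = space.network.n_species
        caps = np.asarray(space.n_max)
        inside = np.all((states[:, :S] >= 0) & (states[:, :S] <= caps), axis=1)
        lab = np.full(sample_times.size, -1, dtype=np.int64)
        if np.any(inside):
            lab[inside] = labels[space.indices_of(states[inside][:, :S],
                                                  states[inside][:, S:])]
        ref = initial_macrostate if initial_macrostate is not None else lab[0]
        x = (lab == ref).astype(float)
        n_lags = min(grid.size, x.size - 2)
        acf = autocorrelation(x, n_lags)
        lags = np.arange(n_lags + 1) * dt
        return lags, acf, _fit_relaxation(lags, acf)
    raise TypeError("source must be a MarkovStateModel or Trajectory")
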