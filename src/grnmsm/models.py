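"""Gene-regulatory-network motifs as stochastic mass-action reaction systems.

Each motif is expressed as a :class:`ReactionNetwork`: a list of protein
species, one or more promoter "axes" (the discrete binding configuration of
each gene's promoter), and elementary reactions with mass-action propensities.
Transcription factors act as homodimers unless a monomer variant is selected;
dimerization is treated as simultaneous with DNA binding, so no explicit dimer
species is carried.

Built-in motifs
---------------
``misa``
    Mutual Inhibition / Self-Activation: two genes A and B; each protein
    dimer activates its own promoter and represses the other gene's promoter.
    Each promoter has four configurations ``00, 10, 01, 11`` (activator bound
    flag, repressor bound flag), giving 16 joint configurations.
``ets_dimer`` / ``ets_monomer``
    Exclusive Toggle Switch: two genes share a single promoter that can be
    unbound (``P00``), bound by the a-repressor (``P10``) or by the
    b-repressor (``P01``); binding is mutually exclusive.
``self_regulating``
    A single self-activating gene with a two-state promoter; dimer or monomer
    self-binding is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "RateParameters",
    "PromoterAxis",
    "Reaction",
    "ReactionNetwork",
    "build_motif",
    "propensity",
    "MOTIFS",
    "misa_preset",
    "ets_dimer_preset",
    "ets_monomer_preset",
    "self_regulating_preset",
]


class MissingParameterError(KeyError):
    """A rate parameter required by the requested motif was not supplied."""


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rate constants, in units of the protein degradation rate k.

    Attributes
    ----------
    g0, g1 : float
        Protein production rate when the gene is repressed / fully active.
    k : float
        Protein degradation rate; defines the unit of time (default 1).
    h_a, f_a : float or None
        Activator binding / unbinding rates (MISA, self-regulating gene).
    h_r, f_r : float or None
        Repressor binding / unbinding rates. For the ETS motifs these are the
        only binding rates and may be spelled ``h`` / ``f``.
    """

    g0: float
    g1: float
    k: float = 1.0
    h_a: float | None = None
    f_a: float | None = None
    h_r: float | None = None
    f_r: float | None = None

    def __post_init__(self):
        for name in ("g0", "g1", "k", "h_a", "f_a", "h_r", "f_r"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"rate {name!r} must be >= 0, got {v}")
        if not self.g1 > self.g0:
            raise ValueError(f"g1 ({self.g1}) must exceed g0 ({self.g0})")

    # aliases used by the ETS motifs
    @property
    def h(self) -> float | None:
        return self.h_r

    @property
    def f(self) -> float | None:
        return self.f_r

    @property
    def X_eq(self) -> float | None:
        """Binding equilibrium constant f_r / h_r."""
        if self.f_r is None or self.h_r is None or self.h_r == 0:
            return None
        return self.f_r / self.h_r

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingParameterError(
                f"missing rate parameter(s) {missing} for this motif"
            )

    def with_updates(self, **kw) -> "RateParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class PromoterAxis:
    """One gene's promoter configuration coordinate."""

    name: str
    states: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction channel.

    The propensity on microstate ``x`` is

        rate * c(n_species) * [axis state is in ``enabled_states``]

    where ``c(n) = 1`` (order 0), ``n`` (order 1) or ``n (n-1)`` / ``n (n-1)/2``
    (order 2, ordered / unordered pairs).  Applying the reaction adds
    ``delta`` to the protein copy numbers and, if ``axis_to`` is set, moves
    promoter axis ``axis`` to that configuration.
    """

    name: str
    rate: float
    order: int = 0
    species: int = -1  # protein index entering the propensity (order >= 1)
    axis: int = -1  # promoter axis the reaction is gated on / changes
    enabled_states: tuple[int, ...] = ()  # axis states where enabled; () = all
    axis_to: int = -1  # new axis state, -1 = unchanged
    delta: tuple[int, ...] = ()  # per-protein copy-number change
    ordered_pairs: bool = True  # order-2 combinatorics convention

    def combinatorics(self, n: int) -> float:
        if self.order == 0:
            return 1.0
        if self.order == 1:
            return float(n)
        c = n * (n - 1)
        return float(c if self.ordered_pairs else c // 2)


@dataclass(frozen=True)
class ReactionNetwork:
    """A motif instance: species, promoter axes, reactions, parameters."""

    motif: str
    species: tuple[str, ...]
    axes: tuple[PromoterAxis, ...]
    reactions: tuple[Reaction, ...]
    params: RateParameters
    dimer_ordered: bool = True
    sequester: bool = True

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    @property
    def axis_sizes(self) -> tuple[int, ...]:
        return tuple(a.size for a in self.axes)

    def axis_labels(self, axis_values: Sequence[int]) -> tuple[str, ...]:
        return tuple(a.states[v] for a, v in zip(self.axes, axis_values))


def propensity(network: ReactionNetwork, microstate: Sequence[int], reaction: Reaction) -> float:
    """Mass-action propensity of ``reaction`` on ``microstate``.

    ``microstate`` is the flat vector ``(n_1..n_S, axis_1..axis_P)``.
    """
    S = network.n_species
    counts = microstate[:S]
    axes = microstate[S:]
    if any(n < 0 for n in counts):
        raise ValueError(f"negative copy number in microstate {tuple(microstate)}")
    if reaction.axis >= 0 and reaction.enabled_states:
        if axes[reaction.axis] not in reaction.enabled_states:
            return 0.0
    n = counts[reaction.species] if reaction.order >= 1 else 0
    return reaction.rate * reaction.combinatorics(n)


def _binding_pair(
    name: str,
    axis: int,
    from_states: Sequence[int],
    to_states: Sequence[int],
    species: int,
    h: float,
    f: float,
    n_species: int,
    stoich: int,
    *,
    ordered: bool,
    sequester: bool,
) -> list[Reaction]:
    """Binding/unbinding reaction pairs for each (from, to) promoter flip."""
    d = [0] * n_species
    d_bind = tuple(d)
    d_unbind = tuple(d)
    if sequester:
        db = list(d)
        db[species] = -stoich
        d_bind = tuple(db)
        du = list(d)
        du[species] = +stoich
        d_unbind = tuple(du)
    out = []
    for s_from, s_to in zip(from_states, to_states):
        out.append(
            Reaction(
                name=f"{name}_bind[{s_from}->{s_to}]",
                rate=h,
                order=stoich,
                species=species,
                axis=axis,
                enabled_states=(s_from,),
                axis_to=s_to,
                delta=d_bind,
                ordered_pairs=ordered,
            )
        )
        out.append(
            Reaction(
                name=f"{name}_unbind[{s_to}->{s_from}]",
                rate=f,
                order=0,
                axis=axis,
                enabled_states=(s_to,),
                axis_to=s_from,
                delta=d_unbind,
            )
        )
    return out


def _production(name, rate, species, axis, states, n_species) -> Reaction:
    d = [0] * n_species
    d[species] = +1
    return Reaction(
        name=name,
        rate=rate,
        order=0,
        axis=axis,
        enabled_states=tuple(states),
        delta=tuple(d),
    )


def _degradation(name, k, species, n_species) -> Reaction:
    d = [0] * n_species
    d[species] = -1
    return Reaction(name=name, rate=k, order=1, species=species, delta=tuple(d))


def _build_misa(params: RateParameters, dimer_ordered: bool, sequester: bool) -> ReactionNetwork:
    params.require("g0", "g1", "k", "h_a", "f_a", "h_r", "f_r")
    # per-gene promoter states "ar": a=activator bound flag, r=repressor bound flag
    states = ("00", "10", "01", "11")
    axes = (PromoterAxis("A", states), PromoterAxis("B", states))
    i00, i10, i01, i11 = range(4)
    rx: list[Reaction] = []
    for gene, (axis, act_sp, rep_sp) in {"A": (0, 0, 1), "B": (1, 1, 0)}.items():
        # activator (own protein dimer) binds/unbinds independently of repressor site
        rx += _binding_pair(
            f"{gene}_act", axis, (i00, i01), (i10, i11), act_sp,
            params.h_a, params.f_a, 2, stoich=2,
            ordered=dimer_ordered, sequester=sequester,
        )
        # repressor (other protein dimer)
        rx += _binding_pair(
            f"{gene}_rep", axis, (i00, i10), (i01, i11), rep_sp,
            params.h_r, params.f_r, 2, stoich=2,
            ordered=dimer_ordered, sequester=sequester,
        )
        # production at g1 only in the activator-only configuration "10"
        rx.append(_production(f"prod_{gene.lower()}_hi", params.g1, act_sp if gene == "A" else 1,
                              axis, (i10,), 2))
        rx.append(_production(f"prod_{gene.lower()}_lo", params.g0, act_sp if gene == "A" else 1,
                              axis, (i00, i01, i11), 2))
    rx.append(_degradation("deg_a", params.k, 0, 2))
    rx.append(_degradation("deg_b", params.k, 1, 2))
    return ReactionNetwork(
        motif="misa", species=("a", "b"), axes=axes, reactions=tuple(rx),
        params=params, dimer_ordered=dimer_ordered, sequester=sequester,
    )


def _build_ets(params: RateParameters, stoich: int, dimer_ordered: bool, sequester: bool) -> ReactionNetwork:
    params.require("g0", "g1", "k", "h_r", "f_r")
    axes = (PromoterAxis("P", ("P00", "P10", "P01")),)
    iP00, iP10, iP01 = range(3)
    rx: list[Reaction] = []
    rx += _binding_pair(
        "a", 0, (iP00,), (iP10,), 0, params.h_r, params.f_r, 2, stoich=stoich,
        ordered=dimer_ordered, sequester=sequester,
    )
    rx += _binding_pair(
        "b", 0, (iP00,), (iP01,), 1, params.h_r, params.f_r, 2, stoich=stoich,
        ordered=dimer_ordered, sequester=sequester,
    )
    # a is repressed only when b is bound (P01); symmetric for b
    rx.append(_production("prod_a_hi", params.g1, 0, 0, (iP00, iP10), 2))
    rx.append(_production("prod_a_lo", params.g0, 0, 0, (iP01,), 2))
    rx.append(_production("prod_b_hi", params.g1, 1, 0, (iP00, iP01), 2))
    rx.append(_production("prod_b_lo", params.g0, 1, 0, (iP10,), 2))
    rx.append(_degradation("deg_a", params.k, 0, 2))
    rx.append(_degradation("deg_b", params.k, 1, 2))
    motif = "ets_dimer" if stoich == 2 else "ets_monomer"
    return ReactionNetwork(
        motif=motif, species=("a", "b"), axes=axes, reactions=tuple(rx),
        params=params, dimer_ordered=dimer_ordered, sequester=sequester,
    )


def _build_self_regulating(params: RateParameters, dimer_ordered: bool, sequester: bool,
                           stoich: int = 2) -> ReactionNetwork:
    params.require("g0", "g1", "k", "h_a", "f_a")
    axes = (PromoterAxis("G", ("U", "B")),)
    rx: list[Reaction] = []
    rx += _binding_pair(
        "self", 0, (0,), (1,), 0, params.h_a, params.f_a, 1, stoich=stoich,
        ordered=dimer_ordered, sequester=sequester,
    )
    # self-activation: high production while bound
    rx.append(_production("prod_hi", params.g1, 0, 0, (1,), 1))
    rx.append(_production("prod_lo", params.g0, 0, 0, (0,), 1))
    rx.append(_degradation("deg", params.k, 0, 1))
    return ReactionNetwork(
        motif="self_regulating", species=("a",), axes=axes, reactions=tuple(rx),
        params=params, dimer_ordered=dimer_ordered, sequester=sequester,
    )


MOTIFS = {
    "misa": _build_misa,
    "ets_dimer": lambda p, o, s: _build_ets(p, 2, o, s),
    "ets_monomer": lambda p, o, s: _build_ets(p, 1, o, s),
    "self_regulating": _build_self_regulating,
}


def build_motif(
    motif_id: str,
    params: RateParameters,
    *,
    dimer_ordered: bool = True,
    sequester: bool = True,
) -> ReactionNetwork:
    """Assemble the full reaction list for a built-in motif.

    Parameters
    ----------
    motif_id : str
        One of ``misa``, ``ets_dimer``, ``ets_monomer``, ``self_regulating``.
    params : RateParameters
        Complete rate set for the motif (a named error is raised otherwise).
    dimer_ordered : bool
        Dimer-binding combinatorics convention: ``h n (n-1)`` ordered pairs
        (default) vs ``h n (n-1) / 2``.
    sequester : bool
        Whether DNA binding removes the bound copies from the free pool
        (dimer: 2 copies, monomer: 1) and unbinding returns them.
    """
    try:
        builder = MOTIFS[motif_id]
    except KeyError:
        raise ValueError(f"unknown motif {motif_id!r}; known: {sorted(MOTIFS)}") from None
    return builder(params, dimer_ordered, sequester)


# ---------------------------------------------------------------------------
# Parameter presets.  The degradation rate k = 1 defines the time unit; the
# binding equilibrium X_eq = f/h = 100 is held fixed when binding kinetics is
# varied.  Production rates are chosen so that the default copy-number
# truncation (30 for MISA) comfortably exceeds g1/k with a stationary leak
# around 1e-5.  See docs/methods.md for the full rationale.
# ---------------------------------------------------------------------------

def misa_preset(f_r: float = 1e-2, *, slow: bool = False, **overrides) -> RateParameters:
    """MISA rate set.

    The baseline regime keeps self-activation near-adiabatic (f_a = 1) while
    repressor exchange is slow (f_r default 1e-2), which yields four
    metastable macrostates.  ``slow=True`` selects the deeply non-adiabatic
    regime (f_r = 1e-4, h_r = 1e-6, with activator kinetics 100x faster than
    repressor kinetics) in which all 16 promoter configurations become
    metastable.
    """
    if slow:
        base = dict(g0=2.0, g1=14.0, k=1.0, h_a=1e-3, f_a=1e-2, h_r=1e-6, f_r=1e-4)
    else:
        base = dict(g0=2.0, g1=14.0, k=1.0, h_a=1e-1, f_a=1.0, h_r=1e-4, f_r=f_r)
    base.update(overrides)
    return RateParameters(**base)


def ets_dimer_preset(f: float = 1e-2, *, X_eq: float = 100.0, **overrides) -> RateParameters:
    """Dimeric exclusive toggle switch; f swept at constant X_eq = f/h."""
    base = dict(g0=1.0, g1=20.0, k=1.0, h_r=f / X_eq, f_r=f)
    base.update(overrides)
    return RateParameters(**base)


def ets_monomer_preset(**overrides) -> RateParameters:
    """Monomeric exclusive toggle switch in the small-number regime."""
    base = dict(g0=2.0, g1=30.0, k=1.0, h_r=1e-4, f_r=1e-2)
    base.update(overrides)
    return RateParameters(**base)


def self_regulating_preset(**overrides) -> RateParameters:
    base = dict(g0=2.0, g1=12.0, k=1.0, h_a=1e-4, f_a=1e-2)
    base.update(overrides)
    return RateParameters(**base)
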