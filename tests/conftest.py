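"""Shared fixtures: tiny analytic models and the full-size motif pipelines.

The expensive motif pipelines (MISA at N = 15,376, the slow-binding variant,
and the dimeric toggle sweep) are session-scoped and built lazily so the
cheap unit tests never pay for them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import grnmsm as g
from grnmsm.models import PromoterAxis, RateParameters, Reaction, ReactionNetwork


def make_flip_network(h: float, f: float) -> ReactionNetwork:
    """Pure two-state promoter flip (no proteins): Q = [[-h, h], [f, -f]]."""
    axis = PromoterAxis("G", ("U", "B"))
    rx = (
        Reaction(name="bind", rate=h, axis=0, enabled_states=(0,), axis_to=1, delta=()),
        Reaction(name="unbind", rate=f, axis=0, enabled_states=(1,), axis_to=0, delta=()),
    )
    params = RateParameters(g0=0.0, g1=1.0)
    return ReactionNetwork(motif="custom", species=(), axes=(axis,),
                           reactions=rx, params=params)


def make_birth_death(gr: float, k: float) -> ReactionNetwork:
    """Single-species birth-death chain (production gr, degradation k n)."""
    rx = (
        Reaction(name="birth", rate=gr, delta=(1,)),
        Reaction(name="death", rate=k, order=1, species=0, delta=(-1,)),
    )
    params = RateParameters(g0=0.0, g1=gr if gr > 0 else 1.0, k=k)
    return ReactionNetwork(motif="custom", species=("x",), axes=(),
                           reactions=rx, params=params)


class DenseLag:
    """Duck-typed stand-in for LagTransitionMatrix around an explicit
    row-stochastic matrix; used for matrix-level oracles."""

    def __init__(self, T: np.ndarray, tau: float = 1.0):
        self.T = np.asarray(T, dtype=float)
        self.tau = tau

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def dot(self, X):
        return self.T @ X

    def propagate_dist(self, p):
        return self.T.T @ p


def lumpable_chain():
    """4-state chain exactly lumpable into blocks {0,1} and {2,3}.

    Rows within a block have equal total probability into each block, which
    is the classical strong-lumpability condition.
    """
    T = np.array([
        [0.60, 0.30, 0.06, 0.04],
        [0.45, 0.45, 0.04, 0.06],
        [0.05, 0.15, 0.50, 0.30],
        [0.10, 0.10, 0.40, 0.40],
    ])
    assert np.allclose(T.sum(axis=1), 1.0)
    # block membership indicator
    chi = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    # lumped 2x2 matrix (identical for any in-block weighting)
    lumped = np.array([[0.90, 0.10], [0.20, 0.80]])
    return T, chi, lumped


@pytest.fixture(scope="session")
def flip():
    """Analytic 2-state flip bundle: network, space, generator, rates."""
    h, f = 0.3, 0.7
    net = make_flip_network(h, f)
    space = g.enumerate_states(net, ())
    gen = g.build_generator(space)
    return {"net": net, "space": space, "gen": gen, "h": h, "f": f}


def _misa_pipeline(preset_kwargs, tau, m, n_max=30):
    net = g.build_motif("misa", g.misa_preset(**preset_kwargs))
    space = g.enumerate_states(net, n_max)
    gen = g.build_generator(space)
    pi = g.stationary(gen)
    T = g.transition_matrix(gen, tau)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = g.spectrum(T, m)
    return {"net": net, "space": space, "gen": gen, "pi": pi, "T": T,
            "spec": spec}


@pytest.fixture(scope="session")
def misa_baseline():
    """MISA at the default repressor kinetics (f_r = 1e-2), tau = 5."""
    bundle = _misa_pipeline({}, tau=5.0, m=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        memb = g.pcca_plus(bundle["spec"], bundle["pi"], 4)
    crisp = g.crispify(memb)
    model = g.coarse_grain(bundle["T"], bundle["pi"], crisp)
    summaries = g.macrostate_summary(model, bundle["space"], bundle["pi"])
    bundle.update(memb=memb, crisp=crisp, model=model, summaries=summaries)
    return bundle


@pytest.fixture(scope="session")
def misa_slow():
    """MISA in the non-adiabatic regime (f_r = 1e-4, h_r = 1e-6), tau = 1."""
    bundle = _misa_pipeline({"slow": True}, tau=1.0, m=20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        memb16 = g.pcca_plus(bundle["spec"], bundle["pi"], 16)
        memb4 = g.pcca_plus(bundle["spec"], bundle["pi"], 4)
    part16 = g.crispify(memb16)
    part4 = g.crispify(memb4)
    bundle.update(memb16=memb16, memb4=memb4, part16=part16, part4=part4)
    return bundle


@pytest.fixture(scope="session")
def ets_sweep():
    """Dimeric toggle switch over the binding-rate grid at X_eq = 100.

    For each f: t_2 and the total global projection error of the 2- and
    3-state MSMs over 250 lag steps.
    """
    rows = []
    for f in (1e-4, 1e-2, 1.0, 1e2, 1e4):
        net = g.build_motif("ets_dimer", g.ets_dimer_preset(f=f))
        space = g.enumerate_states(net, 30)
        gen = g.build_generator(space)
        pi = g.stationary(gen)
        T = g.transition_matrix(gen, 5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = g.spectrum(T, 6)
            err = {}
            for C in (2, 3):
                memb = g.pcca_plus(spec, pi, C)
                model = g.coarse_grain(T, pi, g.crispify(memb))
                err[C] = g.global_error(T, model, 250, pi=pi.pi).total
        rows.append({"f": f, "t2": float(spec.timescales[1]),
                     "err2": err[2], "err3": err[3]})
    return rows


def phenotype_labels(summaries, threshold=7.0):
    """Map macrostate labels to Hi/Lo expression phenotypes."""
    out = {}
    for s in summaries:
        a, b = s.mean_counts[:2]
        out[s.label] = (("Hi" if a > threshold else "Lo") + "/"
                        + ("Hi" if b > threshold else "Lo"))
    return out
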