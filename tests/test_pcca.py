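"""PCCA+ memberships, crisp partitioning, and coarse-graining."""

import numpy as np
import pytest

import grnmsm as g
from grnmsm.models import PromoterAxis, RateParameters, Reaction, ReactionNetwork
from grnmsm.pcca import EmptyMacrostateError
from conftest import DenseLag, lumpable_chain


def two_block_network(coupling=1e-6):
    """Two almost uncoupled 2-state flips: a 4-state chain with two exact
    metastable blocks {0, 1} and {2, 3} linked by a tiny rate."""
    axes = (PromoterAxis("X", ("a", "b")), PromoterAxis("Y", ("u", "v")))
    rx = (
        # fast flips within each block (X axis)
        Reaction(name="x_ab", rate=0.4, axis=0, enabled_states=(0,), axis_to=1, delta=()),
        Reaction(name="x_ba", rate=0.6, axis=0, enabled_states=(1,), axis_to=0, delta=()),
        # slow flips between blocks (Y axis)
        Reaction(name="y_uv", rate=coupling, axis=1, enabled_states=(0,), axis_to=1, delta=()),
        Reaction(name="y_vu", rate=coupling, axis=1, enabled_states=(1,), axis_to=0, delta=()),
    )
    params = RateParameters(g0=0.0, g1=1.0)
    return ReactionNetwork(motif="custom", species=(), axes=axes,
                           reactions=rx, params=params)


@pytest.fixture(scope="module")
def two_block():
    net = two_block_network()
    space = g.enumerate_states(net, ())
    gen = g.build_generator(space)
    pi = g.stationary(gen)
    T = g.transition_matrix(gen, 1.0)
    spec = g.spectrum(T, 3)
    return {"space": space, "gen": gen, "pi": pi, "T": T, "spec": spec}


def test_two_block_memberships_recover_blocks(two_block):
    memb = g.pcca_plus(two_block["spec"], two_block["pi"], 2)
    chi = memb.chi
    # blocks by construction: Y axis is the slow coordinate
    y = two_block["space"].axis_states[:, 1]
    for i in range(4):
        target = np.array([1.0, 0.0]) if y[i] == y[0] else np.array([0.0, 1.0])
        col = chi[i] if chi[i, 0] == max(chi[i]) else chi[i][::-1]
        assert np.abs(np.sort(chi[i]) - np.sort(target)).max() < 1e-3
    labels = g.crispify(memb).labels
    assert len(set(labels[y == 0])) == 1
    assert len(set(labels[y == 1])) == 1
    assert labels[0] != labels[int(np.flatnonzero(y == 1)[0])]


def test_membership_rows_sum_to_one(misa_baseline):
    chi = misa_baseline["memb"].chi
    assert np.abs(chi.sum(axis=1) - 1.0).max() < 1e-9
    assert chi.min() >= 0.0
    assert chi.max() <= 1.0


def test_membership_is_linear_in_subspace_basis(two_block):
    memb = g.pcca_plus(two_block["spec"], two_block["pi"], 2)
    psi = two_block["spec"].psi[:, :2]
    assert np.allclose(memb.chi, psi @ memb.B, atol=1e-9)


def test_pcca_deterministic(two_block):
    m1 = g.pcca_plus(two_block["spec"], two_block["pi"], 2)
    m2 = g.pcca_plus(two_block["spec"], two_block["pi"], 2)
    assert np.array_equal(m1.chi, m2.chi)


def test_crispify_argmax_and_tie_break():
    chi = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0], [0.2, 0.2, 0.6]])
    part = g.crispify(chi)
    assert part.labels.tolist() == [1, 0, 2]  # ties go to the lowest index


def test_crispify_rejects_empty_macrostate():
    chi = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
    with pytest.raises(EmptyMacrostateError, match="reduce C"):
        g.crispify(chi)


def test_coarse_grain_identity_when_C_equals_N(two_block):
    T = two_block["T"]
    chi = np.eye(4)
    model = g.coarse_grain(T, two_block["pi"], chi)
    assert np.allclose(model.T_c, T.dense(), atol=1e-12)
    assert np.allclose(model.pi_c, two_block["pi"].pi)


def test_coarse_grain_reproduces_lumped_chain():
    """On an exactly lumpable chain the projected 2x2 matrix equals the
    analytically lumped one, for crisp and for pi-weighted fuzzy chi."""
    T, chi, lumped = lumpable_chain()
    lag = DenseLag(T)
    # stationary of the 4-state chain
    w, V = np.linalg.eig(T.T)
    pi = np.abs(V[:, np.argmin(np.abs(w - 1))].real)
    pi /= pi.sum()
    model = g.coarse_grain(lag, pi, chi)
    assert np.abs(model.T_c - lumped).max() < 1e-10
    assert model.stationary_check() < 1e-8


def test_coarse_stationary_is_perron_vector_of_coarse_matrix(misa_baseline):
    model = misa_baseline["model"]
    w, V = np.linalg.eig(model.T_c.T)
    v = np.abs(V[:, np.argmin(np.abs(w - 1))].real)
    v /= v.sum()
    assert 0.5 * np.abs(v - model.pi_c).sum() < 1e-8


def test_metastability_beats_random_partitions(two_block):
    """trace(T~) from PCCA+ dominates 100 random crisp partitions."""
    pi = two_block["pi"]
    T = two_block["T"]
    memb = g.pcca_plus(two_block["spec"], pi, 2)
    model = g.coarse_grain(T, pi, g.crispify(memb))
    rng = np.random.default_rng(42)
    best_random = -np.inf
    for _ in range(100):
        labels = rng.integers(0, 2, size=4)
        if len(set(labels.tolist())) < 2:
            continue
        chi = np.zeros((4, 2))
        chi[np.arange(4), labels] = 1.0
        rand_model = g.coarse_grain(T, pi, chi)
        best_random = max(best_random, rand_model.metastability)
    assert model.metastability >= best_random - 1e-12


def test_macrostate_summary_symmetry(misa_baseline):
    """Hi/Lo and Lo/Hi summaries are mirror images for symmetric rates."""
    summaries = misa_baseline["summaries"]
    by_pheno = {}
    for s in summaries:
        a, b = s.mean_counts
        key = ("Hi" if a > 7 else "Lo", "Hi" if b > 7 else "Lo")
        by_pheno[key] = s
    hi_lo = by_pheno[("Hi", "Lo")]
    lo_hi = by_pheno[("Lo", "Hi")]
    assert hi_lo.mean_counts[0] == pytest.approx(lo_hi.mean_counts[1], abs=1e-6)
    assert hi_lo.mean_counts[1] == pytest.approx(lo_hi.mean_counts[0], abs=1e-6)
    assert hi_lo.probability == pytest.approx(lo_hi.probability, abs=1e-8)


def test_contour_set_of_singleton_macrostate():
    T, _, _ = lumpable_chain()
    lag = DenseLag(T)
    w, V = np.linalg.eig(T.T)
    pi = np.abs(V[:, np.argmin(np.abs(w - 1))].real)
    pi /= pi.sum()
    # partition isolating microstate 3
    chi = np.zeros((4, 2))
    chi[:3, 0] = 1.0
    chi[3, 1] = 1.0
    model = g.coarse_grain(lag, pi, g.crispify(chi))

    class _Net:
        species = ("x",)
        axis_sizes = (1,)

        @staticmethod
        def axis_labels(v):
            return ("s",)

    class _Space:
        network = _Net()
        counts = np.arange(4)[:, None]
        axis_states = np.zeros((4, 1), dtype=int)

    summ = g.macrostate_summary(model, _Space(), pi)
    assert summ[1].contour_states.tolist() == [3]
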