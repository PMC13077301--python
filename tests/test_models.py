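"""Unit and property tests for the SEIV/SEIVD equations and integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seivd import (
    CommunityModel,
    InfectionMatrix,
    IntegrationError,
    TraitSet,
    default_community_matrix,
    hill_attenuation,
    observe,
    seiv_rhs,
    seivd_rhs,
    simulate_community,
    simulate_pairwise,
)
from seivd.models import integrate, integrate_pairwise_state


# ---------------------------------------------------------------------------
# Hill attenuation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d, dc, n, expected",
    [
        (0.0, 1e6, 2, 1.0),  # zero debris, no attenuation
        (1e6, 1e6, 2, 0.5),  # half-saturation by construction
        (3e6, 1e6, 2, 0.1),  # 1/(1 + 3^2)
        (1e9, math.inf, 2, 1.0),  # attenuation disabled
    ],
)
def test_hill_attenuation_values(d, dc, n, expected):
    assert hill_attenuation(d, dc, n) == pytest.approx(expected, rel=1e-12)


def test_hill_attenuation_domain_errors():
    with pytest.raises(ValueError):
        hill_attenuation(-1.0, 1e6)
    with pytest.raises(ValueError):
        hill_attenuation(1.0, -1e6)
    with pytest.raises(ValueError):
        hill_attenuation(1.0, 1e6, n=0.0)


@given(
    d=st.floats(min_value=0, max_value=1e12),
    dc=st.floats(min_value=1e-3, max_value=1e12),
    n=st.floats(min_value=0.1, max_value=8),
)
@settings(max_examples=100, deadline=None)
def test_hill_attenuation_in_unit_interval(d, dc, n):
    val = hill_attenuation(d, dc, n)
    assert 0.0 < val <= 1.0


# ---------------------------------------------------------------------------
# pairwise right-hand sides
# ---------------------------------------------------------------------------


def _state(traits, s=0.0, e=None, i=0.0, v=0.0, d=0.0):
    y = np.zeros(traits.n_exposed + 4)
    y[0] = s
    if e is not None:
        y[1 : 1 + traits.n_exposed] = e
    y[1 + traits.n_exposed] = i
    y[2 + traits.n_exposed] = v
    y[3 + traits.n_exposed] = d
    return y


def test_seiv_rhs_no_phage_pure_growth(small_traits):
    y = _state(small_traits, s=1e6)
    dy = seiv_rhs(y, small_traits)
    assert dy[0] == pytest.approx(small_traits.r * 1e6)
    assert np.all(dy[1:] == 0.0)


def test_seiv_rhs_no_burst_no_source_phage_constant(small_traits):
    ts = small_traits.with_(burst_size=0.0)
    y = _state(ts, s=0.0, v=1e7)
    dy = seiv_rhs(y, ts)
    assert dy[2 + ts.n_exposed] == 0.0


def test_seiv_rhs_infection_flux_hand_value():
    # dS/dt = -phi S V = -1e-7 * 1e6 * 1e7 = -1e6 cells/ml/h at r = 0
    ts = TraitSet(r=0.0, phi=1e-7, tau=1.0, n_exposed=4, burst_size=50)
    dy = seiv_rhs(_state(ts, s=1e6, v=1e7), ts)
    assert dy[0] == pytest.approx(-1e6)


def test_seiv_rhs_rejects_nan(small_traits):
    y = _state(small_traits, s=1e6)
    y[0] = math.nan
    with pytest.raises(ValueError):
        seiv_rhs(y, small_traits)


def test_seivd_rhs_reduces_to_seiv_when_dc_infinite(small_traits, rng):
    y = np.abs(rng.normal(1e5, 1e5, small_traits.n_exposed + 4))
    np.testing.assert_allclose(
        seivd_rhs(y, small_traits.with_(debris_halfsat=math.inf)),
        seiv_rhs(y, small_traits),
        rtol=0,
        atol=0,
    )


def test_seivd_rhs_half_saturation_halves_infection_flux(small_traits):
    ts = small_traits.with_(debris_halfsat=1e6)
    y = _state(ts, s=1e6, v=1e7, d=1e6)
    dy_att = seivd_rhs(y, ts)
    y0 = y.copy()
    y0[-1] = 0.0
    dy_free = seivd_rhs(y0, ts)
    # infection flux (the dE1 gain) at D = D_c is exactly half the D = 0 flux
    assert dy_att[1] == pytest.approx(0.5 * dy_free[1], rel=1e-12)


def test_seivd_rhs_matches_independent_rederivation(rng):
    """Full derivative against a literal transcription of the equations."""
    ts = TraitSet(r=0.31, phi=3.3e-8, tau=1.7, n_exposed=6, burst_size=41.0, debris_halfsat=7e5, hill_coeff=2.0)
    y = np.abs(rng.normal(1e6, 1e6, ts.n_exposed + 4))
    s, e = y[0], y[1 : 1 + ts.n_exposed]
    i, v, d = y[1 + ts.n_exposed], y[2 + ts.n_exposed], y[3 + ts.n_exposed]
    k = (ts.n_exposed + 1) / ts.tau
    theta = 1.0 / (1.0 + (d / ts.debris_halfsat) ** 2)
    f = theta * ts.phi * s * v
    expected = np.concatenate(
        [
            [ts.r * s - f],
            [f - k * e[0]],
            k * (e[:-1] - e[1:]),
            [k * (e[-1] - i)],
            [ts.burst_size * k * i - f],
            [k * i],
        ]
    )
    np.testing.assert_allclose(seivd_rhs(y, ts), expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# community model
# ---------------------------------------------------------------------------


def test_community_of_one_pair_reduces_to_pairwise(small_traits):
    mx = InfectionMatrix(("H",), ("P",), np.array([[True]]))
    ts = small_traits.with_(debris_halfsat=5e5)
    model = CommunityModel(mx, {("H", "P"): ts})
    t = np.linspace(0.0, 12.0, 25)
    comm = simulate_community(model, {"H": 2e6}, {"P": 2e5}, t)
    pair = simulate_pairwise(ts, 2e6, 2e5, t)
    for comm_obs, pair_obs, ident in (
        ("host_qINT", "host_qINT", "H"),
        ("phage_qEXT", "free_phage", "P"),
    ):
        a = observe(comm, comm_obs, ident)
        b = observe(pair, pair_obs)
        np.testing.assert_allclose(a, b, rtol=1e-5, atol=1.0)


def test_community_rhs_no_phage_growth_and_constant_debris(small_traits):
    mx = default_community_matrix()
    model = CommunityModel(mx, {pr: small_traits for pr in mx.pairs}, attenuation=False)
    y0 = model.initial_state({h: 1e6 for h in mx.hosts}, {p: 0.0 for p in mx.phages})
    dy = model.rhs(y0)
    np.testing.assert_allclose(dy[:5], small_traits.r * 1e6)
    assert dy[10] == 0.0  # debris constant without lysis


def test_default_matrix_has_nine_interaction_blocks():
    mx = default_community_matrix()
    assert mx.n_interactions == 9
    model = CommunityModel(mx, {pr: TraitSet(r=0.2, phi=1e-7, tau=1.0, n_exposed=2, burst_size=10) for pr in mx.pairs})
    assert len(model.pairs) == 9
    # every pair block carries N_E exposed stages plus one infected stage
    assert model.n_state == 5 + 5 + 1 + 9 * 3


def test_community_missing_traits_raise():
    mx = default_community_matrix()
    with pytest.raises(KeyError):
        CommunityModel(mx, {})


def test_community_kernel_matches_numpy_reference(rng):
    mx = default_community_matrix()
    traits = {}
    for n, pr in enumerate(mx.pairs):
        traits[pr] = TraitSet(
            r=0.15 + 0.01 * mx.hosts.index(pr[0]),
            phi=(1 + n) * 2e-8,
            tau=0.8 + 0.1 * n,
            n_exposed=3 + (n % 3),
            burst_size=20.0 + 5 * n,
            debris_halfsat=1e6 * (1 + mx.hosts.index(pr[0])),
        )
    model = CommunityModel(mx, traits)
    y = np.abs(rng.normal(1e5, 2e5, model.n_state))
    from seivd import _kernels

    ipar, fpar, apar_i, apar_f = model._kernel_args()
    dy_kernel = _kernels.community_rhs(
        y, ipar[0], ipar[1], *apar_i[:4], *apar_f, fpar[0], fpar[1], ipar[2]
    )
    np.testing.assert_allclose(dy_kernel, model.rhs(y), rtol=1e-12)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def test_integrate_exponential_closed_form():
    ts = TraitSet(r=0.2, phi=1e-7, tau=1.0, n_exposed=2, burst_size=10)
    traj = simulate_pairwise(ts, 1e6, 0.0, np.array([0.0, 5.0]), rtol=1e-8)
    assert traj.y[-1, 0] == pytest.approx(1e6 * math.e, rel=1e-6)


def test_integrate_tolerance_self_consistency(rep_traits):
    t = np.linspace(0.0, 8.0, 17)
    a = simulate_pairwise(rep_traits, 2e6, 2e5, t, rtol=1e-6)
    b = simulate_pairwise(rep_traits, 2e6, 2e5, t, rtol=1e-9)
    scale = np.maximum(np.abs(b.y).max(axis=0), 1.0)
    assert (np.abs(a.y - b.y).max(axis=0) / scale).max() < 1e-4


def test_generic_integrate_matches_fast_path(small_traits):
    t = np.linspace(0.0, 6.0, 13)
    y0 = np.zeros(small_traits.n_exposed + 4)
    y0[0] = 2e6
    y0[2 + small_traits.n_exposed] = 2e5
    generic = integrate(lambda y: seiv_rhs(y, small_traits), y0, t, rtol=1e-8)
    fast = integrate_pairwise_state(small_traits, y0, t, rtol=1e-8)
    np.testing.assert_allclose(generic.y, fast.y, rtol=1e-5, atol=1.0)


def test_integrate_input_validation(small_traits):
    with pytest.raises(ValueError):
        simulate_pairwise(small_traits, -1.0, 0.0, np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        simulate_pairwise(small_traits, 1e6, 0.0, np.array([1.0, 0.5]))


def test_trajectory_nonnegative_and_debris_monotone(rep_traits):
    ts = rep_traits.with_(debris_halfsat=1e6)
    traj = simulate_pairwise(ts, 2e6, 2e5, np.linspace(0.0, 16.0, 65))
    assert traj.y.min() >= 0.0
    debris = traj.state("D")
    assert np.all(np.diff(debris) >= -1e-6 * debris.max())


def test_seivd_reduction_to_seiv_on_trajectories(rep_traits):
    t = np.linspace(0.0, 10.0, 21)
    a = simulate_pairwise(rep_traits.with_(debris_halfsat=math.inf), 2e6, 2e5, t)
    b = simulate_pairwise(rep_traits.with_(debris_halfsat=1e30), 2e6, 2e5, t)
    scale = np.maximum(np.abs(a.y).max(axis=0), 1.0)
    assert (np.abs(a.y - b.y).max(axis=0) / scale).max() < 1e-6


def test_burst_accounting_conserves_burst_size():
    """With growth off and adsorption shut after a pulse, phage produced per
    lysed cell converges to beta."""
    ts = TraitSet(r=0.0, phi=0.0, tau=0.5, n_exposed=9, burst_size=37.0)
    # start with all cells freshly exposed; no further adsorption (phi = 0)
    e0 = np.zeros(ts.n_exposed)
    e0[0] = 1e5
    y0 = np.zeros(ts.n_exposed + 4)
    y0[1] = 1e5
    traj = integrate_pairwise_state(ts, y0, np.array([0.0, 20.0]), rtol=1e-10, atol=1e-6)
    produced = traj.y[-1, 2 + ts.n_exposed]
    lysed = traj.y[-1, 3 + ts.n_exposed]
    assert lysed == pytest.approx(1e5, rel=1e-4)
    assert produced / lysed == pytest.approx(ts.burst_size, rel=0.01)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def test_observe_total_phage_counts_infected_centres_once(small_traits):
    traj = simulate_pairwise(small_traits, 1e6, 1e5, np.linspace(0.0, 2.0, 5))
    ne = small_traits.n_exposed
    brute_total = traj.y[:, 2 + ne] + traj.y[:, 1 : 2 + ne].sum(axis=1)
    np.testing.assert_allclose(observe(traj, "total_phage"), brute_total, rtol=1e-12)
    # with no infected cells total equals free
    ctrl = simulate_pairwise(small_traits, 1e6, 0.0, np.linspace(0.0, 2.0, 5))
    np.testing.assert_allclose(observe(ctrl, "total_phage"), observe(ctrl, "free_phage"))


def test_observe_community_projection_sums(rng):
    mx = default_community_matrix()
    traits = {pr: TraitSet(r=0.17, phi=5e-8, tau=1.0, n_exposed=3, burst_size=30, debris_halfsat=1e6) for pr in mx.pairs}
    model = CommunityModel(mx, traits)
    s0 = {h: 2e6 for h in mx.hosts}
    v0 = {p: 2e5 for p in mx.phages}
    traj = simulate_community(model, s0, v0, np.linspace(0.0, 6.0, 7))
    # brute-force: host_qINT = S_i + sum over that host's pair blocks
    for i, h in enumerate(mx.hosts):
        expected = traj.y[:, i].copy()
        for p_idx in range(len(model.pairs)):
            if model.pair_host[p_idx] == i:
                off, ne = model.pair_off[p_idx], model.pair_ne[p_idx]
                expected += traj.y[:, off : off + ne + 1].sum(axis=1)
        np.testing.assert_allclose(observe(traj, "host_qINT", h), expected, rtol=1e-12)
    total = sum(observe(traj, "host_qINT", h) for h in mx.hosts)
    np.testing.assert_allclose(observe(traj, "total_host"), total, rtol=1e-12)


def test_observe_unknown_label_raises(small_traits):
    traj = simulate_pairwise(small_traits, 1e6, 0.0, np.linspace(0.0, 1.0, 3))
    with pytest.raises(ValueError):
        observe(traj, "nonsense")


# ---------------------------------------------------------------------------
# trait-set invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ne, cv", [(0, 1.0), (3, 0.5), (24, 0.2), (99, 0.1)])
def test_latent_cv_formula(ne, cv):
    ts = TraitSet(r=0.1, phi=1e-7, tau=2.0, n_exposed=ne, burst_size=10)
    assert ts.latent_cv == pytest.approx(cv)
    assert ts.stage_rate == pytest.approx((ne + 1) / 2.0)


@pytest.mark.parametrize(
    "kw",
    [
        dict(r=-0.1),
        dict(phi=-1e-9),
        dict(tau=0.0),
        dict(n_exposed=-1),
        dict(burst_size=-5),
        dict(debris_halfsat=0.0),
    ],
)
def test_traitset_invalid_values_rejected(kw):
    base = dict(r=0.2, phi=1e-7, tau=1.0, n_exposed=4, burst_size=50)
    base.update(kw)
    with pytest.raises(ValueError):
        TraitSet(**base)
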