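"""Tests for priors, likelihood, the DRAM sampler, fits and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from seivd import TraitSet
from seivd.inference import (
    LikelihoodSpec,
    LogNormalPrior,
    PriorSpec,
    SamplerSettings,
    TruncNormalPrior,
    coordinate_descent_fit,
    dram_sample,
    effective_sample_size,
    equivalence_test,
    fit_community,
    fit_pairwise_onestep,
    gaussian_log10_loglik,
    gelman_rubin,
    log_likelihood,
    posterior_predictive,
)
from seivd.synthetic import ExperimentDesign, NoiseModel, generate_onestep


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def test_truncnormal_logpdf_matches_scipy():
    pr = TruncNormalPrior(2.0, 1.5, low=0.0, high=5.0)
    a, b = (0.0 - 2.0) / 1.5, (5.0 - 2.0) / 1.5
    for u in (0.1, 1.0, 2.0, 4.9):
        assert pr.logpdf_t(u) == pytest.approx(
            stats.truncnorm.logpdf(u, a, b, loc=2.0, scale=1.5), rel=1e-9
        )
    assert pr.logpdf_t(-0.1) == -math.inf
    assert pr.logpdf_t(5.1) == -math.inf


def test_lognormal_prior_is_normal_in_log10():
    pr = LogNormalPrior(1e-7, 0.5)
    for u in (-8.0, -7.0, -6.2):
        assert pr.logpdf_t(u) == pytest.approx(
            stats.norm.logpdf(u, loc=-7.0, scale=0.5), rel=1e-9
        )
    assert pr.to_native(-7.0) == pytest.approx(1e-7)
    assert pr.from_native(1e-7) == pytest.approx(-7.0)


def test_prior_spec_sampling_respects_support(rng):
    spec = PriorSpec(
        {
            "a": TruncNormalPrior(0.0, 1.0, low=-1.0, high=1.0),
            "b": LogNormalPrior(10.0, 0.2, low=1.0, high=100.0),
        }
    )
    for _ in range(100):
        u = spec.sample_t(rng)
        assert np.isfinite(spec.log_prior(u))
        assert -1.0 <= u[0] <= 1.0
        assert 0.0 <= u[1] <= 2.0  # log10 of [1, 100]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_gaussian_log10_loglik_closed_form():
    sigma = 0.2
    obs = np.array([1e5, 1e6, 1e7])
    assert gaussian_log10_loglik(obs, obs, sigma) == pytest.approx(
        -3 * math.log(sigma * math.sqrt(2 * math.pi))
    )
    # perturbing one point by exactly sigma in log10 units costs 0.5
    pert = obs.copy()
    pert[0] *= 10**sigma
    assert gaussian_log10_loglik(pert, obs, sigma) == pytest.approx(
        -3 * math.log(sigma * math.sqrt(2 * math.pi)) - 0.5
    )


def test_log_likelihood_matches_brute_force_sum(rng, rep_traits):
    data = generate_onestep(rep_traits, noise=NoiseModel(sigma_obs=0.1), seed=5)
    spec = LikelihoodSpec(sigma=0.1)

    def fake_sim(params):
        out = {}
        for key, (times, vals) in data.series().items():
            out[key] = np.nanmean(vals, axis=0) * 1.1
        return out

    value = log_likelihood({}, data, fake_sim, spec)
    sims = fake_sim({})
    brute = 0.0
    for key, (times, vals) in data.series().items():
        for row in vals:
            for j, v in enumerate(row):
                if np.isfinite(v) and v > 0:
                    brute += stats.norm.logpdf(np.log10(v), np.log10(sims[key][j]), 0.1)
    assert value == pytest.approx(brute, rel=1e-9)


# ---------------------------------------------------------------------------
# DRAM sampler
# ---------------------------------------------------------------------------


def test_dram_recovers_2d_gaussian_moments():
    cov = np.array([[2.0, 1.2], [1.2, 1.5]])
    icov = np.linalg.inv(cov)
    mean = np.array([1.0, -2.0])
    lp = lambda x: float(-0.5 * (x - mean) @ icov @ (x - mean))
    res = dram_sample(lp, np.zeros(2), 40_000, seed=7)
    draws = res["chain"][10_000:]
    est_mean = draws.mean(axis=0)
    est_cov = np.cov(draws.T)
    # Monte-Carlo standard error of the mean with autocorrelation
    for i in range(2):
        ess = effective_sample_size(draws[:, i])
        mcse = math.sqrt(cov[i, i] / ess)
        assert abs(est_mean[i] - mean[i]) < 3 * mcse
    np.testing.assert_allclose(est_cov, cov, rtol=0.10)


def test_dram_seed_determinism():
    lp = lambda x: float(-0.5 * x @ x)
    a = dram_sample(lp, np.zeros(3), 2000, seed=11)
    b = dram_sample(lp, np.zeros(3), 2000, seed=11)
    np.testing.assert_array_equal(a["chain"], b["chain"])
    assert a["acceptance_rate"] == b["acceptance_rate"]


def test_dram_bounded_support_respected():
    spec = PriorSpec({"x": TruncNormalPrior(0.5, 2.0, low=0.0, high=1.0)})
    lp = lambda u: spec.log_prior(u)
    res = dram_sample(lp, np.array([0.5]), 5000, seed=3)
    assert res["chain"].min() >= 0.0
    assert res["chain"].max() <= 1.0


def test_dram_requires_finite_start():
    with pytest.raises(ValueError):
        dram_sample(lambda x: -math.inf, np.zeros(1), 100, seed=0)


# ---------------------------------------------------------------------------
# coordinate descent
# ---------------------------------------------------------------------------


def test_coordinate_descent_separable_quadratic():
    target = np.array([1.0, -2.0, 0.5])
    obj = lambda x: float(np.sum((x - target) ** 2))
    res = coordinate_descent_fit(obj, np.zeros(3), [(-5, 5)] * 3, max_sweeps=2)
    np.testing.assert_allclose(res["x"], target, atol=1e-4)
    assert res["improved"]


def test_coordinate_descent_at_optimum_returns_init():
    obj = lambda x: float(np.sum(x**2))
    res = coordinate_descent_fit(obj, np.zeros(2), [(-1, 1)] * 2, max_sweeps=3)
    np.testing.assert_allclose(res["x"], np.zeros(2), atol=1e-4)


def test_coordinate_descent_objective_monotone():
    calls = []

    def obj(x):
        v = float((x[0] - 3) ** 2 + (x[1] + 1) ** 4 + 0.5 * x[0] * x[1])
        calls.append(v)
        return v

    res = coordinate_descent_fit(obj, np.array([0.0, 0.0]), [(-10, 10)] * 2)
    assert res["fun"] <= calls[0]
    assert res["fun"] == min(calls)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def test_gelman_rubin_iid_chains_near_one(rng):
    chains = rng.normal(0.0, 1.0, size=(4, 2000, 2))
    rhat = gelman_rubin(chains)
    assert np.all(rhat < 1.05)


def test_gelman_rubin_disjoint_chains_large():
    a = np.zeros((1, 500, 1))
    b = np.full((1, 500, 1), 10.0)
    chains = np.concatenate([a + np.random.default_rng(0).normal(0, 0.1, a.shape), b], axis=0)
    assert gelman_rubin(chains)[0] > 1.5


def test_gelman_rubin_hand_computed_toy():
    # two chains of four draws; split-R-hat over the four half-chains
    chains = np.array([[[1.0], [2.0], [3.0], [4.0]], [[2.0], [3.0], [4.0], [5.0]]])
    split = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
    w = split.var(axis=1, ddof=1).mean()
    b = 2 * split.mean(axis=1).var(ddof=1)
    var_plus = (2 - 1) / 2 * w + b / 2
    expected = math.sqrt(var_plus / w)
    assert gelman_rubin(chains)[0] == pytest.approx(expected, rel=1e-12)


def test_gelman_rubin_matches_arviz_on_random_chains(rng):
    import arviz

    chains = rng.normal(0, 1, size=(4, 500, 1)) + rng.normal(0, 0.05, size=(4, 1, 1))
    ours = gelman_rubin(chains)[0]
    theirs = float(arviz.rhat(arviz.convert_to_dataset(chains[:, :, 0])).x)
    assert ours == pytest.approx(theirs, abs=0.01)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def noise_free_fit():
    truth = TraitSet(r=math.log(2) / 4, phi=1e-7, tau=1.0, n_exposed=99, burst_size=50.0)
    design = ExperimentDesign.onestep()
    data = generate_onestep(truth, design, NoiseModel(sigma_obs=0.0, detection_floor=0.0), seed=0)
    ens = fit_pairwise_onestep(
        data, design, r=truth.r, sigma=0.05, settings=SamplerSettings(n_steps=1500), seed=1
    )
    return truth, ens


def test_onestep_fit_noise_free_mode_recovers_truth(noise_free_fit):
    truth, ens = noise_free_fit
    mode = ens.draws.iloc[int(np.argmax(ens.log_post))]
    assert mode["beta"] == pytest.approx(truth.burst_size, rel=0.05)
    assert mode["tau"] == pytest.approx(truth.tau, rel=0.05)
    assert mode["phi"] == pytest.approx(truth.phi, rel=0.05)


def test_onestep_posterior_latent_cv_consistency(noise_free_fit):
    """The posterior latent CV is 1/sqrt(N_E_map + 1) by construction."""
    _, ens = noise_free_fit
    ne_map = ens.median("n_exposed")
    cv = 1.0 / math.sqrt(ne_map + 1)
    assert 0.05 < cv < 0.2  # truth 0.1 at N_E = 99


def test_likelihood_sharpens_with_smaller_sigma():
    truth = TraitSet(r=math.log(2) / 4, phi=1e-7, tau=1.0, n_exposed=24, burst_size=50.0)
    design = ExperimentDesign.onestep()
    data = generate_onestep(truth, design, NoiseModel(sigma_obs=0.0, detection_floor=0.0), seed=2)
    sds = {}
    for sigma in (0.05, 0.4):
        ens = fit_pairwise_onestep(
            data, design, r=truth.r, sigma=sigma, settings=SamplerSettings(n_steps=1200), seed=4
        )
        sds[sigma] = ens.draws["beta"].std()
    assert sds[0.05] < sds[0.4]


def test_posterior_predictive_bands_and_degenerate_draw(noise_free_fit):
    truth, ens = noise_free_fit
    design = ExperimentDesign.onestep()
    from seivd.inference import OneStepSimulator

    times = np.asarray(design.times())
    sim = OneStepSimulator(design, truth.r, "phage", times)
    pp = posterior_predictive(ens, sim, n_draws=50, seed=0)
    for key, band in pp["bands"].items():
        assert np.all(band["lo"] <= band["median"] + 1e-12)
        assert np.all(band["median"] <= band["hi"] + 1e-12)
    # single-draw ensemble: band collapses onto the median trajectory
    single = ens.draws.iloc[[0]]
    import copy

    ens1 = copy.copy(ens)
    ens1.draws = single
    pp1 = posterior_predictive(ens1, sim, n_draws=1, seed=0)
    for band in pp1["bands"].values():
        np.testing.assert_allclose(band["lo"], band["hi"], rtol=1e-12)


# ---------------------------------------------------------------------------
# equivalence test
# ---------------------------------------------------------------------------


def test_equivalence_identical_posteriors(rng):
    draws = rng.lognormal(0.0, 0.01, 2000)
    res = equivalence_test(draws, draws, rope_halfwidth=0.5)
    assert res.p_eq > 0.99
    assert res.verdict == "minor difference"


def test_equivalence_separated_posteriors(rng):
    a = rng.lognormal(0.0, 0.05, 2000)
    b = rng.lognormal(5.0, 0.05, 2000)
    res = equivalence_test(a, b, rope_halfwidth=0.1)
    assert res.p_eq < 0.01
    assert res.verdict == "shift"


def test_equivalence_symmetry(rng):
    a = rng.lognormal(0.0, 0.3, 1500)
    b = rng.lognormal(0.25, 0.3, 1700)
    r1 = equivalence_test(a, b, rope_halfwidth=0.1)
    r2 = equivalence_test(b, a, rope_halfwidth=0.1)
    assert r1.p_eq == pytest.approx(r2.p_eq, abs=1e-12)


def test_equivalence_matches_gaussian_convolution(rng):
    """Normal-vs-normal case against the closed-form P(|Delta| <= m)."""
    mu_a, mu_b, s_a, s_b, m = 0.3, 0.1, 0.2, 0.25, 0.15
    a = 10 ** rng.normal(mu_a, s_a, 200_000)
    b = 10 ** rng.normal(mu_b, s_b, 200_000)
    res = equivalence_test(a, b, rope_halfwidth=m)
    s = math.hypot(s_a, s_b)
    exact = stats.norm.cdf((m - (mu_a - mu_b)) / s) - stats.norm.cdf((-m - (mu_a - mu_b)) / s)
    assert res.p_eq == pytest.approx(exact, abs=0.01)


def test_equivalence_empty_rejected():
    with pytest.raises(ValueError):
        equivalence_test(np.array([]), np.array([1.0]))


def test_directional_shift_detected_end_to_end():
    """A 3x burst-size shift between generating contexts is flagged while an
    unshifted trait is judged equivalent."""
    import numpy as np

    from seivd import InfectionMatrix
    from seivd.synthetic import generate_community, initial_conditions_from_moi, scenario_traitshift

    hosts, phages = ("H1",), ("P1",)
    mx = InfectionMatrix(hosts, phages, np.array([[True]]))
    r = {"H1": math.log(2) / 4}
    base = {("H1", "P1"): TraitSet(r=r["H1"], phi=1e-7, tau=1.0, n_exposed=4, burst_size=50, debris_halfsat=1e6)}
    shifted = scenario_traitshift(base, {("H1", "P1"): {"burst_size": 3.0}})
    design = ExperimentDesign.community(hosts=hosts)
    s0, v0 = initial_conditions_from_moi({"H1": 2e6}, 0.1, mx)
    fits = []
    for truth in (base, shifted):
        data = generate_community(truth, mx, design, NoiseModel(sigma_obs=0.1), seed=21)
        fits.append(
            fit_community(
                data, mx, host_r=r, s0=s0, v0=v0, n_exposed=4, sigma=0.1,
                settings=SamplerSettings(n_steps=1500), seed=21,
            )
        )
    key = "beta:H1|P1"
    res_beta = equivalence_test(fits[0].draws[key].to_numpy(), fits[1].draws[key].to_numpy())
    assert res_beta.verdict == "shift"
    assert res_beta.delta_median < 0  # community context has the larger burst
    res_tau = equivalence_test(
        fits[0].draws["tau:H1|P1"].to_numpy(), fits[1].draws["tau:H1|P1"].to_numpy(), rope_halfwidth=0.2
    )
    assert res_tau.verdict != "shift"
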