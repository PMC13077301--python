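"""Reference benchmarks: headline dynamics checks and parameter-recovery harnesses.

Every function here recomputes a quantity from scratch by running the
package's own simulators, estimators and samplers on synthetic data at the
study's designs.  Problem sizes (chain lengths, seed counts) are the module's
stated defaults; the docstrings give the conditions each benchmark probes.

The representative pairwise trait set used by the crash/collapse benchmarks
is phi = 1e-7 ml/h, beta = 50, N_E = 99 (latent CV 0.1), r = ln2/4 per hour,
with S0 = 2e6 cells/ml and V0 = 2e5 virions/ml (MOI 0.1).  The crash
benchmark uses tau = 1 h (one-step regime); the rescue benchmark uses the
tau = 4 h variant of the same set, for which the SEIV/SEIVD crash-vs-rescue
dichotomy holds across the whole D_c range 1e5 - 5e6 cells/ml.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import kstest, norm

from . import _kernels
from .inference import SamplerSettings, dram_sample, fit_community, fit_pairwise_onestep
from .models import (
    CommunityModel,
    InfectionMatrix,
    TraitSet,
    default_community_matrix,
    observe,
    simulate_community,
    simulate_pairwise,
)
from .synthetic import (
    ExperimentDesign,
    NoiseModel,
    generate_community,
    generate_onestep,
    initial_conditions_from_moi,
    sampling_schedule,
)
from .traits import AssaySeries, estimate_latent_period

__all__ = [
    "REPRESENTATIVE_TRAITS",
    "representative_traits",
    "latent_period_cv",
    "community_sampling_points",
    "community_moi",
    "seiv_crash_fold",
    "community_collapse_fold",
    "seivd_rescue_min_host",
    "solver_oracle_error",
    "dram_gaussian_ks",
    "onestep_recovery",
    "community_coverage",
    "latent_first_rise_bias",
]

REPRESENTATIVE_TRAITS = dict(
    r=math.log(2) / 4, phi=1e-7, tau=1.0, n_exposed=99, burst_size=50.0
)
_S0 = 2e6
_V0 = 2e5


def representative_traits(**overrides) -> TraitSet:
    kw = dict(REPRESENTATIVE_TRAITS)
    kw.update(overrides)
    return TraitSet(**kw)


# ---------------------------------------------------------------------------
# closed-form / arithmetic checks
# ---------------------------------------------------------------------------


def latent_period_cv(n_exposed: int = 99, tau: float = 1.0, n_draws: int = 100_000, seed: int = 0) -> dict:
    """Analytic and Monte-Carlo CV of the Erlang adsorption-to-lysis time.

    The chain has ``n_exposed`` exposed stages plus one infected stage, each
    exponential with rate ``(n_exposed + 1)/tau``, so the transit time is
    Erlang(n_exposed + 1) with mean tau and CV ``1/sqrt(n_exposed + 1)``.
    """
    ts = representative_traits(n_exposed=n_exposed, tau=tau)
    rng = np.random.default_rng(seed)
    stages = n_exposed + 1
    draws = rng.exponential(scale=tau / stages, size=(n_draws, stages)).sum(axis=1)
    return {
        "analytic_cv": ts.latent_cv,
        "mc_cv": float(draws.std() / draws.mean()),
        "mc_mean": float(draws.mean()),
        "tau": tau,
    }


def community_sampling_points(interval_h: float = 35.0 / 60.0, duration_h: float = 15.75) -> int:
    """Number of sampling points of the community design (35 min over 15.75 h)."""
    return int(len(sampling_schedule(interval_h, duration_h)))


def community_moi(total_phage: float = 2e8, total_cells: float = 2e9) -> float:
    """Flask-wide MOI from the community inoculation totals."""
    return total_phage / total_cells


# ---------------------------------------------------------------------------
# crash / collapse / rescue dynamics
# ---------------------------------------------------------------------------


def seiv_crash_fold(t_end: float = 16.0, n_points: int = 129) -> float:
    """Fold-decline of host density under pairwise SEIV with the
    representative one-step-regime traits (tau = 1 h)."""
    traj = simulate_pairwise(representative_traits(), _S0, _V0, np.linspace(0.0, t_end, n_points))
    host = observe(traj, "host_qINT")
    return float(host[0] / max(host.min(), 1e-300))


def community_collapse_fold(t_end: float = 10.0, n_points: int = 81) -> float:
    """Minimum (over the five hosts) fold-decline under the 9-pair community
    SEIV model with representative traits and the study's initial densities."""
    matrix = default_community_matrix()
    traits = {pr: representative_traits() for pr in matrix.pairs}
    model = CommunityModel(matrix, traits, attenuation=False)
    s0, v0 = initial_conditions_from_moi({h: _S0 for h in matrix.hosts}, 0.1, matrix)
    traj = simulate_community(model, s0, v0, np.linspace(0.0, t_end, n_points))
    folds = []
    for h in matrix.hosts:
        q = observe(traj, "host_qINT", h)
        folds.append(q[0] / max(q.min(), 1e-300))
    return float(min(folds))


def seivd_rescue_min_host(
    n_grid: int = 20,
    dc_range: tuple = (1e5, 5e6),
    tau: float = 4.0,
    t_end: float = 16.0,
    n_points: int = 129,
) -> dict:
    """Minimum host density over a D_c grid for the pairwise SEIVD model.

    Uses the tau = 4 h variant of the representative traits (the parameter
    set for which both the SEIV crash and SEIVD rescue hold); persistence
    means the host stays above 1 cell/ml through ``t_end``.
    """
    t = np.linspace(0.0, t_end, n_points)
    grid = np.geomspace(dc_range[0], dc_range[1], n_grid)
    mins = []
    for dc in grid:
        ts = representative_traits(tau=tau, debris_halfsat=float(dc))
        host = observe(simulate_pairwise(ts, _S0, _V0, t), "host_qINT")
        mins.append(float(host.min()))
    return {"dc_grid": grid, "min_host": np.array(mins), "worst": float(min(mins))}


# ---------------------------------------------------------------------------
# numerical oracles
# ---------------------------------------------------------------------------


def _rel_supnorm(a: np.ndarray, b: np.ndarray, floor: float = 1.0) -> float:
    """Per-variable sup-norm difference relative to each variable's own scale."""
    scale = np.maximum(np.abs(b).max(axis=0), floor)
    return float((np.abs(a - b).max(axis=0) / scale).max())


def solver_oracle_error(dt: float = 1e-3) -> float:
    """Worst relative sup-norm gap between the adaptive solver and fixed-step
    RK4 (dt in hours) over the benchmark runs (SEIV crash, SEIVD rescue,
    2x2 community)."""
    errs = []
    t = np.linspace(0.0, 16.0, 33)
    for ts in (representative_traits(), representative_traits(tau=4.0, debris_halfsat=1e6)):
        traj = simulate_pairwise(ts, _S0, _V0, t, rtol=1e-10, atol=1e-4)
        y0 = np.zeros(ts.n_exposed + 4)
        y0[0] = _S0
        y0[2 + ts.n_exposed] = _V0
        ipar = np.array([ts.n_exposed, 0, 0], dtype=np.int64)
        fpar = np.array([ts.r, ts.phi, ts.stage_rate, ts.burst_size, ts.debris_halfsat, ts.hill_coeff, math.inf])
        e_i = np.empty(0, dtype=np.int64)
        e_f = np.empty(0, dtype=np.float64)
        ref = _kernels.rk4_fixed(0, y0, t, dt, ipar, fpar, (e_i,) * 5, (e_f,) * 5)
        errs.append(_rel_supnorm(traj.y, np.clip(ref, 0.0, None)))
    # 2x2 community (SEIVD)
    hosts, phages = ("H1", "H2"), ("P1", "P2")
    mx = InfectionMatrix(hosts, phages, np.ones((2, 2), dtype=bool))
    traits = {pr: representative_traits(n_exposed=4, debris_halfsat=1e6) for pr in mx.pairs}
    model = CommunityModel(mx, traits)
    s0, v0 = initial_conditions_from_moi({h: _S0 for h in hosts}, 0.1, mx)
    tc = np.linspace(0.0, 15.75, 29)
    traj = simulate_community(model, s0, v0, tc, rtol=1e-10, atol=1e-4)
    ipar, fpar, apar_i, apar_f = model._kernel_args()
    ref = _kernels.rk4_fixed(1, model.initial_state(s0, v0), tc, dt, ipar, fpar, apar_i, apar_f)
    errs.append(_rel_supnorm(traj.y, np.clip(ref, 0.0, None)))
    return float(max(errs))


def dram_gaussian_ks(n_steps: int = 100_000, seed: int = 0, mean: float = 3.0, sd: float = 2.0) -> float:
    """KS distance between DRAM draws and a known 1-d Gaussian target."""
    log_post = lambda x: float(-0.5 * ((x[0] - mean) / sd) ** 2)
    res = dram_sample(log_post, np.array([0.0]), n_steps, seed=seed)
    draws = res["chain"][n_steps // 5 :, 0]
    return float(kstest(draws, norm(loc=mean, scale=sd).cdf).statistic)


# ---------------------------------------------------------------------------
# parameter-recovery harnesses
# ---------------------------------------------------------------------------


def onestep_recovery(
    n_seeds: int = 20,
    sigma_obs: float = 0.1,
    n_steps: int = 2500,
    seed0: int = 0,
) -> dict:
    """Posterior-median recovery of (phi, tau, beta) from synthetic one-step data.

    Truth: beta = 50, tau = 1 h, phi = 1e-7 ml/h, latent CV 0.1, lognormal
    observation noise ``sigma_obs`` on log10 densities; one DRAM fit per seed
    with the noise scale fixed at its true value.
    """
    truth = representative_traits()
    design = ExperimentDesign.onestep()
    medians = {"phi": [], "tau": [], "beta": []}
    for i in range(n_seeds):
        seed = seed0 + i
        data = generate_onestep(truth, design, NoiseModel(sigma_obs=sigma_obs), seed=seed)
        ens = fit_pairwise_onestep(
            data, design, r=truth.r, sigma=sigma_obs,
            settings=SamplerSettings(n_steps=n_steps), seed=seed,
        )
        for k in medians:
            medians[k].append(ens.median(k))
    out = {k: np.array(v) for k, v in medians.items()}
    out["beta_median_bias"] = float(np.median(out["beta"]) / truth.burst_size - 1.0)
    out["tau_median_bias"] = float(np.median(out["tau"]) / truth.tau - 1.0)
    out["phi_worst_ratio"] = float(
        np.max(np.maximum(out["phi"] / truth.phi, truth.phi / out["phi"]))
    )
    out["truth"] = {"phi": truth.phi, "tau": truth.tau, "beta": truth.burst_size}
    return out


def _coverage_benchmark_truth():
    hosts, phages = ("H1", "H2"), ("P1", "P2")
    mx = InfectionMatrix(hosts, phages, np.array([[True, True], [False, True]]))
    r = {"H1": math.log(2) / 4, "H2": math.log(2) / 5}
    truth = {
        ("H1", "P1"): TraitSet(r=r["H1"], phi=1e-7, tau=1.0, n_exposed=4, burst_size=50, debris_halfsat=1e6),
        ("H1", "P2"): TraitSet(r=r["H1"], phi=5e-8, tau=1.5, n_exposed=4, burst_size=80, debris_halfsat=1e6),
        ("H2", "P2"): TraitSet(r=r["H2"], phi=2e-7, tau=0.8, n_exposed=4, burst_size=30, debris_halfsat=2e6),
    }
    return mx, r, truth


def community_coverage(
    n_runs: int = 10,
    sigma_obs: float = 0.15,
    n_steps: int = 5000,
    seed0: int = 0,
) -> dict:
    """95% credible-interval coverage on the 2-host/2-phage SEIVD benchmark.

    Generates a triplicate community dataset per run (three interacting
    pairs, shared latent CV), fits the joint posterior over per-pair
    (phi, tau, beta) and per-host D_c, and pools the
    truth-inside-95%-interval indicator over parameters and runs.
    """
    mx, r, truth = _coverage_benchmark_truth()
    true_vals = {}
    for (h, p), ts in truth.items():
        key = f"{h}|{p}"
        true_vals[f"phi:{key}"] = ts.phi
        true_vals[f"tau:{key}"] = ts.tau
        true_vals[f"beta:{key}"] = ts.burst_size
    for h in mx.hosts:
        true_vals[f"Dc:{h}"] = truth[(h, "P2")].debris_halfsat
    design = ExperimentDesign.community(hosts=mx.hosts)
    cells = {h: 2e6 for h in mx.hosts}
    s0, v0 = initial_conditions_from_moi(cells, 0.1, mx)
    inside = 0
    total = 0
    for i in range(n_runs):
        seed = seed0 + 100 * i
        data = generate_community(truth, mx, design, NoiseModel(sigma_obs=sigma_obs), seed=seed)
        ens = fit_community(
            data, mx, host_r=r, s0=s0, v0=v0, n_exposed=4, sigma=sigma_obs,
            settings=SamplerSettings(n_steps=n_steps), seed=seed,
        )
        for name in ens.names:
            lo, hi = ens.ci(name)
            inside += int(lo <= true_vals[name] <= hi)
            total += 1
    return {"coverage": inside / total, "n_checks": total, "n_runs": n_runs}


def latent_first_rise_bias(
    n_runs: int = 100,
    tau: float = 1.0,
    n_exposed: int = 99,
    sigma_obs: float = 0.05,
    seed0: int = 0,
) -> dict:
    """Fraction of synthetic one-step curves whose first-rise latent period
    falls below the true mean tau (first-appearance bias at latent CV 0.1)."""
    truth = representative_traits(tau=tau, n_exposed=n_exposed)
    design = ExperimentDesign.onestep()
    below = 0
    detected = 0
    estimates = []
    for i in range(n_runs):
        data = generate_onestep(truth, design, NoiseModel(sigma_obs=sigma_obs), seed=seed0 + i)
        times, values = data.series()[("phage", "PFU_free")]
        series = AssaySeries(times, np.nan_to_num(values, nan=0.0))
        rise = estimate_latent_period(series)
        if not rise.no_burst:
            detected += 1
            estimates.append(rise.time_h)
            below += int(rise.time_h < tau)
    return {
        "fraction_below": below / detected if detected else math.nan,
        "n_detected": detected,
        "mean_first_rise": float(np.mean(estimates)) if estimates else math.nan,
        "tau": tau,
    }
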