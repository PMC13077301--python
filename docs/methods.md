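# Methods

## Model structure and assumptions

The pairwise SEIV model is a nonlinear ODE system over susceptible cells
`S`, exposed stages `E_1..E_NE`, infected cells `I`, and free virions `V`.
Infection transfers mass from `S` to `E_1` at rate `φSV`; the chain
`E_1 → … → E_NE → I → lysis` advances at the common stage rate
`k = (N_E + 1)/τ`, so the adsorption-to-lysis time is Erlang distributed
with mean `τ` and CV `1/√(N_E + 1)` (linear chain trick). Lysis releases
`β` virions per cell. The SEIVD variant adds a debris state `D` that
accumulates lysed cells (`dD/dt = kI`, no decay) and multiplies the
infection flux — the `φSV` terms in `dS/dt`, `dE_1/dt` and the adsorption
loss in `dV/dt` — by the Hill factor `θ(D) = 1/(1 + (D/D_c)^n)` with
`n = 2`. Attenuating entry is the minimal mechanism consistent with
debris acting on adsorption and infection; burst size and chain rate are
left unattenuated. `D_c = ∞` recovers SEIV exactly (verified to solver
tolerance in the tests).

Community scale-up: each interacting pair `(i, j)` of the boolean infection
matrix carries its own `E`-chain, `I` state and traits `(φ_ij, τ_ij,
β_ij, N_E^ij)`; hosts grow at `r_i`; all pairs feed a single shared debris
pool `D` with per-host thresholds `D_c_i`. Per-pair debris pools are out of
scope. Multiple infection is excluded: only susceptible cells adsorb
virions. An optional flag (`adsorb_infected`, off by default) adds loss of
free phage to exposed/infected cells of their host without creating new
infections — the supplementary-model variant whose presence the main
sources leave unstated.

Host growth is pure exponential by default; an optional logistic carrying
capacity exists for phage-free controls that saturate near 10^9 cells/ml
but defaults to infinity everywhere, since lysis rather than resource
scarcity limits hosts on the modelled horizons. Bacterial traits are
constant in time; there is no resistance evolution, no stochastic
(Gillespie) dynamics, no MOI-dependent intracellular outcomes, and no
spatial structure.

### Default infection network

The packaged five-host/five-phage network has nine interactions, modular
between the CBA and PSA groups: phi38:1 → {CBA 38, CBA 18}; phi18:2 →
{CBA 18}; phi18:3 → {CBA 4, CBA 18}; PSA-HP1 and PSA-HS6 → {PSA H100,
PSA 13-15}. The matrix is an ordinary CSV input, not hard-coded.

## Numerics

The core integrator is an adaptive Dormand–Prince 5(4) stepper compiled
with numba, with error control `rtol = 1e-8`, `atol = 1e-2` cells/ml by
default (likelihood evaluations use `rtol = 1e-6`). Steps are shortened to
land exactly on requested output times, so no interpolation error enters
reported grids. The compiled path exists because Bayesian fits need ~10^3–
10^4 ODE solutions per chain; a generic scipy `solve_ivp` path is provided
for user-supplied systems, and the test suite cross-checks the compiled
solver against both scipy RK45 and a fixed-step RK4 oracle (dt = 1e-3 h,
relative sup-norm agreement ~1e-8, asserted < 1e-4). States are clipped to
zero on output; pre-clip negative excursions beyond solver-tolerance scale
raise an integration error, as does step-size underflow (the error carries
the failure time).

Degenerate inputs: `N_E = 0` collapses the chain to `S → I` directly;
`D_c = ∞` disables attenuation; `φ = 0` decouples phage from hosts.

## Trait estimation (conventional)

Growth rate: least-squares slope of ln(density) vs time; the window
defaults to the longest contiguous run (≥ 3 points) with log-linear
R² ≥ 0.995, and is caller-overridable. Adsorption rate: `φ = −slope(ln
V_free vs t)/B` with constant cell density `B`, using all points in the
assay window. Latent period: earliest time the replicate-mean free-phage
curve exceeds baseline mean + z·SD (z = 3, configurable; baseline = first
two points), linearly interpolated between bracketing samples; a flat curve
returns a no-burst sentinel. The paper-style burst size is
`⟨β⟩ = (⟨V₂⟩−⟨V₁⟩)/(⟨T₁⟩−⟨V₁⟩)` with caller-specified pre/post-burst
windows. The first-rise latent period is biased low whenever the latent
distribution has positive variance (the first lysing cells are early-tail
draws); at CV = 0.1 the bias is ~25–30% and the acceptance checks assert
the direction on 100 seeded synthetic curves. OD→CFU conversion is a
log-log regression on user-supplied calibration pairs.

## Synthetic data

Generators reproduce the three study designs: (a) one-step growth curves —
10^8 cells/ml and MOI 0.1, a 15-min adsorption phase, instantaneous exact
1:100 dilution of every state variable, then 5-min free/total-phage
sampling over the lytic cycle; (b) pairwise multi-cycle infections —
2×10^6 CFU/ml, MOI 0.1, qINT/qEXT sampling at 0, 3.5 and 15.75 h with
phage-free controls; (c) the community experiment — five hosts at 2×10^6
cells/ml, five phage at a flask-wide MOI of 0.1 (each phage at
`0.1 × total cells / 5`, matching the printed inoculation totals; a
per-phage MOI convention is also implemented), triplicate sampling every
35 min for 15.75 h (28 points).

Measurement noise is multiplicative log-normal: additive Gaussian noise of
SD `σ_obs` on log₁₀ densities, default 0.15 (resembling qPCR replicate
scatter), with a detection floor of 10² per ml; censored records keep the
floor value and a flag, and are excluded from likelihoods. The generators
do **not** emulate qPCR chemistry, plating error, OD optics,
replicate-level biological variability (replicates share one trajectory and
differ only in noise), or resistance emergence — so passing recovery tests
demonstrate correctness of the inference machinery under the stated noise
model, not robustness to real-data systematics.

## Bayesian inference

Likelihood: Gaussian on log₁₀ densities with per-observable scale σ, every
replicate an independent term; integration failures map to −∞. σ may be
fixed or inferred as a nuisance parameter with a weak log-normal prior
(median 0.15, log₁₀-scale 0.3).

Priors: positive traits (φ, τ, β, D_c, σ) carry log-normal priors —
normal in log₁₀, where sampling happens; `N_E` carries a wide truncated
normal on [0, 200] and is sampled continuously but rounded to the nearest
integer before each likelihood evaluation. One-step priors are centred on
the conventional estimates (φ scale 0.5, τ 0.15, β 0.3 in log₁₀ units).
Community priors default to generic centres (φ 10⁻⁷/0.5, τ 1 h/0.3,
β 50/0.5, D_c 10⁶/0.7); the latent CV is shared (one `N_E`) across pairs.
The scales were chosen weakly informative; the 2×2 coverage benchmark
(below) is the calibration check that they do not over-constrain.

Sampler: adaptive Metropolis with multivariate normal proposals at scale
`2.38²/d` times the running empirical covariance (Welford update,
regularisation 10⁻⁶·I), adaptation starting after 10% of the chain, plus
one delayed-rejection stage retrying a 0.2-scaled proposal with the
acceptance ratio that preserves detailed balance. Burn-in 50%, no thinning.
Correctness checks: exact seed-determinism, bounded-support containment,
moment recovery on known Gaussians, and a KS distance < 0.02 against a 1-d
Gaussian at 10⁵ draws.

Workflow: a cyclic coordinate-descent line search (bounded Brent per
coordinate, monotone objective) initialises chains. For community fits one
replicate is fitted by coordinate descent to re-centre the priors and the
remaining replicates enter the likelihood; the fit window may truncate the
data span (the 6.4 h option reproduces the short-window refit design).
Community SEIV vs SEIVD mode toggles the per-host `D_c_i` block.
Diagnostics: split-R̂ (single chains are split into halves), Geyer
initial-positive-sequence ESS, acceptance rate, and posterior-predictive
2.5/50/97.5% envelopes with data-coverage fractions.

Equivalence testing: traits are compared on the log₁₀ scale with a region
of practical equivalence of half-width 0.1 (≈ ±26% multiplicative,
configurable). `p_eq` is the probability that |Δlog₁₀| lies inside the
ROPE, computed exactly over all cross pairs of the two posterior draw sets
(order-statistics computation, symmetric in its arguments by construction).
Verdicts: "minor difference" at p_eq ≥ 0.95, "shift" at p_eq ≤ 0.05, else
inconclusive; no multiple-testing correction is applied across traits.

## Benchmark problem sizes

The recovery and coverage harnesses in `seivd.benchmarks` state their
sizes explicitly: one-step recovery uses 20 seeds × 2500-step chains with
σ_obs = 0.1 and the noise scale fixed at truth; community coverage uses a
2-host/2-phage, 3-pair SEIVD benchmark (triplicate 28-point design,
σ_obs = 0.15) with 10 runs × 5000-step chains over 11 parameters (per-pair
φ, τ, β and per-host D_c; shared `N_E` fixed). The crash/collapse/rescue
benchmarks use the representative trait set φ = 10⁻⁷ ml/h, β = 50,
N_E = 99, r = ln2/4 h⁻¹ at S₀ = 2×10⁶ cells/ml, V₀ = 2×10⁵ virions/ml:
τ = 1 h for the one-step-regime crash and community collapse, τ = 4 h for
the D_c rescue grid. The τ = 4 h variant is the parameter set for which
the crash-vs-rescue dichotomy holds over the entire D_c range 10⁵–5×10⁶
cells/ml: with τ = 1 h the viral population grows so explosively that
debris (bounded by cumulative lysis, ~4×10⁶ cells/ml) cannot attenuate
infection enough at D_c ≳ 10⁶, and the host still crashes — a genuine
property of the model, confirmed with an independent stiff solver at tight
tolerances.

## Known limitations

- The equivalence between pairwise and community traits is tested on
  synthetic scenarios; no claims about the original biological system are
  produced by this package.
- `N_E` rounding makes the posterior over `N_E` piecewise-constant;
  credible intervals for `N_E` should be read at integer resolution.
- The community fit shares one latent CV across pairs; strain-dependent
  variability is not modelled.
- Left-censored observations are excluded from likelihoods rather than
  integrated (no Tobit-style censored likelihood).
- DRAM is a random-walk sampler; posteriors over ~15+ parameters need
  visibly longer chains (watch R̂ and ESS in the summary output).
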