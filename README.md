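# seivd

Phage–bacteria community dynamics with density-dependent feedback:
compartmental SEIV/SEIVD infection models, conventional and Bayesian
life-history trait inference, and synthetic experiment generators.

## The problem

Virulent phage infecting marine heterotrophic bacteria (*Cellulophaga
baltica* and *Pseudoalteromonas* strains) can be characterised pairwise by
four life-history traits: the host growth rate *r* (1/h), the adsorption
rate φ (ml/h), the mean latent period τ (h), and the burst size β (virions
per lysed cell). Embedding traits measured in short, one-step growth
experiments into multi-cycle population models predicts rapid bacterial
collapse — yet in longer experiments hosts persist, and five-host /
five-phage communities coexist. This package implements the modelling and
inference machinery to study two stabilising mechanisms: **density-dependent
infection attenuation** (a debris-mediated negative feedback) and
**higher-order interactions** (traits that differ between pairwise and
community contexts).

## Models

The pairwise SEIV model tracks susceptible cells *S*, a chain of *N_E*
exposed stages *E₁…E_{N_E}*, infected (lysis-committed) cells *I*, and free
virions *V*:

    dS/dt   = r S − θ(D) φ S V
    dE₁/dt  = θ(D) φ S V − k E₁
    dE_m/dt = k (E_{m−1} − E_m)
    dI/dt   = k (E_{N_E} − I)
    dV/dt   = β k I − θ(D) φ S V
    dD/dt   = k I

with stage rate k = (N_E + 1)/τ, so the adsorption-to-lysis transit time is
Erlang with mean τ and coefficient of variation 1/√(N_E + 1) (the linear
chain trick). The SEIVD variant adds cumulative lysed-cell debris *D* which
attenuates the infection flux through a Hill function
θ(D) = 1 / (1 + (D/D_c)²); θ ≡ 1 (SEIV) when D_c = ∞. The community model
couples 5 hosts and 5 phage through a boolean infection matrix (9 of 25
interactions in the packaged default), with per-pair trait sets, a shared
debris pool and per-host thresholds D_c_i; multiple infection is excluded.

Inference is by delayed-rejection adaptive Metropolis (DRAM): Gaussian
likelihoods on log₁₀ densities, truncated-normal/log-normal priors,
coordinate-descent initialisation, split-R̂ and effective-sample-size
diagnostics, posterior-predictive envelopes, and a Bayesian practical-
equivalence test (ROPE on the log₁₀ scale, probability p_eq) for comparing
traits across contexts.

## Worked example

```python
import math
import numpy as np

from seivd import TraitSet, simulate_pairwise, observe
from seivd.synthetic import ExperimentDesign, NoiseModel, generate_onestep
from seivd.inference import fit_pairwise_onestep, SamplerSettings

traits = TraitSet(r=math.log(2) / 4, phi=1e-7, tau=1.0, n_exposed=99, burst_size=50)

# multi-cycle forecast: SEIV crash vs SEIVD rescue
t = np.linspace(0, 16, 65)
seiv = observe(simulate_pairwise(traits, 2e6, 2e5, t), "host_qINT")
seivd = observe(
    simulate_pairwise(traits.with_(tau=4.0, debris_halfsat=1e6), 2e6, 2e5, t), "host_qINT"
)
print(f"SEIV  host minimum: {seiv.min():.2e} cells/ml  ({seiv[0] / seiv.min():.1e}-fold decline)")
print(f"SEIVD host minimum: {seivd.min():.2e} cells/ml  (persists)")

# Bayesian trait recovery from a synthetic one-step growth curve
design = ExperimentDesign.onestep()          # 15-min adsorption, 1:100 dilution
data = generate_onestep(traits, design, NoiseModel(sigma_obs=0.1), seed=1)
post = fit_pairwise_onestep(data, design, r=traits.r, sigma=0.1,
                            settings=SamplerSettings(n_steps=2500), seed=1)
for name in ("phi", "tau", "beta"):
    lo, hi = post.ci(name)
    print(f"{name:5s} median {post.median(name):.3g}   95% CrI [{lo:.3g}, {hi:.3g}]")
```

Output:

```
SEIV  host minimum: 2.05e-03 cells/ml  (9.7e+08-fold decline)
SEIVD host minimum: 1.17e+04 cells/ml  (persists)
phi   median 1.01e-07   95% CrI [9.7e-08, 1.06e-07]
tau   median 1   95% CrI [0.987, 1.02]
beta  median 49.5   95% CrI [47.4, 51.6]
```

The first two lines show the crash-vs-rescue dichotomy: without attenuation
the model predicts a ~10⁹-fold host decline within 16 h, while debris
feedback (here D_c = 10⁶ cells/ml) keeps the host above 10⁴ cells/ml. The
fit recovers the generating traits (φ = 10⁻⁷ ml/h, τ = 1 h, β = 50) from a
noisy synthetic one-step curve, with 95% credible intervals.

A command-line interface mirrors the library:

```sh
seivd simulate --model seivd --traits traits.csv --t-end 15.75 --out run/
seivd generate --scenario community --truth traits.csv --matrix matrix.csv --out data/
seivd fit --model onestep --data data/onestep_data.csv --seed 1 --out fit/
seivd compare-traits --post-a fitA/posterior.csv --post-b fitB/posterior.csv --rope 0.1
```

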