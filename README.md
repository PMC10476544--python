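# dsemcfa

Two-level dynamic confirmatory factor analysis for intensive longitudinal
item panels — the kind of data produced when a clinical questionnaire (for
example a 7-item, 0–3 mood subscale) is answered repeatedly across therapy
sessions. The package is aimed at psychometricians and applied
methodologists who want to know **how reliably an instrument measures
stable between-person differences versus session-to-session within-person
change**, while respecting the serial dependence between adjacent sessions.

## Model

Each observed response decomposes into a person-level (trait) part and an
occasion-level (state) part:

    y_itk = ν_k + λ_b,k η_b,i + ε_b,ik  +  λ_w,k η_w,it + ε_w,itk

The occasion-level factor follows a person-specific AR(1):

    η_w,it = φ_i η_w,i(t-1) + ζ_it,      ζ_it ~ N(0, σ²_ζ,i)

and the person-level triple (η_b,i, φ_i, log σ²_ζ,i) — trait, carryover,
log innovation variance — is multivariate normal with mean γ + β'x_i and
covariance Σ_b, so carryover and volatility are themselves random effects
that may be predicted by person covariates (e.g., a gender dummy).

Estimation is Bayesian: a Gibbs sampler with forward-filtering
backward-sampling for the latent states, a marginalized Metropolis step
for (φ_i, log σ²_ζ,i) (states integrated out by a scalar Kalman filter),
conjugate updates for the measurement and structural blocks, two chains,
first-half burn-in, and the potential scale reduction (PSR) diagnostic
with automatic iteration doubling and a guard re-run.

Derived outputs mirror the standard reporting of this framework:

- per-item **ICC** (share of variance at the person level),
- per-item **within/between R²** (level-specific reliability),
- **cross-level invariance tests** — posterior of λ_b,k − λ_w,k with a
  95% interval flag — plus data-driven **anchor selection** via a
  mutual-invariance clique over cross-level loading ratios,
- random-effect **correlations** (φ with ζ, φ with trait, ζ with trait),
- **conditional covariate effects** on trait, carryover, and volatility.

## Worked example

```python
import numpy as np
from dsemcfa import (default_true_parameters, simulate_panel, ModelSpec,
                     McmcSettings, run_mcmc, summarize, compute_icc,
                     loading_difference_test)

params = default_true_parameters()          # study-style 7-item truth
data, effects, states = simulate_panel(params, n=333, seed=1)

spec = ModelSpec(item_ids=list(params.item_ids), anchor_item="item_1")
samples = run_mcmc(data, spec, McmcSettings(n_chains=2, n_iterations=2000, seed=2))
s = summarize(samples)

print("mean carryover     ", s["gamma_phi"])
print("ICC item_1         ", compute_icc(samples, "item_1"))
print("invariance item_2  ", loading_difference_test(samples, "item_2"))
```

Output from this exact script (seeds included; values rounded to 3 dp):

```
mean carryover      {'point': 0.514, 'ci_low': 0.413, 'ci_high': 0.598, 'psr': 1.005}
ICC item_1          {'point': 0.298, 'ci_low': 0.244, 'ci_high': 0.348}
invariance item_2   {'point': 0.099, 'ci_low': -0.099, 'ci_high': 0.316, 'invariant': True}
```

The mean carryover interval covers its generative truth of 0.454 — about
45% of a person's latent state deviation persists to the next session.
The ICC near 0.30 says roughly 30% of that item's variance reflects
stable between-person differences. Item 2's generative cross-level gap
is λ_b − λ_w = 0.243, and the posterior of the difference leans positive
but its interval still includes zero: differences of this size sit right
at the detection limit of a panel of this length, which is worth keeping
in mind when reading such invariance tables.

A command-line pipeline wraps the same functionality
(`dsemcfa simulate|fit|recover|report --config config.yaml`), writing
validation, anchor-selection, measurement-table, structural-table and
recovery artifacts plus a seed-stamped manifest.

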