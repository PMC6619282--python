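# frailtysim

Shared-frailty survival modelling, diagnostics and scenario simulation for
clustered and recurrent event data — built to study a specific confounding:
**when does a time-dependent covariate effect masquerade as unobserved
heterogeneity?**

## The scientific problem

A shared frailty model assumes proportional hazards *conditional* on an
unobserved cluster-level random effect Z (mean 1, variance sigma^2):

    lambda(t | Z_i, x_ij) = Z_i Y_ij(t) lambda0(t) exp(x_ij' beta).

Marginally, survivors are selected for low Z, so the observed hazard ratio
between covariate groups shrinks over time even though beta is constant.
A genuinely time-dependent effect beta(t) with *no* frailty produces the
same marginal picture.  With clusters (or recurrent events per subject) the
within-cluster dependence is extra information that should separate the two
explanations — but only if enough of the dependence structure is observed.
This package quantifies how large clusters must be before a frailty-model
likelihood ratio test stops mistaking nonproportional hazards for frailty.

It provides:

* **`frailtysim.families`** — Laplace-transform calculus for gamma, inverse
  Gaussian, positive stable and lognormal frailty: transforms, exact signed
  derivatives, posterior means `-L^(N+1)(c)/L^(N)(c)`, marginal hazard-ratio
  curves, and the median concordance `kappa = 4 L(2 L^{-1}(1/2)) - 1`.
* **`frailtysim.simulate`** — a scenario generator with Weibull baselines
  (`Lambda0(50) = 0.8`, or `0.8 j` for recurrent designs), log-time covariate
  effects `beta(t) = log 5 + beta1 log t`, lognormal or gamma shared
  frailty, and administrative censoring calibrated to a 30% rate.
* **`frailtysim.cox`** — counting-process Cox/Breslow machinery with offsets
  (needed by the EM), Schoenfeld and martingale residuals.
* **`frailtysim.em`** — semiparametric shared-frailty fitting by profile EM
  over the association parameter, the boundary-mixture likelihood ratio
  test (p = P(chi2_1 >= T)/2; 5%-level threshold 2.7055), and
  profile-likelihood intervals for the frailty variance.
* **`frailtysim.diagnostics`** — a Commenges-Andersen-style heterogeneity
  score test and the scaled-Schoenfeld (Grambsch-Therneau) proportional
  hazards test with the Kaplan-Meier time transform.
* **`frailtysim.pipeline`** — replication grids over the design cells and
  the kidney-catheter worked analysis.

See `docs/methods.md` for model details, parametrizations and numerical
choices.

## Worked example

Simulate one clustered cell with **no frailty** but a strong time-dependent
effect (beta(t) = log 5 - 0.41 log t, so the effect vanishes at t = 50),
then ask a gamma frailty model whether it "sees" heterogeneity:

```python
import numpy as np
from frailtysim.simulate import ScenarioConfig, resolve_scenario, simulate_dataset
from frailtysim.em import fit_frailty, lrt_no_frailty
from frailtysim.cox import fit_cox
from frailtysim.diagnostics import zph_test

cell = resolve_scenario(ScenarioConfig(
    structure="clustered", group_size=2, total_size=300,
    weibull_shape=1.0, beta1_level=2, frailty_variance=0.0,
), calib_seed=3)
data = simulate_dataset(cell, seed=7)

cox = fit_cox(data)
print(f"ZPH p-value:               {zph_test(cox).p_value:.2e}")

fit = fit_frailty(data, "gamma")
print(f"frailty variance estimate: {fit.var_hat:.3f}")
print(f"mixture-LRT p-value:       {lrt_no_frailty(fit).p_value:.4f}")
```

Output:

```
ZPH p-value:               1.90e-05
frailty variance estimate: 0.237
mixture-LRT p-value:       0.0268
```

The proportional-hazards test correctly flags nonproportionality, but the
frailty model also reports a "significant" variance of about 0.24 — spurious
evidence of heterogeneity, produced entirely by the time-dependent effect.
Over 500 such replicates the gamma LRT rejects about 12% of the time at
nominal 5% (and about 31% in the matched recurrent-events design), while
the positive stable LRT stays near level — the package's central
quantitative finding.

A CLI mirrors the library: `frailtysim simulate`, `fit`, `test`, `grid`,
`kidney` (see `frailtysim --help`).

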