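# pathwayid

Sequential Bayesian identification of branched chemical transformation
pathways and their kinetic rate constants.

## The problem

When a chemical degrades in a complex biological matrix — the motivating
case is illicit-drug biomarkers (heroin, codeine and their human
metabolites) in untreated wastewater — it transforms along a branched
network of abiotic (e.g. hydrolysis) and microbially-mediated reactions.
Wastewater-based epidemiology needs the transformation rate constants of
every compound in that network, with honest uncertainties, to
back-calculate drug consumption from sewer measurements.  Estimating all
rates at once from batch-experiment time series is badly conditioned:
parameters compensate for each other, posteriors smear out, and a wrong
pathway structure (a missing transformation branch) goes unnoticed.

`pathwayid` implements a level-wise alternative.  The pathway is
decomposed into calibration levels that follow the flow of mass, each
level estimates only the rate constants it can identify, and the
posterior of each parameter — its 95% credibility interval *and* its
fitted distribution shape — becomes the prior wherever that parameter
appears downstream.  Between levels, mass-balance diagnostics test the
assumed structure and propose new branches to unknown transformation
products.

## Model

Each compound obeys first-order kinetics in the style of the Activated
Sludge Modelling framework for Xenobiotics (ASM-X):

    dC_i/dt = Σ_j∈form(i) ν_j r_j − Σ_j∈rem(i) r_j,
    r_j = k_abio,j · C_src(j)            (abiotic edges, k in d⁻¹)
    r_j = k_bio,j · X_TSS · C_src(j)     (biotic edges, k in L gTSS⁻¹ d⁻¹)

so a network is a linear ODE system solved exactly by a matrix
exponential.  A compound with two branches gets a *combinatorial*
parameter (the sum of its branch rates) estimated first; the branch
members become *primary* parameters at a later level, sampled jointly
under a soft constraint keeping their sum inside the total's 95% CrI.

Estimation is adaptive differential-evolution MCMC (DE-MC with sampling
from the past, snooker updates and subspace crossover) on the
range-normalised sum of squared errors

    SSE = Σ_i Σ_j ((ŷ_ij − y_ij)/(ŷ_i,max − ŷ_i,min))²,

mapped to a Gaussian log-likelihood with profiled variance.  Posterior
draws are screened with the Theil inequality coefficient (TIC ≤ 0.3).
Two benchmark schemes are included: Method 2 (the "lumped" approach —
all parameters of a model at once, wide uniform priors) and Method 3
(sequential, but upstream parameters frozen at their medians and branch
pairs reparameterised as member₁ = total − member₂).

## Worked example

A parent compound `PAR` with two observed first-order branch products:
generate a noisy synthetic batch experiment, calibrate with the
sequential method (Method 1) and with fixed-upstream Method 3, and
compare the branch-pair correlation:

```python
import numpy as np
from pathwayid import (
    CalibrationConfig, SamplerConfig, calibrate_method1, calibrate_method3,
    two_branch_fixture,
)

net, synth = two_branch_fixture(seed=1)
config = CalibrationConfig(sampler=SamplerConfig(n_chains=5, max_evals=20_000, seed=1))

m1 = calibrate_method1(net, synth.dataset, config)
m3 = calibrate_method3(net, synth.dataset, config)

print(m1.parameter_table().to_string(index=False))
for label, res in (("Method 1", m1), ("Method 3", m3)):
    stage = res.stages[-1]
    r = np.corrcoef(stage.column("k_abio_PAR_1"), stage.column("k_abio_PAR_2"))[0, 1]
    print(f"{label}: branch LCC = {r:+.3f}")
```

Output:

```
       param   median   cri_lo   cri_hi     family  combinatorial
   k_abio_M1 0.507519 0.479551 0.542230 genextreme          False
   k_abio_M2 0.290644 0.271788 0.311388 genextreme          False
  k_abio_PAR 1.985149 1.895947 2.076458   logistic           True
k_abio_PAR_1 1.190407 1.137002 1.244507 genextreme          False
k_abio_PAR_2 0.797608 0.758313 0.842158 genextreme          False
Method 1: branch LCC = +0.234
Method 3: branch LCC = -1.000
```

The generating rates were k_PAR,1 = 1.2, k_PAR,2 = 0.8, k_M1 = 0.5,
k_M2 = 0.3: every 95% CrI covers its true value, and the combinatorial
total (1.99 ≈ 1.2 + 0.8) was estimated before the split.  The last two
lines show the identifiability contrast at the heart of the method:
under Method 3's hard constraint the two branch rates are perfectly
anti-correlated (Pearson r = −1, structurally non-identifiable at any
|r| > 0.7 threshold), while Method 1's soft sum-constraint leaves the
pair individually identifiable.

The six-biomarker wastewater fixture (HER, 6MAM, MOR, MORG, COE, NCOE
with 7 abiotic + 9 biotic rate constants over four levels) is available
as `heroin_codeine_fixture(seed)`, and the same workflow runs from the
shell:

```sh
pathwayid synth --fixture heroin --seed 7 --out fx/
pathwayid calibrate --method 1 --pathway fx/network.yaml --data fx/data.csv \
    --seed 7 --out run/
pathwayid assess --pathway fx/network.yaml --data fx/data.csv \
    --samples run/final_samples.csv --out report/
pathwayid discover --pathway fx/network.yaml --data fx/data.csv --out gaps/
```

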