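# compmi

Missing-data methods for **binary composite endpoints** in randomized
controlled trials.

A composite endpoint classifies a participant as having an event if a
Boolean combination of binary components holds — "at least one bleeding
event in 30 daily assessments", "death or positive culture". When the
components are partially observed (and not missing simultaneously), a
superficially attractive strategy is to *derive* the endpoint from observed
components where they determine it (an OR-composite is 1 as soon as any
observed component is 1) and exclude the remaining participants. `compmi`
shows why that strategy is dangerous and what to do instead. It provides:

- **`compmi.analytic`** — exact closed forms for the two-component setting:
  even when a component is missing completely at random (MCAR), the derived
  endpoint's missingness depends on the outcome itself (MNAR), and the
  derived-endpoint odds ratio is biased by the factor
  `[1−(1−α)σ]/[1−(1−α)τ]` (σ, τ = per-arm shares of events carried by the
  incomplete component alone; α = its observation probability), while
  complete-record analysis remains valid under MCAR.
- **`compmi.dgm`** — a saturated log-linear generator of three correlated
  binary components per arm, `p_c ∝ exp(LP_c)` over the 8 combinations,
  calibrated so the composite event rates are expit(0.3) ≈ 0.57 (control)
  and expit(1.65) ≈ 0.84 (treatment), i.e. a true treatment log odds ratio
  of 1.35.
- **`compmi.missingness`** — logistic response models for the components
  with MCAR/MAR1/MAR2 presets.
- **`compmi.composite`** — monotone (AND/OR) composite definitions
  evaluated under three-valued Kleene logic: derivability is definedness.
- **`compmi.mi`** — multiple imputation at composite level (MI-CRA,
  MI-Deriv) and component level via chained equations (MIC-main, MIC-x,
  MIC-x-z1), with proper parameter draws, perfect-prediction augmentation,
  and Rubin's-rules pooling.
- **`compmi.analysis`** — the substantive models (logistic log OR; risk
  difference via the identity-link binomial closed form) behind a single
  eight-method dispatcher.
- **`compmi.simstudy`** — a factorial simulation harness with bias,
  empirical/model SE and coverage, each with Monte Carlo errors.
- **`compmi.blocks`** — a pipeline for composites built from 30 daily
  assessments grouped into six five-day blocks, including adjacent-block
  chained-equations imputation and a synthetic daily-data generator.

See `docs/methods.md` for the models, assumptions, defaults, and
limitations.

## Worked example

Closed-form bias surface for two independent components at 0.7 vs 0.2 per
arm:

```sh
compmi bias-surface --trt-marginals 0.7,0.7 --ctrl-marginals 0.2,0.2 --alphas 0.3,0.6,0.9
```

```text
alpha,sigma,tau,or_full,or_deriv,ratio
0.3,0.2307692307692308,0.4444444444444444,17.9753086419753,21.87813620071684,1.21712158808933
0.6,0.2307692307692308,0.4444444444444444,17.9753086419753,19.84384384384384,1.103950103950104
0.9,0.2307692307692308,0.4444444444444444,17.9753086419753,18.37726098191214,1.0223613595706618
```

With 70% of the incomplete component missing (alpha 0.3), the derived
endpoint overstates the odds ratio by 22%; the bias vanishes as alpha → 1.

The same story by simulation — one trial of n = 2000 with components masked
under a MAR mechanism, analyzed four ways:

```python
from compmi.dgm import case_params, simulate_trial
from compmi.missingness import PRESETS, apply_missingness
from compmi.composite import simple_composite
from compmi.analysis import analyze_with_method
from compmi.mi import ImputationSpec

ctrl, trt = case_params("I", "simple")
full = simulate_trial(2000, 0.5, ctrl, trt, "simple", seed=7)
masked = apply_missingness(full, PRESETS["MAR1"], PRESETS["MAR1"], seed=8)
spec = ImputationSpec(m=25, burnin=20, augment=True, seed=9)
for method in ("Full", "CRA", "Deriv", "MIC-x"):
    r = analyze_with_method(masked if method != "Full" else full,
                            simple_composite(), method, spec=spec)
    print(f"{method:8s} {r.estimate: .3f}  (SE {r.se:.3f}, n={r.n_analyzed})")
```

```text
Full      1.396  (SE 0.110, n=2000)
CRA       1.385  (SE 0.173, n=920)
Deriv     1.702  (SE 0.164, n=1506)
MIC-x     1.100  (SE 0.139, n=2000)
```

The true log odds ratio is 1.35. The derived endpoint (`Deriv`) lands more
than two standard errors high on this replicate — its bias is systematic,
as the simulation harness shows over hundreds of replicates
(`compmi simstudy`) — while complete records analyze less than half the
sample. Component-level MI keeps everyone in the analysis with valid
coverage on average (any single replicate, like this one, scatters around
the truth).

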