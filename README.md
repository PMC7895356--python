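# nata — non-adherence tree analysis

`nata` predicts **medication non-adherence before a treatment starts** by
borrowing fault-tree analysis from reliability engineering.  Discontinuation
of a regimen is modelled as the *top event* of a Boolean tree whose leaves
are non-adherence factors (side effects, forgetfulness, supply failures, …),
each carrying a per-day hazard estimated from previous adherence studies.
The package is aimed at clinicians, trial designers and health-services
researchers who want to rank adherence barriers and size interventions
before the first pill is dispensed.

It ships with a worked case study: a hypothetical 10-day out-patient
COVID-19 antiviral regimen for 1000 participants, with factor rates pooled
from six published oseltamivir adherence studies and the tree organised by
the five WHO adherence dimensions (social/economic, patient-, condition-,
healthcare- and therapy-related).

## The model

**Rate pooling.**  A study with `NoP` participants over a `DoM`-day regimen
reporting `count` discontinuations for a factor yields

```
NARS = count / NoP          (per-study proportion)
NAR  = NARS / DoM           (per-day rate)
WNAR = Σᵢ NARᵢ · NoPᵢ / GrandNoP,   GrandNoP = Σᵢ NoPᵢ
```

where the weighted rate pools all studies, with non-observing cohorts still
counted in `GrandNoP`.

**Probability.**  An exponential factor with rate λ occurs within `d` days
with probability `P = 1 − e^(−λd)`.  Independent events combine through the
gates: OR as `1 − Π(1 − Pᵢ)`, AND as `Π Pᵢ`, and priority-AND (all events in
a fixed order) through the standard exponential closed form with partial
rate sums `aₘ = −Σ λⱼ`.

**Simulation.**  A seeded Monte Carlo cohort simulator steps each patient
hourly through the regimen: competing leaf hazards fire with probability
`1 − e^(−r·Δt)` per step, repairable supply subsystems alternate between up
and down states, decaying and age-stratified rates are supported, and the
first event that satisfies a minimal cut set absorbs the patient as
non-adherent.  Attribution of each discontinuation to its triggering factor
gives the contribution ranking, and `apply_improvement` re-runs what-if
scenarios under common random numbers.

## Worked example

```python
from nata import (SimulationConfig, simulate, summarize_uncertainty,
                  contributions, apply_improvement, mean_nac_ratio, wnar)
from nata.fixtures import covid_tree, six_studies

studies = six_studies()
print(f"pooled WNAR for side effects: {wnar(studies, 'SidEff'):.3E} per day")
print(f"mean NAC/NoP ratio across studies: {mean_nac_ratio(studies):.2f}")

tree = covid_tree(studies)
result = simulate(tree, SimulationConfig(patients=1000, days=10, seed=1))
s = summarize_uncertainty(result)
print(f"Day-10 P(NA): {s['mean']:.3f}  (sd {s['sd']:.2f}, "
      f"90% band {s['ci5']:.3f}-{s['ci95']:.3f})")
print(f"non-adherent participants: {result.non_adherent} of {result.patients}")

shares = contributions(result)["factors"]
top3 = sorted(shares.items(), key=lambda kv: -kv[1])[:3]
print("top contributors:", ", ".join(f"{f} {v:.1f}%" for f, v in top3))

improved = apply_improvement(tree, {"SidEff": 0.2, "Forgot": 0.2,
                                    "NoSym": 0.2, "Other": 0.2})
better = simulate(improved, SimulationConfig(patients=1000, days=10, seed=1))
print(f"after a 20% cut of the four main factor rates: "
      f"{better.final_p_na:.3f} ({better.non_adherent} non-adherent)")
```

prints

```
pooled WNAR for side effects: 8.315E-03 per day
mean NAC/NoP ratio across studies: 0.17
Day-10 P(NA): 0.255  (sd 0.44, 90% band 0.232-0.278)
non-adherent participants: 255 of 1000
top contributors: SidEff 30.2%, Forgot 22.4%, NoSym 22.4%
after a 20% cut of the four main factor rates: 0.222 (222 non-adherent)
```

A single cohort is noisy (the binomial standard error at p ≈ 0.22,
n = 1000 is ≈ 0.013; this seed happens to draw high): averaging ten
replicates with `simulate_replicates(tree, SimulationConfig(seed=1,
replicates=10))` gives a mean Day-10 P(NA) of 0.221, and about one in five
participants is predicted to miss at least one pill.  Side effects are the
single biggest driver, so an intervention portfolio that trims the four
leading factor rates by 20% each buys roughly a 3–4 percentage-point
adherence gain — visible in the paired runs above because both use the same
random numbers.

The same analyses are available from the shell:

```sh
nata fixtures --export demo/
nata rates --studies demo/six_studies.csv
nata mcs --tree demo/covid_tree.yaml
nata analytic --tree demo/scenario.yaml --duration 10
nata simulate --tree demo/covid_tree.yaml --patients 1000 --seed 1
nata improve --tree demo/covid_tree.yaml --reduce SidEff=0.2 --reduce Forgot=0.2
```

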