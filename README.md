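# comoyld

Multimorbidity-adjusted years-lost-to-disability (YLD) rates via Monte-Carlo
comorbidity (COMO) simulation.

## The problem

Prevalence-based burden-of-disease studies compute the YLD rate of a disease
sequela as

```
YLD rate_k = prevalence_k × DW_k
```

where `DW_k ∈ [0, 1]` is the disability weight of the sequela's health state.
Summing these rates over sequelae implicitly assumes that disabilities add,
but a person carrying several sequelae at once is not "more than fully
disabled": simple addition overstates the burden, and the bias grows with age
because multimorbidity does.  This package implements the standard correction
used in national burden-of-disease studies, aimed at epidemiologists and
health-metrics analysts who need comorbidity-adjusted YLD rates with
uncertainty, from per-stratum (sex × age band × year) sequela prevalence
tables.

## The model

For each stratum a population of *n* simulants is drawn; simulant *l* is
exposed to sequela *k* independently with probability `p_k` (the prevalence as
a per-person probability).  Its combined disability weight over the set *J_l*
of sequelae it carries is multiplicative,

```
DW_l = 1 − ∏_{k∈J_l} (1 − DW_k),
```

and is attributed back to each sequela in proportion to that sequela's own
weight,

```
ADW_lk = DW_k / Σ_{j∈J_l} DW_j × DW_l .
```

The adjusted YLD rate of sequela *k* is the population mean
`Σ_l ADW_lk / n` (simulants without the sequela contribute zero), and the
whole simulation is repeated (default 1,000 times at 40,000 simulants each)
to obtain 2.5th/97.5th-percentile uncertainty intervals.  An exact
enumeration oracle computes the estimator's expectation in closed form over
all `2^K` exposure subsets for slices of up to 20 sequelae, and serves as the
independent check on the engine.  Aggregation is additive across
sequela → cause → disease group → total (the five groups being NCDs, CDs,
Injuries, MNNs and MDs), with percent change
`100 × (adjusted − unadjusted)/unadjusted` and detection of cause-ranking
shifts of 3 or more steps.

## Worked example

```python
from comoyld import (SimulationConfig, Stratum, exact_adjusted_yld,
                     oracle_fixture, percent_change, run_stratum)

slice_ = oracle_fixture("pair-half")   # two sequelae: p=0.5/0.5, DW=0.4/0.2
stratum = Stratum("female", "60-69", 2015)
config = SimulationConfig(n_simulants=40_000, n_repetitions=200, master_seed=7)
result = run_stratum(slice_, config, stratum)
for sid, (adj, lo, hi) in result.per_sequela.items():
    unadj = result.unadjusted[sid]
    print(f"{sid}: unadjusted {unadj:.1f} -> adjusted {adj:.2f} "
          f"(95% CI {lo:.2f}-{hi:.2f}), change {percent_change(unadj, adj):+.1f}%")
print("exact :", {k: round(v, 2)
                  for k, v in exact_adjusted_yld(slice_).per_sequela.items()})
```

prints

```
s1: unadjusted 200.0 -> adjusted 186.66 (95% CI 184.74-188.64), change -6.7%
s2: unadjusted 100.0 -> adjusted 93.35 (95% CI 92.51-94.27), change -6.6%
exact : {'s1': 186.67, 's2': 93.33}
```

Each sequela's YLD rate (per 1,000 population) drops once the other's
co-occurrence is accounted for — here by ≈6.7%, because one person in four
carries both sequelae — and the Monte-Carlo estimates sit on top of the exact
enumeration values.

The same pipeline runs from the shell: `comoyld synth` writes a synthetic
registry (four CSV tables) whose per-sequela prevalence rises with age,
`comoyld run` simulates every stratum and writes `results.csv`, `report.csv`
(cause/group/total aggregates with CIs and percent changes) and
`rankings.csv`, and `comoyld oracle` writes the exact enumeration for one
stratum:

```sh
comoyld synth --out registry --seed 1
comoyld run --registry registry --out results --preset desk --seed 1
comoyld oracle --registry registry --sex male --age-group 80+ --year 2015 --out oracle
```

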