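# Methods

## Model and assumptions

The package corrects prevalence-based YLD rates for multimorbidity by
microsimulation.  Within one stratum (sex × age band × year) each simulant is
exposed to every sequela independently, with probability equal to the
sequela's per-person prevalence `p_k = prevalence_per_1000 / 1000`.  Sequelae
of the same cause are treated exactly like sequelae of different causes —
independent exposure with co-occurrence allowed.  A simulant's disability
weights combine multiplicatively, `DW_l = 1 − ∏(1 − DW_k)`, which keeps the
combined weight in [0, 1] and equals the single weight when only one sequela
is present.  The combined weight is attributed back to the sequelae present
in proportion to their own weights, so attribution conserves the combined
weight exactly and the adjusted rate of a sequela can never exceed its
unadjusted rate (since `1 − ∏(1 − DW_j) ≤ Σ DW_j`).

Independence is the model's central simplification.  Real comorbidity is
correlated (shared risk factors, disease cascades), and a dependence-aware
sampler would change the size of the correction; dependent sampling and
severity-dependent attribution are deliberately out of scope.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_simulants` | 40,000 | simulants per simulation; sampling error of one repetition scales as `1/√n` |
| `n_repetitions` | 1,000 | independent simulations per stratum; their spread is the uncertainty interval |
| `master_seed` | 0 | single integer seeding every stratum and repetition |
| `ci_level` | 0.95 | percentile interval coverage |

The defaults mirror the protocol of national burden-of-disease studies
(40,000 simulants, 1,000 repetitions per stratum).  The CLI's `--preset desk`
(4,000 × 50) is a smoke-test scale.  Tests and the acceptance script use
smaller sizes chosen as the package's own trade-off between runtime and
Monte-Carlo error: oracle-agreement checks use one 40,000-simulant repetition
per slice, and the synthetic-registry pipeline runs use 10,000 simulants ×
10–20 repetitions, at which the age-gradient signal is several times its
sampling error.

## Uncertainty

The interval on an adjusted rate is the empirical 2.5th/97.5th percentile
(at `ci_level=0.95`, linear interpolation between order statistics) of the
per-repetition means.  Percentile-of-repetitions was chosen over a
normal-approximation interval because it is the direct reading of
"repeat the simulation to obtain the uncertainty" and makes no distributional
assumption.  Aggregate-level intervals (cause, group, total, margins) are
recomputed from the per-repetition *aggregated* means retained in
`StratumResult.rep_means` — never by summing interval endpoints, which
ignores the correlation between sequelae simulated on one shared population.
The interval on a percent change is likewise computed per repetition and then
percentiled.

## Seeding and determinism

Each (stratum, repetition) pair draws from
`SeedSequence([master_seed, *sha256(sex|age_group|year|repetition)])` (the
digest's first four 32-bit words).  Results are therefore bit-identical
across runs and independent of the order in which strata are executed, which
also makes stratum-level parallelism safe.  Population sums are accumulated
in extended (80-bit) precision before the final division, so means are
order-stable and a population of identical simulants averages exactly to its
common value; a simulant carrying a single weighted sequela keeps its own DW
exactly (the attribution ratio is set to 1 rather than recomputed, avoiding
a one-ulp wobble in `1 − (1 − DW)`).

Degenerate inputs: an empty slice yields an empty result; a simulant whose
present sequelae all have zero DW receives zero attributed weight (the
continuous limit of the formula, avoiding 0/0); a zero unadjusted rate makes
the percent change undefined and is reported as NaN rather than a number.
Rank ties are broken by cause identifier ascending so rankings are
reproducible.

## Exact oracle

For a slice of K sequelae the estimator's expectation is enumerated over all
`2^K` exposure subsets in double precision, chunked to bound memory.  The cap
K ≤ 20 is a hard refusal, not a fallback to simulation: the oracle must stay
exact.  The oracle also returns per-simulant second moments, giving the
sampling variance used to judge Monte-Carlo agreement (a 4-standard-error
band).

## Synthetic data

The generator emulates the marginal structure of claims-derived registries,
not any country's disease-specific values (those microdata are not public):

* five disease groups (NCDs, CDs, Injuries, MNNs, MDs), by default 4 causes
  per group × 3 sequelae per cause;
* disability weights drawn once per health state from Beta(2, 8) — bounded
  support, mean 0.2, right-skewed like empirical DW sets;
* prevalence in age band *b* equal to `base × gradient^b × noise`, with
  base 2 per 1,000 in the 5–9 band, gradient 1.5 per band, and one lognormal
  noise factor (σ = 0.5) per (sequela, sex, year) held constant across bands,
  so the expected multimorbidity load rises strictly with age — from ≈0.12
  expected sequelae per child to ≈3 in the 80+ band — and clipped to
  [0, 1000] per 1,000.

Because exposure is generated independent, pipeline tests on synthetic data
demonstrate that the engine recovers the *model's* expectations and the
qualitative age gradient of the correction; they cannot show how the
correction behaves under real, correlated comorbidity, nor reproduce any
published study's magnitudes.

## Known limitations

* Independent exposure only; no dependence modelling.
* All-age margins need external population weights to be interpretable as
  "per 1,000 population"; without weights the unweighted mean of stratum
  rates is reported and flagged.
* The exact oracle is exponential in K and refuses registry-scale slices;
  for those, verification is statistical (Monte-Carlo vs oracle on small
  slices plus conservation/dominance invariants).
* Prevalence-period correction for short-duration conditions, estimation of
  sequela distributions from systematic reviews, and YLL/DALY assembly are
  outside the package's scope.
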