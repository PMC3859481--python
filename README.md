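# triplematch

Propensity-score matching for **three treatment groups**: multinomial
propensity estimation, greedy 1:1:1 nearest-neighbour matching within a
caliper on the logit scale, standardized-difference balance
diagnostics, and a Monte Carlo engine for choosing the optimal caliper
width.

Propensity-score matching is routine for two-arm observational studies,
but three-arm comparisons (drug A vs drug B vs control, dose tiers,
disease-duration strata, …) raise questions the two-group machinery
does not answer: what is the matching distance between three subjects,
how is covariate balance assessed across three groups, and how wide
should the caliper be? This package implements one concrete set of
answers aimed at biostatisticians and epidemiologists analysing
three-arm cohorts, plus the simulation tooling to interrogate the
caliper choice.

## The method in brief

- Each subject gets a vector of propensity scores
  p_k(x) = Pr(T = k | x), k = 1..G, fitted by multinomial logistic
  regression (group G as reference) and mapped to logits
  ℓ_k = logit(p_k).
- Distance between subjects: d(a,b) = Σ_k (ℓ_k(a) − ℓ_k(b))²; a
  triplet's distance is the sum over its three pairs.
- Greedy 1:1:1 matching without replacement: group-1 subjects in
  random order, each matched to the admissible (group-2, group-3) pair
  with the smallest total distance. A pair is admissible when
  d(a,b) ≤ (G−1) · w² · Σ_k s_k², with s_k the SD of logit component
  k and w the caliper multiplier — the rule reduces exactly to the
  classic |Δ logit| ≤ w·s at G = 2.
- Balance: per covariate, the maximum over the three pairwise
  standardized differences; < 0.1 indicates negligible imbalance.
- Caliper study: across Monte Carlo replicates, each caliper width
  w ∈ {0.1, …, 0.8} is scored by mean matching ratio (matched triplets
  / smallest group), mean post-matching standardized differences,
  relative bias and MSE of the matched-sample effect estimates.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

```python
from triplematch import (
    ScenarioConfig, generate_dataset, generate_outcome,
    estimate_multinomial_ps, logit_transform, CaliperSpec,
    greedy_match, matching_ratio, balance_table, estimate_effects,
)
from triplematch.synthetic import COVARIATES

# a 1000-subject cohort, groups 100/200/700, true effects 1 vs control
cfg = ScenarioConfig.from_scenario("1:2:7", seed=42)
table = generate_outcome(generate_dataset(cfg), seed=43)

probs = estimate_multinomial_ps(table, list(COVARIATES))
logits = logit_transform(probs)
groups = table["group"].to_numpy()

caliper = CaliperSpec.from_scores(logits, groups, 0.2)   # w = 0.2
sample = greedy_match(logits, groups, caliper, order_seed=7)
print(f"matching ratio: {100 * matching_ratio(sample):.1f}%")
print(balance_table(table, sample).round(3).to_string(index=False))
eff = estimate_effects(table, sample)
print(f"ETE 1 vs 3: {eff.ete_13:.3f}   ETE 2 vs 3: {eff.ete_23:.3f}")
```

Output:

```
matching ratio: 96.0%
covariate  sd_pre  sd_post  flag_ge_0.1
       C1   0.247    0.174         True
       C2   0.528    0.050        False
       C3   0.427    0.094        False
       C4   0.633    0.047        False
       D1   0.306    0.068        False
       D2   0.246    0.111         True
       D3   0.553    0.063        False
       D4   0.510    0.128         True
ETE 1 vs 3: 0.812   ETE 2 vs 3: 1.056
```

96 of the 100 group-1 subjects found an admissible triplet. Matching
shrinks every covariate's maximal pairwise standardized difference —
most drop below the 0.1 threshold, while three stay marginally above
it (flagged), which is typical for a 1:2:7 design whose smallest arm
is only 100 subjects. The matched-sample effect estimates scatter
around the true value 1 for both contrasts in any single replicate;
their bias and precision as a function of caliper width is what the
simulation engine quantifies.

The same pipeline works on your own data from the shell:

```bash
triplematch match --input subjects.csv --caliper 0.2 --seed 17 --out matched.csv
triplematch balance --input subjects.csv --matched matched.csv
triplematch simulate --scenario 1:2:3 --reps 200 --seed 42 --out table.csv
```

`subjects.csv` needs one row per subject, numeric covariate columns, a
3-level `group` column (1/2/3, highest = control) and optionally an
outcome `Y`.

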