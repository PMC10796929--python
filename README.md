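# trajgwas

GWAS of *change* in cognition, not just its level. `trajgwas` implements a
longitudinal genome-wide association pipeline for repeated cognitive
measurements: each subject's scores follow a piecewise-linear trajectory
with a knot at one year, and every genetic variant is tested for additive
effects on all four trajectory parameters — baseline level, the
baseline-age gradient, the slope from baseline to the knot ("slope 1"),
and the slope from the knot to the end of follow-up ("slope 2").

It is written for biostatisticians and genetic epidemiologists working
with trial-like cohorts: repeated test batteries on a fixed visit
schedule, genotype dosages with imputation quality, and — critically —
enrolment that depended on age and known risk genotypes, which makes the
sample a collider and naive covariate adjustment dangerous.

## The model

For subject *i* at day *t*, with `s1(t) = min(t, 365)/365` and
`s2(t) = max(t − 365, 0)/365` in years:

    E[y_it] = β0 + β_age·(age_i − āge) + β_s1·s1(t) + β_s2·s2(t)
              + γ0·g_i + γ_age·g_i·(age_i − āge) + γ1·g_i·s1(t) + γ2·g_i·s2(t)
              + covariates (sex, risk-locus dosages, 5 ancestry PCs)

fitted per variant by Gaussian GEE with an exchangeable working
correlation and bias-corrected sandwich (robust) Wald tests — one model
per variant, millions at full scale, milliseconds each. Around the scan
sit the standard stages: baseline z-standardisation and domain/composite
scoring; variant QC (call rate, exact HWE, MAF, imputation r², EMAC =
2·N·MAF·r² > 200); a selection-bias diagnostic (GWAS of age and sex as
negative controls, flagged loci promoted to covariates); greedy LD
clumping; external-variant look-ups; and polygenic-score trajectory
associations (REML mixed model). A synthetic-cohort generator reproduces
the study structure — risk-stratified enrolment, 6-monthly visits, 1–11
occasions — and backs the test suite. See `docs/methods.md` for the full
account.

## Worked example

```python
import trajgwas as tg
from trajgwas.pipeline import outcome_tables

# a synthetic cohort: 1,000 subjects, 60 variants, one causal slope-2 locus
cfg = tg.SimulationConfig(n_candidates=1000, n_variants=60, seed=23)
effects = tg.TrueEffects.null().with_effect("var0030", (0.0, 0.0, 0.0, -0.8))
cohort, _ = tg.simulate_cohort(cfg, effects)

_, tables = outcome_tables(cohort.phenotypes)   # z-scores, domains, composite
records, summary = tg.run_scan(
    cohort, tables["global"], risk_variant_ids=("var0001", "var0002")
)
hit = records.loc[records["slope2_p"].idxmin()]
print(f"top slope-2 variant: {hit.variant_id}  "
      f"beta={hit.slope2_beta:.2f}  p={hit.slope2_p:.1e}")
print("lambdas:", {k: round(v, 3) for k, v in summary.lambdas.items()})
```

prints

```
top slope-2 variant: var0030  beta=-0.81  p=0.0e+00
lambdas: {'intercept': 0.705, 'age': 0.842, 'slope1': 1.245, 'slope2': 1.386}
```

The planted variant is recovered as the top slope-2 hit: its carriers
decline by an extra ~0.8 z-units per year per allele after the first year,
matching the simulated effect (the Wald p underflows to zero at this
effect size). The lambdas are noisy — the median chi-square is taken over
only 58 scanned variants here, and the slope-2 one is further inflated by
the genuine signal; at the calibration scale of 10,000 null variants all
four sit near 1 (see `scripts/acceptance.py`).

The same stages run from the shell:

```sh
trajgwas simulate --n-subjects 500 --n-variants 1000 --seed 1 --out run/
trajgwas prep --in run/
trajgwas select-check --in run/
trajgwas scan --in run/ --outcome global
trajgwas run-all --seed 1 --out run2/          # everything, one command
```

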