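# cnvburden

Case/control burden analysis of **large rare copy-number variants (CNVs)**,
built for array-based association studies in which CNVs are called by
several algorithms, filtered to rare large events, and compared between a
disease group and a control group. The package implements the full
analysis chain used in rare-CNV studies of complex disease (the motivating
application is type 2 diabetes in an admixed cohort of 686 cases and 194
controls):

1. **Consensus calling** — per-sample calls from multiple callers are
   clustered by reciprocal overlap (single linkage, RO ≥ 0.5) and only
   events supported by ≥ 2 distinct callers are kept; consensus events
   below 100 kb are dropped.
2. **Rare filtering** — a CNV is *rare* if its carrier frequency among
   controls is < 1% (carriers matched by RO ≥ 0.5, counted per sample)
   and < 50% of its length is covered by common CNVs / segmental
   duplications (population frequency > 1%).
3. **Burden testing** — seven measures per CNV class (deletions,
   duplications, both): CNV rate, sample proportion, total size, average
   size, genic rate, genic sample proportion and genic enrichment
   (genes per kb). Significance by one-sided adaptive label permutation
   (up to 10,000 permutations, early stop at 100 exceedances), both raw
   and adjusted for covariates (sex, BMI, triglycerides, MDS1 ancestry)
   by Freedman–Lane residualization.
4. **Regional association** — per-gene carrier counts compared by the
   two-sided Fisher exact test; candidate-locus overlap tables and
   extraction of genic CNVs private to cases (zero control carriers,
   population frequency < 0.2%).
5. **Gene-set analysis** — hypergeometric over-representation with
   Benjamini–Hochberg correction, and an Enrichment-Map-style network
   whose edges are overlap coefficients |A∩B| / min(|A|, |B|) ≥ 0.5.

Because real cohorts of this kind are not redistributable, the package
ships a **synthetic cohort generator** (`cnvburden.simulate`) that
reproduces the statistical structure of such a study — Poisson per-sample
CNV counts, truncated log-normal sizes, three pseudo-callers with dropout
and boundary jitter, and group-confounded covariates — so every stage
runs, and is tested, without any external data.

## Worked example

```python
from cnvburden import (SimulationConfig, simulate_cohort, annotate_cohort,
                       RareCnvBurden, regional_scan, two_proportion_power)

config = SimulationConfig(n_cases=200, n_controls=120, seed=11)
cohort = simulate_cohort(config)
annotated = annotate_cohort(cohort.calls_by_caller, cohort.samples,
                            cohort.genes, cohort.common_track)
model = RareCnvBurden(annotated, cohort.samples)
results = model.fit(n_perm=10_000, seed=17)
print(results.table[results.table.cnv_class == "both"].to_string(index=False))
```

prints

```
          measure cnv_class       case    control        all    ratio    p_raw  p_adjusted  n_perm
         cnv_rate      both   0.700000   0.541667   0.640625 1.292308 0.055149    0.298246    2048
sample_proportion      both   0.475000   0.416667   0.453125 1.140000 0.203902    0.438596    1024
       total_size      both 207.518615 168.392617 192.846366 1.232350 0.173659    0.506823    1024
     average_size      both 279.120056 312.014353 290.462917 0.894574 0.442495    0.760234     512
       genic_rate      both   0.480000   0.366667   0.437500 1.309091 0.111220    0.298246    1024
 genic_proportion      both   0.350000   0.300000   0.331250 1.166667 0.196881    0.384016     512
 genic_enrichment      both   0.001377   0.001230   0.001322 1.119796 0.282651    0.411306     512
```

Reading the first row: the simulated cases carry 0.70 rare CNVs per
sample against 0.54 in controls (ratio 1.29); the one-sided permutation
p is 0.055 before and 0.298 after covariate adjustment — at this sample
size the excess is not significant, and the adjustment absorbs the part
of the difference that tracks the confounded covariates. `n_perm` shows
where the adaptive rule stopped early for clearly null measures.

Analytic power for a planned comparison:

```python
>>> two_proportion_power(0.42, 0.31, 686, 194)
0.7994...
```

The same pipeline is scriptable from the shell (`cnvburden simulate`,
`consensus`, `rare`, `burden`, `regional`, `geneset`; see `--help`).

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generator, all numerical choices and known limitations.
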