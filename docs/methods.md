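# Methods

This note documents the statistical model behind `cnvburden`, the
assumptions baked into each stage, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and interval arithmetic

All coordinates are 1-based and fully closed internally
(`length_bp = end − start + 1`), the convention in which array CNV
studies print their loci; BED input/output converts at the boundary
(0-based half-open → +1 on start). Reciprocal overlap (RO) between two
intervals is shared bases divided by the length of the *larger*
interval, so RO = 1 only for identical intervals; coverage of an
interval by a track merges the track first so stacked intervals are not
double counted. Kilobase sizes are rounded half-up to one decimal for
display only; every internal computation runs at full precision.

## Consensus calling

Within each sample and CNV type, calls from different callers are
clustered by single-linkage on RO ≥ 0.5 — the standard CNV-region
convention, chosen because it is order-independent and directly
checkable against a transitive-closure oracle. A cluster supported by at
least `min_callers` (default 2) distinct callers emits one consensus
call whose interval is the **union** of its members. Union was chosen
over intersection because it preserves the full extent of the event and
is monotone as supporting calls are added; intersection is available via
`boundary="intersection"` (falling back to the union when chained
linkage makes the common core empty). Deletions never merge with
duplications. Every input call either belongs to an emitting cluster or
carries an exclusion reason, so call counts are conserved.

Sample QC applies four independently switchable filters in order:
sex concordance against an externally supplied inferred sex (skipped
when none is given), completeness of the adjustment covariates,
per-sample call-count outliers above mean + 3 SD, and duplicated sample
identifiers. The four steps mirror the shape of stringent array-QC
protocols; their thresholds are configuration, not assertions about any
particular study, because published QC details of this kind typically
live in supplementary material and vary between cohorts.

## The rare definition

A consensus CNV ≥ 100 kb is *rare* when

1. its carrier frequency among controls is < 1% — carriers are distinct
   control samples with a same-type call at RO ≥ 0.5 (counting carriers,
   not calls, matches how such studies display regional frequencies,
   e.g. "2 (1.03)" for 2 of 194 controls); and
2. less than 50% of its length is covered by the union of common-CNV /
   segmental-duplication intervals (population frequency > 1%).

The same RO ≥ 0.5 threshold is reused for carrier matching, case-only
extraction and population-frequency lookup (maximum frequency over
table intervals matched at RO ≥ 0.5). Containment-based matching for
the frequency table would also be defensible; RO was chosen to keep one
coherent matching rule, and the threshold is an argument everywhere.

A structural property worth knowing: because the carrier frequency is
computed against controls, a control sample's own call counts toward its
frequency. At loci recurrent in controls the rule therefore depletes the
control side slightly more than the case side. This asymmetry is
inherent to control-referenced rarity definitions; the type-I
calibration test (below) uses cohorts with many genes precisely so that
recurrence — and hence this selection effect — is negligible and the
permutation machinery itself is what is measured.

Genic annotation is transcript-span overlap (≥ 1 shared base with a gene
interval), not exon-resolved, matching what a gene BED provides.
Case-only extraction keeps genic rare CNVs of case samples with zero
matching control carriers and population frequency < 0.2%.

## Burden model

`RareCnvBurden` computes, per qc-pass sample and CNV class (deletions,
duplications, both), seven statistics: CNV count; carrier indicator;
total kb; mean kb; number of distinct genes spanned; genic-carrier
indicator; and genes per kb (0 for CNV-free samples). Group summaries
are means of per-sample values (proportions are means of indicators);
the average-size summary averages over CNV-carrying samples only, since
a zero from a CNV-free sample is not a size. `total = count × mean` is
an exact per-sample identity and is tested as such.

Two variants of the genic proportion exist in the literature's
terminology: the proportion of *samples* carrying a genic CNV and the
proportion of *CNVs* that are genic. The per-sample variant is the
primary measure here (it is the one a carrier-level permutation test
acts on naturally); the per-CNV fraction is emitted alongside as
`genic_proportion_per_cnv` so neither reading is lost.

### Permutation inference

The test statistic is mean(case) − mean(control) of the per-sample
statistic; the default alternative is one-sided (cases exceed controls).
The p-value is add-one: `(1 + #{permuted ≥ observed}) / (1 + n_used)`,
so it is never 0. When the number of distinct case/control labellings
fits within the permutation budget the null is enumerated exhaustively
and the p-value is exact (the identity labelling keeps it positive).
Otherwise labels are shuffled in vectorized chunks of 512; the adaptive
rule stops once 100 permuted statistics have reached the observed one —
at that point the estimate's relative precision (~10%) is ample for a
test that is clearly not significant — with a hard cap of `n_perm`
(default 10,000). The threshold is a constant rather than a fraction of
`n_perm` so that small budgets are not stopped on noisy counts.

Covariate adjustment is Freedman–Lane style: the per-sample statistic is
residualized on an intercept plus the covariates (sex coded male = 1,
BMI, triglycerides, MDS1 by default) by ordinary least squares, and the
identical permutation procedure is applied to the residuals. This is the
standard valid construction when a permutation framework must "adjust
for" covariates without a named scheme. A singular design matrix is an
error; a constant statistic yields p = 1 with a warning. A
`two-sided` alternative (|statistic| comparison) is available and is
used when comparing against two-sided analytic benchmarks.

No multiplicity correction is applied across the seven measures — the
"adjusted" p is covariate adjustment, not multiple testing. The regional
scan can attach Benjamini–Hochberg q-values per CNV class
(`fdr=True`, off by default).

### Regional, descriptive and power calculations

Per-gene association uses the two-sided Fisher exact test
(probability-mass rule) on carrier counts via
`scipy.stats.fisher_exact`; the test suite verifies it against an
exact-integer hypergeometric enumeration for all margins ≤ 15 and a
seeded sample of tables with margins ≤ 30 (the full ≤ 30 grid is ~230k
tables; the sampled check covers the same space at a fraction of the
runtime). Group characteristics use the chi-square test without
continuity correction for categorical variables (degenerate tables
return p = 1) and the Mann–Whitney U test with the tie-corrected normal
approximation, no continuity correction, for numeric variables, reported
as median ± IQR.

Post-hoc power for a two-sided two-proportion comparison uses the
pooled-null / unpooled-alternative normal approximation:
`power = Φ((|p1−p2| − z_{α/2}·se0)/se1)` with `se0` from the pooled
proportion. Equal proportions return `Φ(−z_{α/2})` (the one-tail
rejection probability under no effect).

## Gene-set analysis

The input gene list is the union of the regional hits, candidate-locus
hits and case-only genes, with provenance retained. Enrichment is the
hypergeometric upper tail of the hit count against a universe (default:
all genes in the gene-model file), Benjamini–Hochberg corrected, with
sets retained at q ≤ 0.05. The enrichment statistic, database and
thresholds are deliberately configurable: published gene-set maps of
this kind name only the visualization tooling, so the hypergeometric +
BH combination is this package's reconstruction — the minimal defensible
default for over-representation of a fixed gene list. Edges of the
network connect retained sets with overlap coefficient
|A∩B| / min(|A|, |B|) ≥ 0.5 (the Enrichment-Map default; Jaccard is
available), and nodes are labelled `duplications_only` or
`duplications_and_deletions` from the CNV types supporting their member
genes. The graph is emitted as GraphML plus an edge-list TSV; no layout
or rendering is attempted.

## Synthetic cohorts

The generator's defaults *are* the modelled study's conditions: 686
cases / 194 controls; per-sample CNV counts Poisson with rates
526/686 ≈ 0.77 and 131/194 ≈ 0.68; deletion fractions 189/526 ≈ 0.36
and 37/131 ≈ 0.28; sizes log-normal in kb (μ = ln 165, σ = 0.85)
truncated below at 100 kb, giving a ~215 kb median with a long right
tail, matching the reported median ± IQR scale; covariates drawn per
group from the reported medians/IQRs (log-normal for the skewed BMI,
cholesterol and triglycerides; Gaussian for age and the MDS ancestry
coordinates; sex Bernoulli at the reported male fractions), which
reproduces the case/control confounding the adjusted test must handle.
Placement is uniform per chromosome weighted by length — real CNVs
cluster in hotspots, but no within-chromosome spatial distribution is
published to calibrate against — with probability `genic_fraction`
(default 0.65, the scale of the reported genic fraction of rare CNVs) of
centring the event on a random gene. Each true event is emitted by each
of three pseudo-callers (birdsuite-like, ipattern-like, penncnv-like)
independently with probability 1 − `caller_dropout` (default 0.10) and
boundary jitter from a clipped Gaussian (default SD 5 kb) that can never
invert an interval. Lineage from every emitted call to its true event is
recorded, and `truth_table` exposes noise-free per-sample counts, so
recall of the consensus stage is exactly measurable. Identical
configurations (including seed) give byte-identical outputs.

What the generator does **not** emulate: probe-level intensities (so
caller behaviour is a simple dropout/jitter caricature, not
algorithm-specific error), linkage disequilibrium, CNV hotspots and
mechanism-driven recurrence, batch/plate effects, and any direct
covariate→CNV dependence within a group. Consequently, passing tests
demonstrate that the pipeline's logic and inference are correct under
the stated statistical structure — not that any particular biological
conclusion transfers to a real cohort.

## Calibration checks and problem sizes

Two Monte-Carlo properties are asserted by the test suite, at sizes
chosen to give tight-enough binomial error while keeping the suite
fast:

* **Type-I error**: 500 null cohorts (120/120 samples, equal rates,
  confounded covariates, 2,000 genes so locus recurrence — and the
  rare-rule asymmetry described above — is negligible); the adjusted
  one-sided test at α = 0.05 must reject at 0.05 ± 3·binomial SE.
  Null cohorts keep > 100 controls so that a singleton control carrier
  (1/n) stays below the 1% rarity threshold, as it does at the study's
  194.
* **Empirical power**: 200 cohorts at 686/194 with genic-carrier
  probabilities 0.42 vs 0.31 (all CNVs genic, noise-free calls,
  covariates drawn identically in both groups because the analytic
  benchmark assumes unconfounded groups); the two-sided adjusted
  permutation test must reject at the analytic power 0.799 ± 3·binomial
  SE. The two-sided variant is used because the analytic figure is
  two-sided at α = 0.05; the package's default one-sided test answers a
  different (more powerful) question.

## Known limitations

* The per-measure burden values of any specific real study are not
  reproducible from summary statistics alone; this package reproduces
  the *procedure* and its desk-computable quantities (Fisher p-values,
  carrier frequencies, power figures, bookkeeping identities).
* Sex chromosomes are carried through IO and filtering but excluded
  from burden statistics by default (`autosomes_only=False` to include
  them); no sex-aware copy-number handling is attempted.
* The adaptive permutation p for clearly null tests has ~10% relative
  Monte-Carlo error by construction; rerun with `adaptive=False` for
  publication-grade p-values far from the significance boundary.
* No genome-build liftover, probe-level re-calling, family structure, or
  parametric burden regression.
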