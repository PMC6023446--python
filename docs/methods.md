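# Methods

## Input model

A DMET-style dataset is a probes × samples matrix of literal diploid calls.
Calls are canonicalized on read: the two allele symbols (IUPAC bases, the
deletion token `-`, or multi-base insertion strings) are sorted under the
plain string order, so `G/A` and `A/G` are the same genotype.  Half-calls
(`A/`) and any unparseable cell are coerced to `NoCall` and counted in a
parse report rather than failing the run; structural defects (ragged rows,
duplicate probe or sample IDs) are hard errors.  The genotype table defines
the sample universe: class and survival files are intersected against it,
extra samples dropped with a warning, and a class left empty by the
intersection is an error.

## Preprocessing

Probes are dropped when (a) their `NoCall` fraction exceeds
`max_nocall_fraction` (default 0.1) or (b) with `drop_monomorphic` (default
on) they show fewer than two distinct called genotypes.  Monomorphic rows
cannot contribute to any downstream contrast, which is why the default is
aggressive; both knobs are exposed on the CLI.  Each removed probe records
exactly one reason, the `NoCall` check taking precedence.  Filtering is
idempotent.  The genotype-distribution matrix (per-probe counts of every
category, `NoCall` included; rows sum to the sample count) is the
computational contract behind the heat-map view — rendering is left to the
consumer or the optional `--plots` flag.

## Statistical screen

Each (probe, observed genotype) pair yields a 2×2 table of genotype
presence/absence against the two classes, `NoCall` samples excluded
probe-by-probe (not listwise, to preserve power).  The two-sided Fisher
exact p sums hypergeometric point probabilities not exceeding that of the
observed table, with a relative tie tolerance of 1e-7; the implementation
delegates to `scipy.stats.fisher_exact`, which uses exactly this rule, and
the test suite holds it to full enumeration to 1e-10 on every table with
N ≤ 30.  The odds ratio is the cross-product `ad/bc` with the usual
0-cell → 0/∞ conventions.

Multiple-testing correction (none, Bonferroni, Benjamini–Hochberg) is
applied over the **whole family of (probe × genotype) tests**, not over
probes — the family choice is recorded in the output metadata since either
reading is defensible.  Results sort by adjusted p, ties by raw p, probe
ID, then genotype, making the output order fully deterministic.

Hardy–Weinberg testing is per probe: with exactly two alleles among the
called genotypes, allele frequency p̂ is estimated by gene counting and the
1-df χ² compares observed (hom-major, het, hom-minor) counts with
`n·(p̂², 2p̂q̂, q̂²)`.  Monomorphic or >2-allele probes are flagged
not-applicable, never an error.

## Rule mining

Transactions hold one genotype item per called probe plus exactly one class
item; only class-assigned samples participate.  The Fisher row filter keeps
probes whose **minimum raw per-category p** is ≤ the threshold (default
0.05); it is deliberately independent of the corrected screen — it is a
search-space reduction, not an inference — and is computed per row.  Note
it measures marginal association only: a probe whose effect exists only
jointly with another probe can be pruned, so rule-recovery experiments run
with the filter open.

FP-Growth is implemented natively: single-item support scan, drop of
infrequent items, a fixed mining order (support descending, ties by item),
FP-tree insertion, recursive conditional-pattern-base mining with the
single-path shortcut.  The integer support threshold is the smallest count
c with c/n ≥ min_support (a 1e-9 slack guards float rounding).  Rules are
generated only from frequent itemsets containing exactly one class item and
a non-empty genotype antecedent; support and confidence come from exact
itemset supports, antecedent support being guaranteed present by
anti-monotonicity.  Minimum support is measured against **all**
transactions, not per class.  Rules are split by consequent class and
ranked by confidence, ties by support then antecedent token string.
Defaults: filter 0.05, min_support 0.2, min_confidence 0.8.

## Survival screen

Kaplan–Meier uses the product-limit estimator with the
deaths-before-censorings tie rule: a subject censored at t still counts in
the risk set of an event at t.  The median is the smallest event time with
S(t) ≤ 0.5 (tolerance 1e-12), undefined (NaN) when S never reaches 0.5.
The two-group log-rank statistic accumulates, over the pooled distinct
event times, O₁ⱼ − E₁ⱼ with E₁ⱼ = n₁ⱼdⱼ/nⱼ and hypergeometric variance
Vⱼ = dⱼ(n₁ⱼ/nⱼ)(1−n₁ⱼ/nⱼ)(nⱼ−dⱼ)/(nⱼ−1), the Vⱼ term skipped when nⱼ = 1;
χ² = (ΣO₁ⱼ−E₁ⱼ)²/ΣVⱼ against χ²₁.  With no events in either group the
comparison is flagged not applicable.  The hazard ratio is the model-free
(O₁/E₁)/(O₂/E₂) — no Cox model is fitted, matching the intent of pairing a
single effect-size number with each curve.

Groups are genotype-category carriers versus the complement of called
samples.  A probe with exactly two categories yields **one** comparison
(the two splits are mirror images); with more categories, one per
category.  OS and PFS are independent screens ranked by raw log-rank p
(ties by χ² descending, then probe, then genotype); a BH-adjusted column is
appended purely for the reader's convenience and labelled as such.

## Orchestration and determinism

The stage graph is fixed: load → preprocess → {survival screens} ∥
{Fisher + HWE → rule mining}.  The survival branch runs concurrently with
the statistical branch on a two-worker thread pool; `parallel_map`
distributes independent items over a pool bounded by
min(worker_count, cores) and collects results in submission order, so
every artifact is byte-identical for any worker count — the central
engineering property, asserted at byte level in the tests.  A failing
stage is recorded in the run manifest without corrupting the other branch.
All analyses are deterministic; the single seed drives only the synthetic
generator.

## Synthetic data generator

Defaults emulate a modest pharmacogenomics cohort: 200 samples split
~50/50 into RESP/NoRESP, 200 biallelic probes with minor-allele frequency
uniform on [0.1, 0.4] and genotypes in Hardy–Weinberg proportions, 2%
`NoCall`, exponential OS times at baseline hazard 0.05/month (PFS at
0.08/month, clipped to OS so progression never follows death), and
independent uniform censoring whose horizon is solved numerically so the
expected censored fraction hits the target (default 0.3).  Planted effects:
association probes draw the carrier genotype per class at stated
frequencies (0.6 vs 0.1 in the recovery experiments); rules condition class
assignment on joint antecedent carriage at a stated probability; survival
effects multiply the carrier hazard by a stated ratio.  Probes named by a
planted rule or survival effect have their allele pair forced to match the
planted genotype so the effect can materialize.  The generator does not
emulate linkage disequilibrium, probe chemistry, batch effects or real ADME
annotations — passing tests demonstrate the statistics recover clean
planted signals, not performance on correlated real-world panels.

An 8-probe × 12-sample worked-example fixture with hand-computable Fisher
tables, itemsets, rules and KM curves is generated in code (no data files
are shipped); the hand derivations live in the test suite's comments.

## Problem sizes and numerical choices

Calibration and recovery experiments run at the stated study conditions
(null: 200 probes × 100 samples; association: frequency 0.6 vs 0.1 at
n = 200; survival: hazard ratio 3 at n = 200 over 50 probes; rules:
confidence 0.9 at n = 500).  The packaged suite uses 300 null replicates
for the family-wise error check, 100 replicates for each recovery rate, 20
pooled replicates for p-value uniformity, and 200 random instances for the
FP-Growth/brute-force sweep; `scripts/acceptance.py` uses slightly smaller
replicate counts (200/60/15) chosen as a practical desk-scale batch.
Fisher p-values are memoized on cell counts; floats are written with
`%.10g` so output files are byte-stable across platforms and worker
counts.

## Known limitations

* One 2×2 test per genotype category; no r×2 (Freeman–Halton) mode.
* No annotation of hits against dbSNP/PharmGKB and no CEL/CHP parsing —
  only tabular genotype-call exports.
* No Cox regression, confidence bands, or multiplicity control across the
  two survival endpoints.
* Rule interestingness is support/confidence only (no lift/conviction or
  redundancy pruning beyond the class-consequent constraint).
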