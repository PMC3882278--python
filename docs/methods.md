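# Methods

`mirenrich` implements a *target reverse gene expression* screen: it infers
which microRNAs (miRNAs) are plausibly active in a disease contrast from the
coordinated expression shift of their predicted target genes, without
measuring the miRNAs themselves.  The motivating use case is breast-cancer
progression — comparing patients who relapse within five years of surgery
(R+) against those who do not (R−) — but nothing in the implementation is
tissue-specific.

## Model and rationale

A miRNA represses its targets post-transcriptionally.  If a miRNA is more
active in the R+ group, its predicted target set should be over-represented
among genes *down*-regulated in R+ (and symmetrically for reduced activity
and up-regulated genes).  The screen therefore composes four stages:

1. **Directional differential expression.**  Each gene is tested between
   outcome groups with the two-sided Wilcoxon rank-sum test; p-values are
   Benjamini–Hochberg (BH) adjusted across all genes of a dataset, and genes
   with adjusted p strictly below `alpha` (default 0.05) are split into up-
   and down-regulated lists by the sign of the median difference (R+ − R−).
   A directional list feeds enrichment only when it holds at least
   `min_genes` genes (default 30) — smaller lists make target-set overlap
   counts too unstable to interpret.

2. **Target-set enrichment with an empirical threshold.**  For each
   expressed miRNA and each prediction algorithm, the overlap between the
   gene list and the miRNA's predicted target set is scored by the one-sided
   Fisher exact test (hypergeometric upper tail) over the effective universe
   (measured genes ∩ the algorithm's prediction universe); BH runs within
   each (algorithm, list) family.  Because prediction sets overlap heavily
   and share biases, nominal significance is not trusted: the miRNA→target
   association is randomized `n_perm` times (each set replaced by a uniform
   random subset of the universe of the same size), and the lower-tail
   `null_quantile` (default 1%) nearest-rank quantile of the pooled null
   p-values becomes the family's threshold.  A record passes when its
   nominal p is at most the threshold (inclusive, so the boundary is
   deterministic).

3. **KS verification arm.**  Independently of any significance cutoff on
   single genes, per-gene pooled-variance t statistics (R+ − R−) are
   computed for genes passing a presence filter, and a two-sided two-sample
   Kolmogorov–Smirnov test compares the t-value distribution of each
   miRNA's retained targets against the retained non-targets.  BH runs
   within each (algorithm, dataset) family; adjusted p < 0.05 is
   significant.  This arm detects coherent distributional shifts even when
   few individual targets reach genome-wide significance.

4. **Consensus.**  A miRNA becomes a candidate when it is in the
   tissue-expressed set and is flagged by at least `min_algorithms`
   (default 2) distinct prediction algorithms within a single
   (dataset, direction) list.  The `--consensus-scope` options `dataset`
   and `global` pool supports across directions or across everything;
   `list` is the default because it is the strictest reading of
   "supported by at least two algorithms".  Results are summarized in an
   occurrence matrix (rows = datasets, columns = miRNAs, cells `x(a)` with
   `a` supporting algorithms, `-` otherwise).

## Why the calibration threshold lives on the nominal scale

The permutation null is built from fully randomized tables, so every null
family is signal-free and its BH-adjusted p-values concentrate near 1 (the
1% quantile of pooled null *adjusted* values sits around 0.2–0.5).  In an
observed family that contains genuine signal, the true positives occupy the
smallest BH ranks and thereby *deflate* the adjusted p-values of all
remaining null records — an adjusted-scale threshold calibrated on
signal-free permutations then passes ~10–15% of null records per algorithm
exactly when signal is present.  Nominal p-values of null records are
unaffected by their neighbours, so the nominal-scale comparison preserves
the exchangeability the permutation argument needs.  Both thresholds are
computed and reported (`threshold_nominal` is operative,
`threshold_adjusted` is diagnostic), together with `max_retained_nominal`,
the largest nominal p among retained records.  On planted synthetic studies
at default settings this retained-threshold statistic comes out around
0.005 — the same order as published applications of this calibration
report.

## Numerical choices

- **Wilcoxon rank-sum**: exact null by full enumeration when the combined
  sample size is ≤ 20 without ties; otherwise the normal approximation with
  midranks, tie-corrected variance and continuity correction
  (`scipy.stats.mannwhitneyu` supplies both regimes).  The reported
  statistic is the R+ group's (mid)rank sum.
- **Direction** is assigned by the sign of the median difference — the
  rank-test-consistent location summary; significant genes with a zero
  median difference (possible under ties) have no defensible direction and
  are excluded with a logged count.
- **BH** is the plain step-up: sort ascending, multiply by m/rank,
  cumulative minimum from the top, cap at 1.  It is monotone but not
  idempotent; no claim of idempotence is made anywhere.
- **Fisher/hypergeometric tails** come from `scipy.stats.hypergeom.sf`;
  exact-rational enumeration (`fractions.Fraction` + `math.comb`) is used
  as an oracle in tests, never in the pipeline.
- **KS**: D is the exact supremum of the ECDF difference over the pooled
  grid; the p-value uses the classical asymptotic distribution with
  effective size |x||y|/(|x|+|y|).  That formula is conservative at small
  sample sizes, so a minimum retained-target count (default 10) guards it,
  and under-sized records are emitted with a `skipped` flag rather than
  dropped.
- **Null-threshold quantile**: nearest-rank (the ceil(q·m)-th smallest
  pooled value), inclusive comparison at the threshold.  With discrete
  Fisher p-values the inclusive rule necessarily passes the whole p-value
  atom that straddles the quantile, so on synthetic nulls whose prediction
  sets all share one size the realized pass rate sits slightly above the
  quantile level (~1.5% at the 1% level, see Limitations).
- **Probe collapse** keeps, per gene, the probe with the highest median
  expression across all samples; median ties break on the lexicographically
  smallest probe id so the collapse is deterministic.
- **Sub-seeds**: every stochastic stage (simulation sub-streams, per-list
  calibration) derives a 31-bit seed from the run seed plus fixed offsets
  via `numpy.random.SeedSequence`, so reruns are byte-identical and
  changing one stage's configuration never perturbs another's draws.

## The synthetic-study generator

`generate_study` emulates the structure of a case-control cohort: a
genes × samples log-expression matrix with two outcome groups, per-algorithm
miRNA→target prediction sets, an expressed-miRNA list, and a ground-truth
map.  Defaults: 2000 genes, 30+30 samples, 60 miRNAs of which 5 are planted
with disjoint 40-gene regulons, effect size 1.0 within-group SD (shifted
*down* in R+, mirroring repression by an active miRNA; a `direction` flag
flips this), Gaussian equal-variance noise, 3 algorithms each reporting
round(0.7·40) = 28 true targets plus 10% false positives, and the full gene
roster as every algorithm's prediction universe.  Regulons are disjoint by
default so truth-based power accounting is exact (`allow_overlap` lifts
this).  Unplanted miRNAs receive random sets of the same size, drawn
independently per algorithm.

What the generator deliberately does **not** emulate: batch effects,
probe-level structure, correlated co-expression outside the planted
regulons, heavy-tailed noise (the rank-based tests make the noise family
uncritical), varying regulon sizes, and miRNAs with partial or overlapping
activity.  Passing tests on these studies therefore demonstrate that the
pipeline's statistics behave as designed under its own model — calibration
holds on nulls, planted signal of realistic strength is recovered with very
few false calls — not that any particular biological dataset will yield
reliable candidates.

The presence filter's default mode is likewise a synthetic stand-in:
negative-probe detection calls cannot be reproduced from a normalized
matrix, so a value counts as "present" when it exceeds the dataset-wide
expression quantile (default 0.25), and a gene is retained when present in
at least 60% of samples.  Externally computed 0/1 calls can be supplied
instead (`PresenceRule(mode="external_calls")`).

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` exercise: exhaustive oracle
sweeps (every 2×2 table with universe ≤ 30; every tie-free rank assignment
with group sizes ≤ 7); 50 null studies at default size with 200 permutations
for the calibration check; 20 (tests) / 6 (script) full pipeline runs on
planted studies with 200 permutations; and 2000–4000 pooled null genes for
the p-value uniformity check.  These sizes were chosen so the whole
validation runs on one CPU in minutes while keeping Monte-Carlo standard
errors small relative to the effects being checked.

## Known limitations

- With all prediction sets of one fixed size and a fixed-size gene list,
  Fisher p-values are heavily atomic; the inclusive nearest-rank threshold
  then passes the entire atom straddling the quantile and the realized null
  pass rate exceeds the quantile level by the atom's excess mass (~0.5
  percentage points under the generator's defaults).  Real prediction
  databases have widely varying set sizes, which disperses the atoms and
  makes the realized rate converge to the quantile.
- The KS arm requires targets to remain *present*: a very strong repression
  effect pushes targets below the detection quantile in R+ samples and the
  presence filter removes them before the KS stage sees anything.  At the
  default presence settings this bites for planted effects ≳ 1.5 SD.
- Outcome labels must be pre-dichotomized; patients without five-year
  follow-up have to be resolved (excluded or imputed) upstream, and no
  censoring-aware survival modelling is attempted.
- Entrez/Ensembl (or any other) identifier namespaces are opaque strings;
  analyses per annotation system are separate runs, and no cross-mapping is
  performed.
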