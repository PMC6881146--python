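# Methods

## Problem and model

`trapscore` analyzes affinity-purification mass-spectrometry (AP-MS)
experiments that compare a bait purification against a matched mock
(no-bait) purification using spectral counting. The motivating design is a
substrate-trap pulldown: a catalytically dead enzyme (here, a
deubiquitylase trap) immobilized on resin, exposed to whole-animal lysate,
with a parallel mock column estimating nonspecific resin binding. Each
condition is run as 3 independent biological replicates, each injected
twice (2 technical replicates), so one experiment is 12 LC-MS/MS runs per
bait.

The enrichment statistic for protein X in one biological replicate is the
peptide frequency

    F = (C − M) / C

where `C` is X's PSM (peptide spectral match) count summed over the bait
column's technical runs of that replicate, and `M` is the matched mock
sum. `F = 1` means bait-exclusive detection (`M = 0`, `C > 0`), `F = 0`
means no enrichment, `F < 0` depletion. Two cases have no finite F and are
carried as sentinels: *absent* (`C = M = 0`) and *depleted*
(`C = 0 < M`). Sentinels never count as enriched and sort below every
finite F (absent < depleted < finite), giving a deterministic total order.

**Granularity.** F is computed per biological replicate on
technical-replicate sums and then averaged across replicates. It is not
computed on grand means: mean-of-F equals F-of-means only when every
replicate has identical `(C, M)` (F is affine in M at fixed C, but not in
C), and the test suite carries both the equality property and a
counterexample. A published table's printed F column therefore cannot in
general be reproduced from its printed mean-PSM columns — a point the test
suite demonstrates rather than papers over.

**Enrichment thresholds.** Two conventions coexist and both are exposed:
the initial compilation keeps proteins enriched (strict, `F > 0`) in at
least `k = 2` of 3 biological replicates; the final cull requires
enrichment (inclusive, `F ≥ 0`) in all replicates. Defaults follow those
two stages respectively and are overridable per call and in the pipeline
config.

**Normalization.** `normalize_counts` offers `none` (default) and
`total_spectra` (counts per 10,000 total PSMs of each run, applied per
technical run before summation). Raw summed PSMs reproduce all the
worked anchor values, so `none` is the default; total-spectra scaling is
provided for unequal sampling depth between runs.

**Significance.** Per protein, the three per-replicate bait sums are
compared to the three mock sums by a two-sample t-test assuming unequal
variances (Welch statistic, Welch–Satterthwaite degrees of freedom),
delegated to `scipy.stats.ttest_ind(equal_var=False)`. When both samples
have exactly zero variance the statistic is undefined; the degenerate
policy reports `p = 0` for different means and `p = 1` for equal means,
which is the natural limit (a difference observed without any noise) and
matches how such rows are printed in practice. n is the number of
biological replicates (3), not the 6 technical runs: the replicate is the
independent unit.

## Filter cascade

Applied in a fixed order (config can disable stages, not reorder them):

1. **All-replicates cull** — keep proteins enriched (`F ≥ 0`) in every
   biological replicate.
2. **Technical consistency** — remove proteins that, in any replicate,
   have ≥ 2 PSMs in one bait technical run and 0 in another ("multiple"
   read as ≥ 2; a single spectrum vs zero is tolerated).
3. **SD vs control** — remove proteins whose F-score standard deviation
   (over biological replicates) strictly exceeds that of the spiked
   positive control. The control is a protein known to bind the bait in
   every pulldown (for a deubiquitylase trap, ubiquitin itself); its
   replicate-to-replicate scatter calibrates how much F variability a
   genuine interactor may show. The control always survives this stage;
   if it fails an upstream stage the anchor is undefined and the cascade
   aborts with an error rather than filtering without it.
4. **Ribosomal** — remove ribosomal subunits by annotation flag or
   case-insensitive name patterns (default `RpL`, `RpS`, `ribosomal`).
5. **Minimum technical enrichment** — require bait > matched mock in at
   least 2 technical runs (counted across all replicates). The source
   phrasing of this reporting rule is ambiguous; "number of technical
   runs with bait above mock ≥ threshold" is the adopted reading because
   it is computable from the stated data, and the threshold is a config
   knob.
6. **Inspection flag** — manual tandem-spectra inspection is not
   automatable; it enters only as a per-protein boolean annotation
   (default pass).

The SD filter uses the SD over biological-replicate F values (not over
the six technical runs), consistent with the replicate being the unit of
analysis everywhere else.

Every stage returns an exact partition, and `apply_cascade` keeps an
ordered trace: removed sets are pairwise disjoint and their union with
the retained set equals the input (asserted by property tests). Adding a
stage can only shrink the retained set.

## Ranking and comparison

Final tables rank by mean F descending; ties break by bait PSM mean
descending, then protein id ascending (invented tie-break — real data
shows none — chosen so output is a total order and byte-reproducible).
Display rounding (F to 2 decimals, PSM means to 1, p to 3) happens only
at write time. Venn comparison of 2–3 interactomes is an exact exclusive
region partition (checked against brute-force membership enumeration).
Category summaries report whole-percent fractions.

## Synthetic data generator

The generator emulates the replicated bait/mock design with three planted
populations; its defaults are the reference screen used by the end-to-end
tests:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2000 | total proteins incl. control |
| `n_true` | 20 | planted true interactors |
| `n_bio` × `n_tech` | 3 × 2 | replicate design |
| `background_mean` | 3.0 | mean PSM per technical run, background |
| `enrichment_fold` | 15.0 | bait-mean multiplier for true interactors |
| `dispersion` | 0.2 | gamma-Poisson overdispersion (0 = Poisson) |
| `detect_prob` | 0.3 | bait-column detection prob. for background |
| `control_mean` | 60.0 | control bait-column mean per run |
| `control_cv` | 0.1 | control biological CV |
| `ribosomal_frac` | 0.05 | fraction of background labelled ribosomal |

Counts are gamma-mixed Poisson: rate ~ Gamma(1/d, mean·d), count ~
Poisson(rate), giving variance mean + d·mean²; `d = 0` degenerates to
plain Poisson so moment checks are exact. True interactors are
bait-exclusive (mock mean 0) at `fold × background_mean`. Background
binders have equal bait and mock means, but their *bait-column* detection
is thinned by a per-run Bernoulli(`detect_prob`): background binders are
by definition the consistent nonspecific binders of the mock column,
while their appearance in bait-column runs at low abundance is sporadic
instrument sampling — exactly the bait-only flickers the cascade must
reject. The control appears in both columns (mock mean =
`control_mean / 2`, so 0 < F < 1 and the SD filter is genuinely
exercised) with its own CV, independent of the global dispersion.
`control_mean = 60` keeps the probability of a non-enriched control
replicate at the Poisson noise floor near 2 × 10⁻⁸, honoring the
always-enriched contract a spiked control must satisfy — at much lower
abundance, counting noise alone would occasionally break the anchor.

What the generator does **not** emulate: peptide-level identification and
protein inference, shared peptides, run-to-run retention-time structure,
correlated contaminant blocks, and abundance-dependent dispersion. Passing
recovery/null tests therefore show that the *procedure* behaves as
designed under its stated statistical model, not that any particular real
dataset would yield a particular hit count.

`planted_violation_fixture` builds ≤ 10-protein experiments in which
exactly one protein violates exactly one stage's rule while the control
and a clean hit pass everything — each violator is constructed to pass
every *other* stage, so cascade attribution is unambiguous (e.g. the
all-replicates violator has uniform F = −0.05 across replicates so its
SD is 0 and it still beats the mock in 3 technical runs).

## Problem sizes and numerical choices

End-to-end checks run the full pipeline on 2000-protein experiments: one
fixed-seed recovery screen (expected: all 20 planted interactors
recovered, zero background) and a 20-seed null screen with
`enrichment_fold = 1` (expected: on average ≤ 1 background survivor per
seed; observed 0 in 40,000 protein-seed combinations). These sizes make
the whole suite run in seconds while leaving the binomial/Poisson tails
thin enough for the assertions to be stable.

Missing cells in count tables are errors, never implicit zeros — silent
zeros corrupt F. All validation messages name the offending cell.
Floating point: F values are exact rationals of small integers in the
anchor cases, so equality assertions (`mean F == 1.0`, `p == 0.0`) are
exact, not toleranced.

## Known limitations

- Spectral counting is semi-quantitative; no peptide- or intensity-level
  quantification, and no empirical-Bayes shrinkage across proteins
  (deliberately out of scope — the statistic under test is the simple F).
- The Welch test on n = 3 replicates has little power; the p-values are
  reported for ranking context, not multiplicity-corrected inference.
- The SD-vs-control filter depends entirely on the chosen control; a
  control with atypically low variance will over-filter.
- The `≥ 2 technical-run enrichment` reporting rule implements one of
  several defensible readings of an ambiguous convention (see above) and
  is configurable.
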