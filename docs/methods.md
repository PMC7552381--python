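# Methods

## The analysis

`mirsig` implements the downstream computational analysis of a cell-type-
specific miRNA profiling experiment in the EAE mouse model of multiple
sclerosis (MS): small-RNA sequencing of oligodendrocyte (OL) Argonaute-bound
miRNAs at baseline, a pre-symptomatic time point (10 days post-immunization)
and disease peak (20 dpi), in immunized animals and mock-injected controls.
The pipeline consumes the differential-expression (DE) result tables of such
an experiment — it deliberately does not re-fit the count model (edgeR-style
normalisation and exact tests are upstream of this package) — and carries the
result through four stages:

1. **Signature construction.** A miRNA is retained under a contrast when its
   linear fold change is at least `fold_change_min` (default 2, i.e.
   |log2FC| >= 1) and its FDR is at most `fdr_max` (default 0.05). Disease
   contrasts can be paired with the mock contrast spanning the same time
   points; a miRNA passing the thresholds in both members of a pair is an
   induction artefact (the adjuvant/pertussis procedure, not the disease) and
   is excluded on feature identity alone — direction is not compared, because
   an artefact of the induction procedure is disqualifying regardless of its
   sign in either arm. Retained miRNAs are unioned into unique signature
   members, each carrying per-contrast log2 fold changes and directions. On
   the packaged fixture tables this yields the 20-member signature with 15
   up-regulated members in the peak-versus-pre-symptomatic contrast.

2. **Ortholog mapping.** Mouse mature-miRNA names are resolved to human
   TargetScan family names by (i) an explicit override table, (ii) exact
   match of the normalised name, (iii) paralog-letter collapse
   (`miR-10b-5p -> miR-10-5p`) plus exact match, in that order; everything
   else is reported `UNMAPPED` with provenance, never dropped. The packaged
   override encodes the one correspondence no heuristic should invent, the
   cross-arm renaming `miR-203-3p -> miR-203a-5p`. Seed-sequence matching is
   intentionally not attempted: without a seed table it cannot be audited,
   and the name-level procedure reproduces the conserved 11-of-20 mapping.

3. **Risk-gene target enrichment.** For a family with `m` predicted targets
   in a database of `N` genes containing `K` usable risk genes (risk genes
   absent from the universe are dropped, with their count logged — the
   expectation is incoherent otherwise), the expected overlap under uniform
   draws is `E = (K/N) * m`, the hypergeometric mean, and the enrichment
   score is `S = log2(O/E)` for observed overlap `O`. `O = 0` leaves `S`
   undefined; it is encoded as `-inf` (ordered below every finite score,
   written `-inf` in TSV and `null` in JSON) rather than patched with a
   pseudocount, preserving the plain log-ratio definition. Significance is
   calibrated by drawing `n` families uniformly without replacement from the
   database `B` times (defaults `n = 11` = the mapped signature size,
   `B = 1000`) and scoring each drawn family; a family is significant when
   `S > 1` and its permutation p is `<= 0.05`.

4. **Atlas intersection and small-lab statistics.** The risk-gene targets of
   each enriched family are intersected with a cell-type expression atlas set
   (any GMT set; which atlas and which expression cutoff define "expressed"
   is the caller's choice). Utilities cover Benjamini–Hochberg adjustment,
   the 2^-ddCt relative-quantification rule (technical replicates are
   averaged to a per-group mean dCt before differencing, the standard
   workflow), and Fisher's exact test on 2x2 marker-by-condition counts.

## Permutation-null design choices

Two decisions in the permutation test are genuinely open and both options are
shipped, with the defaults documented here:

* **Null pooling.** The default `pooled` null treats all `B * n` per-family
  permuted scores as the null sample, so the p-value estimates the
  probability that a *single random family* outscores the query — the natural
  per-miRNA calibration, and the one whose exhaustive limit (enumerate all
  size-`n` subsets, pool their member scores) equals the family-marginal
  distribution. The alternative `per-replicate` mode reduces each replicate
  to its mean score (`B` null values) for sensitivity analysis of
  signature-level summaries.
* **Tie handling.** The default `strict-greater` counts only permuted scores
  strictly above the true score (`p = #{null > S}/(B*n)`), which can return
  exactly 0; the conservative `greater-or-equal-plus-one` mode,
  `(#{null >= S}+1)/(B*n+1)`, never does, at the price of a positive bias on
  heavily tied nulls. Undefined (`-inf`) null scores never count as higher
  than any true score; an undefined true score is exceeded by every finite
  null score.
* The query family is *not* excluded from the null draw universe; at
  realistic database sizes (thousands of families) its inclusion perturbs the
  null by O(n/F) and keeps the draw exchangeable.
* Each family's permutation stream is derived from the master seed and the
  family name (CRC32-keyed `SeedSequence` substream), so per-family p-values
  are reproducible and independent of the order or composition of the
  signature list.

## Synthetic data: what it emulates, what it does not

`simulate_target_db` plants a per-family fold enrichment `f`: each of the
`m` targets is assigned to the risk class with probability `f*K/N`, then a
gene is drawn uniformly without replacement within its class. The expected
risk overlap is exactly `f*(K/N)*m`, so the enrichment score is an
asymptotically unbiased estimator of `log2 f` — recovery of a planted fold is
an analytic target, not a tuned one. The binomial class count is clamped to
the feasible range `[max(0, m-(N-K)), min(m, K)]`; in the regimes used
(`N = 2000`, `K = 100`, `m <= 600`, `f <= 4`) the unclamped count exceeds the
range with negligible probability, so the clamp does not bias the expectation
in practice. Default study conditions for the planted-recovery checks are
`N = 2000` genes, `K = 100` risk genes, `m = 400` targets and fold 4
(score 2), with 30 null families as background; they mirror the order of
magnitude of a genome-scale target database scaled down to keep a simulation
replicate in milliseconds.

`simulate_de_tables` emulates only the *structure* of DE result tables:
planted features get `log2FC = truth + N(0, 0.15)` and p-values
`1e-3 * Beta(0.01, 1)` (strongly concentrated near zero — a strong,
unambiguous effect model); null features get `log2FC ~ N(0, 0.25)` and
uniform p. The FDR column is the package's own BH adjustment. A
negative-binomial count emitter (`variance = mean + dispersion * mean^2`) is
included for realism-oriented experiments but feeds no pipeline stage.

What passing these tests shows: the statistic recovers planted enrichment
unbiasedly, its null p-value is calibrated, and the filtering/mapping logic
is exact on the packaged tables. What they cannot show: anything about real
TargetScan prediction quality, miRNA annotation drift between miRBase
releases, or correlated target sets among paralogous families — real
databases violate the independent-draw idealisation, which is precisely why
the significance machinery uses a permutation null over the *actual*
database rather than the binomial model.

## Null-calibration harness

The uniformity check for the permutation p redraws the per-family target
counts `m` (uniform on [150, 600), 50 families) in every one of the 500
simulation repeats, with the query being family 0 of the same ensemble. This
makes the query exchangeable with the null families, which is the condition
under which the p-value is uniform; with a fixed heterogeneous `m` layout the
query's score distribution differs from the null marginal and no uniformity
can be expected. The lower bound of 150 keeps `P(O = 0)` (an atom at p near
1) below 5e-4.

## Exact small-lab statistics

`fisher_exact_2x2` enumerates the hypergeometric support with integer
binomial weights and performs one exact rational division at the end; the
two-sided p follows the minimum-likelihood convention (sum over tables whose
point probability does not exceed the observed one), with probability ties
resolved exactly in integer arithmetic — float implementations must blur
ties with a relative epsilon. One-sided tails (`greater`, `less`) are tails
in the top-left cell. `bh_fdr` is the textbook step-up with a reverse
cumulative minimum; both are cross-checked in the test suite against
scipy/statsmodels as independent references.

## Problem sizes and numerical conventions

Simulation-based checks use 200 replicates for mean-score recovery, 100
seeded databases for detection rate, 500 repeats for null calibration
(`B = 125`, `n = 8`, pooled null of 1000), and `B = 10,000` for the
Monte-Carlo-versus-exhaustive comparison on an 8-family database — sizes
chosen so each check resolves its target tolerance with comfortable margin
while a full run stays in seconds. Gene symbols are uppercase-folded before
any set operation. Degenerate inputs fail loudly: empty universes, p-values
outside [0, 1], pairings naming unknown contrasts, draw sizes exceeding the
family count and empty signatures all raise typed errors before any
computation runs.

## Known limitations

* The definition of the database universe (`N`) follows the distinct gene
  symbols of the retained target-file rows; counting transcripts instead
  would rescale `E` for every family. An externally supplied universe is
  accepted for callers who need a different convention.
* Ortholog resolution is name-based; families whose mouse/human
  correspondence is neither name-preserving nor in the override table map to
  `UNMAPPED`.
* Reproducing the published per-family scores (1.20 for miR-155-5p, 1.68 for
  miR-210-3p, 64 risk genes covered) requires the TargetScanHuman v7.2
  predicted-target file and the MS genomic-map risk-gene list, neither of
  which is redistributable here; with those files on disk the `run`
  subcommand reproduces that analysis end-to-end as an optional integration
  run. The packaged checks cover everything up to that external data.
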