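# Methods

## Scope and data model

`enrange` implements the downstream analysis layer of a
distance-resolved enhancer-perturbation study: it consumes tables that
upstream tools already produce — thresholded E2G element–gene links,
CTCF contact-domain (CCD) BED intervals, DESeq2-style per-gene DE
tables, MAGeCK-MLE-style per-gate beta scores, bedGraph coverage, and
per-fragment 4C count vectors — and computes classifications and
statistics from them. Read alignment, count quantification, DE model
fitting, screen effect estimation and 4C read mapping are deliberately
out of scope.

All coordinates are 0-based half-open (BED convention); a TSS is a
single 0-based position. Gene identity is keyed on Ensembl ID; symbols
are carried for display only. Link rows that fail to parse are dropped
with a count rather than aborting, since real link files carry
annotation rows.

## Gene classification

Five mutually exclusive categories are assigned per expressed gene from
score cutoffs τ_low = 0.3 and τ_high = 0.8 and distance windows
(2, 10], (10, 40] and [50, 500] kb (see README for the rule table). The
exclusion clauses of the short/mid rules and the strong-link requirement
of the long rule make the four non-ambiguous predicates mutually
exclusive, so the assigned label does not depend on rule evaluation
order; a property test checks this against an independently coded
predicate-enumeration oracle on randomized genes.

Boundary semantics that the rule text leaves open were fixed once:

* "above 2 kb" is strict (> 2,000 bp), and the short window's lower
  edge is therefore also strict, `(2000, 10000]`. A closed lower edge
  would let a link at exactly 2,000 bp qualify for `short` while being
  invisible to the `no_enhancer` rule, breaking order independence; the
  boundary carries zero probability under continuous distances either
  way.
* Strong links in the uncovered (40, 50) kb gap fall through all rules
  and land in `ambiguous`; no fifth bin is invented.
* The long rule has no proximal-exclusion clause and is implemented as
  written: a gene with both a strong proximal and a strong distal link
  is `long`.
* Representative-link ties at equal maximal score break by smaller
  distance, then leftmost element start, for deterministic output.
* "Inside CCD" requires the element *and* the TSS within a single
  domain interval — the E-P link has two ends, and a link is only
  plausibly constrained by a domain that contains both.
* When a link file has no distance column, distance falls back to
  TSS-to-nearest-element-edge, min(|tss − start|, |tss − end|), 0 when
  the TSS lies inside the element; a mapped distance column always takes
  precedence.

The gene universe is the set of DE-table genes with
baseMean ≥ `min_base_mean` (default 50; use 8 to mirror SLAM-seq-style
shallow nascent data). Universe genes with no links classify as
`no_enhancer`; genes with links but no DE record are excluded — the
analysis universe is *expressed* genes.

## Comparison statistics

**One-sided KS.** D = sup_t [F_x(t) − F_y(t)] is evaluated exactly over
the pooled sample points; positive D means the test group is shifted
toward lower log₂FC. The p-value uses the asymptotic one-sided tail
exp(−2 D² n_x n_y/(n_x + n_y)), clamped to [0, 1]. At the group sizes
this package targets (hundreds to thousands of genes) the asymptotic
tail is accurate; an exact small-sample computation was judged
unnecessary and significance stars below n ≈ 30 should be treated as
qualitative.

**Wilcoxon rank-sum.** Two-sided, midranks for ties; the exact null
distribution when min(n) ≤ 8 without ties, otherwise the tie-corrected
normal approximation with continuity correction (delegated to
`scipy.stats.mannwhitneyu`; an independent full-enumeration oracle
cross-checks the exact path in the tests).

**Response classes.** `downregulated` = log₂FC < −0.8 and FDR < 0.05
(a missing FDR blocks this call); `unaffected` = −0.2 < log₂FC < 0.2
with *no* FDR condition — the band rule is implemented verbatim.
Cross-perturbation overlap tests use the milder −0.3 cutoff for the
conditioning perturbation, and the multi-factor ("mediator-style") set
collects genes below −0.5 in at least two tables.

**Quartile stratification.** Representative enhancers of *all*
short+mid+long genes are pooled and ranked on the chosen feature;
the bottom and top floor(n/4) enhancers define the low/high groups
(|low| = |high| exactly), with deterministic coordinate tie-breaks; a
constant feature is flagged `degenerate` rather than rejected. ChIP
coverage becomes a feature via length-weighted mean bedGraph signal
over each unique representative element (0 where uncovered), which is
invariant to splitting coverage intervals.

**Correlation clustering.** Pairwise-complete Pearson r of log₂FC
vectors over the shared gene set; hierarchical clustering with average
linkage on 1 − r. The reference analysis names neither the distance nor
linkage; average linkage on correlation distance is the common choice
for factor-response heatmaps. Zero-variance tables yield missing
correlations and are appended after the ordered leaves.

No multiple-testing correction is applied across category comparisons;
reported p-values are per test.

## Screen scoring

Raw score = β_low − β_high per target and line. Normalization divides
by the anchor guide's raw score (anchor → 1). Because dividing by the
anchor rectifies the sign of every same-direction effect, a "factors
with normalized score ≤ −0.1" activator selection is impossible under
the plain ratio; the pipeline therefore defaults to `score_sign = -1`
(normalized = −raw/|raw(anchor)|), under which factors required for
reporter expression are negative and the anchor itself scores −1. Both
conventions are exposed; either is invariant to rescaling a line's raw
betas by any nonzero constant. Distance specificity is
Δ = score(E0) − mean(distal lines), ranked descending; single-guide
flow validation uses
fc = [(kd − bg)/mean(ctrl_i − bg)] / anchor_fc.

## 4C arithmetic

Non-blind fragment counts are rescaled by 10⁶/S where S is their sum
minus the two largest non-blind counts (ties broken by coordinate
order; exactly two are excluded). The excluded fragments remain in the
output — so their scaled values may exceed 10⁶ — and blind fragments
pass through untouched. Smoothing is a centered running mean over
non-blind fragment order (default window 21, must be odd) that shrinks
to the available fragments at the edges, matching the endpoint behavior
of the R `runmean` convention the field uses.

## Synthetic cohorts

The generator emulates the study conditions, not real genomes: one
synthetic chromosome, one locus per gene at a 1.4 Mb stride (so loci
and their domains never overlap), one qualifying link per planted
enhancer gene plus 0–3 sub-threshold decoy links, element width 500 bp.
Default category sizes are the published analysis scale —
2,790 / 285 / 209 / 474 genes for no-enhancer / short / mid / long —
with ambiguous genes off by default (the reference analysis discards
them) but plantable by count.

Per-category enhancer strength (EP300-like) is log-normal with location
increasing short → mid → long (0, 0.5, 1.0; σ_log = 1), mirroring the
observed ordering that distal enhancers are intrinsically stronger.
Contact-domain membership is Bernoulli(0.7) per enhancer gene, realized
geometrically (a domain spanning TSS and element, or stopping short of
the TSS). Ubiquitous-expression flags fall from 0.5 (no-enhancer) to
0.15 (long).

Effect presets set the mean log₂FC per category:

* `cohesin`: long −0.5 × feature-percentile × (1 inside CCD, 0.3
  outside); short +0.2; others 0 — long-range genes down, scaled by
  enhancer strength and domain membership, short-range genes slightly
  up (the proximal-competition direction).
* `mediator`: long −0.4, mid −0.3, others 0.
* `null`: all 0.

Noise is N(0, 0.4²); baseMean is 50 + log-normal (so the default
universe filter keeps every gene and planted counts are exact); FDR
comes from z = log₂FC·√n_eff/σ (n_eff = 4) through a two-sided normal
p-value with Benjamini–Hochberg adjustment. Effect magnitudes are
package defaults sized so the published qualitative directions are
detectable at the published group sizes — they are not measured values.
Screens place β_low/high = ±effect/2 + N(0, 0.05²) per line over 3,200
targets, 624 non-targeting controls and an anchor with a uniform strong
effect (2.0). 4C profiles are Poisson counts around a 1/(1+d) decay
with two spike fragments and ~10% blind fragments.

What passing tests show — and what they do not: the synthetic cohorts
have exactly one qualifying link per enhancer gene, clean score gaps,
no overlapping loci, no multi-TSS isoforms, Gaussian homoscedastic
noise, and exact category counts. Recovery and calibration results
therefore validate the *arithmetic and statistics* of the pipeline, not
the biological accuracy of E2G predictions or the behavior of the rules
on messy real link tables (many links per gene near the score cutoffs,
shared enhancers, expression-filter ambiguity).

## Problem sizes and determinism

Simulation-based checks use 100 seeded replicates at the full default
cohort size (3,758 genes, ~7,000 links) for the statistical power,
calibration, stratification and screen-recovery properties, and 10
replicates for exact label recovery; each replicate derives all
randomness from its integer seed, and every generator is a pure
function of (config, seed). Classifying the real thresholded ENCODE
link table against a published DE universe is an integration exercise
requiring external downloads and is not part of the test suite.

## Known limitations

* The one-sided KS p is asymptotic; no exact option.
* One TSS per gene; isoform-resolved distance is out of scope.
* The screen model consumes gene-summary betas; guide-level dispersion
  and MAGeCK estimation uncertainty are invisible to it.
* CCD assignment is binary containment; partial overlap or nested
  domains are not modeled.
* The 4C module normalizes and smooths single profiles; differential
  4C statistics are out of scope.
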