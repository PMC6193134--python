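# Methods

## Text mapping

Product descriptions are normalised (casefold, whitespace collapse, unicode
dash/quote standardisation; idempotent) before any matching. Matching is
two-stage and the order is load-bearing: **exclusion regexes run first**, so a
description such as "phenobarbitone toxicity test" or "insulin syringes x10"
is removed even though it contains a drug name; identification then matches
literal strings as case-insensitive substrings. The original analyses this
package generalises do not specify the matching semantics precisely, so two
choices were fixed here as package policy:

* *Nested matches.* When one matched string lies strictly inside a longer
  matched string at the same position, only the longer survives; this stops
  combination-product names from also counting their constituents. A match of
  the shorter string elsewhere in the text still counts.
* *Deduplication level.* A description may map to several taxonomy entries
  (multivalent products), but within one consultation each entry yields one
  prescription event; the raw description count is kept as `multiplicity`.
  Downstream statistics (rates, diversity, networks) operate on events.

Unmatched, non-excluded descriptions are retained and reported as a coverage
statistic rather than treated as errors — real EHRs always contain products
recorded in ways no rule list can recognise.

## Taxonomy

Three levels: agent → pharmaceutical class (PC) → pharmaceutical family (PF),
with the invariant that every class belongs to exactly one family (violations
are load-time errors). Authorisation is `veterinary`, `human` (human-only
products prescribed under the cascade) or `generic` (descriptions ambiguous
between the two, e.g. "co-amox"). Vaccine, euthanasia, neurological and
replacement-agent descriptions frequently cannot be resolved past family
level; such entries carry `agent = "unresolved"`, no authorisation (reported
as "not estimable"), and are excluded from class-level diversity.

## Synthetic data generator

The generator emulates a sentinel network of volunteer practices. Defaults
(50 practices with 1–4 sites, 5,000 animals at species mix 0.71 dog / 0.27
cat / 0.02 rabbit, one plus Poisson(7) consultations per animal over a
two-year window ≈ 40,000 consultations, prescribing probability 0.65 on the
logit scale with a practice random effect of SD 0.4, authorisation mix
0.93/0.05/0.02) were chosen once to mirror the population the package is
designed for and are not tuned per analysis.

Each consultation draws a presenting complaint (ten categories), which
stochastically assigns it to one of three prescribing contexts: *preventive*
(vaccination and healthy checks), *treatment*, or *euthanasia*. Families are
then drawn from the context's block: one primary family from the block
profile plus each other block member independently with probability 0.22
(preventive) or 0.08 (treatment); with probability 0.03 one family leaks in
from the other non-euthanasia block. Euthanasia consultations never
co-prescribe. This makes within-block co-prescription an order of magnitude
more frequent than cross-block co-prescription, yields an overall
co-prescription rate near 0.45, and gives the network pipeline a known
three-group partition to recover.

Class choice within a family uses a per-practice probability vector drawn
from Dirichlet(2.0) (or supplied explicitly); because the Simpson-type
estimator below is unbiased for 1 − Σp² under multinomial sampling, the
generating vector's diversity is the practice's *true* diversity and is
stored in the ground truth. Agent choice draws the authorisation category
from the configured mix; the built-in taxonomy provides one agent per
(class, authorisation) slot.

Rendered text follows practitioner habits: dose/form suffixes, random casing
and spacing, quantity prefixes, family-level descriptors for vaccines and
euthanasia. A configurable fraction (default 1%) of prescriptions is rendered
illegibly (matching no rule, tracked in ground truth); decoy non-prescription
lines (fees, nail clips; default rate 0.35, of which 5% are
exclusion-triggering strings) exercise the negative paths.

What the generator does **not** emulate: realistic signalment (age, breed,
sex), temporal disease trends, free-text clinical narratives, species-specific
prescribing profiles, or genuinely misspelled drug names. Passing tests
therefore demonstrate correctness of the statistical machinery on data with
the declared structure, not robustness of the rule list to real-world
orthography.

## Rates and the cluster bootstrap

All rates are consultation-level "at least one" counts: the family rate per
10,000 consultations is 10,000 × (consultations with ≥ 1 event of the
family) / (consultations in the stratum). Repeat visits count separately;
an empty stratum raises an error rather than returning zero.

Confidence intervals use a one-stage percentile cluster bootstrap: resample
the observed number of clusters with replacement, recompute the statistic on
the concatenated member rows, take the 2.5/97.5 percentiles of 5,000
replicates (default). Clustering occurs both between sites and between
animals within a practice, and a single nested scheme is not obviously
identified; the package therefore runs two one-stage schemes — clusters =
sites, and clusters = animals stratified by practice — and reports the wider
interval. Percentile intervals (not BCa) keep the method transparent and
swappable. In the degenerate single-cluster case the interval has width zero
and a warning is emitted; if the observed statistic falls outside the
percentile bounds (possible in principle for percentile intervals) the bounds
are clamped to include it, with a warning.

## Prescription diversity

`compute_pd` implements the index exactly as defined; `NP < 2` is *undefined*
(the formula divides by NP(NP−1)), returned as `None`/NaN and excluded from
medians and ranking — not coerced to zero, which would conflate "one
prescription" with "perfectly concentrated prescribing". Reported values are
rounded half-even to two decimals.

`pd_even(k, NP)` gives the even-prescription ceiling. Note a finite-sample
subtlety: because the index is a without-replacement probability, the ceiling
*exceeds* 1 − 1/k at finite NP and decreases toward it as NP grows (k = 2:
0.667 at NP = 4, 0.545 at NP = 12, → 0.5). It is increasing in k at fixed NP.

Benchmarking ranks practices on frequency and diversity independently,
splitting each ranking into five groups of near-equal size; ties break by a
stable sort on practice id, and when n is not divisible by 5 the earlier
(lower) quintiles take the extra members. Practices are benchmarked against
each other rather than against the family's theoretical ceiling, which is
practically unreachable.

## Co-prescription network

Nodes are families with `count` = total prescription events (several agents
of one family in one consultation all count toward node size); edges gain +1
weight per consultation in which the pair of families co-occurs (each
consultation's m distinct families contribute all C(m, 2) pairs, once each).
Sparsification applies the node rule first (drop families under 0.5% of total
prescriptions), then computes the mean edge weight *over the surviving edges*
and keeps only edges strictly exceeding it; edgeless nodes remain as isolates
(an isolated euthanasia node is a finding, not an artefact). The edge mean is
deliberately computed after node removal, and over existing edges rather than
all possible pairs — both points on which the original description is silent.

Group detection runs weighted asynchronous label propagation. Single runs
depend on the random update order, so the package runs `n_runs` (default 20)
seeded repetitions and returns the modal partition (ties to the earliest
run); disconnected components can never merge, and isolates always form
singleton groups. The class-level network is also built and exported, but
group detection is performed at family level only.

## Comparative statistics

Pairwise two-sided Wilcoxon rank-sum tests compare practice-level diversity
between species, with Bonferroni adjustment `min(1, p × n_pairs)`. Because
practice-level diversity contains many exact ties (clusters of practices at
PD = 0), pooled samples of ≤ 10 observations are tested by exhaustive
enumeration of rank assignments (midranks under ties; two-sided p = twice the
smaller tail, capped at 1), and larger samples by the tie-corrected normal
approximation. Kendall correlations use tau-b with the t-approximation
`t = τ √((n−2)/(1−τ²))` on n − 2 degrees of freedom; perfect (anti)concordance
reports p = 0, and constant inputs are signalled as undefined. Undefined
diversity values are dropped listwise per group (rank-sum) or pairwise
(correlation), with counts logged.

## Problem sizes and numerical choices

The test suite exercises desk-scale datasets: ~3,600 consultations for unit
tests, the default ~40,000-consultation configuration for group recovery, a
dense 4-practice/30,000-consultation configuration for diversity recovery
(so that practice-family cells exceed 500 events), and 500 simulated
clustered datasets of 40 × 25 binary outcomes at 500 bootstrap replicates for
interval coverage, whose true marginal proportion is computed by
Gauss–Hermite quadrature. Oracle suites enumerate exhaustively: all class
compositions to 30 prescriptions for the diversity index, brute-force pair
counting for edge weights (1,000 consultations) and Kendall's tau (n ≤ 50),
and full permutation enumeration for small rank-sum tests.

All randomness flows through explicit integer seeds (`numpy` Generators;
derived seeds stay below 2³¹); reruns of any stage with the same seed are
byte-identical, including the pipeline's JSON summary (floats rounded to six
decimals on output).

## Known limitations

* The built-in rule list is synthetic and small (≈130 strings); it
  demonstrates the machinery, not lexical coverage of real product text.
* The bootstrap is percentile-based and one-stage; heavily unbalanced cluster
  sizes or very few clusters will under-cover, as percentile methods do.
* Label propagation on networks with weak block structure is inherently
  unstable; the consensus wrapper reports the modal partition but cannot
  manufacture signal that sparsification has removed.
* Administration-route stratification of diversity requires a `route` column
  on events; the built-in taxonomy does not carry routes.
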