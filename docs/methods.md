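# Methods

## Graph model and cascades

A citation corpus is a directed graph whose nodes are articles and whose
edges run from the citing article to the cited one. The diffusion
cascade of a seed article *s* is *s* together with every article that
has a directed citation path terminating at *s* — the reverse
reachability set — plus the citation edges induced among those members.
All downstream metrics operate on the induced subgraph only: a cascade
is a set of articles, and the only coherent path structure is the one
among its members.

Cycles are tolerated. They can occur in real corpora (simultaneously
published, mutually citing articles), and both reachability and shortest
paths are well-defined on cyclic digraphs; loading a cyclic corpus logs
a notice rather than failing. Self-citations are dropped and duplicate
edges collapsed, each with a logged warning; an edge naming an unknown
article is a hard error, since it usually indicates a truncated export.

By default every article with at least one within-corpus citation heads
a cascade (`all_cascades`, threshold configurable via `min_citations`).
Cascades are computed on the full loaded graph; group labels (e.g.
specialty) are used only to aggregate per-cascade metrics afterwards.
When the seed set is known a priori — as in the synthetic demos, where
only the generated roots are of interest — an explicit seed list can be
passed instead (`citecascade metrics --seeds`).

### Dates

Publication dates are ISO 8601 at day, month, or year precision.
Month-precision dates resolve to day 15, year-precision to July 1 — a
deterministic mid-period convention for bibliographic records that lack
day precision.

## Broadcast metrics

*Cit_s* is the seed's in-degree within the induced cascade edges. For
direct citers, "citations from cascade members" and "citations from any
corpus article" coincide by construction, so the restriction to members
is benign.

The first-year fraction divides the direct citers dated within the
window by *Cit_s*. The window is 365 days, inclusive at both ends.
Citers dated *before* the seed (possible with imprecise dates or
in-press citations) count toward *Cit_s* but never toward the window —
deterministic and conservative. The fraction is undefined when
*Cit_s* = 0.

## Structural virality

**Size** is the member count, seed included.

**Depth** is the mean length of shortest directed paths over ordered
member pairs (i, j), i ≠ j, for which a directed path i → … → j exists.
The normalizer is the number of *connected ordered pairs*: unreachable
pairs are excluded from numerator and denominator alike rather than
assigned an infinite distance, which keeps the statistic the mean of the
path lengths actually summed. Depth is ≥ 1 when defined, equals 1
exactly for a star, and equals (n + 1)/3 for an n-article chain.

**Width** is the mean number of second-step citations divided by the
mean number of first-step citations over members. First-step citations
of i = its in-degree in the induced subgraph; second-step citations of
i = the number of directed walks of length exactly 2 ending at i, i.e.
the citations received by i's direct citers summed with multiplicity.
Since both means divide by the member count, the ratio reduces to
(total length-2 walks)/(total edges). The walk convention yields exactly
0 for a star graph — the defining limiting case — and is the default; a
`second_step="distinct"` switch counts distinct articles at directed
distance exactly 2 instead, for sensitivity analysis.

Depth and width are undefined for single-article cascades and propagate
as missing values, never as 0: coding a size-1 cascade as
zero-depth/zero-width would bias group medians toward the broadcast
regime.

## Innovation index

Articles carry an ordinal implementation-stage category c ∈ 1..8, from
idea description / laboratory evaluation (1) through cadaveric and
animal studies to the five clinical levels of evidence, strongest last
(8). The category-to-label mapping is configuration (`FunnelMap`, YAML
or JSON), not code: the ordinal positions are what the index consumes,
and the pre-clinical ordering convention may legitimately differ between
studies. Categories are inputs — they come from human scoring — and no
text classification is attempted.

The unnormalized score u_g = Σ_c c · p_cg / P_c sums, over the stages a
group occupies, the stage position weighted by the group's share of all
publications at that stage; categories with P_c = 0 contribute nothing
(the share of an empty category is vacuous, not 0/0). The reported index
rescales by the maximum group, computed as (u_g / max u_g) · 100 so the
top group is exactly 100.0 in floating point. The rescaling is
monotone, so ranking by index and by unnormalized score coincide.

## Rankings and comparisons

Group distributions collect the *defined* values of one metric; groups
with no defined values (e.g. all size-1 cascades for depth) are excluded
with a notice. Quantiles use linear interpolation between order
statistics — the definition matters because ties are broken on the 75th
percentile.

Rankings order by descending median, then descending 75th percentile.
To guarantee a total deterministic order on adversarial inputs, two
further levels are applied: descending 90th percentile, then ascending
label. The two extra levels are a package convention beyond the
median/75th rule, which is why each row records the deepest statistic
that was needed (`none`/`p75`/`p90`/`label`) — paper-faithful behaviour
stays auditable.

Pairwise tests are two-sided Mann–Whitney U (used for count-like
metrics: citations, size) or two-sample Kolmogorov–Smirnov (fractions,
depth, width). Mann–Whitney uses scipy's automatic method selection
(exact null for small tie-free samples, tie- and continuity-corrected
normal approximation otherwise); Kolmogorov–Smirnov uses the asymptotic
two-sample p-value, a documented limitation for very small groups.
Multiple comparisons are adjusted with the Benjamini–Hochberg step-up
procedure — the default FDR procedure in biomedical statistics, and the
only one exposed, to keep outputs canonical. Significance is judged on
adjusted p-values when FDR is on.

### Rank correlation with exact p-values

With few groups (typically ~10), asymptotic p-values for rank
correlations are unreliable, so p-values are computed by permutation of
the labels of one ranking:

* **enumeration** — all n! permutations, exact and seed-free, used for
  n ≤ 8 (40,320 permutations) in pairwise comparisons;
* **Monte Carlo** — 100,000 replicates by default, mandatory explicit
  seed, used above the threshold.

The mode, permutation count, and seed are recorded in every result.
Spearman's ρ is computed as the Pearson correlation of (mid)rank
vectors and Kendall's τ as τ-b; both are evaluated vectorized over the
whole permutation matrix. Pairwise p-values are two-sided
(P[|coef| ≥ |observed|], with a 10⁻¹² slack against float noise).

Kendall's W uses the tie-corrected form
W = 12·S / (m²(n³ − n) − m·T) with S the squared deviations of the rank
sums and T the midrank tie correction. Its p-value is one-sided
(P[W ≥ observed]): W is a non-negative concordance coefficient with no
two-sided analogue. The permutation null holds the first ranking fixed
(W is invariant under a common relabeling) and permutes the rest, so the
enumeration space is (n!)^(m−1); enumeration is used when n ≤ 8 *and*
that space fits a 50,000-permutation cap (both configurable), Monte
Carlo otherwise. The cap exists because the literal n-threshold rule is
only meaningful for m = 2.

## Synthetic corpora

The generator emulates the structure of a real innovation-diffusion
corpus — multiple specialty-labeled seed articles, each heading a dated
cascade, with evidence categories distributed over the 8 funnel stages —
from three archetypes: **star** (k direct citers; the broadcast limit),
**chain** (minimal multi-generational case with known closed forms), and
**branching** (Galton–Watson tree with Poisson(λ) offspring per node up
to a maximum generation count; the viral regime). Poisson offspring was
chosen as the standard single-parameter branching-process model. Trees
are strictly parent-citing by default; an optional rewiring rate adds
cross-generational edges (a child also citing an earlier ancestor on its
path) while preserving acyclicity. Citers are always dated after the
articles they cite, so generated corpora are acyclic by construction and
load with zero warnings.

Default study conditions, fixed once: seed date 2000-01-01; per-edge
citation lag uniform on 30–365 days (citation lags of under a month are
rare, and most first citations arrive within a year); the planted
two-group demo uses 10 cascades per group, λ = 2 with 5 generations for
the viral group against k = 20 stars for the broadcast group, with the
viral group's evidence mass concentrated at stage 8 and the broadcast
group's at stage 1. Identifiers are zero-padded and group-prefixed so
outputs are diff-stable; identical configs produce byte-identical
corpora.

What the generator does *not* emulate: cascade-size heavy tails fit to
empirical corpora, cross-cascade citation (cascades are disjoint by
construction), temporal variation in citation rates, or correlations
between cascade shape and evidence category beyond what a config plants.
Tests passing on these corpora therefore demonstrate correctness of the
computations and recoverability of planted structure, not empirical
claims about any real literature.

## Numerical conventions

* Undefined metric values are `None`/NaN and serialize as empty CSV
  cells; they are excluded from distributions, never imputed.
* Oracle-equivalence tests compare against brute-force implementations
  (Floyd–Warshall, adjacency-matrix squaring, repeated edge relaxation,
  exhaustive permutation enumeration) at 10⁻¹² absolute tolerance.
* Permutation p-value comparisons use a 10⁻¹² slack when counting
  |coefficient| ties.
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; the CLI records every seed in its run manifest.
* Problem sizes in the test suite (random digraphs ≤ 50 nodes for
  reachability, ≤ 12 for metric oracles; 200/100 replicate checks;
  100,000 Monte-Carlo replicates) were chosen so the full suite
  completes in a few seconds while exercising every branch.

## Known limitations

* Citation counts are within-corpus; external citations are invisible.
* The asymptotic Kolmogorov–Smirnov p-value is inaccurate for groups of
  fewer than ~10 cascades.
* Kendall's W enumeration is infeasible for many rankings over many
  groups; Monte Carlo with a recorded seed is the intended mode there.
* Time-resolved virality (how depth and width evolve) is out of scope;
  metrics summarize the final cascade shape only.
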