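# Methods

## The CircleMap model

A *scene* is a typed interaction graph plus one CircleMap glyph per
displayed gene. A glyph is a stack of `k` annular rings (positions
`0..k-1`, inner to outer), each bound to one gene × sample score matrix
(a "platform") and a color scale. Each ring is divided into angular
cells: in **full** mode one cell per sample (*spoke*), in **aggregated**
mode one cell per sample group (*segment*). The invariant the whole
package is built around is coordination: a scene has exactly one
cell-index → sample (or group) map, shared by every ring of every glyph,
so any reordering applies to all glyphs identically.

Angles are measured in degrees from 12 o'clock, increasing clockwise —
a fixed convention chosen for clock-reading intuition and determinism.
Unweighted cells split the turn evenly; aggregated segments get extents
proportional to group sizes (a scene flag switches to equal widths).
Extents always sum to 360° within 1e-9.

## Sorting

`sort_samples` performs a lexicographic multi-key sort; a key is either
a gene's values in one ring or a categorical annotation, each ascending
or descending. Direction is applied to *ranks* of the distinct observed
values, so numeric and string keys behave identically. Missing values
rank after every non-missing value under either direction, keeping the
data-poor samples in a contiguous tail. The sort is stable: when all
keys tie, the input (universe) order is the final tie-break. That makes
sorting idempotent and makes a direction flip exactly reverse every
strictly ranked pair.

The sample universe is built from the matrix list by `union` (order of
first appearance; the default, so no sample is dropped) or
`intersection` (ordered as in the first matrix; empty intersection is an
error).

## Aggregation

`aggregate_ring` computes the arithmetic mean of a gene's non-missing
values per group; an all-missing group stays missing. Values are summed
in sorted order with compensated summation, so the result is exactly
invariant to within-group sample order. Aggregation happens in value
space *before* colorization — the segment color is `colorize(mean)`,
never a blend of rendered colors, because color-space averaging depends
on the color model and is not reproducible across renderers. A binary
ring's group mean is a frequency in [0, 1], colorized on a white → dark
ramp.

## Color scales

Continuous scales interpolate linearly low → mid → high between
`vmin`/`vmid`/`vmax` and clip outside the range. The per-matrix default
is symmetric around 0 with `vmax` at the 95th percentile of |values| —
outlier-robust and conventional for omics heatmaps — and can be
overridden per ring. Binary and discrete kinds are categorical lookups.
Missing values map to a single scene-wide grey.

## Network algebra

The graph model keeps nodes as (name, entity type) and edges as an
ordered multiset of (source, target, edge type, track). Undirected
edges are canonicalized to lexicographic endpoint order, so (A,B) and
(B,A) are one edge; directed types (activates, inhibits, component,
member) preserve orientation.

* `extract_subnetwork` returns the induced subgraph of the background on
  the query gene set; with `expand_complexes` it also keeps a
  complex/family node whose protein members (over component/member
  edges) are all selected. Expansion is off by default because a complex
  node without its members renders as a data-less glyph. The operation
  is idempotent and its edges are always a sub-multiset of the
  background's. No neighborhood expansion (e.g. one-hop) is performed:
  filtering is strictly induced-subgraph.
* `overlay_tracks` adds every track edge whose both endpoints are
  displayed, retagged with its track name. Parallel edges from different
  tracks are deliberately kept distinct so the renderer can color each
  by source.
* `edge_support` counts the tracks containing *any* edge between a pair,
  ignoring orientation and type — a track with several edge records
  between the same pair still contributes one, because the count
  measures independent data-set support.

## Rendering

Layout is a seeded Fruchterman–Reingold force-directed placement (500
iterations), scaled to scene units, followed by a pairwise push-apart
pass that guarantees a minimum center distance of one glyph footprint
(computed for a fixed four-ring budget so spacing does not depend on the
data) plus clearance, with a small slack absorbing coordinate rounding.
Identical (graph, seed, config) give identical coordinates; all floats
are serialized at fixed 3-decimal precision and all collections iterate
in insertion order, so the SVG byte stream is fully deterministic.

Edge glyphs: arrowhead marker for activation, T-bar marker for
inhibition, dashed stroke for component/member, plain stroke for
undirected; edges run rim-to-rim and parallel edges are offset
perpendicular to the connecting line. The first two track colors are
purple and brown (curated regulatory vs protein–protein convention),
then a fixed categorical palette. Stable CSS classes — `node`, `edge`,
`spoke`, `segment`, `legend` — are the machine-testable contract; the
test suite checks class counts against the scene's combinatorics
(sector paths = Σ over glyphs of rings × cells, edge groups = edge
multiset size).

## File formats

Matrices are tab-separated, header row = sample ids, first column =
gene symbol; `NA`, `nan`, `NaN` and empty fields parse as missing and
`NA` is written back. Ragged rows abort with the line number — never a
silent truncation. Gene symbols match case-sensitively with no alias
resolution. SIF relations map `pp`→undirected, `-a>`→activates,
`-t|`→inhibits, `component>`→component, `member>`→member; unknown
relations are errors rather than silently undirected, because the edge
type drives the glyph choice. The typed dialect declares nodes
(`entity_type<TAB>name`, types protein/complex/family/smallmolecule/
process) before edges (`source<TAB>target<TAB>relation`); it is a
package-defined format isolated behind its reader so other dialects can
be added. SVG is built with the standard library's element tree and
checked for XML well-formedness in tests.

## Synthetic scenarios

The generators define the study conditions; they are first-class,
tested code.

**Toy (two-gene inhibition).** Latent unit-variance construction: a
shared factor gives the two genes' methylation a population correlation
of exactly `rho_meth` (default 0.8); expression of gene A loads on its
methylation with `rho_meth_expr` (default −0.8); expression of gene B is
built to have population correlation exactly `rho_inhibit` (default
−0.8) with gene A's expression, with its remaining variance drawn from
the component of gene B's methylation orthogonal to expr-A (the
silencing pathway) plus fresh noise. Observed values add
`noise_sd`-scaled measurement noise (default 0.3), which attenuates all
sample correlations by 1/(1+noise_sd²). The loading construction is
feasible for any |rho| < 1, so parameter validation (rather than a
positive-semi-definiteness check) is the only error path;
`rho_inhibit = −1` is admitted as the degenerate limit in which the two
expression profiles are exactly anti-correlated. Default n_samples is
10, matching a small-panel illustration; statistical tests use n = 500.

**Cohort (hypermutated tumors).** n = 120 samples by default, 25%
hypermutated; the driver gene's mutation indicator is
Bernoulli(0.6) in hypermutated and Bernoulli(0.05) in non-hypermutated
samples, other genes mutate at a background rate of 0.05 everywhere.
Copy number is standard normal per gene; expression loads on copy
number and inferred pathway activity on expression with coupling 0.7,
topped up to unit variance with independent noise. The accompanying
typed pathway is an activating chain from the driver with one inhibitory
feedback edge and one complex node with component links. Rates of
0.6/0.05 at a few hundred samples give an aggregated frequency contrast
recoverable well beyond sampling noise; tests verify recovery within
three binomial standard errors at n = 1000.

What the generators deliberately do **not** emulate: real marginal
distributions of tumor omics, mutation spectra, batch effects, or
realistic pathway topology. Passing tests therefore demonstrate the
correctness of the coordination/sorting/aggregation/rendering machinery
and the qualitative recoverability of planted structure — not
performance on real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: toy
correlation checks use 100 seeds at n = 500; oracle comparisons use 100–
200 random cases with ≤ 50-node graphs; the end-to-end scene uses an
8-gene, 40–400-sample cohort. Angular tolerance is 1e-9 degrees;
aggregated means are exactly order-invariant by sorted compensated
summation; the layout's minimum-distance pass uses a 0.01-unit slack
against 3-decimal coordinate rounding.

## Known limitations

* Layout is deterministic but makes no aesthetic guarantees (edge
  crossings, symmetry); it is a seeded force-directed placement, not the
  interactive layout of a browsing UI.
* Discrete scales require every observed code to have a color; unseen
  codes raise rather than guess.
* The HTTP service is read-only over data preloaded at startup — no
  uploads, no sessions, no authentication — and is intended for local or
  trusted-network use.
* One sample universe per scene: a matrix whose samples are disjoint
  from a ring's matrix shows as missing spokes, which is intended, but
  there is no per-ring universe.
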