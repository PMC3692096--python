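# circlemapviz

Coordinated multi-omics ring glyphs — **CircleMaps** — drawn around genes in
a typed interaction network, rendered to deterministic SVG.

## The problem

Heatmaps show the dominant structure of one gene × sample matrix, but a
regulatory relationship between two specific genes is easy to miss: the
genes may cluster far apart, and relating a few rows across several
matrices (expression, methylation, copy number, mutation …) strains the
eye. A CircleMap turns each gene into a circular glyph of nested rings —
one ring per data platform, one angular **spoke** per sample — and places
the glyphs on the pathway graph that connects the genes. The defining
property is *coordination*: every ring of every glyph shares one spoke
order, so a sample sits at the same angle everywhere and a trend can be
traced across an entire pathway.

Three operations make the view useful:

* **Sorting** — pick any ring (or a phenotype annotation) and sort the
  spokes ascending or descending; the permutation propagates to all other
  rings of all glyphs. Multi-key sorts are lexicographic (primary key
  first); missing values always sort last.
* **Aggregation** — partition samples by a categorical annotation
  (subtype, phenotype, outcome) and replace each ring's spokes by one
  **segment** per group, colored by `colorize(mean(values))` — the mean is
  taken in value space, so a binary mutation ring aggregates to a
  mutation *frequency* on a white→dark ramp. Segment widths are
  proportional to group sizes.
* **Network algebra** — a large background network ("SuperPathway" style)
  stays out of view; a gene set extracts its induced subnetwork. Further
  interaction networks overlay as colored **tracks** (an edge is drawn
  only between displayed genes; parallel edges from different sources
  stay distinct), and the per-pair *support count* reports how many
  independent tracks confirm a link.

Edges are typed: activation ends in an arrowhead, inhibition in a T-bar,
complex/family membership links are dashed. Nodes are typed too
(protein, complex, family, small molecule, process); proteins with data
become CircleMap glyphs.

## Worked example

`examples/cohort_aggregation.py` builds a synthetic 200-tumor cohort in
which the driver gene BRAF is mutated at rate 0.6 in the hypermutated
subgroup and 0.05 elsewhere, aggregates the binary mutation ring over
the phenotype partition, and renders the aggregated scene:

```
BRAF mutation frequency in non-hypermutated (n=150): 0.047
BRAF mutation frequency in     hypermutated (n= 50): 0.560
wrote cohort_aggregated.svg (21745 bytes): each gene shows 4 rings of 2
segments, widths proportional to group sizes.
```

The two frequencies are the aggregated segment values — empirical group
means of the 0/1 mutation calls, close to the generative rates — and the
SVG shows them as a dark vs near-white segment on BRAF's innermost ring.
The other examples demonstrate the single-sort reveal of an inhibitory
link (`toy_inhibition_sort.py`) and background filtering / multi-track
overlay with support counts (`network_filter_overlay.py`). Run any of
them from an empty directory:

```sh
python examples/toy_inhibition_sort.py
```

## Command line and HTTP service

The `circlemap` command is a thin wrapper over the library:

```sh
circlemap fixtures cohort --out-dir data --seed 3        # synthetic files
circlemap render \
  --matrix mutation:binary:data/mutation.tsv \
  --matrix expression:continuous:data/expression.tsv \
  --network pathway:data/pathway.tsv \
  --genes data/genes.txt \
  --annotation hypermutated:data/hypermutated.tsv \
  --sort annotation:hypermutated:asc --sort ring:BRAF:mutation:desc \
  --seed 7 --out scene.svg
circlemap validate --config recipe.json                  # parse-only check
circlemap serve recipe.json --port 8040                  # GET /render?...
```

Matrix flags are ordered inner→outer ring. `GET /render` takes `genes`,
`rings`, `sort`, `group_by`, `mode` and `seed` parameters and returns a
document byte-identical to the equivalent CLI run; identical inputs,
seed and configuration always produce byte-identical SVG.

File formats: tab-separated gene × sample matrices (`NA`/empty =
missing), two-column sample annotations, one-symbol-per-line gene sets,
SIF networks (`pp`, `-a>`, `-t|`, `component>`, `member>`) and a typed
dialect whose node lines (`protein<TAB>NAME` …) precede edge lines.

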