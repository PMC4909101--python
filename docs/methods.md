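# Methods

## The visualization model

A *small multiple* is one template chart replicated once per condition so
that the eye compares conditions, not chart layouts. Here the template is
a pathway map or network: a set of nodes with fixed canvas geometry
(center, width, height; origin top-left, y down, the shared GPML/SVG
convention) and undirected edges. For k samples the output is k panels in
a row-major grid, each the identical map differing only in node fill
colors and — under the hide policy — node/edge visibility. Nothing else
varies between panels by construction, which is the property the whole
design protects: panel geometry is computed once from the template and
reused, so any visual difference between panels is a difference in data.

Nodes are of two kinds. *Data nodes* are biological entities (GPML
`DataNode` elements — genes, proteins, metabolites alike; all are bound
uniformly) and may receive measurements. *Decorations* (GPML `Label` and
`Shape` elements) are drawn for context, always in the no-data color, and
are never bound or hidden.

## Data binding

Input tables have a header row, one identifier column, and numeric sample
columns. The auto-binding rule is purely positional: the identifier column
first, then — if the remaining column count is even — consecutive
(value, p) pairs, one per sample; if odd, every remaining column is a
value-only sample. The odd-count fallback is deliberate: pairing an odd
residue would require guessing which column lacks its partner, and the two
possible pairings of an odd count are never both total, so value-only is
the only deterministic, explainable choice. Explicit column lists (via the
config file) override the rule.

Identifier matching is exact and case-sensitive against a chosen node
attribute (the label by default, or any attribute such as `xref_id`).
There is no fuzzy matching and no cross-database identifier translation;
users must supply tables keyed the same way as the map. Duplicate table
identifiers are an error by default (silent first-wins hides upstream data
problems); with `allow_duplicates` the first occurrence wins and discards
are counted in a warning.

Bookkeeping satisfies a conservation law checked by the tests:
|matched nodes| + |distinct unmatched identifiers| = |distinct table
identifiers|. A node missing a value cell in one sample is treated in that
panel exactly like a node whose identifier never occurs in the table.

## Coloring

**Fold-change gradient.** No standard interpolation law exists for this
kind of two-color overlay, so the simplest reproducible one is used:
per-channel linear RGB interpolation with three anchors — down color at
−v_max, neutral at 0, up color at +v_max — clamped outside the range,
channels rounded half-up. v_max defaults to `auto`: the maximum |value|
over *all* samples jointly, so every panel shares one scale; per-panel
scales would defeat comparability, which is the point of small multiples.
Properties guaranteed (and property-tested): symmetry (negating the value
swaps the red and green channels under default colors), monotonicity
toward the up color, and agreement within 1 unit/channel with an
independent brute-force interpolation.

**P-value cutoff.** A step function: p ≤ α and value > 0 → up color;
p ≤ α and value < 0 → down color; otherwise neutral. A significant value
of exactly 0 has no direction and stays neutral. α is a free float in
(0, 1] with the four conventional presets 0.001, 0.01, 0.05, 0.1 exposed;
the comparison is inclusive (p = α is significant). This mode requires a
p column for every sample; a value-only sample under this mode is a
configuration error rather than a guess. A bound value whose p cell is
missing is treated as no-data in this mode (the direction is known but its
significance is not, and coloring it would assert significance).

**No-data policy.** Data nodes without a datum are shown in the neutral
fill (default), greyed in the no-data color, or hidden; hiding a node
removes its incident edges in that panel only. Defaults `#FFFFFF`
(neutral) and `#C0C0C0` (no-data) are conventions, both configurable.

## Formats and numerics

- GPML 2013a namespace. Coordinates are taken as-is except for a uniform
  translation moving the map's bounding box to (0, 0). Group containers
  are flattened (data binds to leaf nodes); interactions whose endpoints
  reference unknown GraphIds (e.g. anchors) are dropped with a warning
  rather than failing the whole map. Writing then reading a map preserves
  counts, labels, kinds and coordinates exactly when the bounding box
  already starts at the origin.
- SIF and GraphML carry no geometry (GraphML only when `x`/`y` keys are
  absent); nodes are placed on a circle of radius proportional to node
  count, ordered by first appearance — deterministic by construction.
- Tables are UTF-8 with decimal-point floats only. Locale comma decimals
  are unsupported: with semicolon separators they are ambiguous, so this
  is documented as a limitation rather than guessed at. Non-numeric,
  empty and non-finite cells are all "missing". Separator sniffing scores
  each candidate (tab, comma, semicolon, whitespace) by the column count
  it yields, requiring ≥ 2 consistent columns over the first ten lines;
  ties break toward the more specific separator (tab first, whitespace
  last).
- SVG output is deterministic: fixed attribute order, coordinates
  formatted to two decimals with trailing zeros stripped, a single
  generic `sans-serif` family, no font embedding. Edges are straight
  segments between node centers clipped at node borders; panel titles are
  the sample names (value-column headers). The legend (up / neutral /
  down / no-data swatches) is an extension of the classic overlay design,
  documented as such.

## The synthetic data generator

`fixtures` builds matched map/table pairs so every stage is testable
without downloads. Defaults emulate a five-sample treatment time course
("0h", "2h", "12h", "24h", "72h") with per-sample p-values over a 20-gene
pathway with 24 edges and 2 decorations — the shape of a typical
time-resolved expression overlay on a central-metabolism map. Values are
zero-mean normal with sd 1.0 (log2-fold-change-like); per sample, each row
is significant with probability `frac_significant` (default 0.4), drawing
p uniformly from [0, 0.025], and otherwise from (0.05, 1], so the 0.05
reference threshold separates the two populations cleanly. A
`frac_unmatched` fraction of rows (default 0.1) gets novel identifiers to
exercise the unmatched path. All draws come from one seeded generator:
same seed, same bytes.

What the generator does *not* emulate: real microarray/RNA-seq noise
structure, correlated significance across time points, many-to-one
probe-to-gene mappings, and real pathway topology (edges are uniform
random pairs; the layout is a grid). Passing tests therefore demonstrate
the mechanics — parsing, binding, coloring, composition — not biological
plausibility of any particular figure.

## Problem sizes

Tests and the acceptance script run maps of 6–25 nodes with 1–10 samples
and up to 100 seeded replicates per invariant; these sizes already
exercise every code path (ties, odd column counts, unmatched identifiers,
hidden hubs) while keeping the whole suite near-instant. The renderer is
linear in nodes × samples and has no practical limit at figure scale.

## Known limitations

- No identifier translation (BridgeDb-style) and no aggregation of
  multiple table rows per node.
- GPML shape fidelity is a non-goal: all nodes render as rounded
  rectangles; GPML edge waypoints/anchors are ignored in favor of straight
  center-to-center segments.
- No PNG/PDF rasterization, no interactive preview, no live WikiPathways
  download.
- One value channel per node: no border-color, node-size or multi-ring
  encodings.
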