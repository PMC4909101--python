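# pathpanels

Project per-sample high-throughput measurements — expression fold changes,
metabolite levels, anything with one signed value (and optionally a
p-value) per biological entity per sample — onto a pathway or network map
as **small multiples**: one colored copy of the map per sample, composed
into a single SVG. Because every panel is the *same* map with only node
fills changing, differences between time points, tissues or treatments are
read across panels by eye, which is exactly what node-level charts on a
single network view make hard.

It is a headless library plus a thin `pathpanels` command, aimed at
computational biologists who want reproducible pathway-overlay figures
from scripts or pipelines rather than from a GUI.

## What it does

1. **Map import** — GPML (the WikiPathways/PathVisio XML dialect); plain
   networks as SIF or GraphML. GPML `DataNode`s become bindable entities;
   `Label`/`Shape` elements become decorations that are drawn grey and
   never carry data. Formats without geometry get a deterministic circular
   layout.
2. **Data import** — delimited text (comma, semicolon, tab or whitespace,
   sniffed automatically) with an identifier column followed by per-sample
   columns. Auto-binding follows column order: an even residual column
   count pairs up as (value, p) per sample; an odd count yields value-only
   samples. Matching against map nodes is exact and case-sensitive.
3. **Styling** — two modes. *Fold-change gradient*: per-channel linear RGB
   interpolation from the down color at −v_max through neutral at 0 to the
   up color at +v_max (shared scale across all panels). *P-value cutoff*:
   a node is colored by the sign of its value iff p ≤ α, else neutral;
   presets α ∈ {0.001, 0.01, 0.05, 0.1}. Defaults: green `#00FF00` up,
   red `#FF0000` down, white neutral, grey `#C0C0C0` no-data. Nodes
   without data can be shown, greyed out, or hidden (hiding a node also
   hides its edges).
4. **Export** — one standalone deterministic SVG: a titled panel per
   sample plus a legend.

## Worked example

```sh
pathpanels fixtures --out-prefix demo --seed 2     # synthetic GPML + CSV
pathpanels render --network demo.gpml --data demo.csv \
    --mode pvalue --cutoff 0.1 --no-data grey --out demo.svg
```

or from Python (`examples/01_render_time_course.py`):

```text
samples: ['0h', '2h', '12h', '24h', '72h']
matched 18 of 20 map genes; unmatched identifiers: ['U1', 'U2']
wrote time_course.svg: 5 panels, 1760 x 744 canvas units
```

Five samples → five panels. 18 of the 20 map genes found a table row
(two rows carry identifiers absent from the map and are reported, not
fatal); in each panel, green/red nodes changed significantly at p ≤ 0.1
in that sample, white ones did not, grey ones have no data there.

The gradient law (`examples/02_fold_change_gradient.py`):

```text
value -2.0 on scale +/-2 -> #FF0000
value -1.0 on scale +/-2 -> #FF8080
value +0.0 on scale +/-2 -> #FFFFFF
value +1.0 on scale +/-2 -> #80FF80
value +2.0 on scale +/-2 -> #00FF00
```

`examples/03_read_formats.py` shows separator sniffing, SIF reading and a
GPML round trip.

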