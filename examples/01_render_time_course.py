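"""Render a five-sample time course as small multiples.

Builds a synthetic ~20-gene pathway and a matching table of per-sample
log2-fold-change-like values with p-values, binds them, colors nodes by
significance (p <= 0.1: green up, red down; else white; grey = no data),
and writes one SVG with five panels.
"""

from pathpanels import (
    ColorMode,
    NoDataPolicy,
    VisualStyle,
    auto_bind,
    build_panels,
    match_identifiers,
    render_svg,
    use_case_fixture,
)

network, table = use_case_fixture(seed=1)
spec = auto_bind(table)
binding = match_identifiers(network, table, spec)
style = VisualStyle(mode=ColorMode.P_VALUE_CUTOFF, cutoff=0.1,
                    no_data_policy=NoDataPolicy.GREY)
panels = build_panels(network, binding, spec, style)
document = render_svg(panels, network, style=style)

with open("time_course.svg", "w", encoding="utf-8") as handle:
    handle.write(document.svg_text)

print(f"samples: {[s.name for s in spec.series]}")
print(f"matched {len(binding.matched_node_ids)} of "
      f"{len(network.data_nodes)} map genes; "
      f"unmatched identifiers: {binding.unmatched_identifiers}")
print(f"wrote time_course.svg: {len(panels)} panels, "
      f"{document.width:g} x {document.height:g} canvas units")
# Each panel is the same map; green/red fills mark genes whose change is
# significant at p <= 0.1 in that sample, so trends are read across panels.
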