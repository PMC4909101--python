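"""Inspect the fold-change gradient law.

Colors interpolate per RGB channel from red (-vmax) through white (0) to
green (+vmax), clamped outside the range.  With vmax="auto" all panels
share the largest absolute value as their scale.
"""

from pathpanels import VisualStyle, color_for_value

style = VisualStyle()
vmax = 2.0
for value in (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0):
    print(f"value {value:+.1f} on scale +/-{vmax:g} -> "
          f"{color_for_value(value, style, vmax)}")
# -2 and below are pure red #FF0000, +2 and above pure green #00FF00,
# 0 is white, and +/-1 sit exactly halfway (#80FF80 / #FF8080).
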