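"""Map node data (or its absence) to fill colors and visibility.

Two coloring modes:

* ``fold_change_gradient`` — piecewise-linear per-channel RGB interpolation
  from ``down_color`` at ``-vmax`` through ``neutral_color`` at 0 to
  ``up_color`` at ``+vmax``, clamped outside that range.
* ``p_value_cutoff`` — a step function: nodes whose p-value is at or below
  the cutoff are colored by the sign of their value (up/down), everything
  else is neutral.

Defaults follow the field convention for expression overlays: green
``#00FF00`` for up-regulation, red ``#FF0000`` for down-regulation, white
for no change and light grey for map elements without data.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, replace

from .binding import NodeDatum
from .model import ConfigError, Node

#: The selectable significance thresholds exposed as presets.
P_VALUE_CUTOFF_PRESETS: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)

_HEX_RE = re.compile(r"#[0-9A-Fa-f]{6}$")


class ColorMode(enum.Enum):
    FOLD_CHANGE_GRADIENT = "fold_change_gradient"
    P_VALUE_CUTOFF = "p_value_cutoff"


class NoDataPolicy(enum.Enum):
    SHOW = "show"
    GREY = "grey"
    HIDE = "hide"


@dataclass(frozen=True)
class VisualStyle:
    """Colors, coloring mode, significance cutoff and no-data policy."""

    up_color: str = "#00FF00"
    down_color: str = "#FF0000"
    neutral_color: str = "#FFFFFF"
    no_data_color: str = "#C0C0C0"
    mode: ColorMode = ColorMode.FOLD_CHANGE_GRADIENT
    cutoff: float = 0.05
    no_data_policy: NoDataPolicy = NoDataPolicy.SHOW
    value_max: float | str = "auto"

    def __post_init__(self) -> None:
        for color in (self.up_color, self.down_color, self.neutral_color, self.no_data_color):
            if not _HEX_RE.match(color):
                raise ConfigError(f"not an #RRGGBB color: {color!r}")
        if not 0.0 < self.cutoff <= 1.0:
            raise ConfigError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.value_max != "auto":
            if not isinstance(self.value_max, (int, float)) or self.value_max <= 0:
                raise ConfigError(f"value_max must be positive or 'auto', got {self.value_max!r}")

    def with_(self, **changes) -> "VisualStyle":
        return replace(self, **changes)


@dataclass(frozen=True)
class NodeAppearance:
    fill: str
    visible: bool


def parse_hex(color: str) -> tuple[int, int, int]:
    return int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16)


def format_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _interpolate(c0: str, c1: str, t: float) -> str:
    a, b = parse_hex(c0), parse_hex(c1)
    return format_hex(tuple(_round_half_up(a[i] + (b[i] - a[i]) * t) for i in range(3)))


def color_for_value(value: float, style: VisualStyle, vmax: float) -> str:
    """Gradient fill for a signed value on the symmetric scale [-vmax, vmax].

    Values at or beyond the scale ends clamp to the pure up/down colors;
    zero is the neutral anchor; in between, each RGB channel interpolates
    linearly toward the adjacent anchor (rounded half-up).
    """
    if not math.isfinite(value):
        raise ValueError("non-finite values must be treated as missing upstream")
    if vmax <= 0:
        raise ValueError(f"vmax must be positive, got {vmax}")
    if value >= vmax:
        return style.up_color
    if value <= -vmax:
        return style.down_color
    if value == 0:
        return style.neutral_color
    target = style.up_color if value > 0 else style.down_color
    return _interpolate(style.neutral_color, target, abs(value) / vmax)


def color_for_significance(value: float, p: float, style: VisualStyle) -> str:
    """Step-function fill: direction color iff p <= cutoff, else neutral.

    A significant value of exactly zero has no direction and stays neutral.
    """
    if not math.isfinite(value):
        raise ValueError("non-finite values must be treated as missing upstream")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p > style.cutoff or value == 0:
        return style.neutral_color
    return style.up_color if value > 0 else style.down_color


def node_appearance(
    node: Node,
    datum: NodeDatum | None,
    style: VisualStyle,
    vmax: float,
) -> NodeAppearance:
    """Resolve a node's fill and visibility under the style.

    Decoration nodes are always drawn in the no-data color and are never
    hidden.  Data nodes without a datum follow the no-data policy: shown
    in the neutral fill, greyed in the no-data color, or hidden.  In
    p-value-cutoff mode a bound datum without a p-value counts as no data.
    """
    if not node.is_data_node:
        return NodeAppearance(fill=style.no_data_color, visible=True)
    if datum is not None and style.mode is ColorMode.P_VALUE_CUTOFF and datum.p is None:
        datum = None
    if datum is None:
        if style.no_data_policy is NoDataPolicy.HIDE:
            return NodeAppearance(fill=style.no_data_color, visible=False)
        if style.no_data_policy is NoDataPolicy.GREY:
            return NodeAppearance(fill=style.no_data_color, visible=True)
        return NodeAppearance(fill=style.neutral_color, visible=True)
    if style.mode is ColorMode.P_VALUE_CUTOFF:
        fill = color_for_significance(datum.value, datum.p, style)
    else:
        fill = color_for_value(datum.value, style, vmax)
    return NodeAppearance(fill=fill, visible=True)
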