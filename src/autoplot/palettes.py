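"""Default colour palettes.

Quantitative plots default to Paul Tol's qualitative schemes (colour-blind
aware); conditions beyond the palette length cycle. Tracing plots use two
fixed scales so stacked isotopologue bars look identical across experiments:

* the short scale covers M+0..M+7 — a rainbow-like 8-colour scheme with
  saturation and value raised for punchier stacks;
* the long scale covers M+0..M+15 — a neutral grey for the unlabelled M+0
  followed by a stepped rainbow of 5 hue blocks in 3 shades each, so the
  block a segment falls in reads off the labelled-atom count at a glance.
"""

from __future__ import annotations

import colorsys

#: Paul Tol "bright" qualitative scheme.
TOL_BRIGHT = (
    "#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE", "#AA3377", "#BBBBBB",
)

#: Paul Tol "muted" qualitative scheme (used when more classes are needed).
TOL_MUTED = (
    "#CC6677", "#332288", "#DDCC77", "#117733", "#88CCEE", "#882255",
    "#44AA99", "#999933", "#AA4499", "#DDDDDD",
)


def _boost(hex_colour: str, sat: float = 1.2, val: float = 1.2) -> str:
    """Scale saturation and value of a hex colour by 20% (clipped at 1)."""
    r, g, b = (int(hex_colour[i:i + 2], 16) / 255 for i in (1, 3, 5))
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    r, g, b = colorsys.hsv_to_rgb(h, min(1.0, s * sat), min(1.0, v * val))
    return "#{:02X}{:02X}{:02X}".format(round(r * 255), round(g * 255), round(b * 255))


#: Tol rainbow stops (discrete 8-class rainbow), before the boost.
_TOL_RAINBOW8 = (
    "#781C81", "#3F56A7", "#4B91C0", "#5FAA9F", "#91BD61", "#D8AF3D",
    "#E77C30", "#D92120",
)

#: Short tracing scale: M+0..M+7.
TRACING_SHORT = tuple(_boost(c) for c in _TOL_RAINBOW8)

#: Long tracing scale: M+0 in neutral grey, then 5 hue blocks x 3 shades
#: (dark -> light within each block) covering M+1..M+15.
_STEPPED_HUES = ("#2166AC", "#1B7837", "#B8860B", "#D95F02", "#B2182B")


def _shades(hex_colour: str) -> tuple[str, str, str]:
    r, g, b = (int(hex_colour[i:i + 2], 16) / 255 for i in (1, 3, 5))
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    out = []
    for s_f, v_f in ((1.0, 0.8), (0.75, 1.0), (0.45, 1.15)):
        rr, gg, bb = colorsys.hsv_to_rgb(h, min(1.0, s * s_f), min(1.0, v * v_f))
        out.append("#{:02X}{:02X}{:02X}".format(round(rr * 255), round(gg * 255),
                                                round(bb * 255)))
    return tuple(out)


TRACING_LONG = ("#888888",) + tuple(c for hue in _STEPPED_HUES for c in _shades(hue))


def quantitative_colours(n: int) -> list[str]:
    """Default colours for n conditions."""
    base = TOL_BRIGHT if n <= len(TOL_BRIGHT) else TOL_MUTED
    return [base[i % len(base)] for i in range(n)]


def tracing_colours(kind: str, max_shift: int) -> list[str]:
    """Colours for stacked isotopologue bars, cycling beyond the scale end."""
    scale = {"short": TRACING_SHORT, "long": TRACING_LONG}.get(kind)
    if scale is None:
        raise ValueError(f"unknown tracing scale {kind!r}; use 'short' or 'long'")
    return [scale[i % len(scale)] for i in range(max_shift + 1)]
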