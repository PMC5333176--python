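"""Deterministic SVG emission for superposed/juxtaposed scenes.

No drawing library is used: the document is assembled from fixed-format
strings so identical inputs yield byte-identical output.  Helices are drawn
as sinusoid paths (a spiral seen from the side), sheets as arrow polygons,
coils as lines and gaps as gray rectangles; a navigation strip with one
line per chain (black segments for gaps, interruptions at chain breaks)
sits below the glyph panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .layout import Glyph, Scene

__all__ = ["RenderConfig", "render_svg"]

_PALETTE = [
    "#1f77b4",
    "#ff7f0e",
    "#2ca02c",
    "#d62728",
    "#9467bd",
    "#8c564b",
    "#e377c2",
    "#17becf",
]


@dataclass
class RenderConfig:
    palette: list[str] = field(default_factory=lambda: list(_PALETTE))
    stroke_width: float = 2.0
    row_height: float = 48.0
    gap_fill: str = "#bbbbbb"
    nav_gap_fill: str = "#000000"
    highlight_fill: str = "#00aa44"
    font: str = "monospace"
    font_size: float = 10.0
    margin: float = 24.0
    glyph_height: float = 14.0
    nav_height: float = 6.0
    nav_spacing: float = 10.0
    nav_scale: float = 8.0  # horizontal units per column in the strip
    opacity_superposed: float = 0.75
    highlight_ids: frozenset[str] = frozenset()

    def color(self, track: int) -> str:
        return self.palette[track % len(self.palette)]


def _f(v: float) -> str:
    return f"{v:.3f}"


def _helix_path(x: float, y: float, length: float, height: float) -> str:
    """Sinusoid polyline approximating a side-on spiral."""
    period = max(height, 1e-6)
    n = max(int(round(length / period)) * 4, 4)
    pts = []
    for k in range(n + 1):
        t = k / n
        px = x + t * length
        py = y - (height / 2.0) * math.sin(2.0 * math.pi * length / period * t)
        pts.append(f"{_f(px)},{_f(py)}")
    return "M" + " L".join(pts)


def _sheet_points(x: float, y: float, length: float, height: float) -> str:
    h = height / 2.0
    head = min(length * 0.4, height)
    bx = x + length - head
    pts = [
        (x, y - h / 2),
        (bx, y - h / 2),
        (bx, y - h),
        (x + length, y),
        (bx, y + h),
        (bx, y + h / 2),
        (x, y + h / 2),
    ]
    return " ".join(f"{_f(px)},{_f(py)}" for px, py in pts)


def _glyph_svg(g: Glyph, color: str, baseline: float, cfg: RenderConfig) -> str:
    x, y = g.anchor[0], baseline - g.anchor[1]
    gh = cfg.glyph_height
    if g.kind == "GAP":
        return (
            f'<rect class="gap-rect" x="{_f(x)}" y="{_f(y - gh / 2)}" '
            f'width="{_f(g.length)}" height="{_f(gh)}" fill="{cfg.gap_fill}" />'
        )
    if g.sse_id is not None and g.sse_id in cfg.highlight_ids:
        color = cfg.highlight_fill
    rotate = ""
    if abs(g.angle_deg) > 1e-9:
        # screen y grows downward, so a positive (counter-clockwise) spatial
        # angle maps to a negative SVG rotation
        rotate = f' transform="rotate({_f(-g.angle_deg)} {_f(x)} {_f(y)})"'
    sid = g.sse_id or ""
    if g.kind == "HELIX":
        body = (
            f'<path class="glyph helix" data-sse="{sid}" d="{_helix_path(x, y, g.length, gh)}" '
            f'fill="none" stroke="{color}" stroke-width="{_f(cfg.stroke_width)}"{rotate} />'
        )
    elif g.kind == "SHEET":
        body = (
            f'<polygon class="glyph sheet" data-sse="{sid}" '
            f'points="{_sheet_points(x, y, g.length, gh)}" fill="{color}"{rotate} />'
        )
    else:  # COIL
        body = (
            f'<line class="glyph coil" data-sse="{sid}" x1="{_f(x)}" y1="{_f(y)}" '
            f'x2="{_f(x + g.length)}" y2="{_f(y)}" stroke="{color}" '
            f'stroke-width="{_f(cfg.stroke_width / 2)}"{rotate} />'
        )
    return body


def _panel(scene: Scene, cfg: RenderConfig, juxtaposed: bool, y0: float) -> tuple[list[str], float]:
    parts: list[str] = []
    n_tracks = len(scene.tracks)
    height = cfg.row_height * (n_tracks if juxtaposed else 1) + cfg.row_height
    for t, glyphs in enumerate(scene.tracks):
        baseline = y0 + cfg.row_height * ((t + 0.5) if juxtaposed else 0.5)
        color = cfg.color(t)
        opacity = 1.0 if juxtaposed else cfg.opacity_superposed
        parts.append(
            f'<g class="track" id="{"jux" if juxtaposed else "sup"}-track-{t}" '
            f'opacity="{_f(opacity)}">'
        )
        if juxtaposed:
            parts.append(
                f'<text x="{_f(4.0)}" y="{_f(baseline - cfg.row_height / 4)}" '
                f'font-family="{cfg.font}" font-size="{_f(cfg.font_size)}" '
                f'fill="{color}">{scene.labels[t]}</text>'
            )
        for g in glyphs:
            parts.append(_glyph_svg(g, color, baseline, cfg))
        parts.append("</g>")
    return parts, y0 + height


def _nav_strip(scene: Scene, cfg: RenderConfig, y0: float) -> tuple[list[str], float]:
    parts = [f'<g class="navigation">']
    y = y0
    for t, segs in enumerate(scene.navigation.segments):
        color = cfg.color(t)
        breaks = sorted(s.start for s in segs if s.kind == "break")
        for seg in segs:
            if seg.kind == "break":
                continue
            spans = _split_span(seg.start, seg.stop, breaks)
            for a, b in spans:
                x1 = cfg.margin + a * cfg.nav_scale
                x2 = cfg.margin + b * cfg.nav_scale
                if seg.kind == "gap":
                    parts.append(
                        f'<rect class="nav-gap" x="{_f(x1)}" y="{_f(y - cfg.nav_height / 2)}" '
                        f'width="{_f(x2 - x1)}" height="{_f(cfg.nav_height)}" '
                        f'fill="{cfg.nav_gap_fill}" />'
                    )
                else:
                    parts.append(
                        f'<line class="nav-chain" x1="{_f(x1 + 0.5)}" y1="{_f(y)}" '
                        f'x2="{_f(x2 - 0.5)}" y2="{_f(y)}" stroke="{color}" '
                        f'stroke-width="{_f(cfg.nav_height / 2)}" />'
                    )
        y += cfg.nav_spacing
    parts.append("</g>")
    return parts, y


def _split_span(start: int, stop: int, breaks: list[int]) -> list[tuple[int, int]]:
    spans = []
    a = start
    for b in breaks:
        if start < b < stop:
            spans.append((a, b))
            a = b
    spans.append((a, stop))
    return [(x, y) for x, y in spans if y > x]


def render_svg(scene: Scene, config: RenderConfig | None = None) -> str:
    """Render a scene (superposed, juxtaposed or both panels) to SVG text."""
    cfg = config or RenderConfig()
    body: list[str] = []
    y = cfg.margin
    modes = ["superposed", "juxtaposed"] if scene.mode == "both" else [scene.mode]
    for m in modes:
        body.append(f'<g class="panel panel-{m}" transform="translate({_f(cfg.margin)} 0)">')
        parts, y = _panel(scene, cfg, juxtaposed=(m == "juxtaposed"), y0=y)
        body.extend(parts)
        body.append("</g>")
        y += cfg.margin / 2
    nav, y = _nav_strip(scene, cfg, y)
    body.extend(nav)
    width = cfg.margin * 2 + max(
        [a + w for a, w in zip(scene.column_anchors, scene.column_widths)] or [100.0],
        default=100.0,
    )
    height = y + cfg.margin
    doc = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">',
        *body,
        "</svg>",
    ]
    return "\n".join(doc) + "\n"
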