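"""2D glyph geometry: straightened reference track, per-SSE angle/shift/length.

The reference chain is drawn completely straightened along +x.  For every
aligned SSE the glyph is placed at its column's reference anchor, offset by
the 2D shift and rotated by the signed angle, both derived from the
superposed 3D coordinates:

* angle — the 3D angle between the two SSE direction vectors (CA of first
  residue to CA of last residue), signed by the z component of
  ``ref_dir x other_dir`` in the superposed world frame;
* shift — the centroid displacement expressed in the reference SSE's local
  frame (x along the reference direction, y from world-z x direction), with
  the out-of-plane component discarded.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gap_alignment import ColumnAlignment, GappedChain, is_gap
from .structure_io import ProteinChain, SecondaryStructureElement, SSEKind

__all__ = [
    "LayoutConfig",
    "Axis",
    "Glyph",
    "NavSegment",
    "NavigationStrip",
    "Scene",
    "sse_axis",
    "glyph_length",
    "glyph_angle",
    "glyph_shift",
    "local_frame",
    "build_scene",
]


@dataclass
class LayoutConfig:
    scale: float = 4.0  # layout units per Å (helix/sheet glyph length)
    coil_residue_width: float = 2.0  # layout units per coil residue
    spacing: float = 3.0  # horizontal padding between columns
    gap_width: float = 8.0  # width of a gray gap rectangle
    min_glyph_length: float = 2.0  # floor for degenerate (1-residue) SSEs
    row_height: float = 48.0  # vertical offset per track in juxtaposed mode
    # '3d': full 3D angle magnitude, sign from the cross product's z component.
    # 'projected': angle between the two directions projected onto the xy plane.
    angle_mode: str = "3d"


@dataclass(frozen=True)
class Axis:
    start: np.ndarray
    end: np.ndarray
    direction: Optional[np.ndarray]  # unit vector, None when start == end


def sse_axis(chain: ProteinChain, sse: SecondaryStructureElement) -> Axis:
    """Axis through the CA of the SSE's first and last residue."""
    coords = chain.sse_coords(sse)
    start, end = coords[0], coords[-1]
    v = end - start
    norm = float(np.linalg.norm(v))
    if norm < 1e-9:
        return Axis(start, end, None)
    return Axis(start, end, v / norm)


def glyph_length(
    chain: ProteinChain,
    sse: SecondaryStructureElement,
    scale: float = 4.0,
    config: LayoutConfig | None = None,
) -> float:
    """Drawable length: 3D end-to-end distance x scale for helix/sheet,
    residue count x per-residue width for coil."""
    cfg = config or LayoutConfig(scale=scale)
    if sse.kind is SSEKind.COIL:
        return sse.residue_count * cfg.coil_residue_width
    ax = sse_axis(chain, sse)
    length = float(np.linalg.norm(ax.end - ax.start)) * scale
    return max(length, cfg.min_glyph_length)


def glyph_angle(ref_axis: Axis, other_axis: Axis, mode: str = "3d") -> float:
    """Signed degrees in (-180, 180] between two SSE axes.

    Magnitude is the 3D angle between the unit directions; the sign comes
    from the z component of ``ref_dir x other_dir`` (the superposed world
    frame's viewing axis).  ``mode='projected'`` instead measures the angle
    between the directions projected onto the xy plane.
    """
    if ref_axis.direction is None or other_axis.direction is None:
        warnings.warn("undefined SSE direction: angle defaults to 0")
        return 0.0
    u, v = ref_axis.direction, other_axis.direction
    if mode == "projected":
        u = np.array([u[0], u[1], 0.0])
        v = np.array([v[0], v[1], 0.0])
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            warnings.warn("degenerate projection: angle defaults to 0")
            return 0.0
        u, v = u / nu, v / nv
    cross = np.cross(u, v)
    # atan2 form is well-conditioned near 0 and 180 deg (acos is not)
    mag = math.degrees(math.atan2(float(np.linalg.norm(cross)), float(np.dot(u, v))))
    cross_z = float(cross[2])
    if cross_z < 0:
        mag = -mag
    if mag <= -180.0:
        mag = 180.0
    return mag


def local_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (x̂, ŷ) of the reference SSE's in-plane frame.

    x̂ is the SSE direction; ŷ = world-z x x̂ (normalized), falling back to
    world-y x x̂ when the direction is parallel to world-z.
    """
    xhat = np.asarray(direction, dtype=float)
    xhat = xhat / np.linalg.norm(xhat)
    up = np.array([0.0, 0.0, 1.0])
    yhat = np.cross(up, xhat)
    if np.linalg.norm(yhat) < 1e-9:
        yhat = np.cross(np.array([0.0, 1.0, 0.0]), xhat)
    return xhat, yhat / np.linalg.norm(yhat)


def glyph_shift(
    ref_chain: ProteinChain,
    ref_sse: SecondaryStructureElement,
    other_chain: ProteinChain,
    other_sse: SecondaryStructureElement,
    scale: float = 4.0,
) -> tuple[float, float]:
    """2D offset (along, across) of the aligned glyph relative to its reference.

    The 3D centroid displacement is projected onto the reference SSE's local
    frame; the out-of-plane component is discarded.
    """
    ax = sse_axis(ref_chain, ref_sse)
    if ax.direction is None:
        warnings.warn("undefined reference direction: shift defaults to (0, 0)")
        return (0.0, 0.0)
    d = other_chain.sse_coords(other_sse).mean(axis=0) - ref_chain.sse_coords(ref_sse).mean(axis=0)
    xhat, yhat = local_frame(ax.direction)
    return (float(np.dot(d, xhat)) * scale, float(np.dot(d, yhat)) * scale)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------


@dataclass
class Glyph:
    sse_id: Optional[str]  # None for GAP
    kind: str  # 'HELIX' | 'SHEET' | 'COIL' | 'GAP'
    column: int
    track: int
    anchor: tuple[float, float]  # start point, shift already applied
    angle_deg: float
    length: float
    shift: tuple[float, float] = (0.0, 0.0)

    def to_dict(self) -> dict:
        return {
            "sse_id": self.sse_id,
            "kind": self.kind,
            "column": self.column,
            "track": self.track,
            "anchor": [self.anchor[0], self.anchor[1]],
            "angle_deg": self.angle_deg,
            "length": self.length,
            "shift": [self.shift[0], self.shift[1]],
        }


@dataclass(frozen=True)
class NavSegment:
    kind: str  # 'chain' | 'gap' | 'break'
    start: int  # column, inclusive
    stop: int  # column, exclusive (== start for zero-width break markers)


@dataclass
class NavigationStrip:
    """Per-chain overview: chain/gap column runs plus break markers.

    For each chain the chain/gap segments partition [0, column_count);
    'break' entries are zero-width markers at the column where a polymer
    discontinuity begins.
    """

    segments: list[list[NavSegment]]
    column_count: int


@dataclass
class Scene:
    alignment: ColumnAlignment
    tracks: list[list[Glyph]]
    navigation: NavigationStrip
    mode: str  # 'superposed' | 'juxtaposed'
    visible_range: tuple[int, int]
    labels: list[str]
    config: LayoutConfig = field(default_factory=LayoutConfig)
    column_anchors: list[float] = field(default_factory=list)
    column_widths: list[float] = field(default_factory=list)

    def to_json(self, indent: int | None = None) -> str:
        doc = {
            "mode": self.mode,
            "visible_range": list(self.visible_range),
            "labels": self.labels,
            "column_anchors": self.column_anchors,
            "column_widths": self.column_widths,
            "tracks": [[g.to_dict() for g in t] for t in self.tracks],
            "navigation": [
                [{"kind": s.kind, "start": s.start, "stop": s.stop} for s in segs]
                for segs in self.navigation.segments
            ],
        }
        return json.dumps(doc, indent=indent, sort_keys=True)


def _nav_segments(row: GappedChain) -> list[NavSegment]:
    segs: list[NavSegment] = []
    for c, slot in enumerate(row.slots):
        kind = "gap" if is_gap(slot) else "chain"
        if segs and segs[-1].kind == kind:
            segs[-1] = NavSegment(kind, segs[-1].start, c + 1)
        else:
            segs.append(NavSegment(kind, c, c + 1))
    return segs


def _break_markers(row: GappedChain) -> list[NavSegment]:
    chain = row.source
    if chain is None or not chain.segment_breaks:
        return []
    markers = []
    for b in sorted(chain.segment_breaks):
        col = None
        for c, slot in enumerate(row.slots):
            if is_gap(slot):
                continue
            sse = chain.sse_by_id(slot)
            if sse.start >= b:
                col = c
                break
        if col is not None:
            markers.append(NavSegment("break", col, col))
    return markers


def build_scene(
    col_align: ColumnAlignment,
    mode: str = "superposed",
    visible_range: tuple[int, int] | None = None,
    config: LayoutConfig | None = None,
) -> Scene:
    """Compute all glyph geometry for a column alignment.

    Every GappedChain in ``col_align`` must carry its source chain (with
    superposed coordinates).  Reference glyphs are laid collinearly left to
    right; aligned glyphs get their column anchor plus shift, rotated by the
    signed angle about the glyph start.  Gap slots become fixed-width gray
    rectangles.  The navigation strip always covers the full column range.
    """
    cfg = config or LayoutConfig()
    ncol = col_align.column_count
    lo, hi = visible_range if visible_range is not None else (0, ncol)
    if not (0 <= lo < hi <= max(ncol, 1)):
        raise ValueError(f"empty or invalid visible range [{lo}, {hi}) for {ncol} columns")

    rows = col_align.gapped
    ref_row = rows[col_align.reference_index]
    ref_chain = ref_row.source
    if any(r.source is None for r in rows):
        raise ValueError("build_scene requires GappedChains with source chains attached")

    # column widths: widest glyph needed in each column across all tracks
    widths = []
    for c in range(ncol):
        w = cfg.gap_width
        for row in rows:
            slot = row.slots[c]
            if not is_gap(slot):
                sse = row.source.sse_by_id(slot)
                w = max(w, glyph_length(row.source, sse, cfg.scale, cfg))
        widths.append(w)
    anchors = []
    x = 0.0
    for c in range(ncol):
        anchors.append(x)
        x += widths[c] + cfg.spacing

    tracks: list[list[Glyph]] = []
    for t, row in enumerate(rows):
        chain = row.source
        glyphs: list[Glyph] = []
        prev: Glyph | None = None
        prev_sse: SecondaryStructureElement | None = None
        for c in range(lo, hi):
            slot = row.slots[c]
            if is_gap(slot):
                glyphs.append(
                    Glyph(None, "GAP", c, t, (anchors[c], 0.0), 0.0, cfg.gap_width)
                )
                continue
            sse = chain.sse_by_id(slot)
            length = glyph_length(chain, sse, cfg.scale, cfg)
            angle = 0.0
            shift = (0.0, 0.0)
            ref_slot = ref_row.slots[c]
            if t != col_align.reference_index and not is_gap(ref_slot):
                ref_sse = ref_chain.sse_by_id(ref_slot)
                angle = glyph_angle(
                    sse_axis(ref_chain, ref_sse), sse_axis(chain, sse), cfg.angle_mode
                )
                shift = glyph_shift(ref_chain, ref_sse, chain, sse, cfg.scale)
            g = Glyph(
                sse_id=slot,
                kind=sse.kind.value,
                column=c,
                track=t,
                anchor=(anchors[c] + shift[0], shift[1]),
                angle_deg=angle,
                length=length,
                shift=shift,
            )
            # coil connector between consecutive drawable SSEs of this chain
            if prev is not None and prev_sse is not None:
                coil = _coil_between(chain, prev_sse, sse)
                if coil is not None:
                    glyphs.append(
                        Glyph(
                            sse_id=coil.sse_id,
                            kind="COIL",
                            column=prev.column,
                            track=t,
                            anchor=(prev.anchor[0] + prev.length, prev.anchor[1]),
                            angle_deg=0.0,
                            length=glyph_length(chain, coil, cfg.scale, cfg),
                        )
                    )
            glyphs.append(g)
            prev, prev_sse = g, sse
        tracks.append(glyphs)

    nav = NavigationStrip(
        segments=[_nav_segments(row) + _break_markers(row) for row in rows],
        column_count=ncol,
    )
    return Scene(
        alignment=col_align,
        tracks=tracks,
        navigation=nav,
        mode=mode,
        visible_range=(lo, hi),
        labels=[row.label or (row.source.source_id if row.source else "") for row in rows],
        config=cfg,
        column_anchors=anchors,
        column_widths=widths,
    )


def _coil_between(
    chain: ProteinChain,
    left: SecondaryStructureElement,
    right: SecondaryStructureElement,
) -> SecondaryStructureElement | None:
    for sse in chain.sses:
        if sse.kind is SSEKind.COIL and sse.start == left.end + 1 and sse.end == right.start - 1:
            return sse
    return None
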