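"""Synthetic structures with known ground truth.

Chains are built from ideal blocks (textbook stereochemistry: alpha-helix
rise 1.5 Å/residue, 100 deg/residue twist, 2.3 Å CA radius; extended strand
3.5 Å/residue), perturbed by per-SSE rigid rotations/translations, optional
coordinate noise and SSE deletions, and expanded into trajectories with
per-SSE flexibility.  Every generator is deterministic under a fixed seed
and returns the ground-truth record the tests compare against; the expected
angles and shifts are computed here with local math, independent of the
layout module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .correspondence import CorrespondenceMap, candidate_pairs
from .structure_io import (
    ProteinChain,
    Residue,
    SecondaryStructureElement,
    SSEKind,
    Trajectory,
    tile_from_kinds,
)

__all__ = [
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
    "HELIX_RADIUS",
    "STRAND_RISE",
    "ChainSpec",
    "RotationOp",
    "PerturbationSpec",
    "SSEGroundTruth",
    "GroundTruth",
    "build_chain",
    "perturb",
    "make_trajectory",
    "fig9_instance",
    "fig10_instance",
    "random_pair_instance",
    "make_sse_sequence",
    "rotation_matrix",
    "perpendicular_axis",
]

HELIX_RISE = 1.5  # Å per residue along the helix axis
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, CA distance from the helix axis
STRAND_RISE = 3.5  # Å per residue for an extended strand
COIL_RISE = 3.0
BLOCK_SPACING = 3.5  # Å between consecutive blocks along +x


@dataclass
class ChainSpec:
    """Ordered (kind, residue_count) blocks laid along +x."""

    blocks: list[tuple[SSEKind, int]]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = "synthetic"
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        self.blocks = [(SSEKind(k), int(n)) for k, n in self.blocks]
        if any(n < 1 for _, n in self.blocks):
            raise ValueError("every block needs at least 1 residue")


def build_chain(spec: ChainSpec) -> ProteinChain:
    """Ideal-geometry chain for a :class:`ChainSpec` (fully deterministic)."""
    coords: list[np.ndarray] = []
    kinds: list[SSEKind] = []
    cursor = np.asarray(spec.origin, dtype=float)
    for kind, n in spec.blocks:
        for i in range(n):
            if kind is SSEKind.HELIX:
                theta = math.radians(HELIX_TWIST_DEG * i)
                p = cursor + np.array(
                    [HELIX_RISE * i, HELIX_RADIUS * math.cos(theta), HELIX_RADIUS * math.sin(theta)]
                )
                last_x = HELIX_RISE * (n - 1)
            elif kind is SSEKind.SHEET:
                p = cursor + np.array([STRAND_RISE * i, 0.4 * (-1.0) ** i, 0.0])
                last_x = STRAND_RISE * (n - 1)
            else:
                p = cursor + np.array(
                    [COIL_RISE * i, 1.2 * math.sin(0.9 * i), 0.6 * math.cos(0.7 * i)]
                )
                last_x = COIL_RISE * (n - 1)
            coords.append(p)
            kinds.append(kind)
        cursor = cursor + np.array([last_x + BLOCK_SPACING, 0.0, 0.0])
    residues = [
        Residue(
            seq_index=i,
            res_id=i + 1,
            icode="",
            name="ALA",
            ca=(float(p[0]), float(p[1]), float(p[2])),
            chain=spec.chain_id,
        )
        for i, p in enumerate(coords)
    ]
    return ProteinChain(
        chain_id=spec.chain_id,
        source_id=spec.source_id,
        residues=residues,
        sses=tile_from_kinds(kinds),
    )


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def rotation_matrix(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    t = math.radians(theta_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def perpendicular_axis(direction: np.ndarray) -> np.ndarray:
    """World-z made perpendicular to ``direction`` (unit result).

    Rotating an SSE about this axis changes its direction vector by exactly
    the rotation angle, with a positive signed angle for positive theta.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    a = z - np.dot(z, d) * d
    n = np.linalg.norm(a)
    if n < 1e-9:  # direction parallel to world-z
        a = np.array([0.0, 1.0, 0.0]) - d * d[1]
        n = np.linalg.norm(a)
    return a / n


@dataclass
class RotationOp:
    theta_deg: float
    axis: tuple[float, float, float] | None = None  # default: perpendicularized world-z
    pivot: str = "start"  # 'start' | 'centroid'


@dataclass
class PerturbationSpec:
    rotations: dict[str, RotationOp] = field(default_factory=dict)
    translations: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    noise_sigma: float = 0.0
    deletions: list[str] = field(default_factory=list)
    seed: int = 0


@dataclass
class SSEGroundTruth:
    sse_id: str
    angle_deg: float  # signed angle between old and new direction vectors
    shift_3d: tuple[float, float, float]  # new centroid - old centroid
    shift_2d: tuple[float, float]  # projected onto the old SSE's local frame, scale 1


@dataclass
class GroundTruth:
    per_sse: dict[str, SSEGroundTruth]
    deleted: list[str]
    noise_sigma: float


def _signed_angle(d_old: np.ndarray, d_new: np.ndarray) -> float:
    mag = math.degrees(math.acos(float(np.clip(np.dot(d_old, d_new), -1.0, 1.0))))
    return -mag if float(np.cross(d_old, d_new)[2]) < 0 else mag


def _frame_projection(d_old: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    xhat = d_old / np.linalg.norm(d_old)
    yhat = np.cross(np.array([0.0, 0.0, 1.0]), xhat)
    if np.linalg.norm(yhat) < 1e-9:
        yhat = np.cross(np.array([0.0, 1.0, 0.0]), xhat)
    yhat = yhat / np.linalg.norm(yhat)
    return float(np.dot(disp, xhat)), float(np.dot(disp, yhat))


def perturb(chain: ProteinChain, pspec: PerturbationSpec) -> tuple[ProteinChain, GroundTruth]:
    """Apply per-SSE rigid motions, noise and deletions; return the ground truth.

    Listed SSEs are rotated about their start CA (or centroid) and
    translated; sigma-noise is then added to every CA; deleted SSEs have
    their residues re-labelled coil (the chain is re-tiled, so sse_ids of
    the result are re-assigned).
    """
    rng = np.random.default_rng(pspec.seed)
    coords = chain.ca_coords()
    new_coords = coords.copy()
    truth: dict[str, SSEGroundTruth] = {}
    for sse in chain.sses:
        rot = pspec.rotations.get(sse.sse_id)
        tvec = np.asarray(pspec.translations.get(sse.sse_id, (0.0, 0.0, 0.0)), dtype=float)
        if rot is None and not np.any(tvec):
            continue
        seg = coords[sse.start : sse.end + 1]
        d_old = seg[-1] - seg[0]
        nrm = np.linalg.norm(d_old)
        d_old = d_old / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        if rot is not None:
            axis = (
                np.asarray(rot.axis, dtype=float)
                if rot.axis is not None
                else perpendicular_axis(d_old)
            )
            R = rotation_matrix(axis, rot.theta_deg)
            pivot = seg.mean(axis=0) if rot.pivot == "centroid" else seg[0]
            moved = (seg - pivot) @ R.T + pivot + tvec
        else:
            moved = seg + tvec
        new_coords[sse.start : sse.end + 1] = moved
        d_new = moved[-1] - moved[0]
        nn = np.linalg.norm(d_new)
        d_new = d_new / nn if nn > 1e-9 else d_old
        disp = moved.mean(axis=0) - seg.mean(axis=0)
        truth[sse.sse_id] = SSEGroundTruth(
            sse_id=sse.sse_id,
            angle_deg=_signed_angle(d_old, d_new),
            shift_3d=tuple(float(v) for v in disp),
            shift_2d=_frame_projection(d_old, disp),
        )
    if pspec.noise_sigma > 0:
        new_coords = new_coords + rng.normal(0.0, pspec.noise_sigma, size=new_coords.shape)

    out = chain.with_coords(new_coords)
    if pspec.deletions:
        missing = [d for d in pspec.deletions if d not in {s.sse_id for s in chain.sses}]
        if missing:
            raise KeyError(f"deletion of unknown SSE id(s): {missing}")
        kinds: list[SSEKind] = []
        for sse in chain.sses:
            k = SSEKind.COIL if sse.sse_id in pspec.deletions else sse.kind
            kinds.extend([k] * sse.residue_count)
        out = out.with_sses(tile_from_kinds(kinds))
    return out, GroundTruth(per_sse=truth, deleted=list(pspec.deletions), noise_sigma=pspec.noise_sigma)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class FrameRecord:
    angles: dict[str, float]  # realized rotation per flexible SSE (degrees)
    disappeared: set[str]  # base-chain sse_ids absent in this frame


def make_trajectory(
    chain: ProteinChain,
    n_frames: int,
    flexibility: dict[str, float] | None = None,
    disappear: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, list[FrameRecord]]:
    """Frames with per-SSE rotations drawn uniformly in +-amplitude.

    ``disappear`` maps (short) SSE ids to a per-frame probability of being
    absent: the SSE's residues are re-labelled coil in that frame, emulating
    short elements vanishing in some time steps.  Returns the trajectory and
    the realized per-frame record.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    flexibility = flexibility or {}
    disappear = disappear or {}
    known = {s.sse_id for s in chain.sses}
    for key in list(flexibility) + list(disappear):
        if key not in known:
            raise KeyError(f"unknown SSE id {key!r}")
    rng = np.random.default_rng(seed)
    frames: list[ProteinChain] = []
    records: list[FrameRecord] = []
    for f in range(n_frames):
        angles = {
            sid: float(rng.uniform(-amp, amp)) for sid, amp in flexibility.items()
        }
        gone = {sid for sid, p in disappear.items() if rng.random() < p}
        pspec = PerturbationSpec(
            rotations={sid: RotationOp(theta) for sid, theta in angles.items()},
            deletions=sorted(gone),
            seed=0,
        )
        frame, _ = perturb(chain, pspec)
        frame.source_id = f"frame{f}"
        frames.append(frame)
        records.append(FrameRecord(angles=angles, disappeared=gone))
    return (
        Trajectory(frames=frames, frame_labels=[f"frame{f}" for f in range(n_frames)]),
        records,
    )


# ---------------------------------------------------------------------------
# worked instances and random instances for the aligner
# ---------------------------------------------------------------------------


def make_sse_sequence(kinds: list[SSEKind], ids: list[str]) -> list[SecondaryStructureElement]:
    """Bare SSE sequence (positions are ordinals; no chain attached)."""
    return [
        SecondaryStructureElement(kind, i, i, sid) for i, (kind, sid) in enumerate(zip(kinds, ids))
    ]


def _point_chain(
    sse_specs: list[tuple[str, SSEKind, float]], source_id: str
) -> ProteinChain:
    """Chain of 2-residue SSEs centred at given x positions, 1-residue coils between."""
    residues: list[Residue] = []
    sses: list[SecondaryStructureElement] = []
    idx = 0
    for k, (sid, kind, cx) in enumerate(sse_specs):
        if k > 0:
            prev_cx = sse_specs[k - 1][2]
            residues.append(
                Residue(idx, idx + 1, "", "ALA", ((prev_cx + cx) / 2.0, 5.0, 0.0))
            )
            sses.append(SecondaryStructureElement(SSEKind.COIL, idx, idx, f"c{k}"))
            idx += 1
        residues.append(Residue(idx, idx + 1, "", "ALA", (cx - 0.5, 0.0, 0.0)))
        residues.append(Residue(idx + 1, idx + 2, "", "ALA", (cx + 0.5, 0.0, 0.0)))
        sses.append(SecondaryStructureElement(kind, idx, idx + 1, sid))
        idx += 2
    return ProteinChain(chain_id="A", source_id=source_id, residues=residues, sses=sses)


def fig9_instance() -> tuple[
    list[SecondaryStructureElement], list[SecondaryStructureElement], CorrespondenceMap
]:
    """The worked greedy step: A tail [sheet j, sheet x, helix y, helix m],
    B tail [helix s, sheet t], correspondence {(j,t), (m,s)}.

    Geometry places centroids so that those two pairs are the unique
    same-kind candidates within the threshold: the search for j skips one
    element of B (s) to reach t, while the search for s skips three elements
    of A (j, x, y) to reach m.
    """
    A = _point_chain(
        [
            ("j", SSEKind.SHEET, 0.0),
            ("x", SSEKind.SHEET, 20.0),
            ("y", SSEKind.HELIX, 40.0),
            ("m", SSEKind.HELIX, 60.0),
        ],
        "figA",
    )
    # sequence order [s, t]; spatial positions make t sit near j and s near m
    B = _point_chain(
        [
            ("s", SSEKind.HELIX, 61.0),
            ("t", SSEKind.SHEET, 1.0),
        ],
        "figB",
    )
    corr = candidate_pairs(A, B, max_dist=5.0)
    assert sorted(corr.pairs) == [("j", "t"), ("m", "s")]
    return A.elements(), B.elements(), corr


def fig10_instance() -> tuple[
    list[SecondaryStructureElement], list[SecondaryStructureElement], CorrespondenceMap
]:
    """An ambiguous instance where the greedy aligner inserts unnecessary gaps.

    The single helix of B (b2) has two equidistant same-kind candidates in A
    (a1 and a3, both at 50 Å); the suffixes differ and make {(a2,b1),
    (a3,b2)} the correct choice, but the greedy tie-break commits (a1,b2)
    and loses a pair.
    """
    A = _point_chain(
        [
            ("a1", SSEKind.HELIX, 0.0),
            ("a2", SSEKind.SHEET, 30.0),
            ("a3", SSEKind.HELIX, 60.0),
        ],
        "fig10A",
    )
    b_residues = [
        Residue(0, 1, "", "ALA", (29.5, 1.0, 0.0)),
        Residue(1, 2, "", "ALA", (30.5, 1.0, 0.0)),
        Residue(2, 3, "", "ALA", (30.0, 20.0, 0.0)),
        Residue(3, 4, "", "ALA", (29.5, 40.0, 0.0)),
        Residue(4, 5, "", "ALA", (30.5, 40.0, 0.0)),
    ]
    B = ProteinChain(
        chain_id="A",
        source_id="fig10B",
        residues=b_residues,
        sses=[
            SecondaryStructureElement(SSEKind.SHEET, 0, 1, "b1"),
            SecondaryStructureElement(SSEKind.COIL, 2, 2, "c1"),
            SecondaryStructureElement(SSEKind.HELIX, 3, 4, "b2"),
        ],
    )
    corr = candidate_pairs(A, B, max_dist=55.0)
    assert sorted(corr.pairs) == [("a1", "b2"), ("a2", "b1"), ("a3", "b2")]
    d1 = corr.distances[("a1", "b2")]
    d3 = corr.distances[("a3", "b2")]
    assert abs(d1 - d3) < 1e-9  # the two candidates are exactly equidistant
    return A.elements(), B.elements(), corr


def random_pair_instance(
    rng: np.random.Generator, max_sses: int = 10
) -> tuple[list[SecondaryStructureElement], list[SecondaryStructureElement], CorrespondenceMap]:
    """Random unambiguous instance: two SSE sequences plus an order-consistent
    1:1 correspondence (every SSE has at most one candidate)."""
    kinds = [SSEKind.HELIX, SSEKind.SHEET]
    nA = int(rng.integers(1, max_sses + 1))
    nB = int(rng.integers(1, max_sses + 1))
    ka = [kinds[rng.integers(0, 2)] for _ in range(nA)]
    kb = [kinds[rng.integers(0, 2)] for _ in range(nB)]
    A = make_sse_sequence(ka, [f"a{i}" for i in range(nA)])
    B = make_sse_sequence(kb, [f"b{i}" for i in range(nB)])
    pairs: list[tuple[str, str]] = []
    i = j = 0
    while i < nA and j < nB:
        if ka[i] is kb[j] and rng.random() < 0.5:
            pairs.append((A[i].sse_id, B[j].sse_id))
            i += 1
            j += 1
        elif rng.random() < 0.5:
            i += 1
        else:
            j += 1
    return A, B, CorrespondenceMap(pairs=pairs, max_dist=float("inf"))
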