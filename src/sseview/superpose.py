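"""Rigid-body superposition (Kabsch) and RMSD used to sort the juxtaposed view.

The initial structural alignment in the original workflow comes from an
external aligner; here residue pairing is supplied explicitly, inferred 1:1
when chain lengths match, or bypassed entirely for pre-superposed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ProteinChain

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "kabsch",
    "rmsd",
    "align_to_reference",
    "sort_by_rmsd",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 pairs, or a collinear point configuration."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``R @ x + t``."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 (reflection?)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class AlignmentResult:
    transform: RigidTransform
    rmsd: float
    residue_pairs: list[tuple[int, int]]


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(ref_points: np.ndarray, mov_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``mov_points`` onto ``ref_points``.

    Reflections are excluded by flipping the sign of the smallest singular
    direction when needed.  Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(mov_points, dtype=float)
    Q = np.asarray(ref_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected two equal (N, 3) point sets")
    if len(P) < 3:
        raise DegenerateGeometryError(f"need at least 3 point pairs, got {len(P)}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    for pts, label in ((P0, "moving"), (Q0, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(1.0, s[0]):
            raise DegenerateGeometryError(f"{label} points are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def align_to_reference(
    ref: ProteinChain,
    moving: ProteinChain,
    pairs: list[tuple[int, int]] | None = None,
    assume_aligned: bool = False,
) -> tuple[AlignmentResult, ProteinChain]:
    """Superpose ``moving`` onto ``ref`` and return (result, transformed copy).

    ``pairs`` are (ref seq_index, moving seq_index) tuples used for the fit;
    when omitted, a 1:1 pairing by seq_index is used (requires equal chain
    lengths).  With ``assume_aligned`` the coordinates are left untouched and
    only the RMSD over the pairs is computed.
    """
    if pairs is None:
        if len(ref) != len(moving):
            raise ValueError(
                "cannot infer residue pairing: chain lengths differ "
                f"({len(ref)} vs {len(moving)}); pass pairs or assume_aligned"
            )
        pairs = [(i, i) for i in range(len(ref))]
    ref_idx = [p[0] for p in pairs]
    mov_idx = [p[1] for p in pairs]
    if not all(0 <= i < len(ref) for i in ref_idx):
        raise IndexError("reference pair index out of range")
    if not all(0 <= i < len(moving) for i in mov_idx):
        raise IndexError("moving pair index out of range")
    ref_pts = ref.ca_coords()[ref_idx]
    mov_pts = moving.ca_coords()[mov_idx]
    if assume_aligned:
        return (
            AlignmentResult(RigidTransform.identity(), rmsd(ref_pts, mov_pts), list(pairs)),
            moving.with_coords(moving.ca_coords()),
        )
    tf = kabsch(ref_pts, mov_pts)
    moved = moving.with_coords(tf.apply(moving.ca_coords()))
    return AlignmentResult(tf, rmsd(ref_pts, tf.apply(mov_pts)), list(pairs)), moved


def sort_by_rmsd(
    results: list[AlignmentResult], chains: list[ProteinChain], reference: ProteinChain
) -> list[ProteinChain]:
    """Reference first, then chains ascending by RMSD (stable on ties)."""
    if len(results) != len(chains):
        raise ValueError("one AlignmentResult per chain required")
    order = sorted(range(len(chains)), key=lambda k: results[k].rmsd)
    return [reference] + [chains[k] for k in order]
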