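"""Which SSEs of an aligned chain correspond to which SSEs of the reference.

Correspondence is decided from spatial distance and type after
superposition.  Two flavours are provided:

* :func:`correspond` — the order-consistent 1:1 matching (dynamic program
  maximizing matched pairs, then minimizing total centroid distance) that
  the column layout consumes.
* :func:`candidate_pairs` — the raw "every same-kind pair within the
  threshold" relation, possibly ambiguous (one-to-many), which is what the
  greedy gap-insertion search actually probes step by step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import ProteinChain, SecondaryStructureElement

__all__ = [
    "CorrespondenceMap",
    "sse_centroid",
    "candidate_pairs",
    "correspond",
    "DEFAULT_MAX_DIST",
]

#: Å threshold separating "same spatial position" from "moved"; the source
#: method fixes no value, so it is configurable everywhere it is used.
DEFAULT_MAX_DIST = 8.0


@dataclass
class CorrespondenceMap:
    """Pairs of (ref sse_id, other sse_id) plus the threshold that produced them.

    ``pairs`` may be a strict matching (output of :func:`correspond`) or an
    ambiguous candidate relation (output of :func:`candidate_pairs`).
    """

    pairs: list[tuple[str, str]]
    max_dist: float
    distances: dict[tuple[str, str], float] = field(default_factory=dict)

    def ref_to_other(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}

    def other_to_ref(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def transpose(self) -> "CorrespondenceMap":
        return CorrespondenceMap(
            pairs=[(b, a) for a, b in self.pairs],
            max_dist=self.max_dist,
            distances={(b, a): d for (a, b), d in self.distances.items()},
        )

    def is_matching(self) -> bool:
        lefts = [a for a, _ in self.pairs]
        rights = [b for _, b in self.pairs]
        return len(set(lefts)) == len(lefts) and len(set(rights)) == len(rights)

    def to_tsv(self) -> str:
        lines = ["ref_sse_id\tother_sse_id\tdistance_A"]
        for a, b in self.pairs:
            d = self.distances.get((a, b))
            lines.append(f"{a}\t{b}\t{'' if d is None else format(d, '.4f')}")
        return "\n".join(lines) + "\n"


def sse_centroid(chain: ProteinChain, sse: SecondaryStructureElement) -> np.ndarray:
    """Arithmetic mean of the SSE's CA coordinates."""
    return chain.sse_coords(sse).mean(axis=0)


def candidate_pairs(
    ref: ProteinChain, other: ProteinChain, max_dist: float = DEFAULT_MAX_DIST
) -> CorrespondenceMap:
    """All same-kind helix/sheet pairs with centroid distance <= max_dist."""
    pairs: list[tuple[str, str]] = []
    dists: dict[tuple[str, str], float] = {}
    for a in ref.elements():
        ca = sse_centroid(ref, a)
        for b in other.elements():
            if b.kind is not a.kind:
                continue
            d = float(np.linalg.norm(sse_centroid(other, b) - ca))
            if d <= max_dist:
                pairs.append((a.sse_id, b.sse_id))
                dists[(a.sse_id, b.sse_id)] = d
    return CorrespondenceMap(pairs=pairs, max_dist=max_dist, distances=dists)


def correspond(
    ref: ProteinChain, other: ProteinChain, max_dist: float = DEFAULT_MAX_DIST
) -> CorrespondenceMap:
    """Optimal order-consistent matching of same-kind SSEs within ``max_dist``.

    Dynamic program over the two SSE sequences; objective is lexicographic:
    maximize the number of matched pairs, then minimize the total centroid
    distance.  Coils are never matched.  ``other`` must already be superposed
    onto ``ref``.
    """
    A = ref.elements()
    B = other.elements()
    ca = [sse_centroid(ref, a) for a in A]
    cb = [sse_centroid(other, b) for b in B]
    n, m = len(A), len(B)

    def pair_dist(i: int, j: int) -> float | None:
        if A[i].kind is not B[j].kind:
            return None
        d = float(np.linalg.norm(ca[i] - cb[j]))
        return d if d <= max_dist else None

    # f[i][j] = best (pairs, -total_dist) for suffixes A[i:], B[j:]
    NEG = (-1, 0.0)
    f: list[list[tuple[int, float]]] = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n or j == m:
                f[i][j] = (0, 0.0)
                continue
            best = max(f[i + 1][j], f[i][j + 1])
            d = pair_dist(i, j)
            if d is not None:
                p, nd = f[i + 1][j + 1]
                cand = (p + 1, nd - d)
                best = max(best, cand)
            f[i][j] = best

    pairs: list[tuple[str, str]] = []
    dists: dict[tuple[str, str], float] = {}
    i = j = 0
    while i < n and j < m:
        d = pair_dist(i, j)
        if d is not None:
            p, nd = f[i + 1][j + 1]
            if (p + 1, nd - d) == f[i][j]:
                pairs.append((A[i].sse_id, B[j].sse_id))
                dists[(A[i].sse_id, B[j].sse_id)] = d
                i += 1
                j += 1
                continue
        if f[i + 1][j] >= f[i][j + 1]:
            i += 1
        else:
            j += 1
    return CorrespondenceMap(pairs=pairs, max_dist=max_dist, distances=dists)
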