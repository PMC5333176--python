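"""Gap insertion: greedy pairwise aligner, DP oracle, multi-chain columns, MD union.

The pairwise aligner is a greedy two-pointer procedure.  At each step it
searches forward in chain B for the counterpart of A's next SSE (counting
the B elements skipped, ``n_gap``) and forward in chain A for the
counterpart of B's next SSE (``m_gap``), then applies the cheaper option:
the chain on the winning side receives ``min(n_gap, m_gap)`` gap slots just
before its current SSE, each gap facing one of the skipped elements of the
other chain.  An SSE with no counterpart ahead occupies a fresh column
opposite a gap.  When one chain runs out, the remainder of the other is
faced with trailing gaps.

``optimal_pair`` is the minimum-total-gaps dynamic program used as the
greedy's test oracle; greedy can insert more gaps than it on ambiguous
(one-to-many) correspondence relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .correspondence import CorrespondenceMap
from .structure_io import (
    ProteinChain,
    SecondaryStructureElement,
    SSEKind,
    StructureError,
    Trajectory,
)

__all__ = [
    "GAP",
    "is_gap",
    "GappedChain",
    "GreedyStepDecision",
    "ColumnAlignment",
    "greedy_pair",
    "optimal_pair",
    "multi_align",
    "md_union",
    "build_union_chain",
]


class _Gap:
    """Singleton marker for an inserted gap slot."""

    _instance: "_Gap | None" = None

    def __new__(cls) -> "_Gap":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "GAP"


GAP = _Gap()


def is_gap(slot: object) -> bool:
    return slot is GAP


@dataclass
class GappedChain:
    """SSE id sequence with GAP slots inserted; stripping gaps recovers the input."""

    slots: list[object]  # sse_id str or GAP
    source: Optional[ProteinChain] = None
    label: str = ""

    @property
    def column_count(self) -> int:
        return len(self.slots)

    def strip(self) -> list[str]:
        return [s for s in self.slots if not is_gap(s)]

    def gap_count(self) -> int:
        return sum(1 for s in self.slots if is_gap(s))

    def column_of(self, sse_id: str) -> int:
        for c, s in enumerate(self.slots):
            if s == sse_id:
                return c
        raise KeyError(sse_id)


@dataclass(frozen=True)
class GreedyStepDecision:
    """Record of one greedy comparison step.

    ``n_gap``: elements skipped in B searching for A's next SSE (None if the
    search failed); ``m_gap``: skipped in A for B's next SSE; ``chosen_side``
    names the chain that received gaps ('A', 'B' or 'none').
    """

    n_gap: Optional[int]
    m_gap: Optional[int]
    chosen_side: str
    gaps_inserted: int


@dataclass
class ColumnAlignment:
    """One GappedChain per input chain, all sharing a column count."""

    gapped: list[GappedChain]
    reference_index: int = 0

    def __post_init__(self) -> None:
        counts = {g.column_count for g in self.gapped}
        if len(counts) > 1:
            raise ValueError(f"unequal column counts: {sorted(counts)}")

    @property
    def column_count(self) -> int:
        return self.gapped[0].column_count if self.gapped else 0

    def to_tsv(self) -> str:
        lines = []
        for g in self.gapped:
            cells = ["-" if is_gap(s) else str(s) for s in g.slots]
            lines.append("\t".join([g.label or "chain"] + cells))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# greedy pairwise aligner
# ---------------------------------------------------------------------------


def _forward_search(
    target_candidates: set[str], seq: Sequence[SecondaryStructureElement], start: int
) -> Optional[int]:
    """Skip count to the first element of seq[start:] that is a candidate."""
    for k in range(start, len(seq)):
        if seq[k].sse_id in target_candidates:
            return k - start
    return None


def greedy_pair(
    A: Sequence[SecondaryStructureElement],
    B: Sequence[SecondaryStructureElement],
    corr: CorrespondenceMap,
) -> tuple[GappedChain, GappedChain, list[GreedyStepDecision]]:
    """Greedy gap insertion between two SSE sequences.

    ``corr.pairs`` holds (A sse_id, B sse_id) candidate pairs; it may be a
    strict matching or an ambiguous relation — the search simply takes the
    nearest candidate ahead of the pointer.
    """
    cand_a: dict[str, set[str]] = {}
    cand_b: dict[str, set[str]] = {}
    for a_id, b_id in corr.pairs:
        cand_a.setdefault(a_id, set()).add(b_id)
        cand_b.setdefault(b_id, set()).add(a_id)

    slots_a: list[object] = []
    slots_b: list[object] = []
    decisions: list[GreedyStepDecision] = []
    i = j = 0
    while i < len(A) or j < len(B):
        if i >= len(A):  # A exhausted: fill with trailing gaps
            slots_a.append(GAP)
            slots_b.append(B[j].sse_id)
            j += 1
            continue
        if j >= len(B):
            slots_a.append(A[i].sse_id)
            slots_b.append(GAP)
            i += 1
            continue
        n_gap = _forward_search(cand_a.get(A[i].sse_id, set()), B, j)
        m_gap = _forward_search(cand_b.get(B[j].sse_id, set()), A, i)
        if n_gap is None and m_gap is None:
            # neither current SSE has a counterpart ahead: A's current gets a
            # fresh column opposite a gap in B; B's current is handled next.
            slots_a.append(A[i].sse_id)
            slots_b.append(GAP)
            i += 1
            decisions.append(GreedyStepDecision(None, None, "B", 1))
            continue
        if m_gap is None or (n_gap is not None and n_gap <= m_gap):
            # ties (n_gap == m_gap) resolve to the A side for determinism
            for k in range(j, j + n_gap):
                slots_a.append(GAP)
                slots_b.append(B[k].sse_id)
            slots_a.append(A[i].sse_id)
            slots_b.append(B[j + n_gap].sse_id)
            decisions.append(
                GreedyStepDecision(n_gap, m_gap, "A" if n_gap > 0 else "none", n_gap)
            )
            i += 1
            j += n_gap + 1
        else:
            for k in range(i, i + m_gap):
                slots_a.append(A[k].sse_id)
                slots_b.append(GAP)
            slots_a.append(A[i + m_gap].sse_id)
            slots_b.append(B[j].sse_id)
            decisions.append(
                GreedyStepDecision(n_gap, m_gap, "B" if m_gap > 0 else "none", m_gap)
            )
            i += m_gap + 1
            j += 1
    return GappedChain(slots_a), GappedChain(slots_b), decisions


# ---------------------------------------------------------------------------
# optimal oracle (dynamic program)
# ---------------------------------------------------------------------------


def optimal_pair(
    A: Sequence[SecondaryStructureElement],
    B: Sequence[SecondaryStructureElement],
    corr: CorrespondenceMap,
) -> tuple[GappedChain, GappedChain]:
    """Minimum-total-gaps alignment of two SSE sequences.

    Dynamic program over (i, j) suffix positions.  A shared column requires
    the pair to be in ``corr``; every unmatched SSE occupies its own column
    opposite a gap, so total gaps = len(A) + len(B) - 2 * matched pairs and
    minimizing gaps is maximizing realizable (order-consistent) pairs.  When
    ``corr`` is itself order-consistent every one of its pairs is realized.
    """
    allowed = set(corr.pairs)
    n, m = len(A), len(B)
    INF = n + m + 1
    f = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            best = INF
            if i < n:
                best = min(best, 1 + f[i + 1][j])
            if j < m:
                best = min(best, 1 + f[i][j + 1])
            if i < n and j < m and (A[i].sse_id, B[j].sse_id) in allowed:
                best = min(best, f[i + 1][j + 1])
            f[i][j] = best

    slots_a: list[object] = []
    slots_b: list[object] = []
    i = j = 0
    while i < n or j < m:
        # preference order on cost ties: match, then gap into A, then gap into B
        if i < n and j < m and (A[i].sse_id, B[j].sse_id) in allowed and f[i][j] == f[i + 1][j + 1]:
            slots_a.append(A[i].sse_id)
            slots_b.append(B[j].sse_id)
            i += 1
            j += 1
        elif j < m and f[i][j] == 1 + f[i][j + 1]:
            slots_a.append(GAP)
            slots_b.append(B[j].sse_id)
            j += 1
        else:
            slots_a.append(A[i].sse_id)
            slots_b.append(GAP)
            i += 1
    return GappedChain(slots_a), GappedChain(slots_b)


# ---------------------------------------------------------------------------
# multi-chain column construction
# ---------------------------------------------------------------------------


def _ref_gap_profile(
    gapped_ref: GappedChain, gapped_other: GappedChain, n_ref: int
) -> tuple[list[int], list[list[object]], list[object]]:
    """Decompose a pairwise result by position in the reference SSE sequence.

    Returns (gap counts before each ref position p in 0..n_ref, the other
    chain's slot ids occupying those ref-gap columns, and the other chain's
    slot aligned with each ref SSE).
    """
    gaps_before = [0] * (n_ref + 1)
    fillers: list[list[object]] = [[] for _ in range(n_ref + 1)]
    aligned: list[object] = [GAP] * n_ref
    p = 0
    for sa, sb in zip(gapped_ref.slots, gapped_other.slots):
        if is_gap(sa):
            gaps_before[p] += 1
            fillers[p].append(sb)
        else:
            aligned[p] = sb
            p += 1
    return gaps_before, fillers, aligned


def multi_align(
    ref: ProteinChain,
    others: Sequence[ProteinChain],
    corrs: Sequence[CorrespondenceMap],
) -> ColumnAlignment:
    """Align every chain to master columns derived from pairwise runs vs ``ref``.

    Each other chain is greedy-paired with the reference independently; the
    master column sequence inserts, before each reference SSE, as many gap
    columns as the worst pairwise run required there (merged left-to-right).
    The reference row occupies position 0 of the result.
    """
    if len(others) != len(corrs):
        raise ValueError("one CorrespondenceMap per other chain required")
    ref_sses = ref.elements()
    n = len(ref_sses)
    profiles = []
    for other, corr in zip(others, corrs):
        ga, gb, _ = greedy_pair(ref_sses, other.elements(), corr)
        profiles.append(_ref_gap_profile(ga, gb, n))

    master_gaps = [0] * (n + 1)
    for gaps_before, _, _ in profiles:
        for p in range(n + 1):
            master_gaps[p] = max(master_gaps[p], gaps_before[p])

    ref_slots: list[object] = []
    for p in range(n):
        ref_slots.extend([GAP] * master_gaps[p])
        ref_slots.append(ref_sses[p].sse_id)
    ref_slots.extend([GAP] * master_gaps[n])

    rows = [GappedChain(ref_slots, source=ref, label=ref.source_id)]
    for (gaps_before, fillers, aligned), other in zip(profiles, others):
        slots: list[object] = []
        for p in range(n + 1):
            slots.extend(fillers[p])
            slots.extend([GAP] * (master_gaps[p] - gaps_before[p]))
            if p < n:
                slots.append(aligned[p])
        rows.append(GappedChain(slots, source=other, label=other.source_id))
    return ColumnAlignment(gapped=rows, reference_index=0)


# ---------------------------------------------------------------------------
# molecular dynamics: union chain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnionSSE:
    """One aggregated SSE: same-kind frame SSEs with overlapping residue ranges."""

    sse_id: str
    kind: SSEKind
    start: int  # min start over members
    end: int  # max end over members
    members: frozenset  # (frame index, frame sse_id)


def build_union_chain(frames: Trajectory) -> list[UnionSSE]:
    """Aggregate helix/sheet SSEs across frames by same-kind interval overlap.

    Returns the artificial union chain: one representative per aggregated
    SSE, ordered by residue position.
    """
    by_kind: dict[SSEKind, list[tuple[int, int, int, str]]] = {}
    for fi, frame in enumerate(frames.frames):
        for sse in frame.elements():
            by_kind.setdefault(sse.kind, []).append((sse.start, sse.end, fi, sse.sse_id))
    unions: list[UnionSSE] = []
    for kind, items in by_kind.items():
        items.sort()
        cur: list[tuple[int, int, int, str]] = []
        cur_end = -1
        for it in items:
            if cur and it[0] > cur_end:
                unions.append(_make_union(kind, cur))
                cur = []
                cur_end = -1
            cur.append(it)
            cur_end = max(cur_end, it[1])
        if cur:
            unions.append(_make_union(kind, cur))
    unions.sort(key=lambda u: (u.start, u.end, u.kind.value))
    return [
        UnionSSE(f"U{k}", u.kind, u.start, u.end, u.members) for k, u in enumerate(unions)
    ]


def _make_union(kind: SSEKind, items: list[tuple[int, int, int, str]]) -> UnionSSE:
    return UnionSSE(
        sse_id="U?",
        kind=kind,
        start=min(i[0] for i in items),
        end=max(i[1] for i in items),
        members=frozenset((i[2], i[3]) for i in items),
    )


def md_union(frames: Trajectory) -> ColumnAlignment:
    """Column alignment of MD frames via the artificial union chain.

    The union chain (every SSE appearing in at least one frame, identified
    across frames by same-kind residue-interval overlap) serves as the
    pairwise pivot: each frame is greedy-paired against it and receives gaps
    where the union chain has an SSE the frame lacks.  The artificial chain
    itself is discarded from the result; all frames share the column count,
    which equals the number of aggregated SSEs.
    """
    unions = build_union_chain(frames)
    pivot = [SecondaryStructureElement(u.kind, u.start, u.end, u.sse_id) for u in unions]
    member_of: dict[tuple[int, str], str] = {}
    for u in unions:
        for fi, sid in u.members:
            member_of[(fi, sid)] = u.sse_id

    rows: list[GappedChain] = []
    for fi, frame in enumerate(frames.frames):
        pairs = [
            (member_of[(fi, s.sse_id)], s.sse_id)
            for s in frame.elements()
            if (fi, s.sse_id) in member_of
        ]
        corr = CorrespondenceMap(pairs=pairs, max_dist=float("inf"))
        g_pivot, g_frame, _ = greedy_pair(pivot, frame.elements(), corr)
        if g_pivot.gap_count() != 0 or g_frame.column_count != len(pivot):
            raise StructureError(
                f"frame {fi}: SSE ordering inconsistent with the union chain"
            )
        rows.append(
            GappedChain(g_frame.slots, source=frame, label=frames.frame_labels[fi])
        )
    return ColumnAlignment(gapped=rows, reference_index=0)
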