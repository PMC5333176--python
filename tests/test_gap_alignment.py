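"""Gap insertion tests: worked instance, DP oracle vs exhaustive enumeration,
greedy vs optimal, multi-chain columns and the MD union chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sseview.correspondence import CorrespondenceMap, correspond
from sseview.gap_alignment import (
    GAP,
    ColumnAlignment,
    GappedChain,
    build_union_chain,
    greedy_pair,
    is_gap,
    md_union,
    multi_align,
    optimal_pair,
)
from sseview.structure_io import SSEKind, Trajectory
from sseview.synthetic import (
    ChainSpec,
    PerturbationSpec,
    build_chain,
    fig9_instance,
    fig10_instance,
    make_sse_sequence,
    make_trajectory,
    random_pair_instance,
)


def full_corr(A, B):
    return CorrespondenceMap(
        pairs=[(a.sse_id, b.sse_id) for a, b in zip(A, B)], max_dist=float("inf")
    )


def total_gaps(*gapped: GappedChain) -> int:
    return sum(g.gap_count() for g in gapped)


def columns_shared(ga: GappedChain, gb: GappedChain, corr: CorrespondenceMap) -> bool:
    """Every realized corr pair sits in one column; no column pairs non-corr SSEs."""
    allowed = set(corr.pairs)
    for sa, sb in zip(ga.slots, gb.slots):
        if not is_gap(sa) and not is_gap(sb) and (sa, sb) not in allowed:
            return False
    return True


def enumerate_min_gaps(A, B, allowed, i=0, j=0):
    """Exhaustive (non-memoized) enumeration over all alignments."""
    if i == len(A) and j == len(B):
        return 0
    best = len(A) + len(B) + 1
    if i < len(A):
        best = min(best, 1 + enumerate_min_gaps(A, B, allowed, i + 1, j))
    if j < len(B):
        best = min(best, 1 + enumerate_min_gaps(A, B, allowed, i, j + 1))
    if i < len(A) and j < len(B) and (A[i].sse_id, B[j].sse_id) in allowed:
        best = min(best, enumerate_min_gaps(A, B, allowed, i + 1, j + 1))
    return best


class TestGreedyPair:
    def test_worked_instance_first_decision(self):
        A, B, corr = fig9_instance()
        ga, gb, decisions = greedy_pair(A, B, corr)
        first = decisions[0]
        assert first.n_gap == 1
        assert first.m_gap == 3
        assert first.chosen_side == "A"
        assert first.gaps_inserted == 1
        # the inserted gap in A faces helix s of B
        col = ga.slots.index(GAP)
        assert gb.slots[col] == "s"

    def test_identical_chains_no_gaps(self):
        A = make_sse_sequence(
            [SSEKind.HELIX, SSEKind.SHEET, SSEKind.HELIX], ["a0", "a1", "a2"]
        )
        B = make_sse_sequence(
            [SSEKind.HELIX, SSEKind.SHEET, SSEKind.HELIX], ["b0", "b1", "b2"]
        )
        ga, gb, decisions = greedy_pair(A, B, full_corr(A, B))
        assert total_gaps(ga, gb) == 0
        assert ga.column_count == 3
        assert all(d.gaps_inserted == 0 for d in decisions)

    def test_trailing_sses_fill_with_gaps(self):
        A = make_sse_sequence([SSEKind.HELIX] * 4, [f"a{i}" for i in range(4)])
        B = make_sse_sequence([SSEKind.HELIX] * 2, [f"b{i}" for i in range(2)])
        corr = CorrespondenceMap([("a0", "b0"), ("a1", "b1")], max_dist=float("inf"))
        ga, gb, _ = greedy_pair(A, B, corr)
        assert gb.slots[-2:] == [GAP, GAP]
        assert ga.strip() == [a.sse_id for a in A]

    def test_unmatched_on_both_sides(self):
        A = make_sse_sequence([SSEKind.HELIX, SSEKind.SHEET], ["a0", "a1"])
        B = make_sse_sequence([SSEKind.SHEET, SSEKind.HELIX], ["b0", "b1"])
        ga, gb, _ = greedy_pair(A, B, CorrespondenceMap([], max_dist=1.0))
        # no correspondences at all: every SSE gets its own column opposite a gap
        assert total_gaps(ga, gb) == 4
        assert ga.column_count == 4

    def test_ambiguous_instance_greedy_worse_than_optimal(self):
        A, B, corr = fig10_instance()
        ga, gb, _ = greedy_pair(A, B, corr)
        oa, ob = optimal_pair(A, B, corr)
        greedy_gaps = total_gaps(ga, gb)
        optimal_gaps = total_gaps(oa, ob)
        assert greedy_gaps > optimal_gaps  # the documented greedy failure
        assert (greedy_gaps, optimal_gaps) == (3, 1)


class TestOptimalPair:
    def test_identical_chains_zero_gaps(self):
        A = make_sse_sequence([SSEKind.HELIX, SSEKind.SHEET], ["a0", "a1"])
        B = make_sse_sequence([SSEKind.HELIX, SSEKind.SHEET], ["b0", "b1"])
        oa, ob = optimal_pair(A, B, full_corr(A, B))
        assert total_gaps(oa, ob) == 0

    def test_worked_instance_same_total_as_greedy(self):
        A, B, corr = fig9_instance()
        ga, gb, _ = greedy_pair(A, B, corr)
        oa, ob = optimal_pair(A, B, corr)
        assert total_gaps(oa, ob) == total_gaps(ga, gb) == 4

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        A, B, corr = random_pair_instance(rng, max_sses=8)
        oa, ob = optimal_pair(A, B, corr)
        expected = enumerate_min_gaps(A, B, set(corr.pairs))
        assert total_gaps(oa, ob) == expected
        assert columns_shared(oa, ob, corr)

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_equals_optimal_on_unambiguous(self, seed):
        rng = np.random.default_rng(1000 + seed)
        A, B, corr = random_pair_instance(rng)
        ga, gb, _ = greedy_pair(A, B, corr)
        oa, ob = optimal_pair(A, B, corr)
        assert total_gaps(ga, gb) == total_gaps(oa, ob)

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_never_beats_optimal(self, seed):
        # ambiguous relations: add extra candidate pairs to a random instance
        rng = np.random.default_rng(2000 + seed)
        A, B, corr = random_pair_instance(rng)
        extra = [
            (a.sse_id, b.sse_id)
            for a in A
            for b in B
            if a.kind is b.kind and rng.random() < 0.2
        ]
        rel = CorrespondenceMap(list(dict.fromkeys(corr.pairs + extra)), float("inf"))
        ga, gb, _ = greedy_pair(A, B, rel)
        oa, ob = optimal_pair(A, B, rel)
        assert total_gaps(ga, gb) >= total_gaps(oa, ob)


class TestGappedChainProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_strip_recovers_input_order(self, seed):
        rng = np.random.default_rng(seed)
        A, B, corr = random_pair_instance(rng)
        for pair_fn in (lambda: greedy_pair(A, B, corr)[:2], lambda: optimal_pair(A, B, corr)):
            ga, gb = pair_fn()
            assert ga.strip() == [a.sse_id for a in A]
            assert gb.strip() == [b.sse_id for b in B]
            assert ga.column_count == gb.column_count
            assert columns_shared(ga, gb, corr)

    def test_gap_freeness_on_identity(self, standard_chain):
        A = standard_chain.elements()
        corr = CorrespondenceMap([(s.sse_id, s.sse_id) for s in A], 0.0)
        ga, gb, _ = greedy_pair(A, A, corr)
        assert total_gaps(ga, gb) == 0

    def test_column_alignment_rejects_ragged_rows(self):
        with pytest.raises(ValueError, match="column counts"):
            ColumnAlignment([GappedChain(["a"]), GappedChain(["b", GAP])])


class TestMultiAlign:
    def test_copies_of_reference_no_gaps(self, standard_chain):
        others = [standard_chain.with_sses(standard_chain.sses) for _ in range(2)]
        corrs = [correspond(standard_chain, o) for o in others]
        ca = multi_align(standard_chain, others, corrs)
        assert ca.column_count == len(standard_chain.elements())
        assert all(g.gap_count() == 0 for g in ca.gapped)

    def test_independent_deletions(self, standard_chain):
        from sseview.synthetic import perturb

        ids = [s.sse_id for s in standard_chain.elements()]  # H1, E3, H5
        miss_first, _ = perturb(standard_chain, PerturbationSpec(deletions=[ids[0]]))
        miss_last, _ = perturb(standard_chain, PerturbationSpec(deletions=[ids[2]]))
        corrs = [correspond(standard_chain, o) for o in (miss_first, miss_last)]
        ca = multi_align(standard_chain, [miss_first, miss_last], corrs)
        ref_row, row1, row2 = ca.gapped
        assert ref_row.gap_count() == 0
        assert is_gap(row1.slots[ref_row.column_of(ids[0])])
        assert row1.gap_count() == 1
        assert is_gap(row2.slots[ref_row.column_of(ids[2])])
        assert row2.gap_count() == 1

    def test_insertion_gives_reference_gap(self, standard_chain):
        # other chain has an extra helix the reference lacks
        bigger = build_chain(
            ChainSpec(
                blocks=[
                    (SSEKind.COIL, 2),
                    (SSEKind.HELIX, 10),
                    (SSEKind.COIL, 3),
                    (SSEKind.SHEET, 5),
                    (SSEKind.COIL, 2),
                    (SSEKind.HELIX, 6),
                    (SSEKind.COIL, 2),
                    (SSEKind.HELIX, 8),  # extra
                    (SSEKind.COIL, 2),
                ],
                source_id="bigger",
            )
        )
        corr = correspond(standard_chain, bigger)
        ca = multi_align(standard_chain, [bigger], [corr])
        ref_row, other_row = ca.gapped
        assert ref_row.gap_count() == 1
        assert other_row.gap_count() == 0
        assert ca.column_count == len(standard_chain.elements()) + 1

    @pytest.mark.parametrize("seed", range(8))
    def test_random_multichain_column_sharing(self, seed):
        rng = np.random.default_rng(3000 + seed)
        ref_sses, _, _ = random_pair_instance(rng)
        from .conftest import chain_from_kinds

        ref = chain_from_kinds(
            [s.kind for s in ref_sses], [s.sse_id for s in ref_sses], "ref"
        )
        others, corrs = [], []
        for k in range(4):
            o_sses, _, _ = random_pair_instance(rng)
            other = chain_from_kinds(
                [s.kind for s in o_sses], [f"k{k}_{s.sse_id}" for s in o_sses], f"o{k}"
            )
            pairs = []
            i = j = 0
            o_elems = other.elements()
            r_elems = ref.elements()
            while i < len(r_elems) and j < len(o_elems):
                if r_elems[i].kind is o_elems[j].kind and rng.random() < 0.5:
                    pairs.append((r_elems[i].sse_id, o_elems[j].sse_id))
                    i += 1
                    j += 1
                elif rng.random() < 0.5:
                    i += 1
                else:
                    j += 1
            others.append(other)
            corrs.append(CorrespondenceMap(pairs, float("inf")))
        ca = multi_align(ref, others, corrs)
        ref_row = ca.gapped[0]
        for row, corr in zip(ca.gapped[1:], corrs):
            assert row.column_count == ca.column_count
            assert row.strip() == [s.sse_id for s in row.source.elements()]
            for a, b in corr.pairs:
                assert ref_row.column_of(a) == row.column_of(b)


class TestMDUnion:
    @pytest.fixture
    def base(self):
        return build_chain(
            ChainSpec(
                blocks=[
                    (SSEKind.COIL, 2),
                    (SSEKind.HELIX, 8),  # a = H1
                    (SSEKind.COIL, 3),
                    (SSEKind.SHEET, 4),  # b = E3
                    (SSEKind.COIL, 2),
                    (SSEKind.HELIX, 2),  # c = H5, short
                    (SSEKind.COIL, 2),
                ],
                source_id="md",
            )
        )

    def test_union_semantics(self, base):
        from sseview.synthetic import perturb

        f1, _ = perturb(base, PerturbationSpec(deletions=["H5"]))  # {a, b}
        f2, _ = perturb(base, PerturbationSpec(deletions=["E3"]))  # {a, c}
        f3, _ = perturb(base, PerturbationSpec())  # {a, b, c}
        traj = Trajectory([f1, f2, f3], ["f1", "f2", "f3"])
        unions = build_union_chain(traj)
        assert [(u.kind, u.start, u.end) for u in unions] == [
            (SSEKind.HELIX, 2, 9),
            (SSEKind.SHEET, 13, 16),
            (SSEKind.HELIX, 19, 20),
        ]
        ca = md_union(traj)
        assert ca.column_count == 3
        grids = [["-" if is_gap(s) else "x" for s in row.slots] for row in ca.gapped]
        assert grids == [["x", "x", "-"], ["x", "-", "x"], ["x", "x", "x"]]

    def test_identical_frames_no_gaps(self, base):
        traj, _ = make_trajectory(base, 4, flexibility={}, seed=0)
        ca = md_union(traj)
        assert all(row.gap_count() == 0 for row in ca.gapped)
        assert ca.column_count == 3

    def test_disappearing_short_helix(self, base):
        traj, records = make_trajectory(
            base, 10, flexibility={"H1": 10.0}, disappear={"H5": 0.5}, seed=7
        )
        ca = md_union(traj)
        unions = build_union_chain(traj)
        short = [u for u in unions if u.kind is SSEKind.HELIX and u.start >= 19]
        assert len(short) == 1  # the union chain contains it exactly once
        col = [u.sse_id for u in unions].index(short[0].sse_id)
        for row, rec in zip(ca.gapped, records):
            assert row.column_count == ca.column_count
            assert is_gap(row.slots[col]) == ("H5" in rec.disappeared)
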