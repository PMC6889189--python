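"""Consistency criterion, greedy intersection, truth labeling."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelfuse.callset_io import RepeatAnnotation
from indelfuse.errors import CoordinateError
from indelfuse.matching import (
    MatchCriterion,
    coordinate_deviation,
    intersect_callsets,
    is_consistent,
    label_against_truth,
    truth_to_calls,
    union_callsets,
)
from indelfuse.varsim import TruthVariant
from tests.conftest import make_call


class TestCoordinateDeviation:
    @pytest.mark.parametrize("p1,p2,expected", [(100, 100, 0), (100, 103, 3), (103, 100, 3)])
    def test_absolute_difference(self, p1, p2, expected):
        assert coordinate_deviation(p1, p2, "chr1", "chr1") == expected

    def test_cross_chromosome_is_an_error(self):
        with pytest.raises(CoordinateError):
            coordinate_deviation(1, 1, "chr1", "chr2")


class TestIsConsistent:
    def test_identical_nonrepeat_calls_match(self, criterion):
        a = make_call(pos=100)
        assert is_consistent(a, make_call(caller="beta", pos=100), criterion)

    def test_nonrepeat_deviation_exceeds_default_tolerance(self, criterion):
        assert not is_consistent(
            make_call(pos=100), make_call(caller="beta", pos=102), criterion
        )

    def test_type_mismatch_never_matches(self, criterion):
        a = make_call(pos=100, vtype="DEL")
        b = make_call(caller="beta", pos=100, vtype="INS")
        assert not is_consistent(a, b, criterion)

    def test_repeat_region_allows_region_length_deviation(self, criterion):
        a = make_call(pos=100, repeat_class="SimpleRepeat", region_length=6)
        b = make_call(
            caller="beta", pos=104, repeat_class="SimpleRepeat", region_length=6
        )
        assert is_consistent(a, b, criterion)
        c = make_call(caller="beta", pos=107, repeat_class="SimpleRepeat", region_length=6)
        assert not is_consistent(a, c, criterion)

    def test_size_must_agree_exactly(self, criterion):
        a = make_call(pos=100, size=2, repeat_class="SimpleRepeat", region_length=50)
        b = make_call(caller="beta", pos=100, size=3, repeat_class="SimpleRepeat",
                      region_length=50)
        assert not is_consistent(a, b, criterion)

    @given(
        pos_a=st.integers(2, 500),
        pos_b=st.integers(2, 500),
        rl=st.integers(0, 20),
        size=st.integers(1, 50),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetric_and_reflexive(self, pos_a, pos_b, rl, size):
        crit = MatchCriterion()
        cls = "SimpleRepeat" if rl else "NonRepeat"
        a = make_call(pos=pos_a, size=size, repeat_class=cls, region_length=rl)
        b = make_call(caller="beta", pos=pos_b, size=size, repeat_class=cls,
                      region_length=rl)
        assert is_consistent(a, b, crit) == is_consistent(b, a, crit)
        assert is_consistent(a, a, crit)


def test_at_dinucleotide_deletion_in_simple_repeat_is_tp(criterion):
    """An AT deletion in an ATATAT run may be reported at any of the three
    dinucleotide starts; a 2 bp shift inside the 6 bp region still counts."""
    annotation = RepeatAnnotation.from_intervals([("chr1", 99, 105, "SimpleRepeat")])
    truth = [TruthVariant("chr1", 101, "DEL", 2, "AT", "", anchor="G")]
    truth_calls = truth_to_calls(truth, annotation)
    call = make_call(pos=102, vtype="DEL", size=2, repeat_class="SimpleRepeat",
                     region_length=6)
    result = label_against_truth([call], truth_calls, criterion)
    assert result.tp == 1 and result.fp == 0 and result.fn == 0


class TestIntersect:
    def test_identity(self, criterion):
        calls = [make_call(pos=p) for p in (100, 200, 300)]
        merged = intersect_callsets(
            calls, [make_call(caller="beta", pos=p) for p in (100, 200, 300)], criterion
        )
        assert len(merged) == 3
        assert all(set(m.callers) == {"alpha", "beta"} for m in merged)

    def test_disjoint_sets_intersect_empty(self, criterion):
        a = [make_call(pos=100)]
        b = [make_call(caller="beta", pos=500)]
        assert intersect_callsets(a, b, criterion) == []

    def test_reads_are_summed(self, criterion):
        a = [make_call(pos=100, reads=10)]
        b = [make_call(caller="beta", pos=100, reads=7)]
        (m,) = intersect_callsets(a, b, criterion)
        assert m.reads == 17

    def test_partial_overlap_hand_case(self, criterion):
        a = [make_call(pos=p) for p in (100, 200, 300)]
        b = [make_call(caller="beta", pos=p) for p in (200, 300)]
        assert len(intersect_callsets(a, b, criterion)) == 2

    def test_output_bounded_by_smaller_set(self, criterion):
        a = [make_call(pos=p) for p in range(100, 400, 10)]
        b = [make_call(caller="beta", pos=p) for p in range(100, 200, 10)]
        assert len(intersect_callsets(a, b, criterion)) <= len(b)


def _random_instance(rng, n_a, n_b):
    """Random calls scattered over a shared repeat landscape."""
    regions = [(50 * i, 50 * i + int(rng.integers(5, 30))) for i in range(6)]

    def rand_calls(caller, n):
        calls = []
        for _ in range(n):
            pos = int(rng.integers(2, 320))
            cls, rl = "NonRepeat", 0
            for s, e in regions:
                if s <= pos - 1 < e:
                    cls, rl = "SimpleRepeat", e - s
                    break
            calls.append(
                make_call(
                    caller=caller,
                    pos=pos,
                    vtype="DEL" if rng.random() < 0.7 else "INS",
                    size=int(rng.integers(1, 3)),
                    repeat_class=cls,
                    region_length=rl,
                )
            )
        return calls

    return rand_calls("alpha", n_a), rand_calls("beta", n_b)


def test_greedy_intersection_equals_maximum_matching(criterion):
    """Brute-force oracle: on small random instances the greedy one-to-one
    matcher recovers a maximum bipartite matching."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        a, b = _random_instance(rng, int(rng.integers(0, 9)), int(rng.integers(0, 9)))
        merged = intersect_callsets(a, b, criterion)
        g = nx.Graph()
        g.add_nodes_from([("a", i) for i in range(len(a))])
        g.add_nodes_from([("b", j) for j in range(len(b))])
        for i, ca in enumerate(a):
            for j, cb in enumerate(b):
                if is_consistent(ca, cb, criterion):
                    g.add_edge(("a", i), ("b", j))
        maximum = nx.algorithms.matching.max_weight_matching(
            g, maxcardinality=True
        )
        assert len(merged) == len(maximum), f"trial {trial}"


class TestLabelAgainstTruth:
    def test_calls_equal_truth_all_tp(self, criterion):
        truth_calls = [make_call(caller="truth", pos=p) for p in (100, 200, 300)]
        result = label_against_truth(
            [make_call(pos=p) for p in (100, 200, 300)], truth_calls, criterion
        )
        assert result.tp == 3 and result.fp == 0 and result.fn == 0

    def test_empty_calls_all_fn(self, criterion):
        truth_calls = [make_call(caller="truth", pos=100 * i) for i in range(1, 6)]
        result = label_against_truth([], truth_calls, criterion)
        assert (result.tp, result.fp, result.fn) == (0, 0, 5)

    def test_counts_conserve(self, criterion):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = _random_instance(rng, int(rng.integers(0, 12)), int(rng.integers(0, 12)))
            result = label_against_truth(a, b, criterion)
            assert result.tp + result.fp == len(a)
            assert result.tp + result.fn == len(b)


def test_union_merges_shared_calls_once(criterion):
    callsets = {
        "alpha": [make_call(pos=100, reads=5), make_call(pos=200, reads=6)],
        "beta": [make_call(caller="beta", pos=100, reads=7)],
        "gamma": [make_call(caller="gamma", pos=300, reads=8)],
    }
    merged = union_callsets(callsets, criterion)
    by_pos = {m.pos: m for m in merged}
    assert set(by_pos) == {100, 200, 300}
    assert set(by_pos[100].callers) == {"alpha", "beta"}
    assert by_pos[100].reads == 12
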