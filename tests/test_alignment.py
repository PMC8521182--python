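import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chopdrop import (
    AlignmentParams,
    align,
    align_matrix,
    gap_penalty,
    worked_fixtures,
)
from chopdrop.alignment import replay_moves
from chopdrop.digestion import FingerprintDB, Fingerprint, NOISELESS
from _oracle import brute_force_distance

weights = st.lists(st.floats(500.0, 1600.0), min_size=0, max_size=6)


class TestGapPenalty:
    @pytest.mark.parametrize("variant", ["squared", "linear-95"])
    def test_zero_resolution_floors_at_L(self, variant):
        assert gap_penalty(0.0, variant=variant) == 500.0

    def test_squared_variant_at_r5(self):
        assert gap_penalty(5.0, variant="squared") == pytest.approx(711.1, abs=0.1)

    def test_linear_variant_at_r5(self):
        assert gap_penalty(5.0, variant="linear-95") == pytest.approx(514.5, abs=0.1)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            gap_penalty(5.0, variant="cubic")

    @given(r_lo=st.floats(0, 100), r_hi=st.floats(0, 100))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_resolution(self, r_lo, r_hi):
        lo, hi = sorted((r_lo, r_hi))
        assert gap_penalty(lo) <= gap_penalty(hi)


class TestAlign:
    def test_worked_fixtures(self, aln500):
        fx = worked_fixtures()
        for name, case in fx.items():
            expected = case["distance"]
            if expected == "G":
                expected = aln500.G
            got = align(case["x"], case["y"], aln500).distance
            if math.isinf(expected):
                assert math.isinf(got), name
            else:
                assert got == pytest.approx(expected), name

    def test_both_empty_distance_zero(self, aln500):
        res = align([], [], aln500)
        assert res.distance == 0.0 and res.feasible

    def test_one_empty_infeasible(self, aln500):
        assert not align([600.0], [], aln500).feasible
        assert not align([], [600.0], aln500).feasible

    def test_negative_weights_rejected(self, aln500):
        with pytest.raises(ValueError):
            align([-1.0], [600.0], aln500)

    def test_reference_fusion_needs_both_directions(self):
        # one query fragment covering two reference fragments (missed
        # cleavage in the query) is only free with fusion_direction=both
        x, y = [1300.0], [600.0, 700.0]
        both = align(x, y, AlignmentParams(G=500.0, fusion_direction="both"))
        printed = align(x, y, AlignmentParams(G=500.0, fusion_direction="as-printed"))
        assert both.distance == 0.0
        assert printed.distance > 0.0

    @pytest.mark.parametrize("fusion", ["as-printed", "both"])
    @pytest.mark.parametrize("G", [500.0, 711.1])
    def test_matches_exhaustive_enumeration(self, G, fusion):
        rng = np.random.default_rng(1234)
        params = AlignmentParams(G=G, fusion_direction=fusion)
        for _ in range(150):
            nx, ny = rng.integers(0, 7, size=2)
            x = rng.uniform(500, 1600, size=nx)
            y = rng.uniform(500, 1600, size=ny)
            expected = brute_force_distance(x, y, G, both_fusions=fusion == "both")
            got = align(x, y, params).distance
            assert got == expected or got == pytest.approx(expected, abs=1e-9)

    @given(x=weights, y=weights)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_oracle_equivalence_property(self, x, y, aln500):
        got = align(x, y, aln500).distance
        expected = brute_force_distance(x, y, aln500.G)
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    @given(x=weights.filter(len), y=weights.filter(len))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_distance_non_decreasing_in_gap_penalty(self, x, y):
        dists = [
            align(x, y, AlignmentParams(G=G)).distance for G in (500.0, 700.0, 1200.0)
        ]
        assert dists == sorted(dists)

    @given(x=weights, y=weights)
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_both_fusion_mode_is_symmetric(self, x, y):
        params = AlignmentParams(G=500.0, fusion_direction="both")
        a = align(x, y, params).distance
        b = align(y, x, params).distance
        # equal up to float summation order
        assert a == b or a == pytest.approx(b, abs=1e-6)

    def test_self_distance_zero(self, small_db, aln500):
        for _, fp in small_db:
            if len(fp):
                assert align(fp, fp, aln500).distance == 0.0

    def test_trace_replays_to_distance(self, aln500):
        rng = np.random.default_rng(9)
        for _ in range(50):
            nx, ny = rng.integers(1, 7, size=2)
            x = rng.uniform(500, 1600, size=nx)
            y = rng.uniform(500, 1600, size=ny)
            res = align(x, y, aln500, trace=True)
            if res.feasible:
                assert replay_moves(x, y, aln500.G, res.moves) == pytest.approx(
                    res.distance, abs=1e-9
                )
            else:
                assert res.moves is None

    def test_trace_and_distance_modes_agree(self, aln500):
        rng = np.random.default_rng(10)
        for _ in range(30):
            x = rng.uniform(500, 1600, size=rng.integers(0, 7))
            y = rng.uniform(500, 1600, size=rng.integers(0, 7))
            assert align(x, y, aln500, trace=True).distance == align(x, y, aln500).distance


class TestAlignMatrix:
    @staticmethod
    def _db(fps):
        return FingerprintDB([(fp.protein_id, fp) for fp in fps], NOISELESS)

    def test_single_pair_equals_align(self, aln500):
        q = Fingerprint("q", (600.0, 900.0))
        d = Fingerprint("d", (610.0, 890.0))
        mat = align_matrix([q], self._db([d]), aln500)
        assert mat.shape == (1, 1)
        assert mat[0, 0] == align(q, d, aln500).distance

    def test_equals_per_pair_align(self, small_db, aln500):
        queries = [fp for _, fp in small_db.entries[:5]]
        mat = align_matrix(queries, small_db, aln500)
        for qi, q in enumerate(queries):
            for di, (_, d) in enumerate(small_db):
                assert mat[qi, di] == align(q, d, aln500).distance

    def test_permuting_db_permutes_columns(self, aln500):
        fps = [Fingerprint(f"d{i}", (500.0 + 100 * i, 900.0)) for i in range(4)]
        q = [Fingerprint("q", (620.0, 950.0))]
        mat = align_matrix(q, self._db(fps), aln500)
        perm = [2, 0, 3, 1]
        mat_p = align_matrix(q, self._db([fps[i] for i in perm]), aln500)
        assert np.array_equal(mat_p[0], mat[0][perm])

    def test_empty_db_rejected(self, aln500):
        with pytest.raises(ValueError):
            align_matrix([Fingerprint("q", (600.0,))], self._db([]), aln500)
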