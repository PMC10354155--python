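import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from absearch.errors import SearchError
from absearch.identity import (IdentityOptions, batch_identity, merge_top_n,
                               pair_identity, top_n, trim_terminal)
from absearch.oracle import oracle_pair_identity, oracle_search
from absearch.regions import RegionMask

L = 20  # small scheme length for hand-checkable vectors


def mask(slots, lm=False):
    return RegionMask("m", frozenset(slots), length_matched=lm)


def vec(**codes):
    v = np.zeros(L, dtype=np.uint8)
    for slot, code in codes.items():
        v[int(slot[1:])] = code
    return v


class TestPairIdentity:
    def test_self_identity_is_100(self):
        a = vec(s0=3, s1=5, s7=2)
        r = pair_identity(a, a, mask(range(L)))
        assert r.identity == 100.0 and r.comparable

    def test_disjoint_occupancy_scores_zero(self):
        a = vec(s0=3, s1=5)
        b = vec(s7=2, s8=4)
        r = pair_identity(a, b, mask(range(L)))
        assert r.identity == 0.0
        assert r.denominator == 4  # one-sided slots all count

    def test_one_sided_indel_counts_in_denominator(self):
        # mask of 6 slots; query occupies 5, target all 6, 4 equal
        m = mask(range(6))
        q = np.zeros(L, dtype=np.uint8)
        t = np.zeros(L, dtype=np.uint8)
        q[[0, 1, 2, 3, 4]] = [1, 2, 3, 4, 5]
        t[[0, 1, 2, 3, 4, 5]] = [1, 2, 3, 4, 9, 9]
        r = pair_identity(q, t, m)
        assert r.matches == 4 and r.denominator == 6
        assert r.identity == pytest.approx(100 * 4 / 6)

    def test_length_matched_gate(self):
        m = mask(range(6), lm=True)
        q = vec(s0=1, s1=2, s2=3)
        t = vec(s0=1, s1=2, s2=3, s3=4)
        r = pair_identity(q, t, m)
        assert not r.comparable and r.identity == 0.0
        # equal residue counts at different slots are comparable
        t2 = vec(s0=1, s1=2, s4=3)
        assert pair_identity(q, t2, m).comparable

    def test_empty_denominator_scores_zero_but_comparable(self):
        r = pair_identity(np.zeros(L, np.uint8), np.zeros(L, np.uint8), mask(range(L)))
        assert r.identity == 0.0 and r.comparable

    def test_ambiguous_never_matches_by_default(self):
        xcode = 21
        a = vec(s0=xcode)
        r = pair_identity(a, a, mask(range(L)))
        assert r.identity == 0.0 and r.denominator == 1
        relaxed = IdentityOptions(ambiguous_matches_nothing=False)
        assert pair_identity(a, a, mask(range(L)), relaxed).identity == 100.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(SearchError):
            pair_identity(np.zeros(L, np.uint8), np.zeros(L + 1, np.uint8), mask([0]))

    @given(data=st.data())
    def test_symmetry_under_all_option_settings(self, data):
        rng_codes = st.integers(0, 21)
        a = np.array(data.draw(st.lists(rng_codes, min_size=L, max_size=L)), dtype=np.uint8)
        b = np.array(data.draw(st.lists(rng_codes, min_size=L, max_size=L)), dtype=np.uint8)
        slots = data.draw(st.lists(st.integers(0, L - 1), min_size=1, unique=True))
        opts = IdentityOptions(
            length_matched=data.draw(st.booleans()),
            include_terminal_gaps=data.draw(st.booleans()),
            ambiguous_matches_nothing=data.draw(st.booleans()))
        m = mask(slots)
        r1 = pair_identity(a, b, m, opts)
        r2 = pair_identity(b, a, m, opts)
        assert r1.identity == r2.identity and r1.comparable == r2.comparable

    @given(data=st.data())
    def test_identity_depends_only_on_masked_slots(self, data):
        a = np.array(data.draw(st.lists(st.integers(0, 21), min_size=L, max_size=L)),
                     dtype=np.uint8)
        b = np.array(data.draw(st.lists(st.integers(0, 21), min_size=L, max_size=L)),
                     dtype=np.uint8)
        slots = data.draw(st.lists(st.integers(0, L - 1), min_size=1, max_size=L // 2,
                                   unique=True))
        m = mask(slots)
        before = pair_identity(a, b, m)
        outside = [s for s in range(L) if s not in set(slots)]
        a2 = a.copy()
        for s in outside:
            a2[s] = data.draw(st.integers(0, 21))
        after = pair_identity(a2, b, m)
        assert before.identity == after.identity

    @given(data=st.data())
    def test_identity_range(self, data):
        a = np.array(data.draw(st.lists(st.integers(0, 21), min_size=L, max_size=L)),
                     dtype=np.uint8)
        b = np.array(data.draw(st.lists(st.integers(0, 21), min_size=L, max_size=L)),
                     dtype=np.uint8)
        r = pair_identity(a, b, mask(range(L)))
        assert 0.0 <= r.identity <= 100.0


class TestTrimTerminal:
    def test_full_span_unchanged(self):
        a = vec(s0=1, s19=2)
        m = mask(range(L))
        assert trim_terminal(a, a, m).tolist() == list(range(L))

    def test_missing_leading_residues_removed(self):
        a = np.zeros(L, np.uint8); a[3:] = 1       # starts at slot 3
        b = np.ones(L, np.uint8)                   # full span
        assert trim_terminal(a, b, mask(range(L))).tolist() == list(range(3, L))

    def test_both_empty_gives_empty_mask_and_zero_identity(self):
        z = np.zeros(L, np.uint8)
        assert trim_terminal(z, z, mask(range(L))).size == 0
        opts = IdentityOptions(include_terminal_gaps=False)
        assert pair_identity(z, z, mask(range(L)), opts).identity == 0.0

    def test_trimmed_identity_ignores_terminal_truncation(self):
        full = np.arange(1, L + 1, dtype=np.uint8)
        trunc = full.copy(); trunc[:4] = 0
        strict = pair_identity(full, trunc, mask(range(L)))
        lenient = pair_identity(full, trunc, mask(range(L)),
                                IdentityOptions(include_terminal_gaps=False,
                                                ambiguous_matches_nothing=False))
        assert strict.identity < 100.0
        assert lenient.identity == 100.0


class TestBatchIdentity:
    def test_empty_matrix(self):
        idents, comp = batch_identity(np.zeros(L, np.uint8),
                                      np.empty((0, L), np.uint8), mask([0]))
        assert idents.size == 0 and comp.size == 0

    def test_identical_row_scores_100(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 21, size=(10, L)).astype(np.uint8)
        q = t[4].copy()
        idents, _ = batch_identity(q, t, mask(range(L)),
                                   IdentityOptions(ambiguous_matches_nothing=False))
        assert idents[4] == 100.0

    @pytest.mark.parametrize("lm,trim,amb", [
        (False, True, True), (True, True, True),
        (False, False, True), (True, False, False),
    ])
    def test_equals_scalar_oracle_row_by_row(self, lm, trim, amb):
        rng = np.random.default_rng(7)
        t = rng.integers(0, 22, size=(50, L)).astype(np.uint8)
        t[rng.random((50, L)) < 0.3] = 0
        q = t[0].copy()
        slots = sorted(rng.choice(L, size=12, replace=False).tolist())
        opts = IdentityOptions(length_matched=lm, include_terminal_gaps=trim,
                               ambiguous_matches_nothing=amb)
        idents, comp = batch_identity(q, t, mask(slots), opts)
        for i in range(50):
            oid, ocomp = oracle_pair_identity(
                q.tolist(), t[i].tolist(), slots, length_matched=lm,
                include_terminal_gaps=trim, ambiguous_matches_nothing=amb)
            assert idents[i] == oid and bool(comp[i]) == ocomp


class TestTopN:
    def test_tie_broken_by_ascending_row(self):
        idents = np.array([10.0, 90.0, 90.0, 50.0])
        comp = np.ones(4, bool)
        assert top_n(idents, comp, 2) == [(1, 90.0), (2, 90.0)]

    def test_threshold_is_inclusive(self):
        idents = np.array([80.0, 95.0, 90.0])
        comp = np.ones(3, bool)
        hits = top_n(idents, comp, 10, threshold=90.0)
        assert hits == [(1, 95.0), (2, 90.0)]

    def test_n_larger_than_population(self):
        idents = np.array([30.0, 60.0])
        hits = top_n(idents, np.ones(2, bool), 10)
        assert hits == [(1, 60.0), (0, 30.0)]

    def test_incomparable_rows_never_returned(self):
        idents = np.array([100.0, 50.0])
        comp = np.array([False, True])
        assert top_n(idents, comp, 5) == [(1, 50.0)]

    @given(data=st.data())
    def test_streamed_merge_equals_whole(self, data):
        n = data.draw(st.integers(1, 60))
        idents = np.array(data.draw(st.lists(
            st.sampled_from([0.0, 25.0, 50.0, 75.0, 100.0]),
            min_size=n, max_size=n)))
        comp = np.ones(n, bool)
        k = data.draw(st.integers(1, 10))
        cut = data.draw(st.integers(0, n))
        whole = top_n(idents, comp, k)
        part1 = top_n(idents[:cut], comp[:cut], k)
        part2 = top_n(idents[cut:], comp[cut:], k,
                      row_ids=np.arange(cut, n))
        assert merge_top_n([part1, part2], k) == whole


class TestOracleSearch:
    def test_single_row_database(self):
        rows = [np.arange(1, L + 1).tolist()]
        out = oracle_search([rows[0]], rows, list(range(L)), 3,
                            ambiguous_matches_nothing=False)
        assert out == [[(0, 100.0)]]
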