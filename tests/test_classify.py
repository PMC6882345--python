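"""Rule matching, the BH boundary and key summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwasgrid import binning, classify
from gwasgrid.errors import ClassificationError, InputError
from gwasgrid.io_formats import CellConfig, GlobalOptions


class TestClassifyCell:
    @pytest.mark.parametrize(
        "count,maf,csq,expected_idx",
        [
            (1, False, False, 1),
            (1, False, True, 2),
            (1, True, False, 3),
            (1, True, True, 4),
            (2, False, False, 5),
            (2, False, True, 6),
            (2, True, False, 7),
            (2, True, True, 8),
            (7, True, True, 8),
            (400, False, False, 5),
        ],
    )
    def test_default_scheme(self, count, maf, csq, expected_idx, default_rules):
        assert classify.classify_cell(count, maf, csq, default_rules).idx == expected_idx

    def test_exhaustive_unique_match(self, default_rules):
        """Every (count, maf, conseq) combination matches exactly one rule."""
        for count in range(1, 6):
            for maf in (False, True):
                for csq in (False, True):
                    matches = [
                        r
                        for r in default_rules
                        if r.maf_flag == maf and r.conseq_flag == csq and r.min_count <= count
                    ]
                    winner = classify.classify_cell(count, maf, csq, default_rules)
                    assert winner is max(matches, key=lambda r: r.min_count)

    def test_multi_tier_config_takes_largest_tier(self):
        rules = [
            CellConfig(1, 1, False, False, "black", False),
            CellConfig(2, 5, False, False, "blue", False),
            CellConfig(3, 50, False, False, "red", True),
        ]
        assert classify.classify_cell(4, False, False, rules).idx == 1
        assert classify.classify_cell(49, False, False, rules).idx == 2
        assert classify.classify_cell(50, False, False, rules).idx == 3

    def test_no_match_raises(self):
        rules = [CellConfig(1, 2, False, False, "black", False)]
        with pytest.raises(ClassificationError):
            classify.classify_cell(1, False, False, rules)


def bh_bruteforce(pvalues, q):
    """Independent step-up scan: literal textbook loop."""
    ps = sorted(pvalues)
    m = len(ps)
    p_star = None
    for i in range(m, 0, -1):
        if ps[i - 1] <= i * q / m:
            p_star = ps[i - 1]
            break
    return p_star


class TestFdrThreshold:
    def test_worked_example(self):
        b = classify.fdr_threshold([0.001, 0.01, 0.02, 0.8], 0.05)
        assert b.p_star == pytest.approx(0.02)
        assert b.nlp_star == pytest.approx(1.69897, abs=1e-5)

    def test_nothing_rejected(self):
        b = classify.fdr_threshold([1.0, 1.0, 1.0], 0.05)
        assert b.p_star is None and b.boundary_col is None

    def test_single_test_reduces_to_q(self):
        assert classify.fdr_threshold([0.04], 0.05).p_star == pytest.approx(0.04)
        assert classify.fdr_threshold([0.06], 0.05).p_star is None

    def test_empty_is_input_error(self):
        with pytest.raises(InputError):
            classify.fdr_threshold([], 0.05)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=120),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_bruteforce(self, ps, q):
        assert classify.fdr_threshold(ps, q).p_star == bh_bruteforce(ps, q)

    def test_boundary_column_semantics(self):
        """A bin straddling the threshold stays grey; exact edge ties count."""
        inside = classify.fdr_threshold([10 ** -1.3], 0.1, pbin=0.125)  # nlp=1.3, bin 10
        assert inside.boundary_col == 11
        edge = classify.fdr_threshold([10 ** -1.375], 0.1, pbin=0.125)  # exactly bin edge
        assert edge.boundary_col == 11

    def test_fixed_threshold_preset(self):
        b = classify.fixed_threshold(-np.log10(5e-8))
        assert b.nlp_star == pytest.approx(7.30103, abs=1e-5)
        assert b.boundary_col == 59

    def test_dispatch_honours_threshold_nlp(self):
        opts = GlobalOptions(threshold_nlp=5.0)
        b = classify.significance_boundary([0.5, 0.9], opts)
        assert b.nlp_star == pytest.approx(5.0)


def make_matrix(count, maf_any=None, conseq_any=None, pbin=0.125, cap=20.0):
    count = np.asarray(count, dtype=np.int64)
    z = np.zeros_like(count, dtype=bool)
    return binning.CountMatrix(
        count=count,
        maf_any=z if maf_any is None else np.asarray(maf_any, dtype=bool),
        conseq_any=z if conseq_any is None else np.asarray(conseq_any, dtype=bool),
        total_variants=int(count.sum()),
        pvalues=np.array([]),
        pbin=pbin,
        cap_nlp=cap,
    )


class TestClassifyMatrix:
    def boundary_at(self, col):
        return classify.SignificanceBoundary(q=0.05, p_star=1e-5, nlp_star=col * 0.125, boundary_col=col)

    def test_bubble_only_when_significant_and_reported(self, default_rules):
        count = np.zeros((2, 160), dtype=int)
        maf = np.zeros_like(count, dtype=bool)
        csq = np.zeros_like(count, dtype=bool)
        count[0, 100] = 3  # significant, idx 8 -> bubble
        maf[0, 100] = csq[0, 100] = True
        count[0, 50] = 3  # non-significant idx 8 -> no bubble
        maf[0, 50] = csq[0, 50] = True
        count[1, 100] = 3  # significant idx 5 (report FALSE) -> no bubble
        cells = classify.classify_matrix(
            make_matrix(count, maf, csq), default_rules, self.boundary_at(80)
        )
        by_pos = {(c.row, c.col): c for c in cells}
        assert by_pos[(0, 100)].bubble and by_pos[(0, 100)].idx == 8
        assert not by_pos[(0, 50)].significant and not by_pos[(0, 50)].bubble
        assert by_pos[(1, 100)].significant and not by_pos[(1, 100)].bubble

    def test_row_major_deterministic_order(self, default_rules):
        count = np.zeros((3, 160), dtype=int)
        count[2, 1] = count[0, 5] = count[0, 2] = count[1, 0] = 1
        cells = classify.classify_matrix(make_matrix(count), default_rules, self.boundary_at(80))
        assert [(c.row, c.col) for c in cells] == [(0, 2), (0, 5), (1, 0), (2, 1)]

    def test_no_boundary_means_nothing_significant(self, default_rules):
        count = np.zeros((1, 160), dtype=int)
        count[0, 159] = 5
        boundary = classify.SignificanceBoundary(0.05, None, None, None)
        cells = classify.classify_matrix(make_matrix(count), default_rules, boundary)
        assert not cells[0].significant

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_bubble_soundness_random_matrices(self, seed, default_rules):
        rng = np.random.default_rng(seed)
        count = rng.integers(0, 4, size=(12, 160))
        maf = rng.random((12, 160)) < 0.3
        csq = rng.random((12, 160)) < 0.3
        cells = classify.classify_matrix(
            make_matrix(count, maf, csq), default_rules, self.boundary_at(int(rng.integers(0, 160)))
        )
        assert len(cells) == int((count > 0).sum())
        assert all(c.significant for c in cells if c.bubble)


class TestKeyCounts:
    def test_counts_by_index(self, default_rules):
        count = np.zeros((5, 160), dtype=int)
        for row in range(3):
            count[row, 10] = 1  # idx 1 singletons
        count[3, 10] = count[4, 10] = 2  # idx 5 pairs
        matrix = make_matrix(count)
        cells = classify.classify_matrix(
            matrix, default_rules, classify.SignificanceBoundary(0.05, None, None, None)
        )
        key = classify.key_counts(cells, matrix, default_rules)
        assert key.per_idx == {1: 3, 5: 2, 2: 0, 3: 0, 4: 0, 6: 0, 7: 0, 8: 0}
        assert key.max_cell_count == 2

    def test_empty_matrix(self, default_rules):
        matrix = make_matrix(np.zeros((2, 160), dtype=int))
        key = classify.key_counts([], matrix, default_rules)
        assert set(key.per_idx.values()) == {0}
        assert key.max_cell_count == 0

    def test_conservation_against_bruteforce(self, default_rules):
        rng = np.random.default_rng(42)
        count = rng.integers(0, 5, size=(30, 160))
        maf = rng.random((30, 160)) < 0.2
        csq = rng.random((30, 160)) < 0.2
        matrix = make_matrix(count, maf, csq)
        cells = classify.classify_matrix(
            matrix, default_rules, classify.SignificanceBoundary(0.05, 1e-5, 5.0, 40)
        )
        key = classify.key_counts(cells, matrix, default_rules)
        assert sum(key.per_idx.values()) == int((count > 0).sum())
        # independent tally straight off the arrays
        tally = {r.idx: 0 for r in default_rules}
        for i in range(30):
            for j in range(160):
                if count[i, j]:
                    r = classify.classify_cell(int(count[i, j]), bool(maf[i, j]), bool(csq[i, j]), default_rules)
                    tally[r.idx] += 1
        assert key.per_idx == tally
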