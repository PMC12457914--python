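import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hullscape as hs
from hullscape.ceda import _row_statistic


class TestEntropyEngine:
    # every printed row and marginal entropy of the four reference tables;
    # two printed values carry last-digit printing errors (see the 2e-5
    # tolerances): the true natural-log entropies are 0.106566 and 0.680999
    @pytest.mark.parametrize(
        "counts,expected,tol",
        [
            ((0, 46), 0.0, 1e-9),
            ((9, 35), 0.50664, 1e-5),
            ((9, 81), 0.32508, 1e-5),
            ((1, 44), 0.10656, 2e-5),
            ((8, 37), 0.46800, 1e-5),
            ((9, 36), 0.50040, 1e-5),
            ((10, 80), 0.34883, 1e-5),
            ((19, 26), 0.68098, 2e-5),
            ((2, 43), 0.181812, 1e-5),
            ((21, 69), 0.54327, 1e-5),
        ],
    )
    def test_printed_entropies(self, counts, expected, tol):
        assert hs.row_entropy(counts) == pytest.approx(expected, abs=tol)

    def test_two_column_entropy_bounded_by_ln2(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            row = rng.integers(0, 100, size=2)
            if row.sum() == 0:
                continue
            assert 0 <= hs.row_entropy(row) <= np.log(2) + 1e-12

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hs.row_entropy((0, 0))


class TestOddsEngine:
    @pytest.mark.parametrize(
        "counts,expected",
        [((19, 26), 0.73077), ((2, 43), 0.04651), ((21, 69), 0.30435),
         ((0, 46), 0.0), ((9, 81), 1 / 9)],
    )
    def test_printed_odds(self, counts, expected):
        assert hs.row_odds(counts) == pytest.approx(expected, abs=1e-5)

    def test_zero_filled_gives_infinity(self):
        assert hs.row_odds((5, 0)) == np.inf


class TestContingencyTable:
    def test_fixture_tables_consistent(self, printed_tables):
        t2 = printed_tables["T2"]
        assert t2.counts.tolist() == [[0, 46], [9, 35]]
        assert t2.col_sums.tolist() == [9, 81]
        assert t2.row_sums.tolist() == [46, 44]
        assert t2.baseline_entropy == pytest.approx(0.32508, abs=1e-5)
        assert t2.baseline_odds == pytest.approx(1 / 9)
        t5 = printed_tables["T5"]
        assert t5.counts.tolist() == [[19, 26], [2, 43]]
        assert t5.baseline_odds == pytest.approx(0.30435, abs=1e-5)

    def test_make_table_crosstab(self):
        codes = np.array(["0", "0", "1", "1", "1"], dtype=object)
        cat = hs.CategorizedFeature(features=("f",), cutoffs=(0.5,), codes=codes)
        tab = hs.make_table(cat, ["blank", "filled", "filled", "blank", "filled"])
        assert tab.counts.tolist() == [[1, 1], [1, 2]]
        assert tab.row_labels == ["0", "1"]

    def test_single_category_equals_column_sums(self):
        codes = np.array(["0"] * 6, dtype=object)
        cat = hs.CategorizedFeature(features=("f",), cutoffs=(0.5,), codes=codes,
                                    categories=["0"])
        tab = hs.make_table(cat, ["blank"] * 2 + ["filled"] * 4)
        assert tab.counts.tolist() == [[2, 4]]
        assert tab.counts[0].tolist() == tab.col_sums.tolist()

    def test_bad_labels_rejected(self):
        codes = np.array(["0", "1"], dtype=object)
        cat = hs.CategorizedFeature(features=("f",), cutoffs=(0.5,), codes=codes)
        with pytest.raises(ValueError, match="labels"):
            hs.make_table(cat, ["blank", "empty"])


class TestEnsembles:
    def test_column_sums_preserved_exactly(self, printed_tables):
        pair = hs.simulate_ensembles(printed_tables["T2"], M=200, seed=0)
        for sims in (pair.alternative, pair.null):
            assert np.all(sims.sum(axis=1) == [9, 81])

    def test_alternative_keeps_structural_zero(self, printed_tables):
        # observed within-blank proportion of row 0 is 0/9, so the
        # alternative ensemble can never put blank counts in row 0
        pair = hs.simulate_ensembles(printed_tables["T2"], M=500, seed=1)
        assert np.all(pair.alternative[:, 0, 0] == 0)

    def test_cell_means_within_three_standard_errors(self, printed_tables):
        t5 = printed_tables["T5"]
        M = 1000
        pair = hs.simulate_ensembles(t5, M=M, seed=2)
        marg = t5.row_sums / t5.total
        for j, n in enumerate(t5.col_sums):
            p = t5.counts[:, j] / n
            for r in range(2):
                for sims, prob in ((pair.alternative, p[r]), (pair.null, marg[r])):
                    mean = sims[:, r, j].mean()
                    se = np.sqrt(n * prob * (1 - prob) / M)
                    assert abs(mean - n * prob) <= max(3 * se, 1e-9)

    def test_reproducible_from_seed(self, printed_tables):
        a = hs.simulate_ensembles(printed_tables["T5"], M=50, seed=9)
        b = hs.simulate_ensembles(printed_tables["T5"], M=50, seed=9)
        assert np.array_equal(a.alternative, b.alternative)
        assert np.array_equal(a.null, b.null)

    def test_invalid_m_rejected(self, printed_tables):
        with pytest.raises(ValueError):
            hs.simulate_ensembles(printed_tables["T2"], M=0, seed=0)


class TestOverlapArea:
    def test_identical_samples_give_one(self):
        x = np.random.default_rng(0).normal(size=500)
        assert hs.overlap_area(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert hs.overlap_area([0.0, 0.1, 0.2], [5.0, 5.1]) == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 400), rng.normal(0.5, 1.2, 600)
        o = hs.overlap_area(a, b)
        assert 0 <= o <= 1
        assert o == pytest.approx(hs.overlap_area(b, a))

    @given(shift=st.floats(-10, 10), scale=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_common_affine_map(self, shift, scale):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 300), rng.normal(1, 1, 300)
        o0 = hs.overlap_area(a, b)
        o1 = hs.overlap_area(a * scale + shift, b * scale + shift)
        assert o1 == pytest.approx(o0, abs=1e-12)

    def test_infinite_odds_share_overflow_bin(self):
        a = np.array([1.0, 2.0, np.inf, np.inf])
        b = np.array([1.0, 2.0, 3.0, np.inf])
        # overflow bin: min(2/4, 1/4) = 0.25; finite bins [1,2) and [2,3]:
        # min(1/4, 1/4) + min(1/4, 2/4) = 0.5
        assert hs.overlap_area(a, b, bins=2) == pytest.approx(0.75)

    def test_point_masses_in_one_bin(self):
        assert hs.overlap_area([2.0] * 10, [2.0] * 7) == 1.0


class TestAssessAndSelect:
    def test_structural_zero_row_overlap_near_zero(self, printed_tables):
        # row (0, 46): the alternative entropy is identically 0 while the
        # null spreads out, so the minimum-error overlap is essentially 0
        v = hs.assess_category(printed_tables["T2"], row=0, statistic="entropy",
                               M=1000, seed=3, tau=0.1)
        assert v.overlap <= 0.01
        assert v.is_major

    def test_t5_odds_overlaps_match_printed_values(self, printed_tables):
        # printed: 0.0200 (category 0) and 0.0140 (category 1)
        ovs = {0: [], 1: []}
        for seed in range(5):
            for row in (0, 1):
                v = hs.assess_category(printed_tables["T5"], row=row,
                                       statistic="odds", M=1000, seed=seed)
                ovs[row].append(v.overlap)
        assert np.mean(ovs[0]) == pytest.approx(0.020, abs=0.015)
        assert np.mean(ovs[1]) == pytest.approx(0.014, abs=0.015)

    def test_select_major_finds_planted_feature(self):
        from hullscape import synthdata
        # bin-conditional blank odds 10:1 (high bin) vs 1:10 (low bin)
        spec = synthdata.PlantedFeatureSpec(
            n_nuts=90, n_blank=45, seed=5,
            effects=[synthdata.PlantedEffect("full-c1", 10 / 11, 1 / 11)],
            features=tuple(f"full-c{i}" for i in range(1, 9)),
        )
        tab = synthdata.make_feature_table(spec)
        verdicts, majors = hs.select_major(tab, order=1, statistic="odds",
                                           M=1000, seed=11, tau=0.1)
        assert any(cat.name == "full-c1" for cat, _ in majors)

    def test_selection_reproducible_at_fixed_seed(self):
        from hullscape import synthdata
        spec = synthdata.PlantedFeatureSpec(
            n_nuts=60, n_blank=8, seed=1,
            features=tuple(f"full-c{i}" for i in range(1, 5)),
        )
        tab = synthdata.make_feature_table(spec)
        v1, _ = hs.select_major(tab, order=1, M=300, seed=21)
        v2, _ = hs.select_major(tab, order=1, M=300, seed=21)
        assert [(v.name, v.category, v.overlap) for v in v1] == \
            [(v.name, v.category, v.overlap) for v in v2]

    def test_order2_assesses_joint_cells(self):
        from hullscape import synthdata
        spec = synthdata.PlantedFeatureSpec(
            n_nuts=40, n_blank=6, seed=2,
            features=("full-c1", "full-c2", "full-c3"),
        )
        tab = synthdata.make_feature_table(spec)
        verdicts, _ = hs.select_major(tab, order=2, M=200, seed=5)
        names = {v.name for v in verdicts}
        assert names == {"full-c1&full-c2", "full-c1&full-c3", "full-c2&full-c3"}
        assert {v.category for v in verdicts} <= {"00", "01", "10", "11"}


def test_row_statistic_handles_degenerate_rows():
    tables = np.array([[[0, 0], [3, 4]]])
    assert _row_statistic(tables, 0, "entropy")[0] == 0.0
    assert _row_statistic(tables, 0, "odds")[0] == 0.0
    assert _row_statistic(np.array([[[2, 0], [1, 1]]]), 0, "odds")[0] == np.inf
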