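import numpy as np
import pytest

import hullscape as hs
from hullscape import synthdata
from hullscape.gsd import NeighbourhoodSystem, stage_triplet, votes_from_distance_table


def _query_from_column(ls, j, cts=("synthetic",)):
    return hs.QueryNut(nut_id=f"q{j}",
                       vectors={ct: ls.matrix[:, j].copy() for ct in cts})


def _three_landscapes(seed=0):
    """Three distinct reference landscapes standing in for CT1/CT2/CT3."""
    lss = []
    for i, ct in enumerate(("ct1", "ct2", "ct3")):
        ls = synthdata.make_block_landscape(
            n_categories=10 + 2 * i, block_sizes=(20, 20),
            blank_rates=(0.5, 0.0), flip_prob=0.15, ct_label=ct,
            seed=seed + i)
        lss.append(ls)
    return lss


class TestCandidateNeighbours:
    def test_exact_match_comes_first_at_distance_zero(self):
        ls = synthdata.make_block_landscape(flip_prob=0.3, seed=1)
        q = _query_from_column(ls, 4)
        q.vectors[ls.ct_label] = ls.matrix[:, 4]
        candi, dists = hs.candidate_neighbours(q, ls, K=5)
        assert dists[0] == 0.0
        assert ls.nut_ids[4] in candi[: int((dists == 0).sum())]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2)
        ls = synthdata.make_block_landscape(n_categories=9,
                                            block_sizes=(12, 12),
                                            flip_prob=0.4, seed=2)
        for trial in range(5):
            v = rng.integers(0, 2, size=9).astype(float)
            q = hs.QueryNut(nut_id="q", vectors={ls.ct_label: v})
            candi, dists = hs.candidate_neighbours(q, ls, K=7)
            d_all = np.linalg.norm(ls.matrix.T - v, axis=1)
            expected = sorted((d_all[j], j) for j in range(ls.n_nuts))[:7]
            assert np.allclose(dists, [d for d, _ in expected])
            assert candi == [ls.nut_ids[j] for _, j in expected]

    def test_dimension_mismatch_rejected(self):
        ls = synthdata.make_block_landscape(seed=3)
        q = hs.QueryNut(nut_id="q", vectors={ls.ct_label: np.zeros(3)})
        with pytest.raises(ValueError, match="length"):
            hs.candidate_neighbours(q, ls, K=3)


class TestOddsG:
    def test_printed_distance_table_yields_zero_votes(self, printed_tables):
        t6 = printed_tables["T6"]
        votes, odds = votes_from_distance_table(
            t6["neighbour_distances"], t6["query_distances"], K=10)
        assert votes == 0
        assert odds == 0.0
        # every query distance exceeds every candidate's own 10th-NN radius
        assert t6["query_distances"].min() > t6["neighbour_distances"].max()

    def test_clone_of_reference_nut_scores_at_least_one_over_k(self):
        ls = synthdata.make_block_landscape(flip_prob=0.2, seed=4)
        for j in (0, 5, 30):
            q = _query_from_column(ls, j)
            assert hs.odds_g(q, ls, K=10) >= 1 / 10

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        ls = synthdata.make_block_landscape(n_categories=8,
                                            block_sizes=(10, 10),
                                            flip_prob=0.4, seed=5)
        K = 4
        X = ls.matrix.T.astype(float)
        for trial in range(10):
            v = rng.integers(0, 2, size=8).astype(float)
            q = hs.QueryNut(nut_id="q", vectors={ls.ct_label: v})
            got = hs.odds_g(q, ls, K=K)

            # brute force: all neighbourhoods, all intersections
            d_q = np.linalg.norm(X - v, axis=1)
            order = sorted((d_q[j], j) for j in range(len(X)))[:K]
            candi = [j for _, j in order]
            best = 0.0
            for d, j in order:
                d_all = np.linalg.norm(X - X[j], axis=1)
                nn = sorted((d_all[m], m) for m in range(len(X)) if m != j)[:K]
                radius = nn[-1][0]
                if d <= radius:
                    inter = len(set(candi) & {m for _, m in nn})
                    best = max(best, inter / K)
            assert got == pytest.approx(best)

    def test_far_query_is_outlier_with_zero_odds(self):
        ls = synthdata.make_block_landscape(flip_prob=0.0, seed=6)
        far = np.full(ls.matrix.shape[0], 7.0)  # far outside the binary cube
        q = hs.QueryNut(nut_id="q", vectors={ls.ct_label: far})
        assert hs.odds_g(q, ls, K=10) == 0.0


class TestClassifyStage:
    @pytest.mark.parametrize(
        "triplet,expected",
        [
            ((0, 0, 0), "before-CT1"),
            ((1, 0, 0), "at-CT1"),
            ((0.5, 0.5, 0), "between-CT1-CT2"),
            ((0, 1, 0), "at-CT2"),
            ((0, 0.5, 0.5), "between-CT2-CT3"),
            ((0, 0, 1), "at-CT3"),
        ],
    )
    def test_canonical_patterns(self, triplet, expected):
        stage, ambiguous = hs.classify_stage(triplet)
        assert stage == expected

    def test_total_and_deterministic(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = tuple(rng.uniform(0, 1, 3))
            s1 = hs.classify_stage(g)
            s2 = hs.classify_stage(g)
            assert s1 == s2
            assert s1[0] in hs.gsd.STAGES


class TestBatchStage:
    def test_cloned_reference_batch_classifies_to_own_ct(self):
        lss = _three_landscapes(seed=10)
        for target in (0, 2):
            ref = lss[target]
            batch = []
            for j in range(0, 30, 3):
                vectors = {}
                for ls in lss:
                    if ls is ref:
                        vectors[ls.ct_label] = ref.matrix[:, j].astype(float)
                    else:
                        # far from the other landscapes
                        vectors[ls.ct_label] = np.full(ls.matrix.shape[0], 5.0)
                batch.append(hs.QueryNut(nut_id=f"q{j}", vectors=vectors))
            report = hs.batch_stage(batch, lss, K=10)
            assert report.batch_stage == f"at-{ref.ct_label.upper()}"

    def test_all_far_batch_is_before_ct1(self):
        lss = _three_landscapes(seed=20)
        batch = [
            hs.QueryNut(
                nut_id="q",
                vectors={ls.ct_label: np.full(ls.matrix.shape[0], 9.0)
                         for ls in lss},
            )
        ]
        report = hs.batch_stage(batch, lss)
        assert report.batch_stage == "before-CT1"
        assert report.triplets[0].odds == (0.0, 0.0, 0.0)

    def test_majority_rule(self):
        lss = _three_landscapes(seed=30)
        ref = lss[2]
        batch = []
        for j in range(10):
            vectors = {ls.ct_label: np.full(ls.matrix.shape[0], 9.0)
                       for ls in lss}
            if j < 8:  # 80% cloned from CT3
                vectors[ref.ct_label] = ref.matrix[:, j].astype(float)
            batch.append(hs.QueryNut(nut_id=f"q{j}", vectors=vectors))
        report = hs.batch_stage(batch, lss, K=10)
        assert report.batch_stage == "at-CT3"
        assert report.vote_distribution["at-CT3"] == 8

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            hs.batch_stage([], _three_landscapes())


class TestBlankPrevalence:
    def test_planted_branch_rates_recovered_exactly(self):
        ls = synthdata.make_block_landscape(
            n_categories=12, block_sizes=(20, 60), blank_rates=(1.0, 0.0),
            flip_prob=0.02, seed=8)
        batch = [_query_from_column(ls, j) for j in range(0, 80, 5)]
        out = hs.blank_prevalence(batch, ls, K=10, n_branches=2)
        blocks = [ls.nut_ids[j].split("-")[0] for j in range(0, 80, 5)]
        for rate, block in zip(out.annotated_rate, blocks):
            assert rate == (1.0 if block == "b1" else 0.0)
        assert out.attrs["n_outliers"] == 0

    def test_all_filled_branch_gives_zero_mean(self):
        ls = synthdata.make_block_landscape(blank_rates=(0.0, 0.0), seed=9)
        batch = [_query_from_column(ls, j) for j in range(5)]
        out = hs.blank_prevalence(batch, ls, K=10, n_branches=2)
        assert out.attrs["mean_rate"] == 0.0

    def test_outlier_query_excluded_from_mean(self):
        ls = synthdata.make_block_landscape(blank_rates=(1.0, 0.0),
                                            flip_prob=0.02, seed=10)
        good = _query_from_column(ls, 0)
        far = hs.QueryNut(nut_id="far",
                          vectors={ls.ct_label: np.full(ls.matrix.shape[0], 9.0)})
        out = hs.blank_prevalence([good, far], ls, K=10, n_branches=2)
        assert out[out.nut_id == "far"].outlier.iloc[0]
        assert out.attrs["n_outliers"] == 1
        assert out.attrs["mean_rate"] == out[~out.outlier].annotated_rate.mean()


def test_neighbourhood_system_radius_is_kth_distance():
    ls = synthdata.make_block_landscape(n_categories=6, block_sizes=(8, 8),
                                        flip_prob=0.4, seed=11)
    sysK = NeighbourhoodSystem.build(ls, K=3)
    X = ls.matrix.T.astype(float)
    for i, nid in enumerate(ls.nut_ids):
        d = sorted(np.linalg.norm(X - X[i], axis=1)[j]
                   for j in range(len(X)) if j != i)
        assert sysK.radius[nid] == pytest.approx(d[2])
        assert len(sysK.neighbours[nid]) == 3
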