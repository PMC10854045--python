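import numpy as np
import pandas as pd
import pytest

from reosig.matrix import rank_within_samples
from reosig.pairs import candidate_pool, pair_f1, reverse_degree, score_pairs
from reosig.simulate import SimConfig, distort_monotone, simulate


class TestRankWithinSamples:
    def test_definition(self):
        m = pd.DataFrame({"s1": [5.0, 1.0, 3.0]}, index=["a", "b", "c"])
        assert list(rank_within_samples(m)["s1"]) == [3, 1, 2]

    def test_tie_averaging(self):
        m = pd.DataFrame({"s1": [2.0, 2.0, 7.0]}, index=["a", "b", "c"])
        assert list(rank_within_samples(m)["s1"]) == [1.5, 1.5, 3]

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(size=(10, 5)),
                         index=[f"g{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(5)])
        pd.testing.assert_frame_equal(
            rank_within_samples(m),
            rank_within_samples(distort_monotone(m, seed=4)),
        )


def _ranks_and_labels(columns):
    """Build a rank table + labels from {sample: (label, r_erg, r_ref)}."""
    data, labels = {}, {}
    for sample, (label, r_a, r_r) in columns.items():
        data[sample] = [r_a, r_r]
        labels[sample] = label
    ranks = pd.DataFrame(data, index=["ERG", "REF"])
    return ranks, pd.Series(labels)


class TestReverseDegree:
    def test_identical_ranks_in_tfn_gives_zero(self):
        ranks, labels = _ranks_and_labels({
            "n1": ("TFN", 2, 2), "n2": ("TFN", 3, 3),
            "p1": ("TFP", 5, 1), "p2": ("TFP", 4, 2),
        })
        assert reverse_degree(ranks, labels, "ERG", "REF") == 0.0

    def test_hand_example(self):
        # TFN diffs -2, -2 -> |−4|/2 = 2; TFP diffs +2, +2 -> 2; sqrt(4)=2
        ranks, labels = _ranks_and_labels({
            "n1": ("TFN", 1, 3), "n2": ("TFN", 1, 3),
            "p1": ("TFP", 4, 2), "p2": ("TFP", 4, 2),
        })
        assert reverse_degree(ranks, labels, "ERG", "REF") == pytest.approx(2.0)

    def test_within_group_cancellation_as_printed(self):
        # +2 and -2 in TFN sum to zero: the printed statistic is 0 even
        # though every TFN sample disagrees
        ranks, labels = _ranks_and_labels({
            "n1": ("TFN", 4, 2), "n2": ("TFN", 2, 4),
            "p1": ("TFP", 5, 1), "p2": ("TFP", 5, 1),
        })
        assert reverse_degree(ranks, labels, "ERG", "REF") == 0.0

    def test_symmetric_under_gene_swap(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.lognormal(size=(6, 10)),
                         index=[f"g{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(10)])
        labels = pd.Series(["TFN"] * 5 + ["TFP"] * 5, index=m.columns)
        ranks = rank_within_samples(m)
        assert reverse_degree(ranks, labels, "g0", "g1") == pytest.approx(
            reverse_degree(ranks, labels, "g1", "g0")
        )

    def test_signed_variant_zeroes_same_direction_gaps(self):
        ranks, labels = _ranks_and_labels({
            "n1": ("TFN", 9, 1), "n2": ("TFN", 8, 2),
            "p1": ("TFP", 9, 1), "p2": ("TFP", 8, 2),
        })
        assert reverse_degree(ranks, labels, "ERG", "REF") > 0
        assert reverse_degree(ranks, labels, "ERG", "REF", signed=True) == 0.0

    def test_missing_gene_is_error(self, tiny_matrix, tiny_labels):
        ranks = rank_within_samples(tiny_matrix)
        with pytest.raises(KeyError, match="NOPE"):
            reverse_degree(ranks, tiny_labels, "ERG", "NOPE")


class TestPairF1:
    def test_perfect_pair(self, tiny_matrix, tiny_labels):
        sen, spe, f1, direction = pair_f1(tiny_matrix, tiny_labels, "ERG", "REF1")
        assert (sen, spe, f1) == (1.0, 1.0, 1.0)
        assert direction == "gt"

    def test_zero_sensitivity_gives_zero_f1(self):
        # anchor between the two groups' shared reference: both orientations fail
        m = pd.DataFrame(
            {"s1": [2.0, 2.0], "s2": [2.0, 2.0], "s3": [2.0, 2.0], "s4": [2.0, 2.0]},
            index=["ERG", "REF"],
        )
        labels = pd.Series(["TFN", "TFN", "TFP", "TFP"], index=m.columns)
        sen, spe, f1, _ = pair_f1(m, labels, "ERG", "REF")
        assert sen == 0.0  # exact ties vote TFN
        assert f1 == 0.0

    def test_training_statistics_reproduce_published_value(self):
        # sensitivity 38/46 and specificity 192/226 give F-1 = 0.8377
        from reosig.signature import harmonic_f1

        assert harmonic_f1(38 / 46, 192 / 226) == pytest.approx(0.8377, abs=5e-5)

    def test_exact_ties_vote_tfn(self):
        m = pd.DataFrame(
            {"n1": [1.0, 2.0], "n2": [2.0, 2.0], "p1": [3.0, 2.0], "p2": [2.0, 2.0]},
            index=["ERG", "REF"],
        )
        labels = pd.Series(["TFN", "TFN", "TFP", "TFP"], index=m.columns)
        sen, spe, f1, direction = pair_f1(m, labels, "ERG", "REF")
        assert direction == "gt"
        assert spe == 1.0  # tie in n2 correctly votes TFN
        assert sen == 0.5  # tie in p2 wrongly votes TFN


class TestScorePairsInvariance:
    def test_scores_invariant_under_monotone_distortion(self):
        m, truth = simulate(SimConfig(n_genes=60, n_tfn=12, n_tfp=8, seed=2))
        plain = score_pairs(m, truth.labels, anchor="ERG")
        warped = score_pairs(distort_monotone(m, seed=5), truth.labels, anchor="ERG")
        pd.testing.assert_frame_equal(plain, warped)

    def test_planted_partners_lead_f1_and_signed_rankings(self):
        m, truth = simulate(SimConfig(seed=1, erg_shift=4.0))
        scores = score_pairs(m, truth.labels, anchor="ERG")
        assert set(scores.head(5)["partner"]) == truth.planted_partners
        signed = score_pairs(m, truth.labels, anchor="ERG", signed=True)
        top_signed = signed.sort_values("reverse_degree", ascending=False).head(5)
        assert set(top_signed["partner"]) == truth.planted_partners
        pool = candidate_pool(scores)
        assert truth.planted_partners <= set(pool["partner"])


class TestCandidatePool:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["partner", "direction", "reverse_degree",
                           "sensitivity", "specificity", "f1"]
        )

    def test_full_overlap_gives_pool_of_top_k(self):
        rows = [(f"g{i:02d}", "gt", 100.0 - i, 0.9, 0.9, (100.0 - i) / 100) for i in range(30)]
        pool = candidate_pool(self._table(rows), top_frac=0.2, top_k=10)
        assert len(pool) == 10
        assert set(pool["partner"]) == {f"g{i:02d}" for i in range(10)}

    def test_disjoint_top_lists_union_to_twenty(self):
        rows = []
        for i in range(20):  # high rdeg, low f1
            rows.append((f"r{i:02d}", "gt", 1000.0 - i, 0.1, 0.1, 0.1 - i / 1000))
        for i in range(20):  # high f1, low rdeg
            rows.append((f"f{i:02d}", "gt", 1.0 - i / 100, 0.9, 0.9, 0.99 - i / 1000))
        pool = candidate_pool(self._table(rows), top_frac=0.2, top_k=10)
        # 20% of 40 = 8 -> top-8 sets are disjoint too: pool is the two top-10s
        assert len(pool) == 20

    def test_matches_brute_force_set_arithmetic(self):
        rng = np.random.default_rng(42)
        rows = [
            (f"g{i:03d}", "gt", float(rng.uniform(0, 50)), 0.5, 0.5,
             float(rng.uniform(0, 1)))
            for i in range(100)
        ]
        table = self._table(rows)
        pool = set(candidate_pool(table, top_frac=0.2, top_k=10)["partner"])

        # independent set computation on plain tuples
        recs = [(r[0], r[2], r[5]) for r in rows]
        by_rd = sorted(recs, key=lambda t: (-t[1], -t[2], t[0]))
        by_f1 = sorted(recs, key=lambda t: (-t[2], -t[1], t[0]))
        n20 = int(np.ceil(0.2 * len(recs)))
        expected = (
            {t[0] for t in by_rd[:10]}
            | {t[0] for t in by_f1[:10]}
            | ({t[0] for t in by_rd[:n20]} & {t[0] for t in by_f1[:n20]})
        )
        assert pool == expected
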