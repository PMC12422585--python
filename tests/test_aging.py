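"""Age binning, class proportions, prevalence, pattern similarity, CIs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chimerabrain.aging import (
    assign_age_bin,
    class_proportions,
    confidence_interval,
    fine_bin_order,
    net_change,
    pattern_similarity,
    prevalence_table,
    similarity_decomposition,
    strength_class_stratification,
)


class TestAssignAgeBin:
    @pytest.mark.parametrize(
        "age,expected",
        [(29, "young"), (30, "middle"), (59.9, "middle"), (60, "old"), (5, "young")],
    )
    def test_coarse_edges(self, age, expected):
        assert assign_age_bin(age, "coarse") == expected

    @pytest.mark.parametrize(
        "age,expected",
        [(7, "5-10"), (62, "60-65"), (66, "65-75"), (72, "65-75"),
         (77, "75-90"), (83, "75-90"), (89, "75-90")],
    )
    def test_fine_bins_with_merges(self, age, expected):
        assert assign_age_bin(age, "fine") == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_age_bin(-1.0)

    def test_fine_bin_ordering(self):
        bins = ["65-75", "5-10", "75-90", "30-35"]
        assert fine_bin_order(bins) == ["5-10", "30-35", "65-75", "75-90"]


def pattern_df(rows):
    return pd.DataFrame(rows)


class TestClassProportions:
    def test_pure_group(self):
        df = pattern_df([{"age_bin": "young", "cls": "chimera"}] * 4)
        out = class_proportions(df)
        assert out.iloc[0][["asynchronous", "chimera", "synchronous"]].tolist() == [
            0, 1, 0
        ]

    def test_counting(self):
        df = pattern_df(
            [{"age_bin": "old", "cls": c}
             for c in ["asynchronous"] * 2 + ["chimera", "synchronous"]]
        )
        row = class_proportions(df).iloc[0]
        assert row["asynchronous"] == 0.5
        assert row["chimera"] == 0.25
        assert row["synchronous"] == 0.25

    def test_sums_to_one(self, rng):
        classes = rng.choice(["asynchronous", "chimera", "synchronous"], 100)
        bins = rng.choice(["young", "middle", "old"], 100)
        df = pattern_df([{"age_bin": b, "cls": c} for b, c in zip(bins, classes)])
        out = class_proportions(df)
        sums = out[["asynchronous", "chimera", "synchronous"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_chunking_invariance(self, rng):
        classes = rng.choice(["asynchronous", "chimera", "synchronous"], 60)
        df = pattern_df([{"age_bin": "young", "cls": c} for c in classes])
        full = class_proportions(df)
        # recompute from chunk counts
        chunks = [df.iloc[:17], df.iloc[17:40], df.iloc[40:]]
        counts = pd.concat(
            [c["cls"].value_counts() for c in chunks]
        ).groupby(level=0).sum()
        for cls in ("asynchronous", "chimera", "synchronous"):
            assert full.iloc[0][cls] == pytest.approx(
                counts.get(cls, 0) / len(df)
            )


class TestNetChange:
    def test_identical_is_zero(self):
        p = {"asynchronous": 0.3, "chimera": 0.5, "synchronous": 0.2}
        assert all(v == 0 for v in net_change(p, p).values())

    def test_signed_differences(self):
        young = {"asynchronous": 0.5, "chimera": 0.5, "synchronous": 0.0}
        old = {"asynchronous": 0.2, "chimera": 0.6, "synchronous": 0.2}
        d = net_change(young, old)
        assert d == pytest.approx(
            {"asynchronous": -0.3, "chimera": 0.1, "synchronous": 0.2}
        )
        assert sum(d.values()) == pytest.approx(0.0, abs=1e-12)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            net_change({"chimera": 1.0}, {"chimera": 1.0})


class TestPrevalenceTable:
    def test_tier_boundaries(self):
        # 100 patterns: one at 6%, one at 4%, one at 2%, rest filler
        rows = (
            [{"age_bin": "young", "cls": "chimera", "labels": (1, 0)}] * 6
            + [{"age_bin": "young", "cls": "chimera", "labels": (0, 1)}] * 4
            + [{"age_bin": "young", "cls": "chimera", "labels": (1, 1)}] * 2
            + [{"age_bin": "young", "cls": "chimera", "labels": (0, 0)}] * 88
        )
        out = prevalence_table(pattern_df(rows)).set_index("labels")
        assert out.loc[[(1, 0)], "tier"].item() == "high"
        assert out.loc[[(0, 1)], "tier"].item() == "medium"
        assert out.loc[[(1, 1)], "tier"].item() == "low"

    def test_exact_boundaries_are_medium(self):
        rows = (
            [{"age_bin": "b", "cls": "chimera", "labels": (1, 0)}] * 3
            + [{"age_bin": "b", "cls": "chimera", "labels": (0, 1)}] * 5
            + [{"age_bin": "b", "cls": "chimera", "labels": (0, 0)}] * 92
        )
        out = prevalence_table(pattern_df(rows)).set_index("labels")
        assert out.loc[[(1, 0)], "tier"].item() == "medium"  # exactly 3%
        assert out.loc[[(0, 1)], "tier"].item() == "medium"  # exactly 5%

    def test_ranking(self):
        rows = (
            [{"age_bin": "b", "cls": "chimera", "labels": (1, 0)}] * 7
            + [{"age_bin": "b", "cls": "chimera", "labels": (0, 1)}] * 3
        )
        out = prevalence_table(pattern_df(rows))
        assert out.sort_values("rank")["labels"].tolist() == [(1, 0), (0, 1)]


def naive_pattern_similarity(patterns):
    M = [tuple(p) for p in patterns]
    n_p, n_cs = len(M), len(M[0])
    total = 0.0
    for i in range(n_p):
        for j in range(n_p):
            if i == j:
                continue
            total += sum(M[i][k] == M[j][k] for k in range(n_cs)) / n_cs
    return total / (n_p * (n_p - 1))


class TestPatternSimilarity:
    def test_identical_patterns(self):
        assert pattern_similarity([(1, 0, 1)] * 5) == pytest.approx(1.0)

    def test_complementary_pair(self):
        assert pattern_similarity([(1, 1, 0), (0, 0, 1)]) == pytest.approx(0.0)

    def test_three_of_nine_differ(self):
        a = (1, 1, 1, 1, 1, 1, 0, 0, 0)
        b = (1, 1, 1, 0, 0, 0, 0, 0, 0)
        assert pattern_similarity([a, b]) == pytest.approx(6 / 9)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pattern_similarity([(1, 0)])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 10**6))
    def test_matches_pairwise_enumeration(self, n_p, seed):
        rng = np.random.default_rng(seed)
        patterns = [tuple(rng.integers(0, 2, 9)) for _ in range(n_p)]
        assert pattern_similarity(patterns) == pytest.approx(
            naive_pattern_similarity(patterns), abs=1e-12
        )

    def test_permutation_invariance(self, rng):
        patterns = [tuple(rng.integers(0, 2, 9)) for _ in range(10)]
        shuffled = list(patterns)
        rng.shuffle(shuffled)
        assert pattern_similarity(patterns) == pytest.approx(
            pattern_similarity(shuffled)
        )


class TestSimilarityDecomposition:
    @staticmethod
    def grid_df():
        """3 regions x 3 individuals with hand-set patterns."""
        pat = {
            (0, "a"): (1, 1, 0), (0, "b"): (1, 1, 0), (0, "c"): (1, 0, 0),
            (1, "a"): (0, 0, 0), (1, "b"): (1, 1, 1), (1, "c"): (0, 1, 0),
            (2, "a"): (1, 0, 1), (2, "b"): (1, 0, 1), (2, "c"): (1, 0, 1),
        }
        return pd.DataFrame(
            [
                {"region": r, "individual": i, "labels": l,
                 "cls": "chimera" if 0 < sum(l) < 3 else
                        "synchronous" if sum(l) == 3 else "asynchronous"}
                for (r, i), l in pat.items()
            ]
        )

    def test_both_modes_match_exhaustive(self):
        df = self.grid_df()
        by_region = [
            naive_pattern_similarity(
                df[df["region"] == r]["labels"].tolist()
            )
            for r in (0, 1, 2)
        ]
        assert similarity_decomposition(df, "individual") == pytest.approx(
            np.mean(by_region)
        )
        by_indiv = [
            naive_pattern_similarity(
                df[df["individual"] == i]["labels"].tolist()
            )
            for i in ("a", "b", "c")
        ]
        assert similarity_decomposition(df, "region") == pytest.approx(
            np.mean(by_indiv)
        )

    def test_identical_region_contributes_one(self):
        df = pd.DataFrame(
            [
                {"region": 0, "individual": i, "labels": (1, 0, 1), "cls": "chimera"}
                for i in range(4)
            ]
        )
        assert similarity_decomposition(df, "individual") == pytest.approx(1.0)

    def test_insufficient_patterns_skipped(self, caplog):
        df = pd.DataFrame(
            [{"region": 0, "individual": "a", "labels": (1, 0), "cls": "chimera"}]
        )
        with caplog.at_level("WARNING"):
            assert similarity_decomposition(df, "individual") is None

    def test_chimera_only_filtering(self):
        df = self.grid_df()
        chim = df[df["cls"] == "chimera"]
        vals = []
        for r, grp in chim.groupby("region"):
            if len(grp) >= 2:
                vals.append(naive_pattern_similarity(grp["labels"].tolist()))
        assert similarity_decomposition(
            df, "individual", chimera_only=True
        ) == pytest.approx(np.mean(vals))


class TestConfidenceInterval:
    def test_constant_samples(self):
        mean, half = confidence_interval([0.4] * 10)
        assert mean == pytest.approx(0.4)
        assert half == pytest.approx(0.0)

    def test_two_point_formula(self):
        from scipy import stats

        mean, half = confidence_interval([0.0, 1.0])
        sigma = np.std([0.0, 1.0], ddof=1)
        assert mean == pytest.approx(0.5)
        assert half == pytest.approx(
            stats.t.ppf(0.975, 1) * sigma / np.sqrt(2)
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([1.0])

    def test_monte_carlo_coverage(self):
        """95% CI covers the true mean of a standard normal in 94-96%
        of 2000 replicates at n = 1e4."""
        rng = np.random.default_rng(777)
        n, reps = 10_000, 2000
        from scipy import stats

        t = stats.t.ppf(0.975, n - 1)
        x = rng.standard_normal((reps, n))
        half = t * x.std(axis=1, ddof=1) / np.sqrt(n)
        covered = (np.abs(x.mean(axis=1)) <= half).mean()
        assert 0.94 <= covered <= 0.96


class TestStrengthStratification:
    def test_uniform_class_dominates_every_bin(self, rng):
        df = pd.DataFrame(
            {"strength": rng.uniform(0, 10, 100), "cls": ["synchronous"] * 100}
        )
        out = strength_class_stratification(df)
        assert (out["dominant"] == "synchronous").all()

    def test_step_function_recovered_within_one_bin(self, rng):
        s = rng.uniform(0, 10, 400)
        cls = np.where(s < 3, "asynchronous",
                       np.where(s < 7, "chimera", "synchronous"))
        df = pd.DataFrame({"strength": s, "cls": cls})
        out = strength_class_stratification(df, n_bins=10)
        doms = out.sort_values("strength_bin")["dominant"].tolist()
        # monotone progression async -> chimera -> sync
        order = {"asynchronous": 0, "chimera": 1, "synchronous": 2}
        ranks = [order[d] for d in doms]
        assert ranks == sorted(ranks)
        assert set(doms) == {"asynchronous", "chimera", "synchronous"}

    def test_proportions_sum_to_one(self, rng):
        df = pd.DataFrame(
            {
                "strength": rng.uniform(0, 5, 120),
                "cls": rng.choice(
                    ["asynchronous", "chimera", "synchronous"], 120
                ),
            }
        )
        out = strength_class_stratification(df)
        sums = out[["asynchronous", "chimera", "synchronous"]].sum(axis=1)
        assert np.allclose(sums, 1.0)
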