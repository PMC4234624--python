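import math

import numpy as np
import pandas as pd
import pytest

from cohortnet.io import AttributeTable
from cohortnet.mapeq import Partition
from cohortnet.segregation import (
    DegenerateNullError,
    group_divergence,
    max_segregation,
    segregation_zscore,
    total_segregation,
    weekly_zscore_series,
)

from _oracles import kl_direct


def make_attrs(values, attribute="gender", vocab=None):
    ids = [f"n{i}" for i in range(len(values))]
    df = pd.DataFrame({attribute: [str(v) for v in values]}, index=pd.Index(ids, name="id"))
    vocab = vocab or tuple(sorted(set(str(v) for v in values)))
    return ids, AttributeTable(df, {attribute: vocab})


class TestGroupDivergence:
    def test_group_matching_global_is_zero(self):
        assert group_divergence([3, 3], [0.5, 0.5]) == pytest.approx(0.0)

    def test_pure_group_against_half_global_is_one_bit(self):
        assert group_divergence([4, 0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_mixed_group_matches_direct_formula(self):
        # 5M/1F group against a 6M/4F global distribution over 10 nodes
        d = group_divergence([5, 1], [0.6, 0.4])
        assert d == pytest.approx(kl_direct([5, 1], [0.6, 0.4]))
        assert d == pytest.approx(0.184, abs=1e-3)

    def test_inconsistent_support_rejected(self):
        with pytest.raises(ValueError):
            group_divergence([1, 1], [1.0, 0.0])


class TestTotalSegregation:
    def test_single_group_is_zero(self):
        ids, attrs = make_attrs(["M"] * 6 + ["F"] * 4)
        part = Partition.one_module(ids)
        assert total_segregation(part, attrs, "gender") == pytest.approx(0.0)

    def test_weighted_sum_matches_hand_evaluation(self):
        # groups (5M,1F) and (1M,3F); global 6M/4F
        ids, attrs = make_attrs(["M"] * 5 + ["F"] + ["M"] + ["F"] * 3)
        part = Partition({i: (1 if k < 6 else 2) for k, i in enumerate(ids)})
        expected = 0.6 * kl_direct([5, 1], [0.6, 0.4]) + 0.4 * kl_direct([1, 3], [0.6, 0.4])
        s = total_segregation(part, attrs, "gender")
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(0.256, abs=5e-3)

    def test_perfect_segregation_reaches_entropy(self):
        ids, attrs = make_attrs(["M"] * 6 + ["F"] * 4)
        part = Partition({i: (1 if k < 6 else 2) for k, i in enumerate(ids)})
        s = total_segregation(part, attrs, "gender")
        assert s == pytest.approx(max_segregation([0.6, 0.4]), abs=1e-12)

    def test_invariant_under_relabeling(self):
        ids, attrs = make_attrs(["M", "M", "F", "F", "M", "F"])
        part_a = Partition({i: k % 2 for k, i in enumerate(ids)})
        part_b = Partition({i: (k % 2) + 7 for k, i in enumerate(ids)})
        assert total_segregation(part_a, attrs, "gender") == pytest.approx(
            total_segregation(part_b, attrs, "gender")
        )

    def test_bounded_by_maximum(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            values = rng.choice(["a", "b", "c"], size=12)
            ids, attrs = make_attrs(values, attribute="section")
            part = Partition({i: int(rng.integers(0, 4)) for i in ids})
            s = total_segregation(part, attrs, "section")
            counts = pd.Series(values).value_counts(normalize=True)
            assert -1e-12 <= s <= max_segregation(counts.to_numpy()) + 1e-12


class TestMaxSegregation:
    @pytest.mark.parametrize(
        "dist, expected",
        [([0.5, 0.5], 1.0), ([1.0], 0.0), ([0.6, 0.4], 0.9710)],
    )
    def test_entropy_values(self, dist, expected):
        assert max_segregation(dist) == pytest.approx(expected, abs=5e-4)


class TestZScores:
    def test_constant_attribute_degenerate(self):
        ids, attrs = make_attrs(["M"] * 8)
        part = Partition({i: k % 2 for k, i in enumerate(ids)})
        with pytest.raises(DegenerateNullError):
            segregation_zscore(part, attrs, "gender", m_perms=100, seed=0)

    def test_calibrated_under_null(self):
        """Attribute assigned independently of a fixed partition: the 5%
        level rejects about 5% of the time (loose band at 300 draws)."""
        rng = np.random.default_rng(7)
        ids = [f"n{i}" for i in range(60)]
        part = Partition({i: k // 10 for k, i in enumerate(ids)})
        hits = 0
        n_draws = 300
        for d in range(n_draws):
            values = rng.choice(["M", "F"], size=60, p=[0.6, 0.4])
            _, attrs = make_attrs(values)
            res = segregation_zscore(part, attrs, "gender", m_perms=300, seed=d)
            hits += abs(res.Z) > 1.96
        assert 0.02 <= hits / n_draws <= 0.09

    def test_perfectly_segregated_strongly_significant(self):
        ids, attrs = make_attrs(["M"] * 15 + ["F"] * 15)
        part = Partition({i: (1 if k < 15 else 2) for k, i in enumerate(ids)})
        res = segregation_zscore(part, attrs, "gender", m_perms=1000, seed=3)
        assert res.Z > 1.96
        assert res.significant

    def test_per_group_flags(self):
        ids, attrs = make_attrs(["M"] * 10 + ["F"] * 10 + ["M", "F"] * 5)
        part = Partition(
            {i: (1 if k < 10 else 2 if k < 20 else 3) for k, i in enumerate(ids)}
        )
        res = segregation_zscore(part, attrs, "gender", m_perms=1000, seed=1, level="per_group")
        assert {"Z", "significant"} <= set(res.groups.columns)
        pure = res.groups.loc[[1, 2]]
        mixed = res.groups.loc[3]
        assert (pure["Z"] > mixed["Z"]).all()

    def test_result_fields_consistent(self):
        ids, attrs = make_attrs(["M"] * 12 + ["F"] * 8)
        part = Partition({i: k % 4 for k, i in enumerate(ids)})
        res = segregation_zscore(part, attrs, "gender", m_perms=200, seed=5)
        assert 0.0 <= res.S <= res.S_max + 1e-12
        assert res.significant == (abs(res.Z) > 1.96)
        assert res.groups["size"].sum() == 20


class TestWeeklySeries:
    def test_single_week_single_attribute(self, small_cohort):
        _, attrs, nets = small_cohort
        from cohortnet.mapeq import detect_communities

        part, _ = detect_communities(nets[0], n_runs=2, seed=0)
        df = weekly_zscore_series(nets[:1], [part], attrs, attributes=("gender",), m_perms=200)
        assert len(df) == 1
        assert set(df.columns) == {"week", "attribute", "S", "S_max", "Z", "significant"}

    def test_section_significant_grade_not_with_section_homophily(self):
        """Communities detected on the pooled first weeks segregate by
        section (the homophily axis) but not by the independent grade."""
        from cohortnet.io import merge_weeks
        from cohortnet.mapeq import detect_communities
        from cohortnet.synthetic import CohortConfig, generate_cohort

        section_hits = grade_ok = 0
        for k in range(5):
            cfg = CohortConfig(homophily_section=8.0, seed=13 + k)
            attrs, nets = generate_cohort(cfg)
            net = merge_weeks(nets[0], nets[1], 2)
            part, _ = detect_communities(net, n_runs=3, seed=2)
            df = weekly_zscore_series([net], [part], attrs, m_perms=500, seed=k)
            by_attr = df.set_index("attribute")
            section_hits += by_attr.loc["section", "Z"] > 1.96
            grade_ok += abs(by_attr.loc["grade", "Z"]) <= 1.96
        assert section_hits >= 4
        assert grade_ok >= 4
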