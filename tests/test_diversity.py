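import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from raretaxa import (
    ace,
    chao1,
    classify,
    correlate,
    profile_otus,
    rarefaction_curve,
    sample_diversity,
    shannon,
    to_relative_abundance,
)
from raretaxa.diversity import significance_stars

count_vectors = st.lists(st.integers(0, 40), min_size=1, max_size=30).filter(
    lambda v: sum(v) > 0
)


class TestShannon:
    def test_uniform_is_log_s(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_single_otu_is_zero(self):
        assert shannon([7]) == 0.0

    def test_hand_computed_two_otus(self):
        expect = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert shannon([3, 1]) == pytest.approx(expect)

    @given(v=count_vectors, k=st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, v, k):
        assert shannon(np.asarray(v) * k) == pytest.approx(shannon(v))

    def test_base_conversion(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)


class TestRichnessEstimators:
    def test_chao1_equals_sobs_without_singletons(self):
        assert chao1([5, 3, 2]) == 3

    def test_chao1_bias_corrected_hand_value(self):
        assert chao1([5, 3, 1, 1, 2]) == pytest.approx(5.5)

    def test_chao1_classic_form(self):
        # f1=2, f2=1 -> S + f1^2/(2 f2) = 5 + 2
        assert chao1([5, 3, 1, 1, 2], bias_corrected=False) == pytest.approx(7.0)

    def test_ace_without_rare_group_is_sobs(self):
        assert ace([11, 20, 100]) == 3

    def test_ace_hand_value(self):
        assert ace([1, 1, 2, 10, 100]) == pytest.approx(8.8376, abs=1e-3)

    def test_ace_all_singletons_falls_back_to_chao1(self):
        v = [1, 1, 1, 1]
        assert ace(v) == pytest.approx(chao1(v))

    @given(v=count_vectors)
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_padding_invariance(self, v):
        arr = np.asarray(v)
        s_obs = int((arr > 0).sum())
        padded = np.concatenate([arr, np.zeros(3, dtype=int)])
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(arr)
        for est in (chao1, ace):
            assert est(arr) >= s_obs - 1e-9
            assert est(padded) == pytest.approx(est(arr))
            assert est(shuffled) == pytest.approx(est(arr))
        assert shannon(arr) <= np.log(max(s_obs, 1)) + 1e-12

    @given(v=count_vectors)
    @settings(max_examples=60, deadline=None)
    def test_matches_reference_implementation(self, v):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        arr = np.asarray(v)
        assert chao1(arr) == pytest.approx(skbio_alpha.chao1(arr, bias_corrected=True))
        rare = arr[(arr > 0) & (arr <= 10)]
        if rare.size and (rare == 1).sum() not in (0, rare.size):
            assert ace(arr) == pytest.approx(skbio_alpha.ace(arr))


class TestRarefaction:
    def test_full_depth_recovers_sobs(self):
        v = [9, 5, 3, 1]
        assert rarefaction_curve(v, [18])[0] == pytest.approx(4.0)

    def test_depth_one_sees_one_otu(self):
        assert rarefaction_curve([4, 4, 2], [1])[0] == pytest.approx(1.0)

    def test_monotone_in_depth(self):
        v = [30, 10, 5, 2, 1, 1]
        curve = rarefaction_curve(v, range(1, sum(v) + 1))
        assert np.all(np.diff(curve) >= -1e-12)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_curve([4, 4, 2], [11])

    def test_matches_subsampling_simulation(self, rng):
        v = np.array([4, 4, 2])
        expect = rarefaction_curve(v, [5])[0]
        reads = np.repeat(np.arange(v.size), v)
        sim = np.mean(
            [np.unique(rng.choice(reads, 5, replace=False)).size for _ in range(20000)]
        )
        assert expect == pytest.approx(sim, abs=0.02)


class TestCorrelate:
    @staticmethod
    def _div(values, scope="all", index="chao1"):
        df = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "scope": scope}
        )
        for name in ("chao1", "ace", "shannon"):
            df[name] = values if name == index else np.nan
        df["s_obs"] = 0
        return df

    @staticmethod
    def _meta(values):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "site": "X",
                "rate_ac": values,
            }
        )

    def test_perfect_linear_relation(self):
        x = [1.0, 2, 3, 4, 5]
        out = correlate(
            self._div(x), self._meta([2 * v for v in x]),
            variables=("rate_ac",), indices=("chao1",),
        )
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] < 0.01
        assert row["stars"] == "***"

    def test_constant_variable_flagged_undefined(self):
        out = correlate(
            self._div([1.0, 2, 3, 4]), self._meta([5.0, 5, 5, 5]),
            variables=("rate_ac",), indices=("chao1",),
        )
        assert bool(out.iloc[0]["undefined"]) and np.isnan(out.iloc[0]["r"])

    def test_hand_computed_r_and_t_test_p(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 4, 3, 5]
        out = correlate(
            self._div(x), self._meta(y), variables=("rate_ac",), indices=("chao1",)
        ).iloc[0]
        assert out["r"] == pytest.approx(0.8)
        t = 0.8 * np.sqrt(3) / np.sqrt(1 - 0.64)
        assert out["p"] == pytest.approx(2 * stats.t.sf(t, df=3))
        assert out["n"] == 5

    def test_absent_metadata_dropped_pairwise(self):
        meta = self._meta([1.0, 2, np.nan, 4, 5])
        out = correlate(
            self._div([1.0, 2, 3, 4, 5]), meta, variables=("rate_ac",),
            indices=("chao1",),
        ).iloc[0]
        assert out["n"] == 4

    def test_star_conventions(self):
        assert significance_stars(0.003) == "***"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.08) == "*"
        assert significance_stars(0.2) == ""
        assert significance_stars(0.03, "conventional") == "*"


class TestSampleDiversity:
    def test_scopes_partition_the_observed_richness(self, default_community):
        table, _, _ = default_community
        X = to_relative_abundance(table)
        profiles, _ = classify(profile_otus(X, table))
        div = sample_diversity(table, scopes=("all", "abundant", "rare"),
                               profiles=profiles)
        wide = div.pivot(index="sample_id", columns="scope", values="s_obs")
        assert (wide["abundant"] + wide["rare"] == wide["all"]).all()

    def test_rare_scope_needs_profiles(self, default_community):
        table, _, _ = default_community
        with pytest.raises(ValueError, match="profiles"):
            sample_diversity(table, scopes=("rare",))
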