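import numpy as np
import pandas as pd
import pytest

from raretaxa import (
    OtuTable,
    RarityConfig,
    classify,
    gradient_subsets,
    gradient_thresholds,
    profile_otus,
    to_relative_abundance,
    venn_site_sharing,
)


def _profiles_from_rows(rows: dict[str, list[float]]) -> pd.DataFrame:
    X = pd.DataFrame(rows).T
    X.columns = [f"s{i}" for i in range(X.shape[1])]
    return profile_otus(X)


class TestProfiles:
    def test_fluctuating_row_summary(self):
        prof = _profiles_from_rows({"o": [0.0001, 0.0002, 0.0001, 0.02]})
        row = prof.loc["o"]
        assert row["mean_ra"] == pytest.approx(0.0051)
        assert row["max_ra"] == 0.02
        assert row["min_nz_ra"] == 0.0001
        assert row["ratio"] == pytest.approx(200.0)
        assert row["occupancy"] == 4

    def test_single_read_is_absolute_singleton(self):
        counts = OtuTable(
            pd.DataFrame({"s1": [1, 99], "s2": [0, 100]}, index=["solo", "big"])
        )
        prof = profile_otus(to_relative_abundance(counts), counts)
        assert prof.at["solo", "ratio"] == 1.0
        assert prof.at["solo", "occupancy"] == 1
        assert prof.at["solo", "singleton_flag"] == "absolute_singleton"

    def test_constant_row_has_unit_ratio(self):
        prof = _profiles_from_rows({"o": [0.002, 0.002, 0.002]})
        assert prof.at["o", "ratio"] == 1.0


class TestClassify:
    def test_rule_applications(self):
        prof = _profiles_from_rows(
            {
                "crt": [0.0001, 0.0002, 0.0001, 0.02],  # ratio 200
                "abund": [0.02, 0.02, 0.02, 0.02],  # mean > 1%
                "flat": [0.001, 0.002, 0.001, 0.001],  # ratio 2
                "mid": [0.0005, 0.005, 0.001, 0.001],  # ratio 10
            }
        )
        out, summary = classify(prof)
        assert out.at["crt", "rarity_class"] == "CRT"
        assert out.at["abund", "fraction_class"] == "ABUNDANT"
        assert out.at["abund", "rarity_class"] == "NA"
        assert out.at["flat", "rarity_class"] == "PER"
        assert out.at["mid", "rarity_class"] == "RARE"
        assert summary["total"] == 4

    def test_singletons_go_to_per(self):
        counts = OtuTable(
            pd.DataFrame({"s1": [1, 500], "s2": [0, 800], "s3": [0, 700]},
                         index=["solo", "big"])
        )
        prof = profile_otus(to_relative_abundance(counts), counts)
        out, _ = classify(prof)
        assert out.at["solo", "rarity_class"] == "PER"

    def test_classes_partition_community(self, default_community, default_relabund):
        table, _, _ = default_community
        out, summary = classify(profile_otus(default_relabund, table))
        assert (
            summary["ABUNDANT"] + summary["CRT"] + summary["RARE"] + summary["PER"]
            == summary["total"]
            == table.n_otus
        )

    def test_invariant_under_reordering(self, default_community, default_relabund):
        table, _, _ = default_community
        base, _ = classify(profile_otus(default_relabund, table))
        rng = np.random.default_rng(0)
        Xp = default_relabund.iloc[
            rng.permutation(table.n_otus), rng.permutation(table.n_samples)
        ]
        perm, _ = classify(profile_otus(Xp))
        pd.testing.assert_series_equal(
            base["rarity_class"].sort_index(), perm["rarity_class"].sort_index()
        )

    def test_raising_threshold_never_shrinks_rare_pool(self, default_relabund):
        prof = profile_otus(default_relabund)
        sizes = []
        for thr in (0.01, 0.02, 0.05, 0.2):
            out, summary = classify(prof, RarityConfig(abundant_threshold=thr))
            sizes.append(summary["total"] - summary["ABUNDANT"])
        assert sizes == sorted(sizes)

    def test_boundary_conventions(self):
        prof = _profiles_from_rows(
            {
                "at_cutoff": [0.01, 0.01, 0.01],  # mean exactly 1% -> rare pool
                "ratio_100": [0.0001, 0.01, 0.005],  # ratio exactly 100 -> CRT
            }
        )
        out, _ = classify(prof)
        assert out.at["at_cutoff", "fraction_class"] == "RARE_POOL"
        assert out.at["ratio_100", "rarity_class"] == "CRT"
        strict, _ = classify(prof, RarityConfig(crt_strict=True))
        assert strict.at["ratio_100", "rarity_class"] == "RARE"


class TestGradient:
    def test_default_gradient_has_19_thresholds(self):
        t = gradient_thresholds(RarityConfig())
        assert len(t) == 19
        assert t[0] == pytest.approx(0.01) and t[-1] == pytest.approx(0.001)

    def test_degenerate_single_threshold(self):
        cfg = RarityConfig(gradient_start=0.01, gradient_end=0.01, gradient_step=0.003)
        assert len(gradient_thresholds(cfg)) == 1

    def test_uneven_step_rejected(self):
        cfg = RarityConfig(gradient_start=0.01, gradient_end=0.001, gradient_step=0.0004)
        with pytest.raises(ValueError, match="evenly"):
            gradient_thresholds(cfg)

    def test_subsets_are_nested(self, default_relabund):
        prof = profile_otus(default_relabund)
        subsets = gradient_subsets(prof, RarityConfig())
        for (t_hi, hi), (t_lo, lo) in zip(subsets, subsets[1:]):
            assert t_lo < t_hi
            assert lo <= hi


class TestVennSiteSharing:
    @staticmethod
    def _meta():
        return pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "c1"], "site": ["A", "A", "B", "C"]}
        )

    def test_partition_of_subset(self):
        X = pd.DataFrame(
            {
                "a1": [1, 0, 1, 1],
                "a2": [1, 0, 0, 0],
                "b1": [1, 1, 0, 1],
                "c1": [1, 0, 0, 1],
            },
            index=["everywhere", "only_b", "only_a", "abc"],
        )
        regions = venn_site_sharing(X, self._meta(), set(X.index))
        assert regions[("A", "B", "C")] == 2  # everywhere + abc
        assert regions[("B",)] == 1  # indigenous to B
        assert regions[("A",)] == 1
        assert sum(regions.values()) == 4

    def test_unknown_sample_site_errors(self):
        X = pd.DataFrame({"zz": [1]}, index=["o"])
        with pytest.raises(ValueError, match="zz"):
            venn_site_sharing(X, self._meta(), {"o"})

    def test_endemics_land_in_single_site_regions(self, default_community):
        table, meta, truth = default_community
        X = to_relative_abundance(table)
        endemic = set(truth.home_site.index[truth.home_site != "shared"])
        regions = venn_site_sharing(X, meta, endemic)
        multi = {c: n for c, n in regions.items() if len(c) > 1 and n > 0}
        assert not multi
        assert sum(regions.values()) == len(endemic)
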