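"""PCoA geometry, group tests, and trajectory smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from qmpipe.ordination import (
    group_median_trajectories,
    pcoa_pearson,
    pearson_log_distance,
    smooth_class_trajectories,
)
from qmpipe.ordination import test_group_separation as group_separation_anova


def _random_profile(seed, n, m):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.gamma(2, 100, size=(n, m)),
                        index=[f"s{i}" for i in range(n)],
                        columns=[f"t{j}" for j in range(m)])


class TestDistances:
    def test_matches_brute_force_one_minus_r(self):
        prof = _random_profile(1, 5, 8)
        dm, _ = pearson_log_distance(prof)
        logx = np.log10(prof.to_numpy() + 1.0)
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else 1 - stats.pearsonr(
                    logx[i], logx[j]).statistic
                assert abs(dm[prof.index[i], prof.index[j]] - expect) < 1e-12

    def test_duplicated_sample_at_distance_zero(self):
        prof = _random_profile(2, 4, 10)
        prof.loc["dup"] = prof.loc["s0"]
        dm, _ = pearson_log_distance(prof)
        assert dm["s0", "dup"] == pytest.approx(0.0, abs=1e-12)
        res = pcoa_pearson(prof)
        np.testing.assert_allclose(res.coordinates.loc["s0"],
                                   res.coordinates.loc["dup"], atol=1e-9)

    def test_constant_sample_excluded_with_note(self):
        prof = _random_profile(3, 4, 6)
        prof.loc["flat"] = 9.0
        dm, excluded = pearson_log_distance(prof)
        assert excluded == ["flat"]
        assert "flat" not in dm.ids


class TestPCoA:
    def test_orthogonal_clusters_separate_on_first_axis(self):
        rng = np.random.default_rng(4)
        a = np.tile([100, 100, 100, 0, 0, 0], (6, 1)) + rng.poisson(3, (6, 6))
        b = np.tile([0, 0, 0, 100, 100, 100], (6, 1)) + rng.poisson(3, (6, 6))
        prof = pd.DataFrame(np.vstack([a, b]),
                            index=[f"x{i}" for i in range(12)])
        dm, _ = pearson_log_distance(prof)
        within = [dm[f"x{i}", f"x{j}"] for i in range(6) for j in range(i)]
        between = [dm[f"x{i}", f"x{j}"] for i in range(6) for j in range(6, 12)]
        assert min(between) > max(within)
        res = pcoa_pearson(prof)
        pc1 = res.coordinates["PC1"]
        assert (pc1.iloc[:6].max() < pc1.iloc[6:].min()) or (
            pc1.iloc[:6].min() > pc1.iloc[6:].max())

    def test_euclidean_embeddable_distances_reconstructed(self):
        # this profile's correlation distances embed exactly (no negative
        # eigenvalues), so coordinates must reproduce them to float precision
        prof = _random_profile(0, 4, 12)
        res = pcoa_pearson(prof)
        assert res.negative_eigenvalue_mass < 1e-12
        dm, _ = pearson_log_distance(prof)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, dm.data, atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        res = pcoa_pearson(_random_profile(5, 8, 10))
        eig = res.eigenvalues.to_numpy()
        assert (np.diff(eig) <= 1e-12).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pcoa_pearson(_random_profile(6, 2, 5))


class TestGroupSeparation:
    def _setup(self, effect):
        rng = np.random.default_rng(9)
        n = 40
        groups = np.repeat(["A", "B"], n // 2)
        base = rng.gamma(2, 100, size=(n, 8))
        base[groups == "B", :4] *= effect
        prof = pd.DataFrame(base, index=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({"group": groups, "age_weeks": 4.0},
                            index=prof.index)
        return pcoa_pearson(prof), meta

    def test_strong_separation_significant(self):
        ordn, meta = self._setup(effect=30.0)
        p = group_separation_anova(ordn, meta, 4.0)
        assert p["PC1"] < 0.001

    def test_single_member_group_excluded(self):
        ordn, meta = self._setup(effect=1.0)
        meta.iloc[0, meta.columns.get_loc("group")] = "C"
        p = group_separation_anova(ordn, meta, 4.0)  # C silently excluded
        assert set(p) == {"PC1", "PC2", "pooled"}

    def test_shuffled_labels_give_uniform_p(self):
        ordn, meta = self._setup(effect=1.0)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(100):
            m = meta.copy()
            m["group"] = rng.permutation(m["group"].to_numpy())
            pvals.append(group_separation_anova(ordn, m, 4.0)["PC1"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_group_medians_match_brute_force(small_sim):
    from qmpipe.profiling import absolute_profile

    prof = absolute_profile(small_sim.counts, small_sim.qpcr,
                            small_sim.copy_numbers, small_sim.taxonomy)
    ordn = pcoa_pearson(prof.cells)
    med = group_median_trajectories(ordn, small_sim.metadata)
    g, tp = med.index[0]
    meta = small_sim.metadata
    members = meta[(meta["group"] == g) & (meta["age_weeks"] == tp)].index
    expect = ordn.coordinates.loc[members, "PC1"].median()
    assert med.loc[(g, tp), "PC1"] == pytest.approx(expect)


class TestTrajectories:
    def _meta(self, ages):
        return pd.DataFrame({"age_weeks": ages},
                            index=[f"s{i}" for i in range(len(ages))])

    def test_constant_abundance_gives_flat_curve(self):
        ages = np.linspace(4, 39, 30)
        prof = pd.DataFrame({"Tax": np.full(30, 999.0)},
                            index=[f"s{i}" for i in range(30)])
        curves = smooth_class_trajectories(prof, self._meta(ages), ["Tax"])
        c = curves[0]
        np.testing.assert_allclose(c.mean, np.log10(1000.0), atol=1e-9)

    def test_linear_log_trend_recovered_within_band(self):
        rng = np.random.default_rng(3)
        ages = np.linspace(4, 39, 80)
        true = 10 ** (3 + 0.05 * ages)
        prof = pd.DataFrame(
            {"Tax": true * np.exp(rng.normal(0, 0.1, 80))},
            index=[f"s{i}" for i in range(80)])
        curves = smooth_class_trajectories(prof, self._meta(ages), ["Tax"],
                                           level=0.95)
        c = curves[0]
        truth_on_grid = 3 + 0.05 * c.age_weeks
        inside = (c.lower <= truth_on_grid) & (truth_on_grid <= c.upper)
        assert inside.mean() > 0.9

    def test_narrower_band_at_lower_level(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(4, 39, 60)
        prof = pd.DataFrame({"Tax": rng.gamma(3, 50, 60)},
                            index=[f"s{i}" for i in range(60)])
        meta = self._meta(ages)
        c30 = smooth_class_trajectories(prof, meta, ["Tax"], level=0.30)[0]
        c95 = smooth_class_trajectories(prof, meta, ["Tax"], level=0.95)[0]
        w30 = c30.upper - c30.lower
        w95 = c95.upper - c95.lower
        assert (w30 < w95).all()

    def test_missing_taxon_skipped(self):
        ages = np.linspace(4, 39, 10)
        prof = pd.DataFrame({"Tax": np.arange(10.0)},
                            index=[f"s{i}" for i in range(10)])
        curves = smooth_class_trajectories(prof, self._meta(ages),
                                           ["Tax", "Ghost"])
        assert [c.taxon for c in curves] == ["Tax"]

    def test_band_contains_mean_curve(self):
        ages = np.linspace(4, 39, 40)
        rng = np.random.default_rng(1)
        prof = pd.DataFrame({"Tax": rng.gamma(2, 30, 40)},
                            index=[f"s{i}" for i in range(40)])
        c = smooth_class_trajectories(prof, self._meta(ages), ["Tax"])[0]
        ok = ~np.isnan(c.mean)
        assert (c.lower[ok] <= c.mean[ok]).all()
        assert (c.mean[ok] <= c.upper[ok]).all()
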