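"""Moderated DE, stratified/adjusted contrasts, variance partition, overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latentmix import downstream as ds
from latentmix.containers import ExpressionMatrix


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])]), "log2norm")


def _two_group_design(n):
    grp = np.repeat([0.0, 1.0], n // 2)
    return pd.DataFrame({"intercept": 1.0, "diagnosis": grp},
                        index=[f"s{j}" for j in range(n)]), grp


class TestModeratedDeg:
    def test_d0_zero_equals_ordinary_t(self, rng):
        y = rng.normal(size=(50, 12))
        design, grp = _two_group_design(12)
        out = ds.moderated_deg(_em(y), design, "diagnosis", d0_override=0)
        ref = stats.ttest_ind(y[:, grp == 1], y[:, grp == 0], axis=1)
        np.testing.assert_allclose(out["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(out["p"], ref.pvalue, atol=1e-10)

    def test_d0_infinite_equals_pooled_variance_t(self, rng):
        y = rng.normal(size=(50, 12))
        design, grp = _two_group_design(12)
        out = ds.moderated_deg(_em(y), design, "diagnosis",
                               d0_override=np.inf)
        resid = y - np.stack([y[:, grp == 0].mean(axis=1),
                              y[:, grp == 1].mean(axis=1)], axis=1)[
            :, grp.astype(int)]
        pooled = (resid ** 2).sum(axis=1).mean() / 10
        expect = (y[:, grp == 1].mean(axis=1) - y[:, grp == 0].mean(axis=1)
                  ) / np.sqrt(pooled * (2 / 6))
        np.testing.assert_allclose(out["t"], expect, atol=1e-10)

    def test_homoscedastic_genes_shrink_to_pooled(self, rng):
        """Equal true variances: fitted d0 is large, t ~ pooled t."""
        y = rng.normal(size=(2000, 12))
        design, _ = _two_group_design(12)
        fitted = ds.moderated_deg(_em(y), design, "diagnosis")
        pooled = ds.moderated_deg(_em(y), design, "diagnosis",
                                  d0_override=np.inf)
        assert fitted.attrs["d0"] > 50
        r = np.corrcoef(fitted["t"], pooled["t"])[0, 1]
        assert r > 0.99

    def test_log2fc_is_group_mean_difference(self, rng):
        y = rng.normal(size=(5, 20))
        y[0, 10:] += 1.5
        design, grp = _two_group_design(20)
        out = ds.moderated_deg(_em(y), design, "diagnosis")
        diff = y[0, grp == 1].mean() - y[0, grp == 0].mean()
        assert out["log2fc"].iloc[0] == pytest.approx(diff)

    def test_insufficient_residual_df(self, rng):
        design, _ = _two_group_design(2)
        with pytest.raises(ValueError, match="degrees of freedom"):
            ds.moderated_deg(_em(rng.normal(size=(5, 2))), design,
                             "diagnosis")


class TestStratifiedCompare:
    def test_missing_diagnosis_stratum_skipped(self, rng):
        y = rng.normal(size=(30, 24))
        em = _em(y)
        diagnosis = pd.Series(["AD"] * 8 + ["normal"] * 8 + ["AD"] * 8,
                              index=em.sample_ids)
        subgroups = pd.Series([1] * 16 + [2] * 8, index=em.sample_ids)
        with pytest.warns(UserWarning, match="skipped"):
            res = ds.stratified_deg_compare(em, diagnosis, subgroups,
                                            merge={})
        assert 2 not in res["per_stratum"]
        assert "joint" in res and len(res["joint"]) == 30

    def test_merge_rule_pools_clusters(self, rng):
        y = rng.normal(size=(20, 24))
        em = _em(y)
        diagnosis = pd.Series((["AD"] * 4 + ["normal"] * 4) * 3,
                              index=em.sample_ids)
        subgroups = pd.Series([1] * 8 + [3] * 8 + [2] * 8,
                              index=em.sample_ids)
        res = ds.stratified_deg_compare(em, diagnosis, subgroups)
        assert set(res["per_stratum"]) == {1, 2}

    def test_venn_counts_consistent(self, rng):
        y = rng.normal(size=(100, 24))
        y[:10, (np.arange(24) % 2 == 0)] += 2.0   # global effects
        em = _em(y)
        diagnosis = pd.Series(np.where(np.arange(24) % 2 == 0, "AD",
                                       "normal"), index=em.sample_ids)
        subgroups = pd.Series([1] * 12 + [2] * 12, index=em.sample_ids)
        res = ds.stratified_deg_compare(em, diagnosis, subgroups, merge={})
        v = res["venn"]
        assert v["joint"] == v["joint_only"] + v["both"]
        assert v["stratified_union"] == v["stratified_only"] + v["both"]


class TestCovariateAdjusted:
    def test_constant_score_reduces_to_joint(self, rng):
        y = rng.normal(size=(50, 20))
        em = _em(y)
        diagnosis = pd.Series(["AD"] * 10 + ["normal"] * 10,
                              index=em.sample_ids)
        scores = pd.Series(0.5, index=em.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            adj = ds.covariate_adjusted_deg(em, diagnosis, scores)
        joint = ds.moderated_deg(em, ds.make_design(diagnosis), "diagnosis")
        np.testing.assert_allclose(adj["q"], joint["q"], atol=1e-12)

    def test_noise_score_similar_deg_count(self, rng):
        y = rng.normal(size=(500, 40))
        y[:40, 20:] += 1.0
        em = _em(y)
        diagnosis = pd.Series(["normal"] * 20 + ["AD"] * 20,
                              index=em.sample_ids)
        joint = ds.moderated_deg(em, ds.make_design(diagnosis), "diagnosis")
        noise = pd.Series(rng.normal(size=40), index=em.sample_ids)
        adj = ds.covariate_adjusted_deg(em, diagnosis, noise)
        assert abs(int(adj["deg"].sum()) - int(joint["deg"].sum())) <= 10


class TestVariancePartition:
    def test_pure_batch_gene(self, rng):
        n = 60
        batch = pd.Series(np.repeat(["a", "b", "c"], n // 3),
                          index=[f"s{j}" for j in range(n)])
        offsets = batch.map({"a": 0.0, "b": 3.0, "c": -3.0}).to_numpy()
        y = offsets[None, :] + rng.normal(0, 0.05, (3, n))
        em = _em(y)
        latent = pd.Series(rng.choice([1, 2], n), index=em.sample_ids)
        frac = ds.variance_partition(em, batch.to_frame("batch"), latent,
                                     top_n_hvg=3)
        assert (frac["batch"] > 0.95).all()

    def test_orthogonal_recovery_50_30_20(self, rng):
        n, g = 500, 100
        f1 = rng.permutation(np.tile([1.0, -1.0], n // 2))
        f2 = rng.permutation(np.tile([1.0, -1.0], n // 2))
        f3 = rng.permutation(np.tile([1.0, -1.0], n // 2))
        y = [np.sqrt(.5) * f1 + np.sqrt(.3) * f2 + np.sqrt(.2) * f3
             + rng.normal(0, 0.05, n) for _ in range(g)]
        em = _em(y)
        ft = pd.DataFrame({"f2": f2, "f3": f3}, index=em.sample_ids)
        frac = ds.variance_partition(em, ft,
                                     pd.Series(f1, index=em.sample_ids),
                                     top_n_hvg=g)
        means = frac.mean(axis=0)
        assert means["latent_factor"] == pytest.approx(0.5, abs=0.05)
        assert means["f2"] == pytest.approx(0.3, abs=0.05)
        assert means["f3"] == pytest.approx(0.2, abs=0.05)

    def test_fractions_sum_to_one(self, rng):
        y = rng.normal(size=(20, 30))
        em = _em(y)
        ft = pd.DataFrame({"z": rng.normal(size=30)}, index=em.sample_ids)
        latent = pd.Series(rng.choice([1, 2, 3], 30), index=em.sample_ids)
        frac = ds.variance_partition(em, ft, latent, top_n_hvg=20)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-8)
        assert (frac.to_numpy() >= -1e-12).all()

    def test_aliased_factors_rejected(self, rng):
        n = 20
        z = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        ft = pd.DataFrame({"z": z, "z2": 2 * z})
        em = _em(rng.normal(size=(5, n)))
        latent = pd.Series(rng.choice([1, 2], n), index=em.sample_ids)
        with pytest.raises(ValueError, match="aliased"):
            ds.variance_partition(em, ft, latent, top_n_hvg=5)


class TestHypergeomOverlap:
    def test_worked_example(self):
        res = ds.hypergeom_overlap([f"a{i}" for i in range(5)],
                                   [f"a{i}" for i in range(4)], 10)
        assert res["overlap"] == 4
        # overlap can only be 4: p = C(5,4) C(5,0) / C(10,4) = 5/210
        assert res["p"] == pytest.approx(5 / 210, abs=1e-15)

    def test_disjoint_sets_p_one(self):
        res = ds.hypergeom_overlap(["a", "b"], ["c", "d"], 10)
        assert res["overlap"] == 0
        assert res["p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        """Exact equality with subset enumeration for universes <= 12."""
        universe = list(range(10))
        set_a = [0, 1, 2, 3]
        for size_b in (2, 4, 6):
            set_b = list(rng.choice(universe, size_b, replace=False))
            obs = len(set(set_a) & set(set_b))
            count = sum(
                1 for combo in itertools.combinations(universe, size_b)
                if len(set(combo) & set(set_a)) >= obs)
            expected = count / math.comb(10, size_b)
            got = ds.hypergeom_overlap(set_a, set_b, 10)["p"]
            assert got == pytest.approx(expected, abs=1e-15)

    def test_matches_scipy_tail(self):
        res = ds.hypergeom_overlap(list(range(40)), list(range(30, 80)), 200)
        ref = stats.hypergeom.sf(res["overlap"] - 1, 200, 40, 50)
        assert res["p"] == pytest.approx(ref, rel=1e-9)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ds.hypergeom_overlap(list(range(11)), [1], 10)


class TestModuleCoexpression:
    def test_perfectly_correlated_module(self, rng):
        base = rng.normal(size=40)
        y = np.vstack([2 * base + 1, -3 * base, base] +
                      [rng.normal(size=40) for _ in range(10)])
        em = _em(y)
        labels = pd.Series([1] * 20 + [2] * 20, index=em.sample_ids)
        res = ds.module_coexpression_cdf(em, ["g0", "g1", "g2"], labels,
                                         n_random=5, seed=0)
        for key in ("all", "subgroup1", "subgroup2"):
            np.testing.assert_allclose(res["values"][key], 1.0, atol=1e-10)

    def test_stratum_specific_coregulation(self, rng):
        """Module co-regulated only in subgroup 1 shows higher |r| there."""
        n1, n2 = 30, 30
        shared = rng.normal(size=n1)
        module = []
        for _ in range(5):
            in_sg1 = shared * 2 + rng.normal(0, 0.3, n1)
            in_sg2 = rng.normal(size=n2)
            module.append(np.r_[in_sg1, in_sg2])
        y = np.vstack(module + [rng.normal(size=n1 + n2) for _ in range(20)])
        em = _em(y)
        labels = pd.Series([1] * n1 + [2] * n2, index=em.sample_ids)
        res = ds.module_coexpression_cdf(em, [f"g{i}" for i in range(5)],
                                         labels, n_random=20, seed=1)
        m = res["mean_abs_r"]
        assert m["subgroup1"] > m["subgroup2"]
        assert m["subgroup1"] > m["random"]

    def test_no_random_control_warns(self, rng):
        em = _em(rng.normal(size=(5, 20)))
        labels = pd.Series([1] * 10 + [2] * 10, index=em.sample_ids)
        with pytest.warns(UserWarning, match="control omitted"):
            res = ds.module_coexpression_cdf(em, ["g0", "g1", "g2"], labels,
                                             n_random=0, seed=0)
        assert np.isnan(res["mean_abs_r"]["random"])

    def test_absent_genes_dropped_then_error(self, rng):
        em = _em(rng.normal(size=(4, 12)))
        labels = pd.Series([1] * 6 + [2] * 6, index=em.sample_ids)
        with pytest.warns(UserWarning, match="absent"):
            with pytest.raises(ValueError, match="fewer than 3"):
                ds.module_coexpression_cdf(em, ["g0", "g1", "zz"], labels,
                                           n_random=0, seed=0)


class TestPairedTissueMarkers:
    def test_wm_and_gm_calls(self):
        fc = pd.DataFrame(
            [[2.5, 2.1, 3.0, 1.1],     # WM: 3 groups >= 2
             [0.4, 0.45, 0.3, 0.9],    # GM: 3 groups <= 0.5
             [1.0, 1.0, 1.0, 1.0]],    # neither
            index=["wm_feat", "gm_feat", "flat"],
            columns=["grp1", "grp2", "grp3", "grp4"])
        res = ds.paired_tissue_markers(fc)
        assert res["wm_markers"] == ["wm_feat"]
        assert res["gm_markers"] == ["gm_feat"]

    def test_too_few_groups_rejected(self):
        fc = pd.DataFrame([[2.0, 2.0]], index=["f"], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            ds.paired_tissue_markers(fc)
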