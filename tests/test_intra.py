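"""Voxelwise GLM and permutation cluster inference on subject map stacks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netlag.intra import (
    DesignMatrix,
    build_group_design,
    cluster_inference,
    corsi_correlation_analysis,
    f_group_contrast,
    fit_voxelwise_glm,
    t_contrast,
)


def two_group_design(n1, n2):
    X = np.zeros((n1 + n2, 2))
    X[:n1, 0] = 1.0
    X[n1:, 1] = 1.0
    return DesignMatrix(X, ["group_A", "group_B"], ["group_A", "group_B"])


class TestGLM:
    def test_two_sample_t_identity(self, rng):
        n1, n2, V = 10, 8, 50
        Y = rng.standard_normal((n1 + n2, V))
        design = two_group_design(n1, n2)
        fit = fit_voxelwise_glm(Y, design)
        t = t_contrast(fit, np.array([1.0, -1.0]))
        ref = stats.ttest_ind(Y[:n1], Y[n1:], axis=0).statistic
        np.testing.assert_allclose(t, ref, atol=1e-10)

    def test_orthogonal_covariate_leaves_contrast(self, rng):
        n1 = n2 = 10
        Y = rng.standard_normal((20, 30))
        design = two_group_design(n1, n2)
        fit0 = fit_voxelwise_glm(Y, design)
        t0 = t_contrast(fit0, np.array([1.0, -1.0]))
        # covariate exactly orthogonal to the group indicators
        cov = np.tile([1.0, -1.0], 10)
        X2 = np.column_stack([design.X, cov])
        d2 = DesignMatrix(X2, ["group_A", "group_B", "cov"], design.interest)
        # the group-contrast point estimate is unchanged by the orthogonal column
        b0 = np.array([1.0, -1.0]) @ fit0.beta
        b2 = np.array([1.0, -1.0, 0.0]) @ fit_voxelwise_glm(Y, d2).beta
        np.testing.assert_allclose(b0, b2, atol=1e-8)

    def test_rank_deficient_raises_with_columns(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X, ["a", "b"], ["a"])

    def test_f_matches_direct_ancova(self, rng):
        """Voxelwise F equals the textbook one-way ANCOVA F on single voxels."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        n = (12, 8, 6)
        groups = np.repeat(["HC", "HET", "HOM"], n)
        part = pd.DataFrame({
            "group": groups,
            "gm_volume": rng.normal(600, 50, sum(n)),
            "education": rng.normal(12, 3, sum(n)),
        })
        design = build_group_design(part)
        Y = rng.standard_normal((sum(n), 20))
        F, q, dof = f_group_contrast(Y, design)
        assert q == 2
        for v in rng.choice(20, size=5, replace=False):
            df = part.assign(y=Y[:, v])
            fit = smf.ols("y ~ C(group) + gm_volume + education", df).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            assert F[v] == pytest.approx(float(tab.loc["C(group)", "F"]), rel=1e-8)

    def test_injected_deficit_peaks_in_blob(self):
        """HOM<HC amplitude deficit puts the peak |t| inside the injected blob."""
        from netlag.cohort import CohortConfig, simulate_cohort

        cfg = CohortConfig(
            group_sizes={"HC": 10, "HET": 4, "HOM": 8}, grid_dims=(12, 14, 12),
            T=48, blob_sigma_mm=3.5, noise_sd=0.3, seed=21,
        )
        coh = simulate_cohort(cfg)
        truth = coh.truth
        name = "ExN"
        j = truth.network_maps.names.index(name)
        blob = truth.network_maps.blob_maps[name][0]
        # subject "maps" = regression of each subject's data on its courses
        V = coh.runs[0].data.reshape(-1, 48)
        maps = []
        for i, sid in enumerate(coh.participants["participant_id"]):
            tc = coh.courses[sid]
            X = np.column_stack([tc, np.ones(48)])
            beta = np.linalg.lstsq(X, coh.runs[i].data.reshape(-1, 48).T, rcond=None)[0]
            maps.append(beta[j])
        maps = np.stack(maps)
        design = build_group_design(coh.participants)
        fit = fit_voxelwise_glm(maps, design)
        c = np.zeros(5)
        c[design.column("group_HC")], c[design.column("group_HOM")] = 1, -1
        t = t_contrast(fit, c)
        peak = np.unravel_index(np.argmax(t), blob.shape)
        assert blob[peak] > 0.5  # inside the deficit blob


class TestClusterInference:
    @staticmethod
    def _design(n=(10, 6, 6)):
        groups = np.repeat(["HC", "HET", "HOM"], n)
        part = pd.DataFrame({
            "group": groups,
            "gm_volume": np.random.default_rng(0).normal(600, 50, sum(n)),
            "education": np.random.default_rng(1).normal(12, 3, sum(n)),
        })
        return build_group_design(part), sum(n)

    def test_all_zero_map_empty_result(self):
        design, n = self._design()
        rng = np.random.default_rng(2)
        maps = np.zeros((n, 6 * 6 * 6)) + rng.standard_normal((n, 1)) * 1e-12
        # constant-ish maps: no voxel passes the forming threshold
        res = cluster_inference(
            maps, np.ones((6, 6, 6), bool), design, contrast="group",
            n_permutations=100, seed=0,
        )
        assert res == []

    def test_clusters_partition_suprathreshold(self, rng):
        design, n = self._design()
        maps = rng.standard_normal((n, 5 * 5 * 5))
        res = cluster_inference(
            maps, np.ones((5, 5, 5), bool), design, contrast="HC_gt_HOM",
            cluster_forming_p=0.2, n_permutations=100, seed=3,
        )
        total = sum(c.size_voxels for c in res)
        from netlag.intra import f_group_contrast  # recompute threshold side

        fit = fit_voxelwise_glm(maps, design)
        c = np.zeros(5)
        c[design.column("group_HC")], c[design.column("group_HOM")] = 1, -1
        t = t_contrast(fit, c)
        thr = stats.t.isf(0.1, fit.dof)
        assert total == int((np.abs(t) > thr).sum())

    def test_strong_effect_detected(self):
        """d=1.5 over a 50-voxel blob, n=22 vs 8: detected at corrected p<0.05."""
        rng = np.random.default_rng(5)
        shape = (8, 8, 8)
        V = int(np.prod(shape))
        blob = np.zeros(shape, bool)
        blob[2:6, 2:6, 2:5] = True  # 48 voxels
        hits = 0
        n_sims = 20
        for s in range(n_sims):
            rng_s = np.random.default_rng(100 + s)
            n1, n2 = 22, 8
            Y = rng_s.standard_normal((n1 + n2, V))
            Y[n1:, blob.ravel()] += 1.5
            part = pd.DataFrame({
                "group": np.repeat(["HC", "HOM"], (n1, n2)),
                "gm_volume": rng_s.normal(600, 50, n1 + n2),
                "education": rng_s.normal(12, 3, n1 + n2),
            })
            design = build_group_design(part, groups=("HC", "HOM"))
            res = cluster_inference(
                Y, np.ones(shape, bool), design, contrast="HC_gt_HOM",
                n_permutations=200, seed=s,
            )
            hits += int(any(c.corrected_p < 0.05 for c in res))
        assert hits >= int(0.9 * n_sims)

    def test_corrected_p_monotone_in_size(self, rng):
        design, n = self._design()
        maps = rng.standard_normal((n, 7 * 7 * 7)) * 2
        res = cluster_inference(
            maps, np.ones((7, 7, 7), bool), design, contrast="group",
            cluster_forming_p=0.1, n_permutations=150, seed=1,
        )
        if len(res) >= 2:
            sizes = [c.size_voxels for c in res]
            ps = [c.corrected_p for c in res]
            order = np.argsort(sizes)[::-1]
            assert all(ps[order[i]] <= ps[order[i + 1]] + 1e-12
                       for i in range(len(order) - 1))


class TestCorsiAnalysis:
    def test_constructed_corsi_effect_recovered(self):
        """Corsi proportional to injected amplitude yields a positive cluster."""
        rng = np.random.default_rng(8)
        shape = (7, 7, 7)
        V = int(np.prod(shape))
        blob = np.zeros(shape, bool)
        blob[2:5, 2:5, 2:5] = True
        n_het, n_hom = 10, 10
        n = n_het + n_hom
        corsi = np.r_[rng.normal(4.6, 0.5, n_het), rng.normal(3.9, 0.4, n_hom)]
        Y = rng.standard_normal((n, V)) * 0.5
        # HOM intra-network amplitude scales with the subject's Corsi span
        Y[n_het:, blob.ravel()] += 2.0 * (corsi[n_het:] - corsi[n_het:].mean())[:, None]
        part = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n)],
            "group": np.repeat(["HET", "HOM"], (n_het, n_hom)),
            "gene": rng.choice(["PINK1", "Park2"], n),
            "gm_volume": rng.normal(600, 50, n),
            "corsi": corsi,
        })
        res = corsi_correlation_analysis(
            Y, part, mask=np.ones(shape, bool), n_permutations=200, seed=2
        )
        assert any(c.corrected_p < 0.05 for c in res["HOM"])
        peak = max(res["HOM"], key=lambda c: c.size_voxels).peak_voxel
        assert blob[peak]

    def test_missing_corsi_excluded(self, rng):
        n = 12
        part = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n)],
            "group": np.repeat(["HET", "HOM"], 6),
            "gene": ["PINK1", "Park2"] * 6,
            "gm_volume": rng.normal(600, 50, n),
            "corsi": [np.nan, 4.2, 4.5, 4.8, 4.1, 4.9, 3.6, 3.9, 4.0, 3.7, 4.1, 3.8],
        })
        Y = rng.standard_normal((n, 30))
        with pytest.warns(UserWarning, match="missing Corsi"):
            corsi_correlation_analysis(Y, part, n_permutations=100, seed=0)

    def test_small_group_skipped(self, rng):
        n = 9
        part = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n)],
            "group": ["HET"] * 3 + ["HOM"] * 6,
            "gene": ["PINK1"] * n,
            "gm_volume": rng.normal(600, 50, n),
            "corsi": rng.normal(4.0, 0.5, n),
        })
        Y = rng.standard_normal((n, 20))
        with pytest.warns(UserWarning, match="skipped"):
            res = corsi_correlation_analysis(Y, part, n_permutations=100, seed=0)
        assert "HET" not in res
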