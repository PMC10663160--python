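"""Meta-analysis pooling, curve clustering, mega-vs-meta concordance."""

import numpy as np
import pandas as pd
import pytest

from sleepbrain import meta as meta_mod
from sleepbrain import synthetic as syn
from sleepbrain.crosssectional import PeakEstimate


def _pk(region, h, se, boundary=False):
    return PeakEstimate(region=region, h_max=h, se=se,
                        ci=(h - 1.96 * se, h + 1.96 * se),
                        boundary_flag=boundary)


class TestPoolPeaks:
    def test_homogeneous_input_degenerates(self, registry):
        peaks = [_pk("Hippocampus", 6.5, 0.3), _pk("Thalamus", 6.5, 0.3),
                 _pk("precuneus", 6.5, 0.3)]
        res = meta_mod.pool_peaks(peaks, registry)
        assert res.pooled_h == pytest.approx(6.5, abs=1e-12)
        assert res.tau2 == 0.0

    def test_matches_hand_computed_dersimonian_laird(self, registry):
        est = np.array([6.0, 6.5, 7.0])
        ses = np.array([0.2, 0.2, 0.2])
        w = 1 / ses ** 2
        mu_fe = np.sum(w * est) / np.sum(w)
        q = np.sum(w * (est - mu_fe) ** 2)
        tau2 = max(0.0, (q - 2) / (np.sum(w) - np.sum(w ** 2) / np.sum(w)))
        wr = 1 / (ses ** 2 + tau2)
        pooled = np.sum(wr * est) / np.sum(wr)
        se = np.sqrt(1 / np.sum(wr))
        peaks = [_pk("Hippocampus", 6.0, 0.2), _pk("Thalamus", 6.5, 0.2),
                 _pk("Caudate", 7.0, 0.2)]
        res = meta_mod.pool_peaks(peaks, registry, equal_blocks=False)
        assert res.pooled_h == pytest.approx(pooled, abs=1e-6)
        assert res.tau2 == pytest.approx(tau2, abs=1e-6)
        assert res.se == pytest.approx(se, abs=1e-6)

    def test_exclusion_rules_applied(self, registry):
        peaks = [_pk("Hippocampus", 6.4, 0.2), _pk("Thalamus", 6.6, 0.2),
                 _pk("TGV", 6.5, 0.2), _pk("CC anterior", 9.9, 0.2),
                 _pk("Caudate", 6.5, 0.2, boundary=True)]
        res = meta_mod.pool_peaks(peaks, registry)
        assert set(res.included) == {"Hippocampus", "Thalamus"}
        assert "TGV" in res.excluded and "CC anterior" in res.excluded
        assert "Caudate" in res.excluded

    def test_equal_block_weighting(self, registry):
        peaks = [_pk("Hippocampus", 6.3, 0.1), _pk("Thalamus", 6.4, 0.2),
                 _pk("precuneus", 6.8, 0.5), _pk("cuneus", 6.9, 0.4),
                 _pk("insula", 7.0, 0.3)]
        res = meta_mod.pool_peaks(peaks, registry)
        w_sub = sum(res.weights[r] for r in ("Hippocampus", "Thalamus"))
        w_cor = sum(res.weights[r] for r in ("precuneus", "cuneus", "insula"))
        assert abs(w_sub - w_cor) < 1e-10

    def test_tau2_zero_equals_fixed_effect(self, registry):
        peaks = [_pk("Hippocampus", 6.2, 0.1), _pk("Thalamus", 6.8, 0.4)]
        res = meta_mod.pool_peaks(peaks, registry, tau2=0.0,
                                  equal_blocks=False)
        w = np.array([1 / 0.1 ** 2, 1 / 0.4 ** 2])
        assert res.pooled_h == pytest.approx(
            np.sum(w * [6.2, 6.8]) / w.sum(), abs=1e-12)

    def test_pooled_within_range_of_inputs(self, registry):
        peaks = [_pk("Hippocampus", 5.9, 0.3), _pk("Thalamus", 7.2, 0.2),
                 _pk("precuneus", 6.1, 0.25)]
        res = meta_mod.pool_peaks(peaks, registry)
        assert 5.9 <= res.pooled_h <= 7.2

    def test_too_few_regions_rejected(self, registry):
        with pytest.raises(ValueError):
            meta_mod.pool_peaks([_pk("Hippocampus", 6.5, 0.2)], registry)


class TestKmeansCurves:
    @pytest.fixture()
    def curve_grid(self):
        return np.arange(4.0, 10.01, 0.1)

    def _family(self, grid, peak, n, rng, scale=1.0):
        rows = {}
        for i in range(n):
            c = -(grid - peak - rng.normal(0, 0.05)) ** 2 * scale + 10.0
            rows[f"r{peak}_{i}"] = c
        return pd.DataFrame(rows).T

    def test_k1_centroid_is_mean_curve(self, curve_grid):
        rng = np.random.default_rng(0)
        curves = self._family(curve_grid, 6.5, 5, rng)
        norm = 100 * curves / curves.max(axis=1).to_numpy()[:, None]
        res = meta_mod.kmeans_curves(curves, k=1, seed=0)
        assert np.allclose(res.centroids[0], norm.mean(axis=0), atol=1e-8)

    def test_planted_families_recovered(self, curve_grid):
        rng = np.random.default_rng(1)
        fams = [self._family(curve_grid, p, 6, rng) for p in (5.5, 6.5, 7.5)]
        curves = pd.concat(fams)
        res = meta_mod.kmeans_curves(curves, k=3, seed=0)
        labels = pd.Series(res.assignments)
        for p in (5.5, 6.5, 7.5):
            fam_labels = labels[[i for i in labels.index
                                 if i.startswith(f"r{p}_")]]
            assert fam_labels.nunique() == 1

    def test_normalized_curves_peak_at_100(self, curve_grid):
        rng = np.random.default_rng(2)
        curves = self._family(curve_grid, 6.5, 4, rng)
        M = 100 * curves.to_numpy() / curves.to_numpy().max(axis=1,
                                                            keepdims=True)
        assert np.allclose(M.max(axis=1), 100.0)

    def test_k_larger_than_regions_rejected(self, curve_grid):
        rng = np.random.default_rng(3)
        curves = self._family(curve_grid, 6.5, 2, rng)
        with pytest.raises(ValueError):
            meta_mod.kmeans_curves(curves, k=5)

    def test_labels_ordered_by_cluster_size(self, curve_grid):
        rng = np.random.default_rng(4)
        big = self._family(curve_grid, 6.5, 8, rng)
        small = self._family(curve_grid, 8.5, 3, rng)
        res = meta_mod.kmeans_curves(pd.concat([big, small]), k=2, seed=0)
        labels = pd.Series(res.assignments)
        sizes = labels.value_counts()
        assert sizes[0] >= sizes[1]


class TestMegaVsMeta:
    def test_single_cohort_identical(self, cross_study, registry):
        res = meta_mod.mega_vs_meta(cross_study, "Hippocampus", registry,
                                    min_cohort_n=100, n_draws=300, seed=1)
        assert res["abs_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_site_offsets_leave_peak_concordant(self, registry):
        # additive cohort offsets shift curves, not their argmax
        cfg = [syn.CohortConfig("A", n_cross=800, age_range=(40, 70),
                                site_offset=0.0),
               syn.CohortConfig("B", n_cross=800, age_range=(40, 70),
                                site_offset=1.5)]
        m = syn.TrueModel(sigma_resid=0.7, sigma_intercept=0.2)
        df = syn.generate_cohorts(cfg, m, seed=13, registry=registry,
                                  regions=["Hippocampus"])
        res = meta_mod.mega_vs_meta(df, "Hippocampus", registry,
                                    min_cohort_n=100, n_draws=400, seed=2)
        assert res["abs_diff"] < 0.3

    def test_small_cohort_excluded_with_log(self, cross_study, registry):
        df = cross_study.copy()
        tiny = df.iloc[:10].copy()
        tiny["cohort"] = "tiny"
        tiny["participant"] = [f"tiny-{i}" for i in range(10)]
        both = pd.concat([df, tiny], ignore_index=True)
        res = meta_mod.mega_vs_meta(both, "Hippocampus", registry,
                                    min_cohort_n=100, n_draws=200, seed=1)
        assert "tiny" in res["skipped_cohorts"]


class TestTau2Reml:
    def test_homogeneous_gives_zero(self):
        t2 = meta_mod.tau2_reml(np.array([6.5, 6.5, 6.5]),
                                np.array([0.2, 0.2, 0.2]))
        assert t2 == pytest.approx(0.0, abs=1e-10)

    def test_reml_close_to_dl_for_balanced_input(self):
        est = np.array([6.0, 6.5, 7.0, 6.2, 6.8])
        ses = np.full(5, 0.2)
        dl, _ = meta_mod.dersimonian_laird(est, ses)
        reml = meta_mod.tau2_reml(est, ses)
        # with equal SEs the estimators agree closely
        assert reml == pytest.approx(dl, rel=0.3, abs=0.02)
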