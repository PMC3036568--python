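"""Phenotyping: overlap statistics, clustering, profiles, image fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from iplconnect import (
    alpha_blend,
    bivariate_cluster_plot,
    classify_density_profile,
    classify_signatures,
    generate_bipolar_cohort,
    generate_profiles,
    generate_rasters,
    misclassification_probability,
    overlay_fuse,
)
from iplconnect.phenotype import DensityProfile, SignatureClassStats


class TestMisclassification:
    def test_printed_glycine_bounds(self):
        """Coupled ON (63+/-13) vs OFF (15+/-7) glycine distributions: both
        error directions stay under the published 0.015 / 0.02 bounds."""
        p_on_as_off, p_off_as_on = misclassification_probability(63, 13, 15, 7)
        assert p_on_as_off <= 0.015
        assert p_off_as_on <= 0.02

    def test_unit_separation_threshold(self):
        # (0,1) vs (4,1): threshold at 2, both tails are the standard-normal
        # tail beyond z=2
        p1, p2 = misclassification_probability(0, 1, 4, 1)
        assert p1 == pytest.approx(norm.sf(2))
        assert p2 == pytest.approx(norm.sf(2))

    def test_equal_means_error(self):
        with pytest.raises(ValueError):
            misclassification_probability(5, 1, 5, 2)
        with pytest.raises(ValueError):
            misclassification_probability(5, 0, 6, 1)

    def test_symmetric_when_equal_sigmas(self):
        p1, p2 = misclassification_probability(10, 3, 20, 3)
        assert p1 == pytest.approx(p2)

    def test_decreasing_in_separation(self):
        ps = [misclassification_probability(0, 2, d, 3)[0] for d in (1, 2, 4, 8, 16)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("params", [(63, 13, 15, 7), (0, 1, 4, 1), (100, 20, 40, 10)])
    def test_monte_carlo_oracle(self, params):
        """Closed-form tails agree with direct simulation of the decision
        rule within 3 standard errors at 1e5 draws."""
        mu1, s1, mu2, s2 = params
        p1, p2 = misclassification_probability(mu1, s1, mu2, s2)
        t = (s2 * mu1 + s1 * mu2) / (s1 + s2)
        rng = np.random.default_rng(42)
        n = 100_000
        x1 = rng.normal(mu1, s1, n)
        x2 = rng.normal(mu2, s2, n)
        toward_2 = (x1 < t) if mu2 < mu1 else (x1 > t)
        toward_1 = (x2 > t) if mu2 < mu1 else (x2 < t)
        for p, hits in ((p1, toward_2), (p2, toward_1)):
            est = hits.mean()
            se = max(np.sqrt(est * (1 - est) / n), 1e-5)
            assert abs(est - p) <= 3 * se


class TestClassifySignatures:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            np.vstack([rng.normal(10, 1, (30, 2)), rng.normal(200, 1, (30, 2))]),
            columns=["glycine", "AGB"],
        )
        res = classify_signatures(X, k=2, seed=0)
        first, second = res.labels[:30], res.labels[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_k_one_single_class(self):
        X = pd.DataFrame({"glycine": [1.0, 2.0, 3.0]})
        res = classify_signatures(X, k=1)
        assert set(res.labels) == {0} and res.stats[0].n == 3

    def test_k_exceeds_n_error(self):
        X = pd.DataFrame({"glycine": [1.0, 2.0]})
        with pytest.raises(ValueError):
            classify_signatures(X, k=3)

    def test_deterministic_and_permutation_equivariant(self):
        X, _ = generate_bipolar_cohort(120, seed=5)
        r1 = classify_signatures(X, k=4, seed=9)
        r2 = classify_signatures(X, k=4, seed=9)
        assert (r1.labels == r2.labels).all()
        perm = np.random.default_rng(1).permutation(len(X))
        r3 = classify_signatures(X.iloc[perm].reset_index(drop=True), k=4, seed=9)
        # permuting cells permutes labels only (up to cluster renaming)
        pairs = set(zip(r1.labels[perm], r3.labels))
        assert len(pairs) == len(set(r1.labels))

    def test_recovery_bounded_by_gaussian_overlap(self):
        """Clusters recovered from the four bipolar glycine/AGB cohorts at
        n=500; accuracy at least 95%, consistent with the small pairwise
        Gaussian overlaps of the planted distributions."""
        from scipy.optimize import linear_sum_assignment

        X, labels = generate_bipolar_cohort(500, seed=17)
        res = classify_signatures(X, k=4, mode="isodata", seed=17)
        names = sorted(set(labels))
        ks = sorted(set(res.labels))
        C = np.zeros((len(names), len(ks)))
        for i, nm in enumerate(names):
            for j, kk in enumerate(ks):
                C[i, j] = np.sum((labels == nm) & (res.labels == kk))
        r, c = linear_sum_assignment(-C)
        assert C[r, c].sum() / len(X) >= 0.95

    def test_stats_record_invariants(self):
        with pytest.raises(ValueError):
            SignatureClassStats("x", {"glycine": 1.0}, {"glycine": -0.1}, 2)
        with pytest.raises(ValueError):
            SignatureClassStats("x", {}, {}, 0)


class TestBivariatePlot:
    def test_four_separated_centroids(self, tmp_path):
        X, labels = generate_bipolar_cohort(400, seed=2)
        out = tmp_path / "clusters.png"
        summary = bivariate_cluster_plot(X, labels, "glycine", "AGB", out)
        assert out.exists()
        assert len(summary) == 4
        cents = summary[["glycine_mean", "AGB_mean"]].to_numpy()
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.linalg.norm(cents[i] - cents[j]) > 10

    def test_rod_centroid_near_origin(self):
        X, labels = generate_bipolar_cohort(400, seed=2)
        summary = bivariate_cluster_plot(X, labels, "glycine", "AGB")
        rod = summary[summary.label == "ROD_BC"].iloc[0]
        assert rod["glycine_mean"] < 15 and rod["AGB_mean"] < 15

    def test_single_cell_zero_dispersion(self):
        X = pd.DataFrame({"glycine": [10.0], "AGB": [20.0]})
        summary = bivariate_cluster_plot(X, ["only"], "glycine", "AGB")
        assert summary.iloc[0]["glycine_sd"] == 0.0

    def test_missing_channel_error(self):
        X = pd.DataFrame({"glycine": [10.0]})
        with pytest.raises(KeyError):
            bivariate_cluster_plot(X, ["a"], "glycine", "AGB")


class TestDensityProfiles:
    def test_clean_heterocellular(self):
        (prof, _), = [p for p in generate_profiles(1, noise_sd=0.0, seed=0) if p[1] == "heterocellular"]
        cls = classify_density_profile(prof)
        assert cls.pairing == "heterocellular"
        assert cls.thicker_flank_nm >= 15.0
        assert cls.flank_b_nm > cls.flank_a_nm  # thicker on the amacrine side
        assert 10.0 <= cls.central_width_nm <= 16.0

    def test_clean_homocellular(self):
        (prof, _), = [p for p in generate_profiles(1, noise_sd=0.0, seed=0) if p[1] == "homocellular"]
        cls = classify_density_profile(prof)
        assert cls.pairing == "homocellular"

    def test_pure_noise_unknown(self):
        (prof, _), = [p for p in generate_profiles(1, noise_sd=0.05, seed=3) if p[1] == "unknown"]
        assert classify_density_profile(prof).pairing == "unknown"

    def test_noisy_profiles_classified(self):
        hits = 0
        profs = generate_profiles(5, noise_sd=0.03, seed=11)
        for prof, label in profs:
            got = classify_density_profile(prof).pairing
            hits += got == label
        assert hits >= 13  # 15 profiles, tolerate rare noise-driven misses

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            DensityProfile(np.linspace(0, 30, 10), np.zeros(10))  # too short
        with pytest.raises(ValueError):
            DensityProfile(np.array([0, 1, 3, 70.0]), np.zeros(4))  # nonuniform


class TestImageFusion:
    def test_gray_overlay_is_identity(self):
        tem, _, _ = generate_rasters(64, seed=0)
        gray = np.full((64, 64, 3), 128, dtype=np.uint8)
        fused = overlay_fuse(tem, gray)
        assert np.array_equal(fused, np.stack([tem] * 3, axis=2))

    def test_black_tem_stays_black(self):
        _, overlay, _ = generate_rasters(64, seed=0)
        fused = overlay_fuse(np.zeros((64, 64), dtype=np.uint8), overlay)
        assert fused.max() == 0

    def test_value_channel_is_tem_exactly(self):
        tem, overlay, _ = generate_rasters(128, seed=1)
        fused = overlay_fuse(tem, overlay)
        assert np.array_equal(fused.max(axis=2), tem)

    def test_planted_hue_recovered(self):
        from matplotlib.colors import rgb_to_hsv

        tem, overlay, truth = generate_rasters(128, seed=1)
        fused = overlay_fuse(tem, overlay)
        r0, r1, c0, c1 = truth["patch"]
        patch = fused[r0:r1, c0:c1].astype(float) / 255.0
        bright = patch.max(axis=2) > 0.1  # hue undefined on near-black pixels
        hues = rgb_to_hsv(patch)[..., 0][bright]
        assert np.allclose(hues, truth["hue"], atol=0.02)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            overlay_fuse(np.zeros((4, 4)), np.zeros((5, 5, 3)))


class TestAlphaBlend:
    def test_endpoints(self):
        base = np.full((4, 4, 3), 100, dtype=np.uint8)
        layer = np.full((4, 4, 3), 200, dtype=np.uint8)
        assert np.array_equal(alpha_blend(base, layer, 0.0), base)
        assert np.array_equal(alpha_blend(base, layer, 1.0), layer)

    def test_midpoint(self):
        base = np.full((4, 4, 3), 100, dtype=np.uint8)
        layer = np.full((4, 4, 3), 200, dtype=np.uint8)
        assert np.array_equal(alpha_blend(base, layer, 0.5), np.full((4, 4, 3), 150, dtype=np.uint8))

    def test_mask_alpha(self):
        base = np.zeros((2, 2, 3), dtype=np.uint8)
        layer = np.full((2, 2, 3), 200, dtype=np.uint8)
        mask = np.array([[0.0, 1.0], [0.5, 0.0]])
        out = alpha_blend(base, layer, mask)
        assert out[0, 1, 0] == 200 and out[1, 0, 0] == 100 and out[0, 0, 0] == 0

    def test_alpha_out_of_range(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            alpha_blend(img, img, 1.5)
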