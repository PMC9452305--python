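"""Spatial statistics: segregation index invariances and oracles, distance
shuffles, enrichment, density maps and bouton detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from viscmap.spatial import (
    bouton_neuron_segregation,
    density_map,
    detect_boutons,
    enrichment_index,
    pairwise_distance_shuffle_test,
    pooled_segregation_index,
    relative_positions,
    segregation_index,
)

from _si_oracle import si_bruteforce


def gaussian_clusters(rng, sep, spread=25.0, n=50, m=50):
    X = rng.normal([0.0, 0.0], spread, (n, 2))
    Y = rng.normal([sep, 0.0], spread, (m, 2))
    return X, Y


class TestSegregationIndex:
    def test_interleaved_1d_points_negative_by_enumeration(self):
        """X = {0, 2}, Y = {1, 3}: anti-clustered; the implementation's
        automatic exhaustive enumeration must match the literal formula
        evaluated over all 24 label permutations."""
        X = np.array([[0.0], [2.0]])
        Y = np.array([[1.0], [3.0]])
        r = segregation_index(X, Y)
        assert r.exhaustive and r.n_permutations == 24
        perms = list(itertools.permutations(range(4)))
        si_ref, num_ref, den_ref = si_bruteforce(X, Y, perms)
        assert np.isclose(r.si, si_ref, rtol=1e-12)
        assert r.si < 0
        assert np.isclose(r.numerator, -0.5)

    def test_distant_tight_clusters_strongly_segregated(self):
        rng = np.random.default_rng(0)
        X, Y = gaussian_clusters(rng, sep=1000.0, spread=10.0, n=20, m=20)
        r = segregation_index(X, Y, seed=0)
        assert r.si > 0.5

    def test_symmetric_in_groups(self):
        """SI(X, Y) == SI(Y, X) when the same label partitions are used:
        swapping groups reorders the concatenated point vector, so the
        permutation values are remapped and the group halves exchanged."""
        rng = np.random.default_rng(1)
        n, m = 15, 25
        X, Y = gaussian_clusters(rng, sep=40.0, n=n, m=m)
        perms = np.vstack(
            [np.random.default_rng(9).permutation(n + m) for _ in range(50)]
        )
        a = segregation_index(X, Y, permutations=perms)
        remapped = np.where(perms >= n, perms - n, perms + m)
        perms_swapped = np.column_stack([remapped[:, n:], remapped[:, :n]])
        b = segregation_index(Y, X, permutations=perms_swapped)
        assert np.isclose(a.numerator, b.numerator, rtol=1e-9)
        assert np.isclose(a.si, b.si, rtol=1e-9)

    def test_similarity_invariance(self):
        """Translation, rotation and uniform scaling leave SI unchanged."""
        rng = np.random.default_rng(2)
        X, Y = gaussian_clusters(rng, sep=60.0, n=12, m=14)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        perms = np.vstack([np.random.default_rng(3).permutation(26) for _ in range(40)])
        base = segregation_index(X, Y, permutations=perms).si
        moved = segregation_index(
            3.0 * X @ R.T + 100.0, 3.0 * Y @ R.T + 100.0, permutations=perms
        ).si
        assert np.isclose(base, moved, rtol=1e-9)

    def test_monotone_in_cluster_separation(self):
        rng = np.random.default_rng(0)
        base_X = rng.normal(0, 25.0, (50, 2))
        base_Y = rng.normal(0, 25.0, (50, 2))
        sis = []
        for sep in (0, 25, 50, 100, 200):
            r = segregation_index(base_X, base_Y + [sep, 0.0], seed=0)
            sis.append(r.si)
        assert all(a < b for a, b in zip(sis, sis[1:]))

    def test_groups_smaller_than_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            segregation_index(np.zeros((1, 2)), np.ones((5, 2)))

    def test_pooling_averages_numerators_before_dividing(self):
        rng = np.random.default_rng(4)
        pairs = [gaussian_clusters(rng, sep=60.0, n=10, m=10) for _ in range(3)]
        pooled = pooled_segregation_index(pairs, n_permutations=200, seed=1)
        nums, dens = [], []
        for k, (X, Y) in enumerate(pairs):
            r = segregation_index(X, Y, n_permutations=200, seed=1 + k)
            nums.append(r.numerator)
            dens.append(r.denominator)
        assert np.isclose(pooled.si, np.mean(nums) / np.mean(dens), rtol=1e-12)


class TestRelativePositions:
    def _frame(self, pos, labels, fov=0):
        return pd.DataFrame(
            {
                "fov_id": fov,
                "x_um": pos[:, 0],
                "y_um": pos[:, 1],
                "z_um": 0.0,
                "label": labels,
            }
        )

    def test_reference_centroid_maps_to_origin(self):
        pos = np.array([[1.0, 1.0], [3.0, 5.0], [10.0, 10.0]])
        df = self._frame(pos, ["ref", "ref", "other"])
        out = relative_positions(df, "ref")
        ref = out[out["label"] == "ref"]
        assert np.allclose([ref["x_um"].mean(), ref["y_um"].mean()], 0.0)

    def test_translation_invariant(self):
        pos = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        df1 = self._frame(pos, ["ref", "a", "b"])
        df2 = self._frame(pos + 50.0, ["ref", "a", "b"])
        a = relative_positions(df1, "ref")[["x_um", "y_um"]].to_numpy()
        b = relative_positions(df2, "ref")[["x_um", "y_um"]].to_numpy()
        assert np.allclose(a, b)

    def test_fov_without_reference_dropped(self, caplog):
        pos = np.array([[0.0, 0.0], [1.0, 1.0]])
        df = pd.concat(
            [self._frame(pos, ["ref", "a"], fov=0), self._frame(pos, ["a", "b"], fov=1)]
        )
        with caplog.at_level("WARNING"):
            out = relative_positions(df, "ref")
        assert set(out["fov_id"]) == {0}


class TestDistanceShuffle:
    def test_mixed_labels_match_shuffled(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, (60, 2))
        labels = np.array(["a", "b"] * 30)
        out = pairwise_distance_shuffle_test(pos, labels, n_shuffles=30, seed=0)
        ks = ks_2samp(out["within_observed"], out["within_shuffled"]).statistic
        assert ks < 0.1

    def test_segregated_clusters_have_small_within_distances(self):
        rng = np.random.default_rng(1)
        pos = np.vstack([rng.normal(0, 5, (30, 2)), rng.normal(200, 5, (30, 2))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        out = pairwise_distance_shuffle_test(pos, labels, n_shuffles=20, seed=0)
        assert np.median(out["within_observed"]) < np.median(out["within_shuffled"])

    def test_single_point_groups_return_cross_only(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0]])
        out = pairwise_distance_shuffle_test(pos, np.array(["a", "b"]), n_shuffles=2)
        assert out["within_observed"].size == 0
        assert np.allclose(out["cross_observed"], [5.0])

    def test_boutons_at_neuron_positions_indistinguishable(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (40, 2))
        out = bouton_neuron_segregation(pts, pts.copy(), n_shuffles=20, seed=0)
        ks = ks_2samp(out["cross_observed"], out["within_observed"]).statistic
        assert ks < 0.15

    def test_offset_boutons_are_far(self):
        rng = np.random.default_rng(3)
        neurons = rng.normal(0, 10, (25, 2))
        boutons = rng.normal(200, 10, (25, 2))
        out = bouton_neuron_segregation(neurons, boutons, n_shuffles=20, seed=0)
        assert np.median(out["cross_observed"]) > np.median(out["cross_shuffled"])

    def test_single_bouton_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bouton_neuron_segregation(np.zeros((5, 2)), np.zeros((1, 2)))


class TestEnrichmentAndDensity:
    @pytest.mark.parametrize(
        "p_pos,p_neg,expected", [(0.3, 0.3, 0.0), (0.4, 0.0, 1.0), (0.0, 0.4, -1.0)]
    )
    def test_enrichment_identities(self, p_pos, p_neg, expected):
        assert enrichment_index(p_pos, p_neg) == expected

    def test_enrichment_undefined_for_double_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert enrichment_index(0.0, 0.0) is None

    def test_density_peaks_at_single_point(self):
        x, y, dens = density_map(np.array([[10.0, 20.0]]), bandwidth_um=5.0)
        iy, ix = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(x[ix] - 10.0) < 1.0 and abs(y[iy] - 20.0) < 1.0

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        x, y, dens = density_map(rng.uniform(0, 50, (20, 2)), bandwidth_um=8.0)
        cell = (x[1] - x[0]) * (y[1] - y[0])
        assert abs(dens.sum() * cell - 1.0) < 0.01

    def test_two_domains_recovered_at_60um(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0.0, 0.0], 20.0, (200, 2))
        b = rng.normal([60.0, 0.0], 20.0, (200, 2))
        extent = (-80.0, 140.0, -80.0, 80.0)
        xa, ya, da = density_map(a, bandwidth_um=15.0, extent=extent, grid_n=111)
        xb, yb, db = density_map(b, bandwidth_um=15.0, extent=extent, grid_n=111)
        pa = np.unravel_index(np.argmax(da), da.shape)
        pb = np.unravel_index(np.argmax(db), db.shape)
        sep = np.hypot(xa[pa[1]] - xb[pb[1]], ya[pa[0]] - yb[pb[0]])
        assert abs(sep - 60.0) < 15.0


class TestDetectBoutons:
    def test_blank_image_gives_no_boutons(self):
        assert detect_boutons(np.zeros((64, 64))).shape == (0, 2)

    def test_single_disk_centroid_recovered(self):
        yy, xx = np.mgrid[:64, :64]
        img = ((yy - 30) ** 2 + (xx - 40) ** 2 < 5**2).astype(float)
        cents = detect_boutons(img)
        assert len(cents) == 1
        assert np.hypot(cents[0][0] - 30, cents[0][1] - 40) < 1.0

    def test_two_disks_counted(self):
        yy, xx = np.mgrid[:64, :64]
        img = (
            ((yy - 15) ** 2 + (xx - 15) ** 2 < 4**2)
            | ((yy - 45) ** 2 + (xx - 45) ** 2 < 4**2)
        ).astype(float)
        assert len(detect_boutons(img)) == 2
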