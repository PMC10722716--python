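import numpy as np
import pandas as pd
import pytest

from eegmci import netica, simulate
from eegmci.core import BandScheme
from eegmci.inverse import SpectroCorticalImage


def _images(values_list):
    bands = BandScheme()
    return [SpectroCorticalImage(values=v, subject_id=f"s{i}", bands=bands)
            for i, v in enumerate(values_list)]


def _planted_cohort(n_per_group=40, nv=100, seed=3, noise_sd=0.0,
                    effects=None):
    effects = effects or (
        simulate.NetworkEffect("a", 2000.0, 600.0, 1500.0, 600.0),
        simulate.NetworkEffect("b", 1000.0, 400.0, 1000.0, 400.0),
    )
    spec = simulate.CohortSpec(n_hc=n_per_group, n_mci=n_per_group,
                               seed=seed, networks=effects)
    maps = simulate.generate_network_maps(len(effects), nv, seed=5)
    imgs, loadings = simulate.simulate_spectro_images(spec, maps,
                                                      noise_sd=noise_sd)
    return spec, maps, imgs, loadings


class TestGroupMatrix:
    def test_shape(self, rng):
        gm = netica.build_group_matrix(
            _images([rng.random((10, 5)) for _ in range(3)]))
        assert gm.matrix.shape == (3, 50)

    def test_unflatten_round_trip(self, rng):
        v = rng.random((10, 5))
        gm = netica.build_group_matrix(_images([v]))
        assert np.array_equal(gm.unflatten(gm.matrix[0]), v)

    def test_band_major_column_index(self, rng):
        """Column of (band=alpha, voxel=7) is 2*Nv + 7 (enumeration)."""
        v = rng.random((10, 5))
        gm = netica.build_group_matrix(_images([v]))
        col = gm.column_of("alpha", 7)
        assert col == 2 * 10 + 7
        assert gm.matrix[0, col] == v[7, 2]
        # exhaustive enumeration over every (band, voxel) pair
        for b in range(5):
            for vox in range(10):
                assert gm.matrix[0, gm.column_of(b, vox)] == v[vox, b]

    def test_shape_mismatch_names_subject(self, rng):
        imgs = _images([rng.random((10, 5)), rng.random((11, 5))])
        with pytest.raises(ValueError, match="s1"):
            netica.build_group_matrix(imgs)


class TestFitGroupICA:
    def test_two_planted_components_recovered(self):
        """Zero noise, two planted networks: fitted maps match the planted
        maps above |r| = 0.95 after |correlation| assignment."""
        _, maps, imgs, _ = _planted_cohort()
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        m = netica.match_components(dec, maps)
        assert (m["correlation"].abs() > 0.95).all()

    def test_rank_one_data_single_component(self, rng):
        base = rng.random((10, 5))
        coeff = rng.random(8) * 5 + 1
        imgs = _images([c * base for c in coeff])
        gm = netica.build_group_matrix(imgs)
        dec = netica.fit_group_ica(gm, k=1, seed=0)
        resid = gm.matrix - dec.reconstruct()
        centered = gm.matrix - gm.matrix.mean(axis=0)
        assert (np.linalg.norm(resid) / np.linalg.norm(centered)) < 0.01

    def test_same_seed_identical_loadings(self):
        _, _, imgs, _ = _planted_cohort(n_per_group=15)
        gm = netica.build_group_matrix(imgs)
        a = netica.fit_group_ica(gm, k=2, seed=9)
        b = netica.fit_group_ica(gm, k=2, seed=9)
        assert np.array_equal(a.loadings, b.loadings)

    def test_component_order_by_total_power(self):
        _, _, imgs, _ = _planted_cohort()
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        power = dec.total_power()
        assert np.all(np.diff(power) <= 0)

    def test_sign_convention(self):
        _, _, imgs, _ = _planted_cohort()
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        for k in range(dec.k):
            assert dec.maps[k, np.argmax(np.abs(dec.maps[k]))] > 0

    def test_k_too_large_rejected(self, rng):
        gm = netica.build_group_matrix(
            _images([rng.random((10, 5)) for _ in range(3)]))
        with pytest.raises(ValueError, match="k="):
            netica.fit_group_ica(gm, k=4)

    def test_noiseless_reconstruction_at_true_rank(self):
        _, _, imgs, _ = _planted_cohort()
        gm = netica.build_group_matrix(imgs)
        dec = netica.fit_group_ica(gm, k=2, seed=7)
        centered = gm.matrix - gm.matrix.mean(axis=0)
        rel = (np.linalg.norm(centered - dec.loadings @ dec.maps)
               / np.linalg.norm(centered))
        assert rel < 0.01


class TestProjection:
    def test_training_subject_projects_to_own_loadings(self):
        _, _, imgs, _ = _planted_cohort(n_per_group=20)
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        proj = netica.project_subject(dec, imgs[3])
        assert np.allclose(proj, dec.loadings[3], atol=1e-6)

    def test_cohort_mean_projects_to_zero(self):
        _, _, imgs, _ = _planted_cohort(n_per_group=20)
        gm = netica.build_group_matrix(imgs)
        dec = netica.fit_group_ica(gm, k=2, seed=7)
        mean_img = SpectroCorticalImage(
            values=gm.unflatten(gm.matrix.mean(axis=0)), subject_id="mean",
            bands=BandScheme())
        proj = netica.project_subject(dec, mean_img)
        scale = dec.loadings.std(axis=0)
        assert np.all(np.abs(proj) < 1e-6 * scale)

    def test_held_out_loading_recovery_within_5pct(self):
        """A fresh subject with known planted loadings is recovered within
        5% of the loading scale at zero noise (after the training-set
        scale alignment)."""
        spec, maps, imgs, loadings = _planted_cohort()
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        m = netica.match_components(dec, maps)
        L_true = loadings[["a", "b"]].to_numpy()
        true_new = np.array([2100.0, 800.0])
        img = spec.baseline_power + (true_new @ maps.reshape(2, -1))
        new = SpectroCorticalImage(
            values=np.maximum(img, 0.0).reshape(5, -1).T,
            subject_id="new", bands=BandScheme())
        proj = netica.project_subject(dec, new)
        Lc = L_true - L_true.mean(axis=0)
        for _, row in m.iterrows():
            k, ti = int(row["component"]), int(row["true_map"])
            t, f = Lc[:, ti], dec.loadings[:, k]
            scale = (t @ f) / (t @ t)
            est = proj[k] / scale
            truth = true_new[ti] - L_true[:, ti].mean()
            assert abs(est - truth) < 0.05 * L_true[:, ti].std()

    def test_projection_linear_in_image(self):
        _, _, imgs, _ = _planted_cohort(n_per_group=20)
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        a, b = imgs[0].values, imgs[1].values
        combo = SpectroCorticalImage(values=0.5 * a + 0.5 * b,
                                     subject_id="c", bands=BandScheme())
        pa = netica.project_subject(dec, imgs[0])
        pb = netica.project_subject(dec, imgs[1])
        pc = netica.project_subject(dec, combo)
        # projection acts on the centred vector: affine combination with
        # weights summing to one is preserved exactly
        assert np.allclose(pc, 0.5 * pa + 0.5 * pb, atol=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        _, _, imgs, _ = _planted_cohort(n_per_group=5)
        dec = netica.fit_group_ica(netica.build_group_matrix(imgs), k=2,
                                   seed=7)
        bad = SpectroCorticalImage(values=rng.random((7, 5)),
                                   subject_id="x", bands=BandScheme())
        with pytest.raises(ValueError, match="shape"):
            netica.project_subject(dec, bad)


class TestCompareNetworks:
    def _null_decomposition(self, rng, n=80, k=3):
        dec = netica.ICADecomposition(
            maps=rng.standard_normal((k, 50)),
            loadings=rng.standard_normal((n, k)),
            mean_image=np.zeros(50), subject_ids=[f"s{i}" for i in range(n)],
            bands=BandScheme(), n_voxels=10, seed=0)
        return dec

    def test_type_one_error_calibrated(self, rng):
        """Identical group distributions: rejection rate at p<0.05 is
        about 0.05 (seeded simulation, 200 replicates)."""
        groups = np.array(["HC"] * 40 + ["MCI"] * 40)
        rejections = 0
        total = 0
        for r in range(67):  # 67 replicates x 3 components ~ 200 tests
            dec = self._null_decomposition(rng)
            comps = netica.compare_networks(dec, groups, n_perm=499, seed=r)
            rejections += sum(c.p_one_tailed < 0.05 for c in comps)
            total += len(comps)
        rate = rejections / total
        assert 0.03 <= rate <= 0.07

    def test_planted_deficit_detected(self, rng):
        """1 pooled-SD deficit at 40/40: detected in >90% of repetitions."""
        groups = np.array(["HC"] * 40 + ["MCI"] * 40)
        hits = 0
        reps = 40
        for r in range(reps):
            dec = self._null_decomposition(rng, k=1)
            dec.loadings[40:, 0] -= 1.0  # MCI one SD lower
            comps = netica.compare_networks(dec, groups, n_perm=499, seed=r)
            hits += comps[0].p_one_tailed < 0.05
        assert hits / reps > 0.9

    def test_tail_complementarity(self, rng):
        """Flipping the alternative gives p' = 1 - p + P(t = t_obs)."""
        groups = np.array(["HC"] * 10 + ["MCI"] * 10)
        dec = self._null_decomposition(rng, n=20, k=2)
        lo = netica.compare_networks(dec, groups, n_perm=2000, seed=5)
        hi = netica.compare_networks(dec, groups, n_perm=2000, seed=5,
                                     alternative="greater")
        for a, b in zip(lo, hi):
            # continuous loadings: P(t == t_obs) = 1/(n_perm+1) (observed
            # permutation only)
            assert a.p_one_tailed + b.p_one_tailed == pytest.approx(
                1.0 + 1.0 / 2001.0, abs=1e-12)

    def test_t_sign_matches_direction(self, rng):
        groups = np.array(["HC"] * 20 + ["MCI"] * 20)
        dec = self._null_decomposition(rng, n=40, k=1)
        dec.loadings[20:, 0] -= 2.0
        c = netica.compare_networks(dec, groups, n_perm=199, seed=1)[0]
        assert c.t < 0
        assert c.mean_mci < c.mean_hc

    def test_artifact_components_excluded(self, rng):
        groups = np.array(["HC"] * 10 + ["MCI"] * 10)
        dec = self._null_decomposition(rng, n=20, k=3)
        dec.artifact_flags[1] = True
        comps = netica.compare_networks(dec, groups, n_perm=99, seed=0)
        assert [c.component for c in comps] == [0, 2]

    def test_small_group_rejected(self, rng):
        dec = self._null_decomposition(rng, n=5)
        with pytest.raises(ValueError, match="2 subjects"):
            netica.compare_networks(dec, ["HC"] * 4 + ["MCI"], n_perm=9)
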