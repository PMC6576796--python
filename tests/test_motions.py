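"""Superposition, RMSF, PCA, RMSIP and conformer clustering."""

import numpy as np
import pytest

from fragnet import (cluster_conformers, hull_overlap, pca_ensemble,
                     project_and_spread, rmsf_profile, rmsip, superpose)
from fragnet.ensemble import AtomSelection

from conftest import make_ca_ensemble, random_rotation


def grid_search_rmsd(mobile, target):
    """Brute-force oracle: Euler-angle grid search with nested refinement."""
    from scipy.spatial.transform import Rotation
    mc = mobile - mobile.mean(0)
    tc = target - target.mean(0)

    def scan(centers, spans, n):
        best, best_angles = np.inf, None
        axes = [np.linspace(c - s, c + s, n) for c, s in zip(centers, spans)]
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                    d = mc @ R.T - tc
                    r = np.sqrt((d ** 2).sum() / len(mobile))
                    if r < best:
                        best, best_angles = r, (a, b, c)
        return best, best_angles

    best, angles = scan((np.pi, np.pi / 2, np.pi), (np.pi, np.pi / 2, np.pi), 25)
    span = np.pi / 12
    for _ in range(6):
        best, angles = scan(angles, (span,) * 3, 9)
        span /= 4
    return best


class TestSuperpose:
    def test_rigid_copies_fit_exactly(self, rng):
        base = rng.normal(size=(8, 3)) * 5
        frames = [base]
        for _ in range(4):
            frames.append(base @ random_rotation(rng).T + rng.normal(size=3) * 20)
        ens = make_ca_ensemble(np.stack(frames))
        fit = superpose(ens, reference=0)
        np.testing.assert_allclose(fit.rmsd, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.ensemble.coords[3], base, atol=1e-9)

    def test_reference_fits_itself(self, rng):
        ens = make_ca_ensemble(rng.normal(size=(3, 6, 3)) * 4)
        fit = superpose(ens, reference=1)
        assert fit.rmsd[1] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_atoms_raises(self, rng):
        ens = make_ca_ensemble(rng.normal(size=(2, 2, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            superpose(ens)

    def test_matches_grid_search_oracle(self, rng):
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        ens = make_ca_ensemble(np.stack([b, a]))
        fit = superpose(ens, reference=0)
        assert fit.rmsd[1] == pytest.approx(grid_search_rmsd(a, b), abs=1e-3)

    def test_never_increases_rmsd(self, rng):
        base = rng.normal(size=(10, 3)) * 5
        moved = base + rng.normal(size=(10, 3))
        ens = make_ca_ensemble(np.stack([base, moved]))
        fit = superpose(ens, reference=0)
        raw = np.sqrt(((moved - base) ** 2).sum() / 10)
        assert fit.rmsd[1] <= raw + 1e-12


class TestRMSF:
    def test_alternating_unit_displacement(self):
        coords = np.zeros((4, 5, 3))
        coords[::2, 0, 0] = 1.0
        coords[1::2, 0, 0] = -1.0
        prof = rmsf_profile(make_ca_ensemble(coords))
        assert prof.atom_rmsf[0] == pytest.approx(1.0)
        assert prof.atom_rmsf[1] == 0.0
        assert prof.pseudo_b[0] == pytest.approx(8 * np.pi ** 2 / 3)

    def test_static_ensemble_is_zero(self, rng):
        frame = rng.normal(size=(1, 6, 3)) * 5
        prof = rmsf_profile(make_ca_ensemble(np.repeat(frame, 3, axis=0)))
        np.testing.assert_allclose(prof.atom_rmsf, 0.0, atol=1e-12)

    def test_single_frame_raises(self, rng):
        with pytest.raises(ValueError, match="single frame"):
            rmsf_profile(make_ca_ensemble(rng.normal(size=(1, 5, 3))))

    def test_isotropic_gaussian_gives_sigma_sqrt3(self, rng):
        sigma = 0.5
        coords = rng.normal(0, sigma, size=(10_000, 4, 3))
        prof = rmsf_profile(make_ca_ensemble(coords))
        np.testing.assert_allclose(prof.atom_rmsf, sigma * np.sqrt(3), rtol=0.02)


class TestPCA:
    def test_line_displaced_frames_have_pc1_fraction_one(self, rng):
        base = rng.normal(size=(6, 3)) * 5
        direction = rng.normal(size=(6, 3))
        direction /= np.linalg.norm(direction)
        amps = rng.normal(size=20)
        coords = base[None] + amps[:, None, None] * direction[None]
        pca = pca_ensemble(make_ca_ensemble(coords))
        assert pca.variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_trace_identity(self, rng):
        coords = rng.normal(size=(50, 5, 3)) * 2
        pca = pca_ensemble(make_ca_ensemble(coords))
        flat = coords.reshape(50, -1)
        assert pca.eigenvalues.sum() == pytest.approx(
            flat.var(axis=0, ddof=0).sum(), abs=1e-8)

    def test_eigenvectors_orthonormal(self, rng):
        pca = pca_ensemble(make_ca_ensemble(rng.normal(size=(30, 4, 3))))
        g = pca.eigenvectors.T @ pca.eigenvectors
        np.testing.assert_allclose(g, np.eye(g.shape[0]), atol=1e-8)

    def test_rotated_input_same_spectrum(self, rng):
        coords = rng.normal(size=(40, 5, 3)) * 3
        R = random_rotation(rng)
        a = pca_ensemble(make_ca_ensemble(coords))
        b = pca_ensemble(make_ca_ensemble(coords @ R.T))
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-6)

    def test_single_frame_raises(self, rng):
        with pytest.raises(ValueError):
            pca_ensemble(make_ca_ensemble(rng.normal(size=(1, 5, 3))))


class TestProjections:
    def _pca_and_ens(self, rng):
        coords = rng.normal(size=(30, 5, 3))
        ens = make_ca_ensemble(coords)
        return ens, pca_ensemble(ens)

    def test_unit_square_hull_area(self, rng):
        ens, pca = self._pca_and_ens(rng)
        cloud = project_and_spread(ens, pca)
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        cloud.points = corners
        from fragnet.motions import _hull_polygon
        assert _hull_polygon(corners).area == pytest.approx(1.0)

    def test_identical_clouds_full_overlap(self, rng):
        ens, pca = self._pca_and_ens(rng)
        cloud = project_and_spread(ens, pca)
        assert hull_overlap(cloud, cloud) == pytest.approx(1.0)

    def test_disjoint_clouds_zero_overlap(self, rng):
        ens, pca = self._pca_and_ens(rng)
        a = project_and_spread(ens, pca)
        import copy
        b = copy.deepcopy(a)
        b.points = a.points + 1e4
        assert hull_overlap(a, b) == 0.0

    def test_component_out_of_range(self, rng):
        ens, pca = self._pca_and_ens(rng)
        with pytest.raises(IndexError):
            project_and_spread(ens, pca, components=(1, 99))


class TestRMSIP:
    def test_identical_subspaces(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(12, 5)))
        val, d = rmsip(q, q, k=5)
        assert val == pytest.approx(1.0)
        np.testing.assert_allclose(d, np.eye(5), atol=1e-12)

    def test_orthogonal_subspaces(self):
        a = np.eye(6)[:, :2]
        b = np.eye(6)[:, 2:4]
        val, _ = rmsip(a, b, k=2)
        assert val == 0.0

    def test_rotated_by_45_degrees(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[np.cos(np.pi / 4)], [np.sin(np.pi / 4)]])
        val, _ = rmsip(a, b, k=1)
        assert val == pytest.approx(np.cos(np.pi / 4))

    def test_symmetric_and_bounded(self, rng):
        a, _ = np.linalg.qr(rng.normal(size=(9, 4)))
        b, _ = np.linalg.qr(rng.normal(size=(9, 4)))
        v1, _ = rmsip(a, b, k=4)
        v2, _ = rmsip(b, a, k=4)
        assert v1 == pytest.approx(v2)
        assert 0.0 <= v1 <= 1.0

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            rmsip(np.eye(4), np.eye(5), k=2)


class TestClusterConformers:
    def test_two_tight_bundles(self, rng):
        a = rng.normal(size=(5, 3))
        frames = [a + rng.normal(0, 0.05, size=(5, 3)) for _ in range(6)]
        frames += [a + 10.0 + rng.normal(0, 0.05, size=(5, 3)) for _ in range(4)]
        res = cluster_conformers(make_ca_ensemble(np.stack(frames)), rmsd_cutoff=1.0)
        assert res.sizes == [6, 4]
        assert set(res.labels[:6]) == {0} and set(res.labels[6:]) == {1}

    def test_large_cutoff_single_cluster(self, rng):
        ens = make_ca_ensemble(rng.normal(size=(8, 5, 3)))
        res = cluster_conformers(ens, rmsd_cutoff=1e6)
        assert res.sizes == [8]
        assert res.representatives[0] in range(8)

    def test_three_state_generator_labels(self, rng):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(6, 3)) * 3
        centers = [base, base + 20, base - 20]
        truth, frames = [], []
        for f in range(50):
            s = f % 3
            truth.append(s)
            frames.append(centers[s] + rng.normal(0, 0.1, size=(6, 3)))
        res = cluster_conformers(make_ca_ensemble(np.stack(frames)), rmsd_cutoff=2.0)
        truth = np.array(truth)
        for s in range(3):
            assert len(set(res.labels[truth == s])) == 1
        assert sum(res.sizes) == 50

    def test_deterministic(self, rng):
        coords = rng.normal(size=(12, 4, 3))
        a = cluster_conformers(make_ca_ensemble(coords), 1.5)
        b = cluster_conformers(make_ca_ensemble(coords), 1.5)
        np.testing.assert_array_equal(a.labels, b.labels)
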