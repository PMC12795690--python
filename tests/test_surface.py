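"""Surface module: parsing, level-set sampling, chemical and curvature features."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ppisurf.errors import DegenerateChainError, FormatError
from ppisurf.surface import (
    AtomCloud, DEFAULT_ATOM_RADII, DEFAULT_CURVATURE_SCALES, ELEMENT_VOCAB,
    SamplerConfig, SurfacePointCloud, _soft_distance, compute_chemical_features,
    compute_curvatures, featurize, read_structure, sample_surface,
)
from conftest import make_cloud


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestReadStructure:
    def test_three_atom_parse(self, three_atom_pdb):
        cloud = read_structure(three_atom_pdb, "pdb", min_chain_atoms=1)
        assert len(cloud) == 3
        assert cloud.chains == ["A"]
        assert sorted(cloud.elements) == ["C", "N", "O"]

    def test_out_of_vocabulary_atom_dropped(self, oov_pdb):
        cloud = read_structure(oov_pdb, "pdb", min_chain_atoms=1)
        assert len(cloud) == 2
        assert cloud.dropped_atoms == 1

    def test_degenerate_chain_raises_by_default(self, three_atom_pdb):
        with pytest.raises(DegenerateChainError, match="A"):
            read_structure(three_atom_pdb, "pdb")

    def test_two_chain_tabular_round_trip(self, two_chain_pdb, tmp_path):
        cloud = read_structure(two_chain_pdb, "pdb")
        assert cloud.chains == ["A", "B"]
        out = tmp_path / "dump.tsv"
        cloud.to_tsv(out)
        back = AtomCloud.from_tsv(out)
        assert list(back.chain_id) == list(cloud.chain_id)
        assert list(back.residue_index) == list(cloud.residue_index)
        np.testing.assert_allclose(back.coords, cloud.coords, atol=1e-9)

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_bytes(b"\x00\x01 not a structure")
        with pytest.raises(FormatError):
            read_structure(bad, "pdb", min_chain_atoms=1)


# ---------------------------------------------------------------------------
# Level-set sampling
# ---------------------------------------------------------------------------

class TestSampleSurface:
    def test_single_atom_sphere(self):
        cloud = make_cloud([[0.0, 0.0, 0.0]])
        cfg = SamplerConfig(seeds_per_atom=200, rng_seed=3)
        pts, normals = sample_surface(cloud, cfg)
        r_expected = DEFAULT_ATOM_RADII["C"] + cfg.level_set_offset
        radii = np.linalg.norm(pts, axis=1)
        assert np.allclose(radii, r_expected, atol=2e-2)
        # normals parallel to the radial direction
        cos = np.abs(np.sum(normals * pts / radii[:, None], axis=1))
        assert np.min(cos) > 1 - 1e-6

    def test_determinism_bitwise(self):
        cloud = make_cloud([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        cfg = SamplerConfig(seeds_per_atom=15, rng_seed=7)
        p1, n1 = sample_surface(cloud, cfg)
        p2, n2 = sample_surface(cloud, cfg)
        assert np.array_equal(p1, p2) and np.array_equal(n1, n2)

    def test_normals_are_unit(self):
        cloud = make_cloud(np.random.default_rng(0).normal(scale=3, size=(10, 3)))
        _, normals = sample_surface(cloud, SamplerConfig(seeds_per_atom=8, rng_seed=1))
        assert np.max(np.abs(np.linalg.norm(normals, axis=1) - 1.0)) <= 1e-6

    def test_subsample_spacing_respected(self):
        cloud = make_cloud([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        cfg = SamplerConfig(seeds_per_atom=30, subsample_spacing=1.5, rng_seed=2)
        pts, _ = sample_surface(cloud, cfg)
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() >= 1.5 - 1e-9

    def test_normals_match_finite_difference_gradient(self):
        cloud = make_cloud([[0, 0, 0], [3.2, 0, 0], [0, 3.2, 0], [1.5, 1.5, 2.5]])
        cfg = SamplerConfig(seeds_per_atom=10, rng_seed=5)
        pts, normals = sample_surface(cloud, cfg)
        radii = np.array([DEFAULT_ATOM_RADII[e] for e in cloud.elements])
        eps = 1e-5
        fd = np.zeros_like(pts)
        for ax in range(3):
            shift = np.zeros(3)
            shift[ax] = eps
            fp, _ = _soft_distance(pts + shift, cloud.coords, radii, cfg.smoothing_sigma)
            fm, _ = _soft_distance(pts - shift, cloud.coords, radii, cfg.smoothing_sigma)
            fd[:, ax] = (fp - fm) / (2 * eps)
        fd /= np.linalg.norm(fd, axis=1, keepdims=True)
        rel = np.linalg.norm(fd - normals, axis=1)
        assert rel.max() <= 1e-3


# ---------------------------------------------------------------------------
# Chemical features
# ---------------------------------------------------------------------------

class TestChemicalFeatures:
    def test_single_carbon_one_hot(self):
        cloud = make_cloud([[0.0, 0.0, 0.0]])
        pts, _ = sample_surface(cloud, SamplerConfig(seeds_per_atom=50, rng_seed=0))
        chem = compute_chemical_features(pts, cloud)
        c_idx = ELEMENT_VOCAB.index("C")
        assert np.allclose(chem[:, c_idx], 1.0)
        assert np.allclose(np.delete(chem, c_idx, axis=1), 0.0)

    def test_weights_normalized(self):
        rng = np.random.default_rng(4)
        cloud = make_cloud(rng.normal(scale=4, size=(30, 3)),
                           elements=list(rng.choice(["C", "N", "O", "S"], size=30)))
        pts = rng.normal(scale=5, size=(40, 3))
        chem = compute_chemical_features(pts, cloud)
        np.testing.assert_allclose(chem.sum(axis=1), 1.0, atol=1e-6)

    def test_neighbors_match_exhaustive_search(self):
        rng = np.random.default_rng(11)
        cloud = make_cloud(rng.normal(scale=6, size=(50, 3)))
        pts = rng.normal(scale=6, size=(20, 3))
        k = 16
        _, idx = cKDTree(cloud.coords).query(pts, k=k)
        d_all = np.linalg.norm(pts[:, None, :] - cloud.coords[None, :, :], axis=2)
        brute = np.argsort(d_all, axis=1)[:, :k]
        assert np.array_equal(np.sort(idx, axis=1), np.sort(brute, axis=1))


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def sphere_samples(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v, v.copy()


class TestCurvature:
    def test_plane_is_flat(self):
        g = np.stack(np.meshgrid(np.linspace(-5, 5, 25),
                                 np.linspace(-5, 5, 25)), -1).reshape(-1, 2)
        pts = np.concatenate([g, np.zeros((len(g), 1))], axis=1)
        normals = np.tile([0.0, 0.0, 1.0], (len(g), 1))
        curv = compute_curvatures(pts, normals)
        assert np.abs(curv).max() <= 1e-2

    @pytest.mark.parametrize("seed", range(5))
    def test_sphere_analytic_recovery(self, seed):
        pts, normals = sphere_samples(2000, 5.0, seed)
        curv = compute_curvatures(pts, normals, scales=[1.0])
        det, tr = curv[:, 0], curv[:, 1]
        assert abs(det.mean() - 0.04) / 0.04 <= 0.15
        assert abs(tr.mean() - 0.4) / 0.4 <= 0.15

    def test_output_width_per_scale(self):
        pts, normals = sphere_samples(300, 5.0, 1)
        assert compute_curvatures(pts, normals, scales=[1, 2, 3, 5, 10]).shape[1] == 10
        assert compute_curvatures(pts, normals, scales=[2.0]).shape[1] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts, normals = sphere_samples(500, 5.0, seed)
        pts += 0.15 * rng.normal(size=pts.shape)  # roughen the surface
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
        t = rng.normal(scale=20, size=3)
        c0 = compute_curvatures(pts, normals)
        c1 = compute_curvatures(pts @ rot.T + t, normals @ rot.T)
        assert np.max(np.abs(c0 - c1)) <= 1e-3


# ---------------------------------------------------------------------------
# Fused featurization
# ---------------------------------------------------------------------------

class TestFeaturize:
    def test_feature_width_and_layout(self):
        rng = np.random.default_rng(9)
        cloud = make_cloud(rng.normal(scale=5, size=(40, 3)),
                           elements=list(rng.choice(["C", "N", "O", "S"], size=40)))
        surf = featurize(cloud, SamplerConfig(seeds_per_atom=8, rng_seed=0))
        assert surf.features.shape[1] == 32
        assert surf.chem.shape[1] == 22
        assert surf.curv.shape[1] == 2 * len(DEFAULT_CURVATURE_SCALES)
        np.testing.assert_array_equal(surf.features[:, :22], surf.chem)
        np.testing.assert_array_equal(surf.features[:, 22:], surf.curv)

    def test_tsv_and_npz_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        cloud = make_cloud(rng.normal(scale=5, size=(20, 3)))
        surf = featurize(cloud, SamplerConfig(seeds_per_atom=6, rng_seed=0))
        surf.to_tsv(tmp_path / "s.tsv")
        surf.to_npz(tmp_path / "s.npz")
        back_tsv = SurfacePointCloud.from_tsv(tmp_path / "s.tsv")
        back_npz = SurfacePointCloud.from_npz(tmp_path / "s.npz")
        np.testing.assert_allclose(back_tsv.features, surf.features, atol=1e-6)
        np.testing.assert_array_equal(back_npz.features, surf.features)
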