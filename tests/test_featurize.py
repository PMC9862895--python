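import numpy as np
import pytest

from catsite import featurize as fz
from catsite import pdb_model as pm


class TestOccupancy:
    def test_limits_and_monotonicity(self):
        r = 1.7
        assert fz.occupancy(0.0, r) == 1.0
        d = np.linspace(0.1, 8.0, 200)
        occ = fz.occupancy(d, r)
        assert np.all(np.diff(occ) <= 0)          # non-increasing everywhere
        tail = occ[d > r]
        assert np.all(np.diff(tail) < 0)          # strictly below saturation
        assert fz.occupancy(r, r) == pytest.approx(1 - np.exp(-1))
        assert fz.occupancy(100.0, r) < 1e-20

    def test_crossing_distance_closed_form(self):
        for r in (1.2, 1.52, 1.7, 2.0):
            d = fz.occupancy_crossing_distance(r)
            assert fz.occupancy(d, r) == pytest.approx(1e-4, rel=1e-9)
            # "about twice the atom radius"
            assert d / r == pytest.approx((-np.log1p(-1e-4)) ** (-1 / 12))
            assert 2.0 < d / r < 2.3

    def test_vectorized_matches_scalar(self):
        d = np.array([0.5, 1.0, 2.0, 4.0])
        got = fz.occupancy(d, 1.7)
        want = [fz.occupancy(float(x), 1.7) for x in d]
        assert np.allclose(got, want)


class TestAtomTyping:
    def test_protein_template_types(self):
        cases = [
            (pm.Atom("C", [0, 0, 0], name="CG", res_name="PHE"), "A"),
            (pm.Atom("C", [0, 0, 0], name="CB", res_name="PHE"), "C"),
            (pm.Atom("N", [0, 0, 0], name="ND1", res_name="HIS"), "NA"),
            (pm.Atom("N", [0, 0, 0], name="N", res_name="ALA"), "N"),
            (pm.Atom("O", [0, 0, 0], name="O", res_name="ALA"), "OA"),
            (pm.Atom("S", [0, 0, 0], name="SG", res_name="CYS"), "SA"),
        ]
        entry = pm.ChainEntry("t", "A", "X" * len(cases),
                              [a for a, _ in cases], np.zeros((1, 3)))
        typed = fz.assign_atom_types(entry)
        assert [t.type_code for t in typed] == [c for _, c in cases]

    def test_charged_sidechain_channels(self):
        nz = pm.Atom("N", [0, 0, 0], name="NZ", res_name="LYS")
        od1 = pm.Atom("O", [0, 0, 0], name="OD1", res_name="ASP")
        entry = pm.ChainEntry("t", "A", "KD", [nz, od1], np.zeros((1, 3)))
        t_nz, t_od1 = fz.assign_atom_types(entry)
        ch = dict(zip(fz.CHANNELS, t_nz.channels))
        assert ch["positive"] and not ch["negative"]
        ch = dict(zip(fz.CHANNELS, t_od1.channels))
        assert ch["negative"] and ch["acceptor"]

    def test_every_atom_carries_excluded_volume(self):
        entry = pm.ChainEntry("t", "A", "A",
                              [pm.Atom("FE", [0, 0, 0], name="FE",
                                       res_name="HEM")], np.zeros((1, 3)))
        t, = fz.assign_atom_types(entry)
        assert t.channels[fz.CHANNELS.index("excluded")]
        assert t.channels[fz.CHANNELS.index("metal")]

    def test_ligand_aromatic_ring_perception(self):
        # planar hexagon with 1.4 A bonds -> all carbons aromatic
        ang = np.arange(6) * np.pi / 3
        atoms = [pm.Atom("C", [1.4 * np.cos(a), 1.4 * np.sin(a), 0.0])
                 for a in ang]
        lig = pm.Ligand("BNZ", atoms)
        typed = fz.assign_atom_types(lig)
        assert all(t.type_code == "A" for t in typed)

    def test_ligand_chain_not_aromatic(self):
        atoms = [pm.Atom("C", [1.5 * i, 0, 0]) for i in range(5)]
        typed = fz.assign_atom_types(pm.Ligand("ALK", atoms))
        assert all(t.type_code == "C" for t in typed)


@pytest.fixture(scope="module")
def typed_atoms():
    atoms = [pm.Atom("C", [0, 0, 0], name="CG", res_name="PHE"),
             pm.Atom("O", [2, 0, 0], name="O", res_name="ALA"),
             pm.Atom("N", [0, 2, 0], name="NZ", res_name="LYS")]
    entry = pm.ChainEntry("t", "A", "FAK", atoms, np.zeros((1, 3)))
    return fz.assign_atom_types(entry)


class TestGrids:
    def test_excluded_channel_dominates_voxelwise(self, typed_atoms):
        g = fz.compute_grid(typed_atoms, [0.5, 0.5, 0.0]).values
        excl = g[fz.CHANNELS.index("excluded")]
        for k in range(fz.N_CHANNELS):
            assert np.all(g[k] <= excl + 1e-12)

    def test_translation_equivariance(self, typed_atoms):
        center = np.array([0.5, -0.3, 0.2])
        shift = np.array([7.3, -2.1, 11.0])
        g1 = fz.compute_grid(typed_atoms, center).values
        moved = [fz.TypedAtom(pm.Atom(t.base.element, t.base.coords + shift,
                                      name=t.base.name,
                                      res_name=t.base.res_name),
                              t.type_code, t.channels) for t in typed_atoms]
        g2 = fz.compute_grid(moved, center + shift).values
        assert np.allclose(g1, g2, atol=1e-9)

    def test_compute_grids_matches_compute_grid(self, typed_atoms):
        centers = np.array([[0.0, 0.0, 0.0], [1.0, -1.0, 0.5]])
        fast = fz.compute_grids(typed_atoms, centers)
        for i, c in enumerate(centers):
            slow = fz.compute_grid(typed_atoms, c).values
            assert np.allclose(fast[i], slow, atol=1e-5)

    def test_grid_shape_and_range(self, typed_atoms):
        g = fz.compute_grid(typed_atoms, [0, 0, 0])
        assert g.values.shape == (8, 19, 19, 19)
        assert g.values.min() >= 0.0 and g.values.max() <= 1.0

    def test_spacing_validation(self, typed_atoms):
        with pytest.raises(ValueError):
            fz.compute_grid(typed_atoms, [0, 0, 0], spacing=0.0)

    def test_grids_roundtrip(self, typed_atoms, tmp_path):
        centers = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        grids = fz.compute_grids(typed_atoms, centers)
        path = tmp_path / "g.npz"
        fz.write_grids(path, grids, centers, spacing=1.0, chain_ref="t_A")
        got, got_centers, header = fz.read_grids(path)
        assert np.allclose(got, grids)
        assert np.allclose(got_centers, centers)
        assert header["chain_ref"] == "t_A"
        assert header["channels"] == list(fz.CHANNELS)


class TestSurface:
    def test_sas_points_on_expanded_spheres(self, toy_protein):
        entry = toy_protein.entry
        pts = fz.sas_points(entry, tessellation_level=1)
        heavy = [a for a in entry.atoms if a.is_heavy]
        xyz = np.array([a.coords for a in heavy])
        expanded = np.array([a.vdw_radius for a in heavy]) + 1.4
        d = np.linalg.norm(pts.points[:, None, :] - xyz[None, :, :], axis=-1)
        # no point is buried inside any expanded sphere
        assert np.all(d.min(axis=1) >= expanded[d.argmin(axis=1)] - 1e-6)
        # every point lies on some atom's expanded sphere
        on_sphere = np.isclose(d, expanded[None, :], atol=1e-6).any(axis=1)
        assert on_sphere.all()
        assert pts.chain_ref == f"{entry.structure_id}_{entry.chain_id}"

    def test_tessellation_density_increases(self, toy_protein):
        lo = fz.sas_points(toy_protein.entry, tessellation_level=0)
        hi = fz.sas_points(toy_protein.entry, tessellation_level=2)
        assert len(hi) > len(lo)

    def test_labels_follow_ligand_occupancy_threshold(self, toy_protein):
        entry = toy_protein.entry
        pts = fz.sas_points(entry, tessellation_level=1)
        labeled = fz.label_ligandability(pts, entry.ligands)
        occ = np.max([fz.ligand_occupancy(pts.points, l)
                      for l in entry.ligands], axis=0)
        assert np.array_equal(labeled.is_ligandable, occ > 1e-4)
        assert labeled.is_ligandable.any()
        assert not labeled.is_ligandable.all()

    def test_points_tsv_roundtrip(self, tmp_path, rng):
        pts = fz.SurfacePointSet(rng.normal(size=(20, 3)),
                                 rng.random(20) > 0.5, rng.random(20), "c_A")
        path = tmp_path / "p.tsv"
        fz.write_points_tsv(pts, path)
        got = fz.read_points_tsv(path, chain_ref="c_A")
        assert np.allclose(got.points, np.round(pts.points, 3))
        assert np.array_equal(got.is_ligandable, pts.is_ligandable)
        assert np.allclose(got.prediction, pts.prediction, atol=1e-6)
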