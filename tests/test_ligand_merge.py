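import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from catsite import ligand_merge as lm
from catsite import pdb_model as pm
from catsite import synthetic_fixtures as synth


def _random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


class TestKabsch:
    def test_recovers_random_rigid_transform(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(12, 3)) * 5
            rot, trans = _random_rigid(rng)
            moved = pts @ rot.T + trans
            r_est, t_est = lm.kabsch(moved, pts)
            fitted = moved @ r_est.T + t_est
            assert lm.rmsd(fitted, pts) < 1e-6
            assert np.linalg.det(r_est) == pytest.approx(1.0)

    def test_agrees_with_scipy_align_vectors(self, rng):
        pts = rng.normal(size=(20, 3)) * 4
        rot, trans = _random_rigid(rng)
        moved = pts @ rot.T + trans + rng.normal(0, 0.1, size=(20, 3))
        r_est, t_est = lm.kabsch(moved, pts)
        # scipy solves the same least-squares problem on centered clouds
        r_ref, _ = Rotation.align_vectors(pts - pts.mean(0),
                                          moved - moved.mean(0))
        assert np.allclose(r_est, r_ref.as_matrix(), atol=1e-8)

    def test_rmsd_validation(self):
        with pytest.raises(ValueError):
            lm.rmsd(np.zeros((2, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            lm.rmsd(np.zeros((0, 3)), np.zeros((0, 3)))
        assert lm.rmsd([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)


def _chain_with_noise(base: pm.ChainEntry, delta: float, sid: str,
                      ligands=None) -> pm.ChainEntry:
    """Copy of `base` with alternating +/- delta x-displacement of every
    atom: the optimal superposition is the identity and its CA RMSD is
    `delta` (zero mean, no net rotation for an even count)."""
    signs = np.array([1.0 if i % 2 == 0 else -1.0
                      for i in range(len(base.ca_coords))])
    ca = base.ca_coords + np.outer(signs, [delta, 0, 0])
    shift = {}
    for i in range(len(base.ca_coords)):
        shift[i + 1] = signs[i] * delta
    atoms = [pm.Atom(a.element, a.coords + [shift.get(a.res_id[0], 0.0), 0, 0],
                     name=a.name, res_name=a.res_name, res_id=a.res_id)
             for a in base.atoms]
    return pm.ChainEntry(sid, "A", base.sequence, atoms, ca,
                         list(ligands or []))


@pytest.fixture(scope="module")
def three_pocket_toy():
    spec = synth.FixtureSpec(seed=21, n_residues=60, n_pockets=3,
                             ligand_size=10, structure_id="merge3")
    return synth.make_toy_protein(spec).entry


class TestSuperpose:
    def test_identical_chains(self, three_pocket_toy):
        sup = lm.superpose(three_pocket_toy, three_pocket_toy)
        assert sup is not None and sup.rmsd < 1e-9

    def test_gate_on_sequence_similarity(self, three_pocket_toy):
        other = pm.ChainEntry("x", "A", "W" * 60, three_pocket_toy.atoms,
                              three_pocket_toy.ca_coords)
        assert lm.superpose(three_pocket_toy, other) is None


class TestMergeCluster:
    def test_rmsd_gate_strict_at_2(self, three_pocket_toy):
        base = three_pocket_toy
        ligs = base.ligands
        ref = pm.ChainEntry("ref", "A", base.sequence, base.atoms,
                            base.ca_coords, [ligs[0]])
        near = _chain_with_noise(base, 0.5, "near", [ligs[1]])
        far = _chain_with_noise(base, 2.5, "far", [ligs[2]])
        reps = lm.merge_cluster([ref, near, far])
        by_id = {r.structure_id: r for r in reps}
        assert "ref" in by_id
        # the 0.5 A chain merges in, the 2.5 A chain stays separate
        assert len(by_id["ref"].ligands) == 2
        assert "far" in by_id and len(by_id["far"].ligands) == 1

    def test_fig2_scenario_shared_plus_unique_ligands(self, three_pocket_toy):
        base = three_pocket_toy
        shared, u1, u2 = base.ligands
        c1 = pm.ChainEntry("c1", "A", base.sequence, base.atoms,
                           base.ca_coords, [shared, u1])
        shared_copy = pm.Ligand(shared.het_id,
                                [pm.Atom(a.element, a.coords.copy(),
                                         name=a.name, res_name=a.res_name,
                                         res_id=a.res_id)
                                 for a in shared.atoms],
                                res_seq=shared.res_seq)
        c2 = pm.ChainEntry("c2", "A", base.sequence, base.atoms,
                           base.ca_coords, [shared_copy, u2])
        reps = lm.merge_cluster([c1, c2])
        assert len(reps) == 1
        # shared ligand transplant clashes with the kept copy and is dropped
        assert len(reps[0].ligands) == 3

    def test_all_chains_accounted_for_and_ref_coords_unchanged(
            self, three_pocket_toy):
        base = three_pocket_toy
        chains = [pm.ChainEntry(f"c{i}", "A", base.sequence, base.atoms,
                                base.ca_coords, [base.ligands[i]])
                  for i in range(3)]
        before = base.ca_coords.copy()
        reps = lm.merge_cluster(chains)
        assert sum(len(r.ligands) for r in reps) == 3
        for r in reps:
            assert np.array_equal(r.ca_coords, before)

    def test_transplanted_ligand_keeps_source(self, three_pocket_toy):
        base = three_pocket_toy
        lig = base.ligands[1]
        lig.source = "donor_A"
        ref = pm.ChainEntry("ref", "A", base.sequence, base.atoms,
                            base.ca_coords, [base.ligands[0]])
        donor = pm.ChainEntry("donor", "A", base.sequence, base.atoms,
                              base.ca_coords, [lig])
        reps = lm.merge_cluster([ref, donor])
        assert len(reps) == 1
        sources = {l.source for l in reps[0].ligands}
        assert "donor_A" in sources

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            lm.merge_cluster([])


def test_sort_chains_orders_by_ligand_information(three_pocket_toy):
    base = three_pocket_toy
    rich = pm.ChainEntry("rich", "A", base.sequence, base.atoms,
                         base.ca_coords, base.ligands[:2])
    poor = pm.ChainEntry("poor", "A", base.sequence, base.atoms,
                         base.ca_coords, base.ligands[:1])
    assert [c.structure_id for c in lm.sort_chains([poor, rich])] \
        == ["rich", "poor"]
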