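import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from conftest import brute_force_rmsd
from enzymd import synthetic_data as sd
from enzymd import trajectory_features as tf
from enzymd.io_formats import StructureModel, TrajectoryData


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).standard_normal((6, 3))
        rot, trans, rmsd = tf.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((5, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + [3.0, -1.0, 2.0]
        _, _, rmsd = tf.kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_displaced_atom_matches_brute_force(self):
        rng = np.random.default_rng(2)
        ref = rng.standard_normal((4, 3)) * 2
        mob = ref.copy()
        mob[2] += [1.0, 0.0, 0.0]
        _, _, rmsd = tf.kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(brute_force_rmsd(mob, ref), abs=1e-6)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(12):
            ref = rng.standard_normal((5, 3)) * 3
            mob = ref + 0.5 * rng.standard_normal((5, 3))
            _, _, rmsd = tf.kabsch_superpose(mob, ref)
            assert rmsd == pytest.approx(brute_force_rmsd(mob, ref), abs=1e-6)

    def test_transform_is_applied_correctly(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal((7, 3))
        mob = ref + 0.1 * rng.standard_normal((7, 3))
        rot, trans, rmsd = tf.kabsch_superpose(mob, ref)
        fitted = mob @ rot.T + trans
        assert np.sqrt(((fitted - ref) ** 2).sum(1).mean()) == pytest.approx(
            rmsd, abs=1e-10)

    def test_degenerate_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            tf.kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            tf.kabsch_superpose(line[:2], line[:2])


def _toy_traj(structure, frames):
    return TrajectoryData(np.asarray(frames, dtype=float), 100.0, structure)


class TestSeries:
    def test_frozen_trajectory_zero_rmsd(self, small_template):
        s, _ = small_template
        traj = _toy_traj(s, np.repeat(s.coords[None], 4, axis=0))
        np.testing.assert_allclose(tf.rmsd_series(traj, s), 0.0, atol=1e-9)

    def test_translation_removed(self, small_template):
        s, _ = small_template
        traj = _toy_traj(s, [s.coords + [10.0, 0.0, 0.0]])
        assert tf.rmsd_series(traj, s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_invariant_to_global_rigid_motion(self, small_template):
        rng = np.random.default_rng(5)
        s, _ = small_template
        frames = s.coords[None] + 0.4 * rng.standard_normal((3, s.n_atoms, 3))
        base = tf.rmsd_series(_toy_traj(s, frames), s)
        R = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
        moved = frames @ R.T + np.array([4.0, 5.0, -6.0])
        np.testing.assert_allclose(
            tf.rmsd_series(_toy_traj(s, moved), s), base, atol=1e-8
        )

    def test_rog_dumbbell(self):
        s = StructureModel(["C1", "C2"], ["C", "C"], [1, 2], ["LIG", "LIG"],
                           ["A", "A"], [[0, 0, 0], [2.0, 0, 0]])
        s.ligand_flag[:] = False
        traj = _toy_traj(s, s.coords[None])
        assert tf.rog_series(traj)[0] == pytest.approx(1.0)

    def test_rog_single_atom_zero(self):
        s = StructureModel(["C1"], ["C"], [1], ["ALA"], ["A"], [[1.0, 2, 3]])
        assert tf.rog_series(_toy_traj(s, s.coords[None]))[0] == 0.0

    def test_rog_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        coords = rng.standard_normal((10, 3)) * 4
        elements = list("CNOSC") * 2
        s = StructureModel([f"X{i}" for i in range(10)], elements,
                           np.arange(1, 11), ["ALA"] * 10, ["A"] * 10, coords)
        rog = tf.rog_series(_toy_traj(s, coords[None]))[0]
        m = np.array([tf.ATOMIC_MASS[e] for e in elements])
        com = (m[:, None] * coords).sum(0) / m.sum()
        direct = np.sqrt((m * ((coords - com) ** 2).sum(1)).sum() / m.sum())
        assert rog == pytest.approx(direct, rel=1e-12)


class TestRMSF:
    def test_frozen_zero(self, small_template):
        s, _ = small_template
        traj = _toy_traj(s, np.repeat(s.coords[None], 5, axis=0))
        np.testing.assert_allclose(tf.rmsf(traj), 0.0, atol=1e-9)

    def test_alternating_atom(self):
        # one atom alternating +-a along x among many anchored atoms
        rng = np.random.default_rng(7)
        base = rng.standard_normal((60, 3)) * 5
        a = 0.8
        frames = np.repeat(base[None], 200, axis=0)
        frames[::2, 0, 0] += a
        frames[1::2, 0, 0] -= a
        s = StructureModel([f"CA" for _ in range(60)], ["C"] * 60,
                           np.arange(1, 61), ["ALA"] * 60, ["A"] * 60, base)
        out = tf.rmsf(_toy_traj(s, frames), tf.AtomSelection("calpha"))
        assert out[0] == pytest.approx(a, rel=0.05)

    def test_invariant_to_global_rigid_motion(self, small_template):
        rng = np.random.default_rng(8)
        s, _ = small_template
        frames = s.coords[None] + 0.3 * rng.standard_normal((6, s.n_atoms, 3))
        base = tf.rmsf(_toy_traj(s, frames))
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        np.testing.assert_allclose(
            tf.rmsf(_toy_traj(s, frames @ R.T + [1, 2, 3])), base, atol=1e-8
        )


def _antiparallel_pair():
    """Two ideal extended strands placed antiparallel with registered
    hydrogen bonds (rigid placement found once by maximizing the inter-
    strand Kabsch-Sander bond count)."""
    s, _ = sd.make_template(8, sheet_spans=[(1, 8)], seed=0)
    mask = ~s.ligand_flag
    coords_a = s.coords[mask]
    flip = np.diag([1.0, -1.0, -1.0])
    coords_b = coords_a @ flip.T + np.array([0.75, 6.0, 2.0])
    names = [n for n, f in zip(s.atom_names, s.ligand_flag) if not f]
    elements = [e for e, f in zip(s.elements, s.ligand_flag) if not f]
    rids = list(s.residue_ids[mask]) + [r + 8 for r in s.residue_ids[mask]]
    rnames = [r for r, f in zip(s.residue_names, s.ligand_flag) if not f]
    return StructureModel(names * 2, elements * 2, np.array(rids), rnames * 2,
                          ["A"] * len(rids), np.vstack([coords_a, coords_b]))


class TestSecondaryStructure:
    def test_short_chain_has_no_helix(self):
        s, _ = sd.make_template(4, helix_spans=[(1, 4)], seed=0)
        labels = tf.assign_secondary_structure(s.coords, s)
        assert "H" not in labels

    def test_ideal_helix_interior_is_h(self):
        # proline-free sequence: Pro cannot donate the amide hydrogen
        s, _ = sd.make_template(30, helix_spans=[(5, 24)], seed=1,
                                sequence="A" * 30)
        labels = tf.assign_secondary_structure(s.coords, s)
        assert all(lab == "H" for lab in labels[7:21])
        # the i -> i+4 energies inside the span are bona fide bonds
        bb = tf.BackboneIndex(s)
        hb = tf._hbond_matrix(s.coords, bb)
        assert all(hb[i, i + 4] for i in range(6, 18))

    def test_antiparallel_strands_labelled(self):
        s = _antiparallel_pair()
        labels = tf.assign_secondary_structure(s.coords, s)
        assert (labels[:8] == "E_anti").any()
        assert (labels[8:] == "E_anti").any()
        assert "E_para" not in labels

    def test_helix_fraction_decreases_with_perturbation(self):
        s, _ = sd.make_template(24, helix_spans=[(1, 24)], seed=2)
        bb = tf.BackboneIndex(s)
        rng = np.random.default_rng(9)
        amplitudes = rng.uniform(0.0, 0.8, size=300)
        fractions = []
        for a in amplitudes:
            coords = s.coords + a * rng.standard_normal(s.coords.shape)
            labels = tf.assign_secondary_structure(coords, bb)
            fractions.append((labels == "H").mean())
        rho, _ = spearmanr(amplitudes, fractions)
        assert rho < -0.5


class TestSSFractions:
    def test_coil_chain(self):
        s, _ = sd.make_template(10, seed=3)
        # fully randomized loops: no helix span, fractions live in coil/bend
        traj = _toy_traj(s, s.coords[None])
        df, summ = tf.ss_fractions(traj)
        assert df["h_alpha"].iloc[0] == 0.0
        assert df.iloc[0].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_every_frame(self, small_template,
                                              small_spec, small_replicates):
        _, reps = small_replicates
        df, _ = tf.ss_fractions(reps[0])
        np.testing.assert_allclose(df.sum(axis=1), 1.0, atol=1e-12)

    def test_helix_template_fraction_matches_labels(self, small_template):
        s, _ = small_template
        traj = _toy_traj(s, s.coords[None])
        df, _ = tf.ss_fractions(traj)
        labels = tf.assign_secondary_structure(s.coords, s)
        assert df["h_alpha"].iloc[0] == pytest.approx((labels == "H").mean())


class TestMDFeatureBlock:
    def test_width_is_32(self, small_template, small_replicates):
        s, _ = small_template
        _, reps = small_replicates
        block = tf.md_feature_block(reps, s)
        assert len(block) == 32

    def test_frozen_replicates_zero_rmsd(self, small_template):
        s, _ = small_template
        frames = np.repeat(s.coords[None], 3, axis=0)
        reps = [_toy_traj(s, frames), _toy_traj(s, frames)]
        block = tf.md_feature_block(reps, s)
        for name, value in block.items():
            if name.startswith("rmsd"):
                assert value == pytest.approx(0.0, abs=1e-9), name

    def test_replicate_order_invariance(self, small_template, small_replicates):
        s, _ = small_template
        _, reps = small_replicates
        a = tf.md_feature_block(reps, s)
        b = tf.md_feature_block(list(reversed(reps)), s)
        for name in a:
            assert a[name] == pytest.approx(b[name]), name
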