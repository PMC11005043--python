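import numpy as np
import pytest
from scipy import stats

from enzymd import robustness_stats as rs
from enzymd import trajectory_features as tf
from enzymd.io_formats import StructureModel, TrajectoryData


def _cloud_structure(n=6, seed=0):
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((n, 3)) * 3
    return StructureModel([f"CA" for _ in range(n)], ["C"] * n,
                          np.arange(1, n + 1), ["ALA"] * n, ["A"] * n, coords)


class TestChunking:
    def test_exact_single_chunk(self):
        s = _cloud_structure()
        traj = TrajectoryData(np.repeat(s.coords[None], 100, 0), 100.0, s)
        chunks = rs.chunk_trajectory(traj, chunk_ns=10.0)
        assert len(chunks) == 1 and chunks[0].n_frames == 100

    def test_1001_frames_at_10ps_drops_one(self):
        s = _cloud_structure()
        traj = TrajectoryData(np.repeat(s.coords[None], 1001, 0), 10.0, s)
        chunks = rs.chunk_trajectory(traj, chunk_ns=10.0)
        assert len(chunks) == 1 and chunks[0].n_frames == 1000

    def test_concatenation_recovers_prefix(self):
        rng = np.random.default_rng(1)
        s = _cloud_structure()
        frames = s.coords[None] + rng.standard_normal((95, s.n_atoms, 3))
        traj = TrajectoryData(frames, 100.0, s)
        chunks = rs.chunk_trajectory(traj, chunk_ns=3.0)  # 30-frame chunks
        joined = np.concatenate([c.frames for c in chunks])
        np.testing.assert_array_equal(joined, frames[:90])

    def test_chunk_longer_than_trajectory_rejected(self):
        s = _cloud_structure()
        traj = TrajectoryData(np.repeat(s.coords[None], 5, 0), 100.0, s)
        with pytest.raises(ValueError):
            rs.chunk_trajectory(traj, chunk_ns=10.0)


class TestAnova:
    def test_identical_groups(self):
        res = rs.anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_decomposition(self):
        res = rs.anova_oneway([np.array([1.0, 2, 3]), np.array([2.0, 3, 4])])
        assert res["F"] == pytest.approx(1.5)
        assert res["p"] == pytest.approx(stats.f.sf(1.5, 1, 4))

    def test_location_invariance(self):
        g = [np.array([1.0, 2, 5]), np.array([2.0, 4, 4.5])]
        a = rs.anova_oneway(g)
        b = rs.anova_oneway([x + 100 for x in g])
        assert a["F"] == pytest.approx(b["F"])

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.standard_normal(8), rng.standard_normal(9) + 0.3
            f = rs.anova_oneway([a, b])["F"]
            t, _ = stats.ttest_ind(a, b)
            assert f == pytest.approx(t**2, rel=1e-10)

    def test_degenerate_constant_input(self):
        res = rs.anova_oneway([np.full(3, 2.0), np.full(4, 2.0)])
        assert (res["F"], res["p"]) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            rs.anova_oneway([np.array([1.0, 2.0])])


class TestChunkAnovaMatrix:
    def test_step_drift_detected(self):
        rng = np.random.default_rng(3)
        series = []
        for _ in range(3):
            s = rng.normal(1.0, 0.1, 200)
            s[100:] += 1.0  # drift from chunk 3 onwards
            series.append(s)
        p, sig = rs.chunk_anova_matrix({"v": series}, frames_per_chunk=50)
        assert p.shape == (3, 1)
        assert not sig.loc["chunk2", "v"]
        assert sig.loc["chunk3", "v"] and sig.loc["chunk4", "v"]

    def test_replicate_means_mode(self):
        rng = np.random.default_rng(4)
        series = [rng.normal(1.0, 0.1, 100) for _ in range(5)]
        p, _ = rs.chunk_anova_matrix({"v": series}, frames_per_chunk=25,
                                     mode="replicate_means")
        assert p.shape == (3, 1)
        assert ((p >= 0) & (p <= 1)).all().all()


class TestHausdorff:
    def test_identical_paths_zero(self):
        rng = np.random.default_rng(5)
        P = rng.standard_normal((3, 6, 3))
        assert rs.hausdorff_distance(P, P).delta_h == pytest.approx(0.0,
                                                                    abs=1e-7)

    def test_subset_property(self):
        rng = np.random.default_rng(6)
        Q = rng.standard_normal((5, 6, 3))
        P = Q[:3]
        d = rs.hausdorff_distance(P, Q)
        assert d.directed_pq == pytest.approx(0.0, abs=1e-7)
        assert d.delta_h == pytest.approx(d.directed_qp)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            fp, fq = rng.integers(1, 6, size=2)
            P = rng.standard_normal((fp, 5, 3)) * 2
            Q = rng.standard_normal((fq, 5, 3)) * 2
            d = rs.hausdorff_distance(P, Q)
            m = np.array([[tf.kabsch_superpose(P[i], Q[j])[2]
                           for j in range(fq)] for i in range(fp)])
            expect = max(m.min(axis=1).max(), m.min(axis=0).max())
            assert d.delta_h == pytest.approx(expect, abs=1e-9)
            assert d.delta_h == max(d.directed_pq, d.directed_qp)

    def test_symmetry_and_triangle_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            paths = [rng.standard_normal((3, 5, 3)) * 2 for _ in range(3)]
            d01 = rs.hausdorff_distance(paths[0], paths[1]).delta_h
            d10 = rs.hausdorff_distance(paths[1], paths[0]).delta_h
            d02 = rs.hausdorff_distance(paths[0], paths[2]).delta_h
            d12 = rs.hausdorff_distance(paths[1], paths[2]).delta_h
            assert d01 == pytest.approx(d10, abs=1e-9)
            assert d02 <= d01 + d12 + 1e-9


class TestPSA:
    def test_matrix_properties_and_duplicates(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((3, 5, 3)) * 2
        b = a + 10 * rng.standard_normal((3, 5, 3))
        dist, order = rs.psa_matrix([a, a.copy(), b])
        np.testing.assert_allclose(dist, dist.T)
        np.testing.assert_allclose(np.diag(dist), 0.0)
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-7)
        assert len(order) == 3

    def test_two_separated_pairs_cluster_together(self):
        rng = np.random.default_rng(10)
        base1 = rng.standard_normal((3, 5, 3))
        base2 = base1 + 30.0 * rng.standard_normal((3, 5, 3))
        paths = [base1, base1 + 0.01, base2, base2 + 0.01]
        dist, order = rs.psa_matrix(paths)
        order = list(order)
        pos = {i: order.index(i) for i in range(4)}
        assert abs(pos[0] - pos[1]) == 1
        assert abs(pos[2] - pos[3]) == 1


@pytest.mark.parametrize("value,expected", [
    (0.3, "identical"), (2.16, "intermediate"), (3.5, "highly_different"),
    (0.0, "identical"), (0.5, "intermediate"), (3.0, "intermediate"),
])
def test_similarity_bands(value, expected):
    assert rs.classify_similarity(value) == expected


def test_similarity_rejects_negative():
    with pytest.raises(ValueError):
        rs.classify_similarity(-0.1)


class TestRetention:
    def test_distinct_amplitudes_retained(self):
        rng = np.random.default_rng(11)
        series = [np.abs(rng.normal(1.0, 0.1, 100)),
                  np.abs(rng.normal(1.5, 0.1, 100)),
                  np.abs(rng.normal(2.0, 0.1, 100))]
        res = rs.retention_shuffle_test(series, seed=0)
        assert res["retained"] and res["anova_p"] < 0.05
        assert res["fold_means"].shape == (20, 3)

    def test_identical_replicates_give_f_zero(self):
        rng = np.random.default_rng(12)
        s = rng.normal(1.0, 0.1, 100)
        res = rs.retention_shuffle_test([s, s.copy()], seed=0)
        assert res["anova_p"] == pytest.approx(1.0)
        assert not res["retained"]
        np.testing.assert_allclose(res["fold_means"]["rep1"],
                                   res["fold_means"]["rep2"])


class TestChooseMinLength:
    def _matrix(self, values):
        import pandas as pd

        arr = np.asarray(values, dtype=float)
        return pd.DataFrame(arr, index=[f"chunk{i + 2}" for i in
                                        range(arr.shape[0])],
                            columns=[f"v{i}" for i in range(arr.shape[1])])

    def test_all_agree_gives_first_length(self):
        res = rs.choose_min_length(self._matrix(np.full((5, 10), 0.9)))
        assert res["chunk_index"] == 1 and res["length_ns"] == 10.0

    def test_no_agreement_gives_longest_with_warning(self):
        with pytest.warns(UserWarning):
            res = rs.choose_min_length(self._matrix(np.full((5, 10), 0.001)))
        assert res["chunk_index"] == 6 and res["warning"]

    def test_partial_agreement_prefix(self):
        p = np.full((6, 10), 0.5)
        p[4:, :3] = 0.001  # 30% of variants break after chunk 5
        res = rs.choose_min_length(self._matrix(p))
        assert res["chunk_index"] == 5
        assert res["length_ns"] == 50.0
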