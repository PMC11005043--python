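import warnings

import numpy as np
import pytest

from enzymd import synthetic_data as sd
from enzymd import experiments as ex


@pytest.fixture(scope="session")
def small_template():
    """40-residue template with one helix, plus its sequence."""
    structure, seq = sd.make_template(
        40, helix_spans=[(10, 29)], seed=7, ligand_anchor_residues=(19, 20, 21)
    )
    return structure, seq


@pytest.fixture(scope="session")
def small_spec():
    return sd.SynthSpec(
        n_variants=6, hot_positions=list(range(5, 35)), replicates=2,
        frames_per_traj=12, dt_ps=100.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_replicates(small_template, small_spec):
    structure, seq = small_template
    variants = sd.make_variant_library(small_spec, seq)
    reps = sd.simulate_replicates(variants[1], structure, small_spec, 1)
    return variants, reps


@pytest.fixture(scope="session")
def schema20():
    """Full-featurization run on a 20-variant library, timed (shared by the
    schema acceptance checks)."""
    import time

    t0 = time.perf_counter()
    summary = ex.schema_summary(seed=0, n_variants=20)
    summary["seconds"] = time.perf_counter() - t0
    return summary


@pytest.fixture(scope="session")
def recovery300():
    """The planted-response recovery library: 300 variants, SEQ+MD blocks,
    5 replicate trajectories each (shared by the recovery acceptance
    checks)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, spec = ex.recovery_library(seed=1, n_variants=300)
    return table, spec


def rigid_transform(rng):
    """Random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.standard_normal(3) * 5.0


def brute_force_rmsd(mobile, reference, n_starts=60, seed=0):
    """Independent minimum-RMSD oracle: coarse random-quaternion grid
    followed by local refinement of the rotation vector."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(0)
    ref = reference - reference.mean(0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((mob @ R.T - ref) ** 2).sum(1).mean())

    rng = np.random.RandomState(seed)
    starts = Rotation.random(n_starts, random_state=rng).as_rotvec()
    best = np.inf
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 2000})
        best = min(best, res.fun)
    return best
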