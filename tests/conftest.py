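import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published():
    """The packaged reference-table transcriptions."""
    from conpath_dms import fixtures

    return fixtures.make_reference_fixtures()


@pytest.fixture(scope="session")
def toy_reference():
    from conpath_dms.synthetic import toy_dimer

    return toy_dimer()


def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray, seed: int = 0) -> float:
    """Independent oracle: minimum RMSD over rigid motions by multi-start
    rotation-vector search (centroids aligned, Nelder-Mead refinement)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rotvec):
        mat = Rotation.from_rotvec(rotvec).as_matrix()
        diff = mob @ mat.T - ref
        return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)] + [
        Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_rotvec()
        for _ in range(40)
    ]
    best = np.inf
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best
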