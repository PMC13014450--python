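import numpy as np
import pytest

from thermotraj import synthetic as syn


@pytest.fixture(scope="session")
def helix12():
    return syn.build_ideal_helix(12)


@pytest.fixture(scope="session")
def hairpin5():
    return syn.build_beta_hairpin(5)


@pytest.fixture(scope="session")
def strand8():
    return syn.build_extended_strand(8)


@pytest.fixture(scope="session")
def toy_protein():
    spec = syn.ToyProteinSpec(
        n_helix=12,
        n_per_strand=5,
        charge_pairs=[
            syn.ChargePair(2, "LYS", 15, "ASP", 3.5),
            syn.ChargePair(6, "ARG", 19, "GLU", 3.8),
        ],
    )
    return syn.build_toy_protein(spec)


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle: nested grid search over rotations.

    Translations are removed by centering (optimal for unweighted RMSD);
    the rotation is found by refining a ZYZ Euler-angle grid.  Accurate to
    well below 1e-3 Å on small point sets.
    """
    from scipy.spatial.transform import Rotation

    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_for(rotvec):
        rot = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((rot.apply(m) - r) ** 2, axis=1)))

    # grid over rotation vectors (no gimbal degeneracy), nested refinement
    best_vec = np.zeros(3)
    step = np.pi / 4
    best = np.inf
    candidate = best_vec
    for _ in range(16):
        grid = np.arange(-4, 5) * step
        for a in best_vec[0] + grid:
            for b in best_vec[1] + grid:
                for c in best_vec[2] + grid:
                    v = rmsd_for(np.array([a, b, c]))
                    if v < best:
                        best = v
                        candidate = np.array([a, b, c])
        best_vec = candidate
        step /= 3.0
    return float(best)
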