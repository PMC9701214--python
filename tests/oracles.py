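"""Independent oracles used by several test modules.

Kept free of the implementation paths they verify: the rigid-motion oracle
searches Euler angles numerically instead of using the SVD solution, and
the PCA oracle diagonalizes the covariance matrix directly.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rigid_motion_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rigid motions by Euler-angle search.

    For a fixed rotation the optimal translation aligns centroids, so the
    search is over the 3 Euler angles only: a coarse grid followed by
    Nelder-Mead refinement from the best grid point.
    """
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    def rmsd_at(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        delta = mob_c @ rot.T - ref_c
        return float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))

    grid = np.arange(-180.0, 180.0, 20.0)
    best_angles, best = None, np.inf
    for a in grid:
        for b in np.arange(-90.0, 90.1, 20.0):
            for c in grid:
                v = rmsd_at((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)
    res = minimize(rmsd_at, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def gaussian_radial_profile_error(fes, counts: np.ndarray, min_count: int = 100,
                                  shell_width: float = 0.25) -> float:
    """Max |radial free-energy profile - r^2/2| for a standard 2-D Gaussian.

    Boltzmann inversion of the unit isotropic Gaussian density gives
    F(r) = r^2/2 (kT) up to the minimum shift.  Azimuthal averaging over
    radial shells removes per-bin Poisson noise, so the profile converges to
    the analytic parabola where shells are well populated
    (counts >= min_count per contributing bin).
    """
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    r = np.sqrt(xx**2 + yy**2)
    well = counts >= min_count
    shells = np.floor(r / shell_width).astype(int)
    profile_r, profile_f = [], []
    for s in np.unique(shells[well]):
        in_shell = well & (shells == s)
        profile_r.append(float(np.mean(r[in_shell])))
        profile_f.append(float(np.mean(fes.grid[in_shell])))
    profile_r = np.array(profile_r)
    profile_f = np.array(profile_f)
    analytic = profile_r**2 / 2.0
    # both profiles are minimum-shifted to zero before comparison
    return float(np.max(np.abs((profile_f - profile_f.min())
                               - (analytic - analytic.min()))))


def pca_by_eigendecomposition(pooled: np.ndarray, k: int = 2):
    """Standard-scale (population std) then diagonalize the covariance.

    Returns (eigenvalues desc, components with largest-|loading| positive).
    """
    scaled = (pooled - pooled.mean(axis=0)) / pooled.std(axis=0)
    cov = np.cov(scaled, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    comps = v[:, :k].T.copy()
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return w, comps
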