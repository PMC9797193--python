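"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is deliberately written the slow, obvious way (explicit loops,
direct likelihood evaluation, plain Monte Carlo) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.optimize import minimize


def smoothed_perimeter_loop(vertices: np.ndarray, halfwidth: int) -> float:
    """Perimeter after +-halfwidth periodic vertex averaging, via explicit loops."""
    n = len(vertices)
    sm = np.zeros_like(vertices, dtype=float)
    for i in range(n):
        acc = np.zeros(2)
        for j in range(-halfwidth, halfwidth + 1):
            acc += vertices[(i + j) % n]
        sm[i] = acc / (2 * halfwidth + 1)
    total = 0.0
    for i in range(n):
        total += float(np.linalg.norm(sm[(i + 1) % n] - sm[i]))
    return total


def mc_polygon_area(vertices: np.ndarray, n_points: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo point-in-polygon area estimate."""
    rng = np.random.default_rng(seed)
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = MplPath(vertices).contains_points(pts)
    box = float(np.prod(hi - lo))
    return box * inside.mean()


def ml_lme_loglik(theta_log_sd, y, X, Z_list):
    """Negative marginal ML log-likelihood at log-SD parameters (last = residual)."""
    sds = np.exp(np.asarray(theta_log_sd))
    n = len(y)
    V = sds[-1] ** 2 * np.eye(n)
    for sd, Z in zip(sds[:-1], Z_list):
        V += sd**2 * (Z @ Z.T)
    sign, logdet = np.linalg.slogdet(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    q = float(r @ np.linalg.solve(V, r))
    return 0.5 * (logdet + q + n * np.log(2 * np.pi)), beta


def ml_lme_oracle(y, X, Z_list):
    """Direct maximum-likelihood fit by multi-start simplex over log-SDs.

    Returns (loglik, beta, sds).  Independent of any mixed-model library.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = len(Z_list) + 1
    sd_y = float(np.std(y, ddof=1))
    starts = [
        np.log(np.r_[np.full(k - 1, f * sd_y), sd_y])
        for f in (0.05, 0.2, 0.5)
    ] + [np.log(np.r_[np.full(k - 1, 1e-4 * sd_y), sd_y])]
    best = None
    for t0 in starts:
        res = minimize(
            lambda t: ml_lme_loglik(t, y, X, Z_list)[0],
            t0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 6000, "maxfev": 9000},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll, beta = ml_lme_loglik(best.x, y, X, Z_list)
    return -nll, beta, np.exp(best.x)


def mc_max_abs_z_adjusted(z_values, corr, n_draws: int = 1_000_000, seed: int = 0):
    """Monte-Carlo single-step adjusted p-values: 1 - P(max_j |Z_j| <= |z_i|)."""
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(np.asarray(corr, dtype=float))
    A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Z = rng.standard_normal((n_draws, len(corr))) @ A.T
    maxabs = np.abs(Z).max(axis=1)
    return np.array([float(np.mean(maxabs > abs(z))) for z in np.atleast_1d(z_values)])


def voxelized_mesh_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Marching-cubes surface area of a binary volume (z, y, x order)."""
    from skimage.measure import marching_cubes, mesh_surface_area

    verts, faces, _, _ = marching_cubes(mask.astype(float), 0.5, spacing=spacing)
    return float(mesh_surface_area(verts, faces))
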