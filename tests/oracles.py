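"""Independent reference implementations used to cross-check the package.

Every function here deliberately avoids the code paths it validates:
convolution by fine-grid quadrature instead of the analytic exp*erfc form,
stiff ODE integration instead of eigendecomposition, dense least squares
instead of variable projection, Monte-Carlo rejection sampling instead of
grid flood fill, and a projection-based dihedral instead of the
cross-product construction.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from photokin.kinetics import KineticScheme, rate_matrix


def convolved_exponential(k: float, t: float, mu: float, sigma: float,
                          dt: float = 1e-5) -> float:
    """exp(-k t) (x) normalized Gaussian, by trapezoidal quadrature."""
    lo = mu - 10.0 * sigma
    if t <= lo:
        return 0.0
    tp = np.linspace(lo, t, max(int((t - lo) / dt), 10) + 1)
    gauss = np.exp(-((tp - mu) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
    return float(np.trapezoid(gauss * np.exp(-k * (t - tp)), tp))


def ode_concentrations(scheme: KineticScheme, delays: np.ndarray,
                       rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Populations by stiff integration of dc/dt = K c + IRF(t) p0."""
    K = rate_matrix(scheme)
    p0 = scheme.initial_vector()
    mu, sigma = scheme.irf_center, scheme.irf_sigma
    t0 = min(float(delays.min()), mu - 8.0 * sigma)

    def rhs(t, c):
        g = np.exp(-((t - mu) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        return K @ c + g * p0

    sol = solve_ivp(rhs, (t0, float(delays.max())), np.zeros(len(p0)),
                    method="Radau", t_eval=delays, rtol=rtol, atol=atol,
                    max_step=sigma / 2)  # never step over the IRF pulse
    assert sol.success
    return sol.y  # (n_comp, n_delay)


def dense_lstsq_spectra(C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-wavelength spectra by scipy dense least squares; D is
    (n_delay, n_wl); returns (n_wl, n_comp)."""
    from scipy.linalg import lstsq

    out = np.empty((D.shape[1], C.shape[1]))
    for j in range(D.shape[1]):
        out[j] = lstsq(C, D[:, j])[0]
    return out


def mc_pocket_volume(occluders: np.ndarray, radii: np.ndarray, seed_point: np.ndarray,
                     search_radius: float, probe: float, n_samples: int,
                     rng: np.random.Generator) -> float:
    """Volume of {x : |x - seed| <= R, dist(x, atom_i) > r_i + probe} by
    rejection sampling (valid when that region is connected)."""
    pts = rng.uniform(-search_radius, search_radius, size=(n_samples, 3))
    inside = np.einsum("ij,ij->i", pts, pts) <= search_radius**2
    pts = pts[inside] + seed_point
    free = np.ones(len(pts), dtype=bool)
    for atom, r in zip(occluders, radii):
        free &= np.linalg.norm(pts - atom, axis=1) > (r + probe)
    cube = (2.0 * search_radius) ** 3
    return cube * free.sum() / n_samples


def projection_dihedral(p: np.ndarray) -> float:
    """Signed dihedral (deg) via projection onto the plane normal to the
    central bond — independent of the cross-product construction."""
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    e2 = b2 / np.linalg.norm(b2)
    # project -b1 and b3 onto the plane perpendicular to the central bond
    u = -b1 + np.dot(b1, e2) * e2
    w = b3 - np.dot(b3, e2) * e2
    cos = np.dot(u, w)
    sin = np.dot(np.cross(u, w), e2)
    return float(np.degrees(np.arctan2(sin, cos)))


def random_scheme(rng: np.random.Generator, n_transient: int = 4,
                  reversible: bool = True) -> KineticScheme:
    """A random valid reversible chain scheme (real eigenvalues guaranteed
    for tridiagonal rate structures)."""
    labels = tuple(f"S{i}" for i in range(n_transient)) + ("ground",)
    rates = {}
    for i in range(n_transient):
        nxt = labels[i + 1]
        rates[(labels[i], nxt)] = float(10 ** rng.uniform(-1.5, 0.3))
        if reversible and i + 1 < n_transient and rng.random() < 0.5:
            rates[(nxt, labels[i])] = float(10 ** rng.uniform(-1.5, 0.0))
    pops = {labels[0]: 0.7, labels[1]: 0.3}
    return KineticScheme(labels, rates, pops, irf_center=0.0,
                         irf_fwhm=float(rng.uniform(0.06, 0.2)))
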