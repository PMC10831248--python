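"""Independent reference implementations used to check the package's fast paths."""

import numpy as np


def fraction_bound_fixed_point(R, L, K, iters=10000, tol=1e-13):
    """Mass-action bound fraction via damped fixed-point iteration on the
    complex concentration (independent of the closed-form quadratic)."""
    C = 0.0
    for _ in range(iters):
        Lf = max(L - C, 0.0)
        g = R * Lf / (K + Lf)
        d = R * K / (K + Lf) ** 2  # local contraction rate
        alpha = 1.0 / (1.0 + d)
        C_new = (1 - alpha) * C + alpha * g
        C_new = min(max(C_new, 0.0), min(R, L))
        if abs(C_new - C) <= tol * max(1.0, C_new):
            C = C_new
            break
        C = C_new
    return C / R


def two_gaussian_mixture_density(x, mu1, mu2, w1, w2, sigma):
    """Analytic two-Gaussian mixture density, unit area for w1 + w2 = 1."""
    x = np.asarray(x, float)

    def pdf(mu):
        return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))

    return w1 * pdf(mu1) + w2 * pdf(mu2)


def grid_search_two_component(x, y, mu1_grid, mu2_grid, area_grid, sigma_eff):
    """Brute-force residual-norm minimization over the constraint box."""
    best = (np.inf, None)
    sq2pi = np.sqrt(2 * np.pi)
    for mu1 in mu1_grid:
        g1 = np.exp(-0.5 * ((x - mu1) / sigma_eff) ** 2) / (sigma_eff * sq2pi)
        for mu2 in mu2_grid:
            g2 = np.exp(-0.5 * ((x - mu2) / sigma_eff) ** 2) / (sigma_eff * sq2pi)
            for a1 in area_grid:
                resid_base = y - a1 * g1
                for a2 in area_grid:
                    r = float(np.linalg.norm(resid_base - a2 * g2))
                    if r < best[0]:
                        best = (r, (mu1, mu2, a1, a2))
    return best
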