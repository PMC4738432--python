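"""Independent reference implementations used only to check the package.

Each oracle re-derives a quantity by a different route (direct transcription,
normal equations, grid search, tree walking) and must stay decoupled from
the code paths it validates.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- regression

def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Slope/intercept of y on x via explicitly solved normal equations."""
    X = np.vstack([np.ones(len(x)), x]).T
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1]), float(beta[0])


def gls_direct(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """GLS coefficients by the direct matrix-inverse formula."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


# ----------------------------------------------------------------- Boltzmann

def boltzmann_grid_fit(t: np.ndarray, m: np.ndarray, n_grid: int = 60):
    """Grid-refined least squares for the falling Boltzmann sigmoid.

    For fixed (t0, dx) the model is linear in the asymptotes, so each grid
    point is solved in closed form; the best cell is then refined by
    Nelder-Mead.  Returns (A1, A2, t0, dx, rss).
    """
    from scipy.optimize import minimize

    def profile_rss(t0, dx):
        s = 1.0 / (1.0 + np.exp(np.clip((t - t0) / dx, -500, 500)))
        X = np.vstack([s, 1.0 - s]).T      # columns multiply A1 and A2
        coef, *_ = np.linalg.lstsq(X, m, rcond=None)
        rss = float(np.sum((X @ coef - m) ** 2))
        return rss, coef

    t0_grid = np.linspace(t[0], t[-1], n_grid)
    dx_grid = np.geomspace((t[1] - t[0]) * 2, (t[-1] - t[0]) / 2, n_grid)
    best = None
    for t0 in t0_grid:
        for dx in dx_grid:
            rss, coef = profile_rss(t0, dx)
            if best is None or rss < best[0]:
                best = (rss, t0, dx, coef)
    _, t0b, dxb, _ = best

    res = minimize(lambda p: profile_rss(p[0], abs(p[1]))[0], [t0b, dxb],
                   method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
    t0f, dxf = res.x[0], abs(res.x[1])
    rss, coef = profile_rss(t0f, dxf)
    return float(coef[0]), float(coef[1]), float(t0f), float(dxf), rss


def windowed_slope(t: np.ndarray, m: np.ndarray, center: float, half_width: float) -> float:
    """|slope| of the points within the window, by normal equations."""
    sel = (t >= center - half_width) & (t <= center + half_width)
    slope, _ = ols_normal_equations(t[sel], m[sel])
    return abs(slope)


# ----------------------------------------------------------------- Rothermel
# Independent transcription of the surface-spread equation chain, evaluated
# directly from SI inputs in one expression block.

def rothermel_spread_oracle(sav_si, heat_si, load_si, depth_si, mf, mx,
                            st, se, rho_p_si, wind_m_s=0.0, slope_frac=0.0):
    """Spread rate in m/min, transcribed equation by equation."""
    ft = 0.3048
    lb = 0.45359237                           # kg
    btu = 1.05505585262                       # kJ
    sigma = sav_si * ft                       # 1/m -> 1/ft
    w0 = load_si * 0.09290304 / lb            # kg/m^2 -> lb/ft^2 (sq ft exact)
    delta = depth_si / ft
    h = heat_si / (btu / lb)                  # kJ/kg -> Btu/lb
    rho_p = rho_p_si * 0.028316846592 / lb    # kg/m^3 -> lb/ft^3 (cu ft exact)
    U = wind_m_s / ft * 60.0                  # m/s -> ft/min

    rho_b = w0 / delta
    beta = rho_b / rho_p
    beta_op = 3.348 * sigma**-0.8189
    ratio = beta / beta_op
    g_max = sigma**1.5 / (495.0 + 0.0594 * sigma**1.5)
    A = 133.0 * sigma**-0.7913
    gamma = g_max * ratio**A * np.exp(A * (1.0 - ratio))
    wn = w0 / (1.0 + st)
    r = mf / mx
    eta_m = 0.0 if r >= 1.0 else max(0.0, min(1.0, 1.0 - 2.59 * r + 5.11 * r**2 - 3.52 * r**3))
    eta_s = min(1.0, 0.174 * se**-0.19)
    IR = gamma * wn * h * eta_m * eta_s
    xi = np.exp((0.792 + 0.681 * np.sqrt(sigma)) * (beta + 0.1)) / (192.0 + 0.2595 * sigma)
    eps = np.exp(-138.0 / sigma)
    Qig = 250.0 + 1116.0 * mf
    C = 7.47 * np.exp(-0.133 * sigma**0.55)
    B = 0.02526 * sigma**0.54
    E = 0.715 * np.exp(-3.59e-4 * sigma)
    phi_w = 0.0 if U == 0 else C * U**B * ratio**-E
    phi_s = 5.275 * beta**-0.3 * slope_frac**2
    R = IR * xi * (1.0 + phi_w + phi_s) / (rho_b * eps * Qig)
    if eta_m == 0.0:
        R = 0.0
    return R * ft                              # ft/min -> m/min


# -------------------------------------------------------------------- trees

def mrca_depth_matrix(tree):
    """Brownian covariance by brute-force ancestor-set intersection.

    For every tip pair, collects the full ancestor path of each and takes
    the deepest shared node's root distance.
    """
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: str(l.taxon.label))
    labels = [str(l.taxon.label).strip() for l in leaves]

    def path(node):
        out = [node]
        while out[-1].parent_node is not None:
            out.append(out[-1].parent_node)
        return out

    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        pi = path(leaves[i])
        set_i = set(id(nd) for nd in pi)
        V[i, i] = leaves[i].distance_from_root()
        for j in range(i + 1, n):
            for nd in path(leaves[j]):
                if id(nd) in set_i:
                    V[i, j] = V[j, i] = nd.distance_from_root()
                    break
    return labels, V
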