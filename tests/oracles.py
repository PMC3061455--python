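"""Independent reference implementations used only by the tests.

Each oracle follows a different route than the library code it checks:
brute-force loops, explicit matrix inverses, exhaustive enumeration, or —
for the spherical-conductor magnetic field — a Legendre-series surface
potential fed into a Geselowitz surface-integral quadrature.
"""

import itertools

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, lpmv

MU0 = 4e-7 * np.pi


# ---------------------------------------------------------------------------
# spherical-conductor field via surface-potential quadrature
# ---------------------------------------------------------------------------

def sphere_surface_potential(r_surf, r0, q, R, sigma=0.33, nmax=80):
    """Potential on the surface of a homogeneous conducting sphere (centre
    origin, radius R) from an internal current dipole, by the classic
    Legendre expansion in the dipole's own frame."""
    b = np.linalg.norm(r0)
    zhat = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    p_r = q @ zhat
    q_t = q - p_r * zhat
    pt = np.linalg.norm(q_t)
    if pt > 1e-15 * np.linalg.norm(q):
        xhat = q_t / pt
    else:
        xhat = np.array([1.0, 0.0, 0.0]) if abs(zhat[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        xhat = xhat - (xhat @ zhat) * zhat
        xhat /= np.linalg.norm(xhat)
    yhat = np.cross(zhat, xhat)
    rs = np.atleast_2d(r_surf)
    ct = np.clip(rs @ zhat / R, -1.0, 1.0)
    phi = np.arctan2(rs @ yhat, rs @ xhat)
    V = np.zeros(len(rs))
    for n in range(1, nmax + 1):
        Pn = eval_legendre(n, ct)
        Pn1 = lpmv(1, n, ct)  # includes the Condon-Shortley phase
        V += (2 * n + 1) / n * (b / R) ** (n - 1) * (
            n * p_r * Pn - pt * Pn1 * np.cos(phi)
        )
    return V / (4 * np.pi * sigma * R**2)


def sphere_field_quadrature(
    r_sensor, r0, q, R, sigma=0.33, ntheta=100, nphi=200, nmax=80
):
    """Magnetic field outside a homogeneous conducting sphere: primary
    Biot-Savart term plus the Geselowitz surface integral of the boundary
    potential, evaluated by Gauss-Legendre x trapezoid quadrature."""
    x, wgl = leggauss(ntheta)
    phi = 2 * np.pi * np.arange(nphi) / nphi
    wphi = 2 * np.pi / nphi
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1 - ct**2)
    pts = R * np.column_stack(
        [(st * np.cos(ph)).ravel(), (st * np.sin(ph)).ravel(), ct.ravel()]
    )
    w = (np.outer(wgl, np.ones(nphi)) * wphi * R**2).ravel()
    V = sphere_surface_potential(pts, r0, q, R, sigma, nmax)
    nrm = pts / R
    d = np.asarray(r_sensor, float)[None, :] - pts
    dn = np.linalg.norm(d, axis=1)
    kern = np.cross(nrm, d) / dn[:, None] ** 3
    B_vol = -MU0 * sigma / (4 * np.pi) * np.sum(w[:, None] * V[:, None] * kern, axis=0)
    dd = np.asarray(r_sensor, float) - r0
    B_p = MU0 / (4 * np.pi) * np.cross(q, dd) / np.linalg.norm(dd) ** 3
    return B_p + B_vol


# ---------------------------------------------------------------------------
# brute-force linear-algebra references
# ---------------------------------------------------------------------------

def naive_trial_covariance(data, idx):
    """Mean over trials of demeaned per-trial sample covariance (loops)."""
    nt, nc, _ = data.shape
    out = np.zeros((nc, nc))
    for t in range(nt):
        x = data[t][:, idx]
        x = x - x.mean(axis=1, keepdims=True)
        out += x @ x.T / len(idx)
    return out / nt


def naive_lcmv(L, R):
    """W = R^-1 L (L^T R^-1 L)^-1 with explicit inverses (full-rank L)."""
    Rinv = np.linalg.inv(R)
    return Rinv @ L @ np.linalg.inv(L.T @ Rinv @ L)


def naive_mn(L, G):
    return np.linalg.inv(G) @ L


def naive_dspm(L, G, Rnn):
    W = naive_mn(L, G)
    cols = []
    for k in range(W.shape[1]):
        w = W[:, k]
        cols.append(w / np.sqrt(w @ Rnn @ w))
    return np.column_stack(cols)


def naive_sloreta(L, G):
    Ginv = np.linalg.inv(G)
    S = L.T @ Ginv @ L
    evals, evecs = np.linalg.eigh(S)
    S_inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return Ginv @ L @ S_inv_sqrt


def exact_wilcoxon_z(diff):
    """Z from exhaustive sign enumeration: (W+ - mean)/sd over all 2^n
    assignments of signs to the midranks of |d| (zeros dropped)."""
    from scipy.stats import rankdata

    d = np.asarray(diff, float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.array(
        [
            sum(ri for ri, s in zip(r, signs) if s)
            for signs in itertools.product((0, 1), repeat=len(d))
        ],
        dtype=float,
    )
    sd = ws.std(ddof=0)
    if sd == 0:
        return 0.0
    return float((w_obs - ws.mean()) / sd)
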