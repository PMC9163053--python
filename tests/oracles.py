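"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch, without reusing the
package's code paths: a densely-refined Gauss double integral, a
latitude/longitude quadrature SASA, exhaustive hypergeometric enumeration for
the Fisher exact test, and the closed-form Welch statistic.
"""

from __future__ import annotations

import math

import numpy as np


def dense_gauss_integral(curve_a: np.ndarray, curve_b: np.ndarray,
                         refine: int = 100) -> float:
    """Gauss linking double integral between two polylines, each segment
    refined ``refine``-fold before summation."""
    def resample(c):
        pts = []
        for k in range(len(c) - 1):
            for s in range(refine):
                pts.append(c[k] + (c[k + 1] - c[k]) * s / refine)
        pts.append(c[-1])
        return np.array(pts)

    a, b = resample(np.asarray(curve_a)), resample(np.asarray(curve_b))
    ra, dra = 0.5 * (a[:-1] + a[1:]), np.diff(a, axis=0)
    rb, drb = 0.5 * (b[:-1] + b[1:]), np.diff(b, axis=0)
    total = 0.0
    chunk = 256  # bound peak memory of the pairwise tensors
    for lo in range(0, ra.shape[0], chunk):
        sep = ra[lo:lo + chunk, None, :] - rb[None, :, :]
        dist = np.linalg.norm(sep, axis=2)
        cross = np.cross(dra[lo:lo + chunk, None, :], drb[None, :, :])
        total += float((np.einsum("mnk,mnk->mn", sep, cross) / dist**3).sum())
    return total / (4.0 * np.pi)


def quadrature_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
                    n_theta: int = 60, n_phi: int = 120) -> np.ndarray:
    """Per-bead SASA by latitude/longitude surface quadrature (area weights
    sinθ dθ dφ), independent of the sphere-point sampling in the package."""
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                     np.cos(tt)], axis=-1).reshape(-1, 3)
    weights = (np.sin(tt) * (np.pi / n_theta) * (2 * np.pi / n_phi)).reshape(-1)
    n = coords.shape[0]
    out = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * dirs
        others = np.delete(np.arange(n), i)
        if others.size:
            d = np.linalg.norm(pts[:, None, :] - coords[others][None, :, :],
                               axis=2)
            exposed = ~(d < expanded[others][None, :]).any(axis=1)
        else:
            exposed = np.ones(pts.shape[0], dtype=bool)
        out[i] = expanded[i] ** 2 * weights[exposed].sum()
    return out


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_hyper(x):
        return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
                - math.lgamma(r2 - c1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.exp(log_hyper(x)) for x in range(lo, hi + 1)}
    observed = probs[a]
    return sum(p for p in probs.values() if p <= observed * (1 + 1e-9))


def welch_p(x, y) -> float:
    """Closed-form Welch unequal-variance two-sample t-test (two-sided)."""
    from scipy.stats import t as t_dist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t_stat = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(2.0 * t_dist.sf(abs(t_stat), df))


def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
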