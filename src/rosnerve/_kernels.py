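"""Numerical kernels for the explicit reaction-diffusion update.

The forward-Euler/central-difference (FTCS) update is written twice: a
compiled loop (numba, used whenever numba imports) and a vectorized numpy
fallback.  Both integrate

    c <- c + dt * ( div(D grad c) + RP - RS * c )

in flux form: the face flux between voxels a and b along an axis uses the
harmonic mean of their axis diffusion coefficients (zero if either side is
zero), divided by the squared voxel edge of that axis.  Domain boundaries
are no-flux, so with RP = RS = 0 the total amount is conserved to rounding.

Face coefficient arrays are precomputed (units 1/s):

    fx[i, j, k] = harm(Dxx[i], Dxx[i+1]) * res_xy**2     (shape nx-1, ny, nz)
    fy, fz analogous with res_xy, res_z.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


def harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Series-resistance (harmonic) mean 2ab/(a+b), zero if either side is 0."""
    s = a + b
    out = np.zeros(np.broadcast(a, b).shape, dtype=np.float64)
    np.divide(2.0 * a * b, s, out=out, where=s > 0)
    return out


def face_coefficients(dxx: np.ndarray, dzz: np.ndarray, res_xy: float,
                      res_z: float):
    """Precompute per-face rate coefficients from voxel diffusion maps."""
    fx = harmonic_mean(dxx[:-1, :, :], dxx[1:, :, :]) * res_xy**2
    fy = harmonic_mean(dxx[:, :-1, :], dxx[:, 1:, :]) * res_xy**2
    fz = harmonic_mean(dzz[:, :, :-1], dzz[:, :, 1:]) * res_z**2
    return np.ascontiguousarray(fx), np.ascontiguousarray(fy), \
        np.ascontiguousarray(fz)


def run_chunk_numpy(c, fx, fy, fz, rp, rs, dt, nsteps):
    """Vectorized reference implementation of ``nsteps`` FTCS updates."""
    c = c.copy()
    for _ in range(nsteps):
        lap = rp - rs * c
        d = fx * (c[1:, :, :] - c[:-1, :, :])
        lap[:-1, :, :] += d
        lap[1:, :, :] -= d
        d = fy * (c[:, 1:, :] - c[:, :-1, :])
        lap[:, :-1, :] += d
        lap[:, 1:, :] -= d
        if fz.size:
            d = fz * (c[:, :, 1:] - c[:, :, :-1])
            lap[:, :, :-1] += d
            lap[:, :, 1:] -= d
        c = c + dt * lap
    return c


@njit(cache=True)
def _run_chunk_jit(c, fx, fy, fz, rp, rs, dt, nsteps):  # pragma: no cover
    nx, ny, nz = c.shape
    a = c.copy()
    b = np.empty_like(c)
    for _ in range(nsteps):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    v = a[i, j, k]
                    acc = rp[i, j, k] - rs[i, j, k] * v
                    if i > 0:
                        acc += fx[i - 1, j, k] * (a[i - 1, j, k] - v)
                    if i < nx - 1:
                        acc += fx[i, j, k] * (a[i + 1, j, k] - v)
                    if j > 0:
                        acc += fy[i, j - 1, k] * (a[i, j - 1, k] - v)
                    if j < ny - 1:
                        acc += fy[i, j, k] * (a[i, j + 1, k] - v)
                    if k > 0:
                        acc += fz[i, j, k - 1] * (a[i, j, k - 1] - v)
                    if k < nz - 1:
                        acc += fz[i, j, k] * (a[i, j, k + 1] - v)
                    b[i, j, k] = v + dt * acc
        a, b = b, a
    return a


@njit(cache=True)
def _run_chunk_jit_2d(c, fx, fy, rp, rs, dt, nsteps):  # pragma: no cover
    nx, ny = c.shape
    a = c.copy()
    b = np.empty_like(c)
    for _ in range(nsteps):
        for i in range(nx):
            for j in range(ny):
                v = a[i, j]
                acc = rp[i, j] - rs[i, j] * v
                if i > 0:
                    acc += fx[i - 1, j] * (a[i - 1, j] - v)
                if i < nx - 1:
                    acc += fx[i, j] * (a[i + 1, j] - v)
                if j > 0:
                    acc += fy[i, j - 1] * (a[i, j - 1] - v)
                if j < ny - 1:
                    acc += fy[i, j] * (a[i, j + 1] - v)
                b[i, j] = v + dt * acc
        a, b = b, a
    return a


def run_chunk(c, fx, fy, fz, rp, rs, dt, nsteps):
    """Advance the field by ``nsteps`` explicit steps, returning a new array."""
    if not HAVE_NUMBA:
        return run_chunk_numpy(c, fx, fy, fz, rp, rs, float(dt), int(nsteps))
    if c.shape[2] == 1:
        # single-slice models: drop the unit-length axis for cache-friendly loops
        out = _run_chunk_jit_2d(
            np.ascontiguousarray(c[:, :, 0]), np.ascontiguousarray(fx[:, :, 0]),
            np.ascontiguousarray(fy[:, :, 0]), np.ascontiguousarray(rp[:, :, 0]),
            np.ascontiguousarray(rs[:, :, 0]), float(dt), int(nsteps))
        return out[:, :, None]
    return _run_chunk_jit(c, fx, fy, fz, rp, rs, float(dt), int(nsteps))
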