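"""Low-level D2Q9 BGK stepping kernels (numba-accelerated, numpy fallback).

One call advances the populations by a full collide-stream cycle with the
second-order (Guo) forcing scheme.  The friction part of the body force,
``-kappa*U``, depends on the corrected macroscopic velocity itself; the
half-force velocity shift is therefore solved implicitly per node:

    U = (m + fc/2) / (rho + kappa/2),   F = fc - kappa*U,

which is exact and unconditionally stable in kappa.  Populations are stored
and accumulated in double precision throughout (the low-Reynolds,
force-dominated balance is round-off sensitive).

The kernel returns the squared L2 change and squared L2 norm of the velocity
field over the step, so callers can monitor convergence without extra passes.
"""

from __future__ import annotations

import numpy as np

EX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
EY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
W = np.array(
    [4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36]
)
CS2 = 1.0 / 3.0

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=True)
def _step_numba(f, fnew, ux, uy, rho, fccx, fccy, owner, kappa, inv_tau, sumx, sumy):
    nx, ny, _ = f.shape
    src_w = 1.0 - 0.5 * inv_tau
    diff2 = 0.0
    norm2 = 0.0
    for e in range(sumx.shape[0]):
        sumx[e] = 0.0
        sumy[e] = 0.0
    for ix in range(nx):
        ixm = nx - 1 if ix == 0 else ix - 1
        ixp = 0 if ix == nx - 1 else ix + 1
        for iy in range(ny):
            iym = ny - 1 if iy == 0 else iy - 1
            iyp = 0 if iy == ny - 1 else iy + 1
            # pull streaming from the periodic neighbours
            l0 = f[ix, iy, 0]
            l1 = f[ixm, iy, 1]
            l2 = f[ix, iym, 2]
            l3 = f[ixp, iy, 3]
            l4 = f[ix, iyp, 4]
            l5 = f[ixm, iym, 5]
            l6 = f[ixp, iym, 6]
            l7 = f[ixp, iyp, 7]
            l8 = f[ixm, iyp, 8]
            r = l0 + l1 + l2 + l3 + l4 + l5 + l6 + l7 + l8
            mx = l1 - l3 + l5 - l6 - l7 + l8
            my = l2 - l4 + l5 + l6 - l7 - l8
            el = owner[ix, iy]
            gx = fccx[el]
            gy = fccy[el]
            # implicit half-force velocity (friction folded in)
            denom = r + 0.5 * kappa
            u = (mx + 0.5 * gx) / denom
            v = (my + 0.5 * gy) / denom
            fx = gx - kappa * u
            fy = gy - kappa * v
            du = u - ux[ix, iy]
            dv = v - uy[ix, iy]
            diff2 += du * du + dv * dv
            norm2 += u * u + v * v
            sumx[el] += u
            sumy[el] += v
            ux[ix, iy] = u
            uy[ix, iy] = v
            rho[ix, iy] = r
            usq = 1.5 * (u * u + v * v)
            uf = u * fx + v * fy
            # k = 0
            feq = (4.0 / 9.0) * r * (1.0 - usq)
            s = (4.0 / 9.0) * src_w * (-3.0 * uf)
            fnew[ix, iy, 0] = l0 - inv_tau * (l0 - feq) + s
            # axis directions, w = 1/9
            w1 = 1.0 / 9.0
            # k = 1: e=(1,0)
            eu = u
            ef = fx
            feq = w1 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w1 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 1] = l1 - inv_tau * (l1 - feq) + s
            # k = 2: e=(0,1)
            eu = v
            ef = fy
            feq = w1 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w1 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 2] = l2 - inv_tau * (l2 - feq) + s
            # k = 3: e=(-1,0)
            eu = -u
            ef = -fx
            feq = w1 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w1 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 3] = l3 - inv_tau * (l3 - feq) + s
            # k = 4: e=(0,-1)
            eu = -v
            ef = -fy
            feq = w1 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w1 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 4] = l4 - inv_tau * (l4 - feq) + s
            # diagonal directions, w = 1/36
            w5 = 1.0 / 36.0
            # k = 5: e=(1,1)
            eu = u + v
            ef = fx + fy
            feq = w5 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w5 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 5] = l5 - inv_tau * (l5 - feq) + s
            # k = 6: e=(-1,1)
            eu = -u + v
            ef = -fx + fy
            feq = w5 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w5 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 6] = l6 - inv_tau * (l6 - feq) + s
            # k = 7: e=(-1,-1)
            eu = -u - v
            ef = -fx - fy
            feq = w5 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w5 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 7] = l7 - inv_tau * (l7 - feq) + s
            # k = 8: e=(1,-1)
            eu = u - v
            ef = fx - fy
            feq = w5 * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
            s = w5 * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
            fnew[ix, iy, 8] = l8 - inv_tau * (l8 - feq) + s
    return diff2, norm2


def _step_numpy(f, fnew, ux, uy, rho, fccx, fccy, owner, kappa, inv_tau, sumx, sumy):
    """Vectorized reference implementation of the same collide-stream cycle.

    Kept independent of the numba kernel so the two can be cross-checked.
    """
    src_w = 1.0 - 0.5 * inv_tau
    # pull streaming
    loc = np.empty_like(f)
    for k in range(9):
        loc[:, :, k] = np.roll(f[:, :, k], shift=(EX[k], EY[k]), axis=(0, 1))
    r = loc.sum(axis=2)
    mx = loc @ EX.astype(float)
    my = loc @ EY.astype(float)
    gx = fccx[owner]
    gy = fccy[owner]
    denom = r + 0.5 * kappa
    u = (mx + 0.5 * gx) / denom
    v = (my + 0.5 * gy) / denom
    fx = gx - kappa * u
    fy = gy - kappa * v
    du = u - ux
    dv = v - uy
    diff2 = float((du * du + dv * dv).sum())
    norm2 = float((u * u + v * v).sum())
    sumx[:] = np.bincount(owner.ravel(), weights=u.ravel(), minlength=sumx.size)
    sumy[:] = np.bincount(owner.ravel(), weights=v.ravel(), minlength=sumy.size)
    ux[:] = u
    uy[:] = v
    rho[:] = r
    usq = 1.5 * (u * u + v * v)
    uf = u * fx + v * fy
    for k in range(9):
        eu = EX[k] * u + EY[k] * v
        ef = EX[k] * fx + EY[k] * fy
        feq = W[k] * r * (1.0 + 3.0 * eu + 4.5 * eu * eu - usq)
        s = W[k] * src_w * (3.0 * (ef - uf) + 9.0 * eu * ef)
        fnew[:, :, k] = loc[:, :, k] - inv_tau * (loc[:, :, k] - feq) + s
    return diff2, norm2


def step(
    f, fnew, ux, uy, rho, fccx, fccy, owner, kappa, inv_tau,
    backend="numba", elem_sums=None,
):
    """Advance one collide-stream cycle; returns (diff2, norm2) of velocity.

    ``elem_sums = (sumx, sumy)`` receives the per-element sums of the updated
    node velocities (allocated internally when omitted), so element averages
    come out of the same memory pass.
    """
    if elem_sums is None:
        n = int(fccx.shape[0])
        elem_sums = (np.empty(n), np.empty(n))
    sumx, sumy = elem_sums
    if backend == "numba" and HAVE_NUMBA:
        return _step_numba(f, fnew, ux, uy, rho, fccx, fccy, owner, kappa, inv_tau, sumx, sumy)
    return _step_numpy(f, fnew, ux, uy, rho, fccx, fccy, owner, kappa, inv_tau, sumx, sumy)
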