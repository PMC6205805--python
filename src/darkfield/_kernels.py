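"""Compiled inner loops for the sphere-pack projection.

Two kernels: an additive per-sphere chord accumulation (overlaps double
counted) and the exact chord-union projection.  The union kernel computes,
for every transverse fine-grid sample, the length of the union of all
sphere chords along z, clipped to the slab [0, t].  Spheres are
monodisperse; the caller passes centre coordinates sorted by y so each
image row only touches a y-window of candidates.

Within a row the window is ordered by centre z.  Chord intervals generated
in that order are *nearly* sorted by their lower edge (an interval can only
be displaced by spheres whose centres lie within one diameter in z), so a
linear-time insertion pass yields a fully sorted list, after which a single
sweep merges overlaps and accumulates the union length.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def chord_sum_air_path(cx, cy, cz, radius, thickness, x0, y0, spacing, nx, ny):
    """Per-ray *sum* of sphere chords clipped to [0, thickness].

    Unlike :func:`union_air_path`, overlapping chords are double counted:
    every sphere contributes its full clipped chord independently.  Returns
    an (ny, nx) float64 map.
    """
    out = np.zeros((ny, nx), dtype=np.float64)
    r2 = radius * radius
    for s in range(cx.shape[0]):
        jlo = int(math.ceil((cy[s] - radius - y0) / spacing))
        jhi = int(math.floor((cy[s] + radius - y0) / spacing))
        if jlo < 0:
            jlo = 0
        if jhi > ny - 1:
            jhi = ny - 1
        for j in range(jlo, jhi + 1):
            dy = cy[s] - (y0 + j * spacing)
            rx2 = r2 - dy * dy
            if rx2 <= 0.0:
                continue
            rx = math.sqrt(rx2)
            ilo = int(math.ceil((cx[s] - rx - x0) / spacing))
            ihi = int(math.floor((cx[s] + rx - x0) / spacing))
            if ilo < 0:
                ilo = 0
            if ihi > nx - 1:
                ihi = nx - 1
            for i in range(ilo, ihi + 1):
                dx = cx[s] - (x0 + i * spacing)
                h2 = rx2 - dx * dx
                if h2 <= 0.0:
                    continue
                h = math.sqrt(h2)
                z0 = cz[s] - h
                z1 = cz[s] + h
                if z0 < 0.0:
                    z0 = 0.0
                if z1 > thickness:
                    z1 = thickness
                if z1 > z0:
                    out[j, i] += z1 - z0
    return out


@njit(cache=True)
def union_air_path(cx, cy, cz, radius, thickness, x0, y0, spacing, nx, ny):
    """Exact per-ray union of sphere chords, clipped to [0, thickness].

    Parameters are centre coordinate arrays sorted by ``cy``, the common
    sphere radius, the slab thickness, and the sample raster (origin,
    spacing, counts).  Returns an (ny, nx) float64 air-path map.
    """
    out = np.zeros((ny, nx), dtype=np.float64)
    n_sph = cx.shape[0]
    if n_sph == 0:
        return out
    r2 = radius * radius
    # scratch buffers sized to the worst-case row window
    wx = np.empty(n_sph, dtype=np.float64)
    wz = np.empty(n_sph, dtype=np.float64)
    wr2 = np.empty(n_sph, dtype=np.float64)
    iv_lo = np.empty(n_sph, dtype=np.float64)
    iv_hi = np.empty(n_sph, dtype=np.float64)
    for j in range(ny):
        y = y0 + j * spacing
        lo = np.searchsorted(cy, y - radius)
        hi = np.searchsorted(cy, y + radius)
        if hi <= lo:
            continue
        # collect the row window, keep spheres actually cut by this row,
        # ordered by centre z
        order = np.argsort(cz[lo:hi])
        m = 0
        for k in order:
            q = lo + k
            dy = cy[q] - y
            rx2 = r2 - dy * dy
            if rx2 > 0.0:
                wx[m] = cx[q]
                wz[m] = cz[q]
                wr2[m] = rx2
                m += 1
        if m == 0:
            continue
        for i in range(nx):
            x = x0 + i * spacing
            n_iv = 0
            for q in range(m):
                dx = wx[q] - x
                h2 = wr2[q] - dx * dx
                if h2 <= 0.0:
                    continue
                h = math.sqrt(h2)
                z0 = wz[q] - h
                z1 = wz[q] + h
                if z0 < 0.0:
                    z0 = 0.0
                if z1 > thickness:
                    z1 = thickness
                if z1 <= z0:
                    continue
                # insertion into the nearly-sorted interval list
                p = n_iv
                while p > 0 and iv_lo[p - 1] > z0:
                    iv_lo[p] = iv_lo[p - 1]
                    iv_hi[p] = iv_hi[p - 1]
                    p -= 1
                iv_lo[p] = z0
                iv_hi[p] = z1
                n_iv += 1
            if n_iv == 0:
                continue
            total = 0.0
            cur_lo = iv_lo[0]
            cur_hi = iv_hi[0]
            for q in range(1, n_iv):
                if iv_lo[q] > cur_hi:
                    total += cur_hi - cur_lo
                    cur_lo = iv_lo[q]
                    cur_hi = iv_hi[q]
                elif iv_hi[q] > cur_hi:
                    cur_hi = iv_hi[q]
            total += cur_hi - cur_lo
            out[j, i] = total
    return out
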