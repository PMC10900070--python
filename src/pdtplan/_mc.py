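"""Numba voxel Monte Carlo kernel.

Single-threaded photon-packet transport on a labeled cuboid-voxel grid:

* free paths sampled in optical depth, consumed across voxels by exact
  3D DDA boundary traversal (µt re-read per voxel);
* fluence scored with the track-length estimator, so voxels with zero
  absorption (the Intralipid-filled cavity) score correctly;
* implicit capture (weight x albedo at interactions), Henyey–Greenstein
  scattering with the local g, Russian roulette below weight 1e-4 with
  survival probability 0.1;
* BOUNDARY-labeled voxels terminate packets and accumulate escaped weight.

All lengths inside the kernel are cm. The energy ledger is exact per
history (roulette gains/losses are booked against the absorbed tally), so
absorbed + escaped equals the launched weight to floating-point roundoff.

The RNG is xorshift64*: tiny, seedable, and fully deterministic inside a
single-threaded kernel run.
"""

import math

import numpy as np
from numba import njit

# region labels (must match geometry.Region)
_BOUNDARY = 3

# source kinds
SRC_ISOTROPIC_POINT = 0
SRC_FLAT_CLEAVED = 1
SRC_SPHERICAL_DIFFUSER = 2

_W_MIN = 1.0e-4
_P_SURVIVE = 0.1
_U64 = np.uint64


@njit(cache=True, inline="always")
def _rand(state):
    """xorshift64* -> float64 in [0, 1)."""
    s = state[0]
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    state[0] = s
    return float(s * _U64(2685821657736338717) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_exp(state):
    """Exponential deviate, strictly positive."""
    return -math.log(1.0 - _rand(state))


@njit(cache=True, inline="always")
def _isotropic_dir(state):
    ct = 2.0 * _rand(state) - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ph = 2.0 * math.pi * _rand(state)
    return st * math.cos(ph), st * math.sin(ph), ct


@njit(cache=True, inline="always")
def _orthobasis(nx, ny, nz):
    """Two unit vectors orthogonal to the unit vector n."""
    if abs(nz) < 0.9:
        # e1 = normalize(n x z)
        ex, ey, ez = ny, -nx, 0.0
    else:
        ex, ey, ez = 0.0, nz, -ny  # n x x
    norm = math.sqrt(ex * ex + ey * ey + ez * ez)
    ex /= norm
    ey /= norm
    ez /= norm
    # e2 = n x e1
    fx = ny * ez - nz * ey
    fy = nz * ex - nx * ez
    fz = nx * ey - ny * ex
    return ex, ey, ez, fx, fy, fz


@njit(cache=True, inline="always")
def _hg_cos(state, g):
    if abs(g) < 1.0e-6:
        return 2.0 * _rand(state) - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rand(state))
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _scatter(state, ux, uy, uz, g):
    """New direction after a Henyey–Greenstein deflection about (ux,uy,uz)."""
    ct = _hg_cos(state, g)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ph = 2.0 * math.pi * _rand(state)
    cp = math.cos(ph)
    sp = math.sin(ph)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _launch(state, src_kind, sx, sy, sz, ax, ay, az, r_core, cos_max, r_sphere):
    if src_kind == SRC_ISOTROPIC_POINT:
        ux, uy, uz = _isotropic_dir(state)
        return sx, sy, sz, ux, uy, uz
    if src_kind == SRC_FLAT_CLEAVED:
        e1x, e1y, e1z, e2x, e2y, e2z = _orthobasis(ax, ay, az)
        r = r_core * math.sqrt(_rand(state))
        ph = 2.0 * math.pi * _rand(state)
        px = sx + r * (math.cos(ph) * e1x + math.sin(ph) * e2x)
        py = sy + r * (math.cos(ph) * e1y + math.sin(ph) * e2y)
        pz = sz + r * (math.cos(ph) * e1z + math.sin(ph) * e2z)
        # uniform in solid angle within the acceptance cone
        ct = 1.0 - _rand(state) * (1.0 - cos_max)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        ph2 = 2.0 * math.pi * _rand(state)
        ux = st * math.cos(ph2) * e1x + st * math.sin(ph2) * e2x + ct * ax
        uy = st * math.cos(ph2) * e1y + st * math.sin(ph2) * e2y + ct * ay
        uz = st * math.cos(ph2) * e1z + st * math.sin(ph2) * e2z + ct * az
        return px, py, pz, ux, uy, uz
    # spherical diffuser: Lambertian emission from the bulb surface
    nx, ny, nz = _isotropic_dir(state)
    px = sx + r_sphere * nx
    py = sy + r_sphere * ny
    pz = sz + r_sphere * nz
    e1x, e1y, e1z, e2x, e2y, e2z = _orthobasis(nx, ny, nz)
    ct = math.sqrt(_rand(state))  # cosine-weighted about the outward normal
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ph = 2.0 * math.pi * _rand(state)
    ux = st * math.cos(ph) * e1x + st * math.sin(ph) * e2x + ct * nx
    uy = st * math.cos(ph) * e1y + st * math.sin(ph) * e2y + ct * ny
    uz = st * math.cos(ph) * e1z + st * math.sin(ph) * e2z + ct * nz
    return px, py, pz, ux, uy, uz


@njit(cache=True)
def run_transport(
    labels,  # uint8 3D, C-contiguous
    mua,  # float64[4], cm^-1 per region label
    mus,  # float64[4]
    g,  # float64[4]
    pitch,  # voxel edge, cm
    n_packets,
    seed,  # uint64
    src_kind,
    sx,
    sy,
    sz,  # source position, cm (grid-corner origin)
    ax,
    ay,
    az,  # source axis (unit vector; flat fiber)
    r_core,  # fiber core radius, cm
    cos_max,  # cos of acceptance half-angle
    r_sphere,  # diffuser bulb radius, cm
    phi,  # float64 3D accumulator (track length x weight, cm)
):
    NX, NY, NZ = labels.shape
    state = np.empty(1, dtype=np.uint64)
    state[0] = _U64(seed) * _U64(6364136223846793005) + _U64(1442695040888963407)
    if state[0] == _U64(0):
        state[0] = _U64(0x9E3779B97F4A7C15)

    absorbed = 0.0
    escaped = 0.0

    for _ in range(n_packets):
        x, y, z, ux, uy, uz = _launch(
            state, src_kind, sx, sy, sz, ax, ay, az, r_core, cos_max, r_sphere
        )
        w = 1.0
        ix = int(math.floor(x / pitch))
        iy = int(math.floor(y / pitch))
        iz = int(math.floor(z / pitch))
        if ix < 0 or ix >= NX or iy < 0 or iy >= NY or iz < 0 or iz >= NZ:
            escaped += w
            continue
        tau = _rand_exp(state)

        while True:
            lbl = labels[ix, iy, iz]
            if lbl == _BOUNDARY:
                escaped += w
                break
            mt = mua[lbl] + mus[lbl]

            # distance to the next voxel face along the current direction
            if ux > 0.0:
                tx = ((ix + 1) * pitch - x) / ux
            elif ux < 0.0:
                tx = (ix * pitch - x) / ux
            else:
                tx = 1.0e30
            if uy > 0.0:
                ty = ((iy + 1) * pitch - y) / uy
            elif uy < 0.0:
                ty = (iy * pitch - y) / uy
            else:
                ty = 1.0e30
            if uz > 0.0:
                tz = ((iz + 1) * pitch - z) / uz
            elif uz < 0.0:
                tz = (iz * pitch - z) / uz
            else:
                tz = 1.0e30
            tb = tx
            if ty < tb:
                tb = ty
            if tz < tb:
                tb = tz
            if tb < 0.0:
                tb = 0.0

            if mt * tb < tau:
                # cross into the next voxel
                phi[ix, iy, iz] += w * tb
                x += ux * tb
                y += uy * tb
                z += uz * tb
                tau -= mt * tb
                if tx <= ty and tx <= tz:
                    ix += 1 if ux > 0.0 else -1
                elif ty <= tz:
                    iy += 1 if uy > 0.0 else -1
                else:
                    iz += 1 if uz > 0.0 else -1
                if ix < 0 or ix >= NX or iy < 0 or iy >= NY or iz < 0 or iz >= NZ:
                    escaped += w
                    break
            else:
                # interaction inside this voxel
                step = tau / mt
                phi[ix, iy, iz] += w * step
                x += ux * step
                y += uy * step
                z += uz * step
                absorbed += w * mua[lbl] / mt
                w *= mus[lbl] / mt
                if w <= 0.0:
                    break
                ux, uy, uz = _scatter(state, ux, uy, uz, g[lbl])
                tau = _rand_exp(state)
                if w < _W_MIN:
                    if _rand(state) < _P_SURVIVE:
                        # unbiased roulette; book the injected weight
                        absorbed += w - w / _P_SURVIVE
                        w /= _P_SURVIVE
                    else:
                        absorbed += w
                        break

    return absorbed, escaped
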