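"""Numba random-walk kernel for analog photon transport.

Scalar per-photon loop over a scene of nested prisms (outer ellipse, epidermis
inner ellipse, circular solids), compiled with numba.  Each photon owns a
PCG32 stream derived from (run seed, photon index), so runs are reproducible
and phase pairs launched with the same seed share random numbers photon by
photon (common random numbers).

Terminal codes: 0 detected exit, 1 exit outside the detector axial window,
2 absorbed, 3 end-cap loss, 4 event-cap termination.
"""

import math

import numpy as np
from numba import njit

CODE_DETECTED = 0
CODE_MISSED = 1
CODE_ABSORBED = 2
CODE_ENDCAP = 3
CODE_CAPPED = 4

# tissue label ints (must match finger_model.TissueLabel)
_LAB_DERMIS = 1
_LAB_EPI = 2

_SURF_NONE = -1  # collision in the bulk
_SURF_CAP = 0
_SURF_OUTER = 1
_SURF_INNER = 2
_SURF_CIRC0 = 3  # + circle index

_BIG = 1.0e30
_TMIN = 1.0e-9
_EPS = 1.0e-7

_U64 = np.uint64


@njit(cache=True)
def _sm64(z):
    """splitmix64 finalizer; used to derive per-photon stream parameters."""
    z = z + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True)
def _pcg32(state, inc):
    old = state
    state = old * _U64(6364136223846793005) + inc
    xs = (((old >> _U64(18)) ^ old) >> _U64(27)) & _U64(0xFFFFFFFF)
    rot = old >> _U64(59)
    out = ((xs >> rot) | (xs << ((_U64(32) - rot) & _U64(31)))) & _U64(0xFFFFFFFF)
    return state, out


@njit(cache=True)
def _rand(state, inc):
    state, out = _pcg32(state, inc)
    return state, (np.float64(out) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True, fastmath=True)
def _ray_ellipse(py, pz, dy, dz, ia2, ib2):
    """Distance to the ellipse y^2*ia2 + z^2*ib2 = 1 along (dy, dz); _BIG if none.

    ``ia2``/``ib2`` are the inverse squared semi-axes."""
    A = dy * dy * ia2 + dz * dz * ib2
    if A < 1e-300:
        return _BIG
    B = 2.0 * (py * dy * ia2 + pz * dz * ib2)
    C = py * py * ia2 + pz * pz * ib2 - 1.0
    disc = B * B - 4.0 * A * C
    if disc <= 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t = (-B - sq) / (2.0 * A)
    if t > _TMIN:
        return t
    t = (-B + sq) / (2.0 * A)
    if t > _TMIN:
        return t
    return _BIG


@njit(cache=True, fastmath=True)
def _ray_circle(py, pz, dy, dz, cy, cz, r):
    A = dy * dy + dz * dz
    if A < 1e-300:
        return _BIG
    oy = py - cy
    oz = pz - cz
    B = 2.0 * (oy * dy + oz * dz)
    C = oy * oy + oz * oz - r * r
    disc = B * B - 4.0 * A * C
    if disc <= 0.0:
        return _BIG
    sq = math.sqrt(disc)
    t = (-B - sq) / (2.0 * A)
    if t > _TMIN:
        return t
    t = (-B + sq) / (2.0 * A)
    if t > _TMIN:
        return t
    return _BIG


@njit(cache=True, fastmath=True)
def _unit_circle(state, inc):
    """Uniform (cos, sin) of a random azimuth via rejection (trig-free)."""
    while True:
        state, u1 = _rand(state, inc)
        state, u2 = _rand(state, inc)
        a = 2.0 * u1 - 1.0
        b = 2.0 * u2 - 1.0
        m = a * a + b * b
        if 1e-12 < m <= 1.0:
            return state, (a * a - b * b) / m, 2.0 * a * b / m


@njit(cache=True, fastmath=True)
def _deflect(ux, uy, uz, ct, cp, sp):
    """Rotate a unit direction by deflection cosine ct and azimuth (cp, sp)."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def _cosine_about_plane_normal(my, mz, u1, cp, sp):
    """Cosine-weighted direction about a unit axis (0, my, mz)."""
    ct = math.sqrt(u1)
    st = math.sqrt(1.0 - u1)
    # frame: m = (0, my, mz), t1 = (0, -mz, my), t2 = (1, 0, 0)
    dx = st * sp
    dy = ct * my - st * cp * mz
    dz = ct * mz + st * cp * my
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def trace(
    L,
    ay,
    az,
    has_inner,
    iay,
    iaz,
    ccy,
    ccz,
    cr,
    clabel,
    crefl,
    refl_dermis,
    refl_epi,
    mu_t,
    albedo,
    gpar,
    px,
    py,
    pz,
    dx,
    dy,
    dz,
    lab0,
    cid0,
    seed,
    event_cap,
    det_lo,
    det_hi,
    n_bins,
    bins,
    code,
    exit_angle,
    exit_axial,
    nevents,
):
    n = px.shape[0]
    ncirc = ccy.shape[0]
    half_bin = 180.0 / n_bins
    ia_oy = 1.0 / (ay * ay)
    ia_oz = 1.0 / (az * az)
    ia_iy = 1.0 / (iay * iay)
    ia_iz = 1.0 / (iaz * iaz)
    inv_mu = 1.0 / mu_t
    mn_o = ay if ay < az else az
    mn_i = iay if iay < iaz else iaz
    for i in range(n):
        h = _sm64(seed ^ _sm64(_U64(i) + _U64(0x9E3779B9)))
        state = h
        inc = (_sm64(h) << _U64(1)) | _U64(1)
        state, _ = _pcg32(state, inc)

        x = px[i]
        y = py[i]
        z = pz[i]
        ux = dx[i]
        uy = dy[i]
        uz = dz[i]
        lab = lab0[i]
        cid = cid0[i]
        nev = 0
        c = CODE_CAPPED
        ang = -1.0
        # conservative clearance to the nearest boundary: while the sampled
        # free path stays below it, no geometry test can trigger
        safe = 0.0

        while nev < event_cap:
            state, u = _rand(state, inc)
            s = -math.log(u) * inv_mu[lab]

            if s < safe:
                # guaranteed collision: skip all boundary tests
                x += s * ux
                y += s * uy
                z += s * uz
                safe -= s
                surf = _SURF_NONE
            else:
                tmin = s
                surf = _SURF_NONE
                if ux > 1e-300:
                    t = (L - x) / ux
                    if t < tmin:
                        tmin = t
                        surf = _SURF_CAP
                elif ux < -1e-300:
                    t = -x / ux
                    if t < tmin:
                        tmin = t
                        surf = _SURF_CAP

                if lab == _LAB_EPI:
                    t = _ray_ellipse(y, z, uy, uz, ia_oy, ia_oz)
                    if t < tmin:
                        tmin = t
                        surf = _SURF_OUTER
                    t = _ray_ellipse(y, z, uy, uz, ia_iy, ia_iz)
                    if t < tmin:
                        tmin = t
                        surf = _SURF_INNER
                elif cid >= 0:
                    t = _ray_circle(y, z, uy, uz, ccy[cid], ccz[cid], cr[cid])
                    if t < tmin:
                        tmin = t
                        surf = _SURF_CIRC0 + cid
                else:  # dermis / pulp
                    if has_inner:
                        t = _ray_ellipse(y, z, uy, uz, ia_iy, ia_iz)
                        if t < tmin:
                            tmin = t
                            surf = _SURF_INNER
                    else:
                        t = _ray_ellipse(y, z, uy, uz, ia_oy, ia_oz)
                        if t < tmin:
                            tmin = t
                            surf = _SURF_OUTER
                    for k in range(ncirc):
                        ddy = y - ccy[k]
                        ddz = z - ccz[k]
                        rt = cr[k] + tmin
                        if ddy * ddy + ddz * ddz > rt * rt:
                            continue
                        t = _ray_circle(y, z, uy, uz, ccy[k], ccz[k], cr[k])
                        if t < tmin:
                            tmin = t
                            surf = _SURF_CIRC0 + k

                x += tmin * ux
                y += tmin * uy
                z += tmin * uz

                if surf == _SURF_NONE:
                    # refresh the clearance bound at the collision site:
                    # end caps, then region-specific lower bounds (Lipschitz
                    # bound (1 - f) * min-semi-axis for interior ellipses)
                    cl = x if x < L - x else L - x
                    if lab == _LAB_EPI:
                        fo = math.sqrt(y * y * ia_oy + z * z * ia_oz)
                        t = (1.0 - fo) * mn_o
                        if t < cl:
                            cl = t
                        fi = math.sqrt(y * y * ia_iy + z * z * ia_iz)
                        t = (fi - 1.0) * mn_i
                        if t < cl:
                            cl = t
                    elif cid >= 0:
                        dd = math.sqrt(
                            (y - ccy[cid]) ** 2 + (z - ccz[cid]) ** 2
                        )
                        t = cr[cid] - dd
                        if t < cl:
                            cl = t
                    else:
                        if has_inner:
                            fi = math.sqrt(y * y * ia_iy + z * z * ia_iz)
                            t = (1.0 - fi) * mn_i
                        else:
                            fo = math.sqrt(y * y * ia_oy + z * z * ia_oz)
                            t = (1.0 - fo) * mn_o
                        if t < cl:
                            cl = t
                        for k in range(ncirc):
                            dd = math.sqrt((y - ccy[k]) ** 2 + (z - ccz[k]) ** 2)
                            t = dd - cr[k]
                            if t < cl:
                                cl = t
                    safe = cl * 0.999999 if cl > 0.0 else 0.0

            if surf == _SURF_NONE:
                # collision: survive as a scatter with probability mu_s / mu_t
                nev += 1
                state, u = _rand(state, inc)
                al = albedo[lab]
                if u >= al:
                    c = CODE_ABSORBED
                    break
                # conditional on survival, u / albedo is again uniform(0, 1)
                u1 = u / al
                g = gpar[lab]
                if g != 0.0:
                    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                    ct = (1.0 + g * g - f * f) / (2.0 * g)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    ct = 2.0 * u1 - 1.0
                state, cp, sp = _unit_circle(state, inc)
                ux, uy, uz = _deflect(ux, uy, uz, ct, cp, sp)
                continue

            nev += 1
            if surf == _SURF_CAP:
                c = CODE_ENDCAP
                break
            if surf == _SURF_OUTER:
                a = math.atan2(y, z) * (180.0 / math.pi)
                if a < 0.0:
                    a += 360.0
                ang = a
                if det_lo <= x <= det_hi:
                    b = int((a + half_bin) * n_bins / 360.0) % n_bins
                    bins[b] += 1
                    c = CODE_DETECTED
                else:
                    c = CODE_MISSED
                break

            # internal interface: Lambertian reflect/transmit governed by the
            # entered region's surface parameters
            if surf == _SURF_INNER:
                ny = y * ia_iy
                nz = z * ia_iz
                if lab == _LAB_EPI:
                    ent = _LAB_DERMIS
                    entr = refl_dermis
                    ent_cid = -1
                else:
                    ent = _LAB_EPI
                    entr = refl_epi
                    ent_cid = -1
            else:
                k = surf - _SURF_CIRC0
                ny = y - ccy[k]
                nz = z - ccz[k]
                if cid == k:
                    ent = _LAB_DERMIS
                    entr = refl_dermis
                    ent_cid = -1
                else:
                    ent = clabel[k]
                    entr = crefl[k]
                    ent_cid = k
            nn = math.sqrt(ny * ny + nz * nz)
            ny /= nn
            nz /= nn
            sgn = 1.0 if (uy * ny + uz * nz) > 0.0 else -1.0

            state, u = _rand(state, inc)
            if u < entr:
                my = -sgn * ny
                mz = -sgn * nz
            else:
                my = sgn * ny
                mz = sgn * nz
                lab = ent
                cid = ent_cid
            state, u1 = _rand(state, inc)
            state, cp, sp = _unit_circle(state, inc)
            ux, uy, uz = _cosine_about_plane_normal(my, mz, u1, cp, sp)
            x += _EPS * ux
            y += _EPS * uy
            z += _EPS * uz
            safe = 0.0

        code[i] = c
        exit_angle[i] = ang
        exit_axial[i] = x
        nevents[i] = nev
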