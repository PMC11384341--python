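"""Numba photon-transport kernel for the layered slab geometry.

Transport model: exponential free paths with total attenuation mu_t,
discrete-interaction weight reduction (deposit w*mu_a/mu_t per
interaction), Henyey-Greenstein deflection, unpolarized Fresnel
reflection at the outer top/bottom boundaries, Russian roulette below a
weight threshold.  Roulette adjustments are booked against the absorbed
tally (zero mean) so the four exit fractions sum to the launched weight
exactly, not just in expectation.

Geometry: z in [0, d_tissue) is gray matter, [d_tissue, d_tissue+d_back)
the absorbing backing; x, y in [-half_extent, half_extent].  Photons
leaving the sides are terminated and tallied as lost.  Fluence uses the
path-length estimator with sub-voxel segment deposition.
"""

import numpy as np
from numba import njit

_EPS = 1e-12
_CHORD = 1e-9  # nudge across boundaries


@njit(cache=True)
def _hg_cos(g):
    u = np.random.random()
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - frac * frac) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True)
def sample_hg_cosines(n, g, seed):
    """Draw n Henyey-Greenstein deflection cosines (diagnostics/tests)."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _hg_cos(g)
    return out


@njit(cache=True)
def _fresnel_reflectance(n1, n2, cosi):
    """Unpolarized Fresnel reflectance for incidence cosine ``cosi`` > 0."""
    if cosi > 1.0:
        cosi = 1.0
    sini = np.sqrt(max(0.0, 1.0 - cosi * cosi))
    sint = n1 / n2 * sini
    if sint >= 1.0:
        return 1.0  # total internal reflection
    cost = np.sqrt(1.0 - sint * sint)
    if sini < 1e-9:  # normal incidence
        r = (n1 - n2) / (n1 + n2)
        return r * r
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _spin(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost if uz >= 0.0 else -cost
    else:
        temp = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
        nz = -sint * cosp * temp + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _deposit(fluence, w, x0, y0, z0, ux, uy, uz, length, half_extent, voxel, inv_vol):
    """Path-length fluence estimator: spread w*length over traversed voxels."""
    nx, ny, nz = fluence.shape
    n_sub = int(length / (0.5 * voxel)) + 1
    ds = length / n_sub
    for k in range(n_sub):
        # jittered sample point per substep: unbiased, no voxel aliasing
        s_mid = (k + np.random.random()) * ds
        xm = x0 + ux * s_mid
        ym = y0 + uy * s_mid
        zm = z0 + uz * s_mid
        ix = int((xm + half_extent) / voxel)
        iy = int((ym + half_extent) / voxel)
        iz = int(zm / voxel)
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            fluence[ix, iy, iz] += w * ds * inv_vol


@njit(cache=True)
def run_kernel(
    n_photons,
    seed,
    mua_tissue,
    mus_tissue,
    g,
    n_tissue,
    n_outside,
    d_tissue,
    d_back,
    mua_back,
    half_extent,
    source_half_width,
    roulette_threshold,
    roulette_survival,
    tally_fluence,
    fluence,
    voxel,
    hist,
    hist_max,
):
    """Simulate ``n_photons`` and fill tallies.

    Returns (absorbed, reflected_top, transmitted_backing, lost_side,
    sum_weighted_path, sum_path, sum_detected_weighted_path,
    sum_detected_weight).
    """
    np.random.seed(seed)
    absorbed = 0.0
    reflected = 0.0
    transmitted = 0.0
    lost_side = 0.0
    sum_wpath = 0.0  # integral of weight over tissue path, all photons
    sum_path = 0.0  # unweighted tissue path, all photons
    sum_det_wpath = 0.0  # exit-weight * path, photons escaping the top
    sum_det_w = 0.0
    z_bottom = d_tissue + d_back
    inv_vol = 1.0 / (voxel * voxel * voxel)
    n_bins = hist.shape[0]

    for _ in range(n_photons):
        x = (2.0 * np.random.random() - 1.0) * source_half_width
        y = (2.0 * np.random.random() - 1.0) * source_half_width
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        path = 0.0  # tissue path of this photon
        alive = True

        while alive:
            tau = -np.log(np.random.random() + _EPS)
            while tau > 0.0 and alive:
                in_tissue = z < d_tissue
                mua = mua_tissue if in_tissue else mua_back
                mus = mus_tissue if in_tissue else 0.0
                mut = mua + mus

                # distance to the axial layer boundary along uz
                if uz > _EPS:
                    z_next = d_tissue if in_tissue else z_bottom
                    d_axial = (z_next - z) / uz
                elif uz < -_EPS:
                    z_next = 0.0 if in_tissue else d_tissue
                    d_axial = (z_next - z) / uz
                else:
                    d_axial = 1e30

                # distance to the lateral walls
                d_side = 1e30
                if ux > _EPS:
                    d_side = (half_extent - x) / ux
                elif ux < -_EPS:
                    d_side = (-half_extent - x) / ux
                if uy > _EPS:
                    d = (half_extent - y) / uy
                    if d < d_side:
                        d_side = d
                elif uy < -_EPS:
                    d = (-half_extent - y) / uy
                    if d < d_side:
                        d_side = d

                d_free = tau / mut if mut > 0.0 else 1e30
                s = d_free
                event = 0  # 0 interact, 1 axial boundary, 2 side wall
                if d_axial < s:
                    s = d_axial
                    event = 1
                if d_side < s:
                    s = d_side
                    event = 2

                if in_tissue:
                    sum_wpath += w * s
                    path += s
                    if tally_fluence:
                        _deposit(fluence, w, x, y, z, ux, uy, uz, s,
                                 half_extent, voxel, inv_vol)

                x += ux * s
                y += uy * s
                z += uz * s
                tau -= s * mut

                if event == 2:
                    lost_side += w
                    alive = False
                elif event == 1:
                    # classify by which plane was hit
                    if uz > 0.0 and abs(z - d_tissue) < abs(z - z_bottom):
                        # tissue -> backing internal interface (index matched)
                        z = d_tissue + _CHORD
                    elif uz < 0.0 and abs(z) < abs(z - d_tissue):
                        # top outer boundary
                        r = _fresnel_reflectance(n_tissue, n_outside, -uz)
                        if np.random.random() < r:
                            uz = -uz
                            z = _CHORD
                        else:
                            reflected += w
                            sum_det_wpath += w * path
                            sum_det_w += w
                            alive = False
                    elif uz < 0.0:
                        # backing -> tissue internal interface
                        z = d_tissue - _CHORD
                    else:
                        # bottom outer boundary
                        r = _fresnel_reflectance(n_tissue, n_outside, uz)
                        if np.random.random() < r:
                            uz = -uz
                            z = z_bottom - _CHORD
                        else:
                            transmitted += w
                            alive = False
                else:
                    # interaction: absorb a fraction of the weight, then scatter
                    if mut > 0.0:
                        dw = w * mua / mut
                        absorbed += dw
                        w -= dw
                        cost = _hg_cos(g if in_tissue else 0.0)
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _spin(ux, uy, uz, cost, phi)
                    tau = 0.0

                if alive and w < roulette_threshold:
                    if np.random.random() < roulette_survival:
                        gain = w / roulette_survival - w
                        absorbed -= gain  # zero-mean book-keeping
                        w /= roulette_survival
                    else:
                        absorbed += w
                        alive = False

        # per-photon tissue pathlength histogram (launch weight 1)
        sum_path += path
        ib = int(path / hist_max * n_bins)
        if ib >= n_bins:
            ib = n_bins - 1
        hist[ib] += 1.0

    return (absorbed, reflected, transmitted, lost_side, sum_wpath, sum_path,
            sum_det_wpath, sum_det_w)
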