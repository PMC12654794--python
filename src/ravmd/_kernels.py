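"""Compiled force kernel for the common fast path.

Per-step force evaluation dominates trajectory cost.  For the most common
setup — Calpha-only chains under the surrogate potential with CA-CA distance
restraints — this module provides a numba-compiled kernel computing baseline
energy/forces plus the replica-averaged restraint energy/forces in one pass
over explicit loops.  It reproduces the vectorized numpy implementation
(`potential.energy_and_forces` + `averaging.ReplicaRestraintEngine`) to
floating-point reordering accuracy; a regression test cross-checks the two on
random configurations.  Setups the kernel does not cover (angle restraints,
side-chain-mapped restraints, cosine-series torsions) fall back to the numpy
path automatically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["force_kernel", "kernel_supported"]


def kernel_supported(cfg, engine) -> bool:
    """True when the compiled fast path covers this potential/restraint setup."""
    if cfg.torsion_coeffs:
        return False
    if engine is not None and (engine.n_theta or engine.n_gamma):
        return False
    return True


@njit(cache=True)
def _force_kernel_impl(
    c,            # (M, n, 3) coordinates
    # potential parameters
    k_bond, d0, k_theta, theta0, eps_rep, r_rep,
    has_wells, g1, g2, big_b, bias, coup,
    # distance restraints
    di, dj, dlo, dhi, da, dsig, dkap, dm,
    # averaging state
    use_avg, group_size, gid, pw_group, pw_own, scale_energy,
):
    m_rep, n, _ = c.shape
    e_base = np.zeros(m_rep)
    e_restr = np.zeros(m_rep)
    f = np.zeros((m_rep, n, 3))

    for m in range(m_rep):
        # bonds
        for i in range(n - 1):
            bx = c[m, i + 1, 0] - c[m, i, 0]
            by = c[m, i + 1, 1] - c[m, i, 1]
            bz = c[m, i + 1, 2] - c[m, i, 2]
            d = np.sqrt(bx * bx + by * by + bz * bz)
            dev = d - d0
            e_base[m] += 0.5 * k_bond * dev * dev
            w = k_bond * dev / d
            f[m, i, 0] += w * bx
            f[m, i, 1] += w * by
            f[m, i, 2] += w * bz
            f[m, i + 1, 0] -= w * bx
            f[m, i + 1, 1] -= w * by
            f[m, i + 1, 2] -= w * bz

        # virtual-bond angles
        if n >= 3 and k_theta > 0.0:
            for i in range(n - 2):
                ux = c[m, i, 0] - c[m, i + 1, 0]
                uy = c[m, i, 1] - c[m, i + 1, 1]
                uz = c[m, i, 2] - c[m, i + 1, 2]
                vx = c[m, i + 2, 0] - c[m, i + 1, 0]
                vy = c[m, i + 2, 1] - c[m, i + 1, 1]
                vz = c[m, i + 2, 2] - c[m, i + 1, 2]
                nu = np.sqrt(ux * ux + uy * uy + uz * uz)
                nv = np.sqrt(vx * vx + vy * vy + vz * vz)
                cosv = (ux * vx + uy * vy + uz * vz) / (nu * nv)
                if cosv > 1.0:
                    cosv = 1.0
                elif cosv < -1.0:
                    cosv = -1.0
                th = np.arccos(cosv)
                s2 = 1.0 - cosv * cosv
                if s2 < 1e-16:
                    s2 = 1e-16
                sinv = np.sqrt(s2)
                dev = th - theta0
                e_base[m] += 0.5 * k_theta * dev * dev
                dth = k_theta * dev
                iu = 1.0 / nu
                iv = 1.0 / nv
                # d theta / d r1 and d r3
                g1x = (cosv * ux * iu - vx * iv) / (nu * sinv)
                g1y = (cosv * uy * iu - vy * iv) / (nu * sinv)
                g1z = (cosv * uz * iu - vz * iv) / (nu * sinv)
                g3x = (cosv * vx * iv - ux * iu) / (nv * sinv)
                g3y = (cosv * vy * iv - uy * iu) / (nv * sinv)
                g3z = (cosv * vz * iv - uz * iu) / (nv * sinv)
                f[m, i, 0] -= dth * g1x
                f[m, i, 1] -= dth * g1y
                f[m, i, 2] -= dth * g1z
                f[m, i + 1, 0] += dth * (g1x + g3x)
                f[m, i + 1, 1] += dth * (g1y + g3y)
                f[m, i + 1, 2] += dth * (g1z + g3z)
                f[m, i + 2, 0] -= dth * g3x
                f[m, i + 2, 1] -= dth * g3y
                f[m, i + 2, 2] -= dth * g3z

        # torsional terms: two-well + bias + nearest-neighbor coupling
        n_dih = n - 3
        if n_dih >= 1 and (has_wells or coup != 0.0):
            gam = np.empty(n_dih)
            grads = np.empty((n_dih, 4, 3))
            for t in range(n_dih):
                b1x = c[m, t + 1, 0] - c[m, t, 0]
                b1y = c[m, t + 1, 1] - c[m, t, 1]
                b1z = c[m, t + 1, 2] - c[m, t, 2]
                b2x = c[m, t + 2, 0] - c[m, t + 1, 0]
                b2y = c[m, t + 2, 1] - c[m, t + 1, 1]
                b2z = c[m, t + 2, 2] - c[m, t + 1, 2]
                b3x = c[m, t + 3, 0] - c[m, t + 2, 0]
                b3y = c[m, t + 3, 1] - c[m, t + 2, 1]
                b3z = c[m, t + 3, 2] - c[m, t + 2, 2]
                n1x = b1y * b2z - b1z * b2y
                n1y = b1z * b2x - b1x * b2z
                n1z = b1x * b2y - b1y * b2x
                n2x = b2y * b3z - b2z * b3y
                n2y = b2z * b3x - b2x * b3z
                n2z = b2x * b3y - b2y * b3x
                nb = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
                xx = n1x * n2x + n1y * n2y + n1z * n2z
                cx = n1y * n2z - n1z * n2y
                cy = n1z * n2x - n1x * n2z
                cz = n1x * n2y - n1y * n2x
                yy = (cx * b2x + cy * b2y + cz * b2z) / nb
                gam[t] = np.arctan2(yy, xx)
                n1sq = n1x * n1x + n1y * n1y + n1z * n1z
                n2sq = n2x * n2x + n2y * n2y + n2z * n2z
                wa = -nb / n1sq
                wd = nb / n2sq
                ax = wa * n1x
                ay = wa * n1y
                az = wa * n1z
                dx = wd * n2x
                dy = wd * n2y
                dz = wd * n2z
                c1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb * nb)
                c3 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb * nb)
                grads[t, 0, 0] = ax
                grads[t, 0, 1] = ay
                grads[t, 0, 2] = az
                grads[t, 1, 0] = -(1.0 + c1) * ax + c3 * dx
                grads[t, 1, 1] = -(1.0 + c1) * ay + c3 * dy
                grads[t, 1, 2] = -(1.0 + c1) * az + c3 * dz
                grads[t, 2, 0] = c1 * ax - (1.0 + c3) * dx
                grads[t, 2, 1] = c1 * ay - (1.0 + c3) * dy
                grads[t, 2, 2] = c1 * az - (1.0 + c3) * dz
                grads[t, 3, 0] = dx
                grads[t, 3, 1] = dy
                grads[t, 3, 2] = dz
            dde = np.zeros(n_dih)
            if has_wells:
                norm = 1.0 - np.cos(g1 - g2)
                for t in range(n_dih):
                    u1 = 1.0 - np.cos(gam[t] - g1)
                    u2 = 1.0 - np.cos(gam[t] - g2)
                    e_base[m] += big_b * u1 * u2
                    dde[t] += big_b * (np.sin(gam[t] - g1) * u2
                                       + u1 * np.sin(gam[t] - g2))
                    if bias != 0.0:
                        e_base[m] += bias * u2 / norm
                        dde[t] += bias * np.sin(gam[t] - g2) / norm
            if coup != 0.0 and n_dih >= 2:
                for t in range(n_dih - 1):
                    diff = gam[t + 1] - gam[t]
                    e_base[m] += -coup * np.cos(diff)
                    s = coup * np.sin(diff)
                    dde[t] += -s
                    dde[t + 1] += s
            for t in range(n_dih):
                if dde[t] != 0.0:
                    for off in range(4):
                        f[m, t + off, 0] -= dde[t] * grads[t, off, 0]
                        f[m, t + off, 1] -= dde[t] * grads[t, off, 1]
                        f[m, t + off, 2] -= dde[t] * grads[t, off, 2]

        # WCA excluded volume over non-bonded pairs
        if n >= 3 and eps_rep > 0.0:
            for i in range(n):
                for j in range(i + 2, n):
                    rx = c[m, j, 0] - c[m, i, 0]
                    ry = c[m, j, 1] - c[m, i, 1]
                    rz = c[m, j, 2] - c[m, i, 2]
                    r2 = rx * rx + ry * ry + rz * rz
                    if r2 < r_rep * r_rep:
                        sr6 = (r_rep * r_rep / r2) ** 3
                        e_base[m] += eps_rep * (sr6 * sr6 - 2.0 * sr6 + 1.0)
                        mag = 12.0 * eps_rep * (sr6 * sr6 - sr6) / r2
                        f[m, j, 0] += mag * rx
                        f[m, j, 1] += mag * ry
                        f[m, j, 2] += mag * rz
                        f[m, i, 0] -= mag * rx
                        f[m, i, 1] -= mag * ry
                        f[m, i, 2] -= mag * rz

    # distance restraints with frozen-foreign partial averaging
    n_r = di.shape[0]
    scale = float(group_size) if use_avg else 1.0
    for m in range(m_rep):
        g = gid[m]
        for p in range(n_r):
            i = di[p]
            j = dj[p]
            rx = c[m, j, 0] - c[m, i, 0]
            ry = c[m, j, 1] - c[m, i, 1]
            rz = c[m, j, 2] - c[m, i, 2]
            y = np.sqrt(rx * rx + ry * ry + rz * rz)
            if use_avg:
                pw = y ** (-dm[p])
                tot = pw_group[g, p] - pw_own[m, p] + pw
                ybar = (tot / group_size) ** (-1.0 / dm[p])
                dfac = (ybar / y) ** (dm[p] + 1.0) / group_size
            else:
                ybar = y
                dfac = 1.0
            # flat-bottom penalty value and derivative at ybar
            if ybar > dhi[p]:
                x = ybar - dhi[p]
            elif ybar < dlo[p]:
                x = ybar - dlo[p]
            else:
                x = 0.0
            ax = abs(x)
            lc = ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)
            s4 = dsig[p] ** 4
            x4 = x ** 4
            denom = s4 + x4
            pfrac = x4 / denom
            q = 1.0 + dkap[p] * lc
            e_restr[m] += da[p] * pfrac * q
            dp = 4.0 * s4 * x ** 3 / denom ** 2
            dq = dkap[p] * np.tanh(x)
            dv = da[p] * (dp * q + pfrac * dq)
            coef = scale * dv * dfac / y
            f[m, j, 0] -= coef * rx
            f[m, j, 1] -= coef * ry
            f[m, j, 2] -= coef * rz
            f[m, i, 0] += coef * rx
            f[m, i, 1] += coef * ry
            f[m, i, 2] += coef * rz

    if scale_energy and use_avg:
        for m in range(m_rep):
            e_restr[m] *= scale
    return e_base, e_restr, f


def force_kernel(coords, cfg, engine, averaged, scale_energy):
    """Baseline + restraint energies and forces via the compiled kernel.

    Returns (e_base (M,), e_restraint (M,), forces (M, n, 3)); matches the
    numpy path to floating-point reordering accuracy.
    """
    if cfg.torsion_wells is not None:
        has_wells, (g1, g2, big_b) = True, cfg.torsion_wells
    else:
        has_wells, g1, g2, big_b = False, 0.0, 0.0, 0.0
    if engine is not None and engine.n_dist:
        use_avg = bool(averaged and engine.active and engine.group_size > 1)
        pw_group = engine._pw_group_d if use_avg else np.zeros((1, engine.n_dist))
        pw_own = engine._pw_own_d if use_avg else np.zeros((coords.shape[0],
                                                            engine.n_dist))
        args = (engine._di, engine._dj, engine._dlo, engine._dhi, engine._dA,
                engine._dsig, engine._dkap, engine._dm, use_avg,
                engine.group_size, engine._gid, pw_group, pw_own,
                bool(scale_energy))
    else:
        z = np.zeros(0)
        args = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
                z, z, z, z, z, z, False, 1,
                np.zeros(coords.shape[0], dtype=np.int64),
                np.zeros((1, 0)), np.zeros((coords.shape[0], 0)), False)
    return _force_kernel_impl(
        coords, cfg.k_bond, cfg.d0, cfg.k_theta, cfg.theta0, cfg.eps_rep,
        cfg.r_rep, has_wells, float(g1), float(g2), float(big_b),
        float(cfg.torsion_well_bias), float(cfg.dihedral_coupling), *args)
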