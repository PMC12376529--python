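"""Numba kernels for the overdamped shell dynamics.

The public, readable NumPy implementations of the individual energy terms
live in :mod:`nucleomech.shell_model`; these kernels fuse them into a
single force/energy evaluation so the damped gradient flow can take the
hundreds of thousands of small steps a run needs.  The two code paths are
cross-checked against each other (and against finite differences) in the
test suite.

Integration scheme
------------------
The motion is a damped gradient flow eta * dr/dt = F(r).  A forward Euler
step is taken with an adaptive substep: a trial step is accepted only if
the Lyapunov functional

    L = U_e + U_b + U_V + U_rep + P * (V - V_ref)

does not increase (up to roundoff slack); on rejection the substep is
halved, on acceptance it is grown geometrically up to a cap.  This keeps
the discrete flow on the energy-descent path that the continuous equation
defines, at whatever step size the locally stiffest mode allows.
``V_ref`` only conditions the floating-point arithmetic (P*V is orders of
magnitude larger than its physically relevant changes).

Vertex-vertex repulsion uses a Verlet pair list (all non-bonded pairs
within ``cutoff + skin``) rebuilt via a uniform spatial grid whenever the
accumulated displacement could invalidate it.  The same pair list yields
the minimum non-bonded distance used for membrane-contact (breakdown)
detection.
"""

import numpy as np
from numba import njit

# status codes returned by `integrate`
OK = 0
BREAKDOWN = 1
STEP_COLLAPSE = 2
HARD_CORE = 3

_GROW = 1.2
_SHRINK = 0.5
_DT_MIN = 1e-15


@njit(cache=True, fastmath=True)
def forces_energy(pos, faces, edges, edge_faces, pairs,
                  l0, V0, Ke, Kb, KV, Kr, D, P, Vref, F_out):
    """Total force field and energy decomposition for one configuration.

    Returns (L, Vtot, Ue, Ub, UV, Urep, fmemb, min_pair_dist) where L is
    the conditioned Lyapunov value and fmemb the mean edge spring force
    Ke*(l - l0).  ``min_pair_dist`` is the smallest non-bonded pair
    distance seen in ``pairs`` (inf when the list is empty).
    """
    nV = pos.shape[0]
    nF = faces.shape[0]
    nE = edges.shape[0]
    F_out[:] = 0.0
    N = np.empty((nF, 3))
    Nn = np.empty(nF)

    # per-face volumes are referenced to the instantaneous centroid so the
    # volume energy is translation invariant; the centroid chain term of
    # its gradient is accumulated in G and distributed below
    mx = 0.0; my = 0.0; mz = 0.0
    for i in range(nV):
        mx += pos[i, 0]; my += pos[i, 1]; mz += pos[i, 2]
    mx /= nV; my /= nV; mz /= nV

    UV = 0.0
    Vt = 0.0
    Gx = 0.0; Gy = 0.0; Gz = 0.0
    for f in range(nF):
        a = faces[f, 0]; b = faces[f, 1]; c = faces[f, 2]
        ax = pos[a, 0] - mx; ay = pos[a, 1] - my; az = pos[a, 2] - mz
        bx = pos[b, 0] - mx; by = pos[b, 1] - my; bz = pos[b, 2] - mz
        cx = pos[c, 0] - mx; cy = pos[c, 1] - my; cz = pos[c, 2] - mz
        bcx = by * cz - bz * cy; bcy = bz * cx - bx * cz; bcz = bx * cy - by * cx
        cax = cy * az - cz * ay; cay = cz * ax - cx * az; caz = cx * ay - cy * ax
        abx = ay * bz - az * by; aby = az * bx - ax * bz; abz = ax * by - ay * bx
        Nx = bcx + cax + abx; Ny = bcy + cay + aby; Nz = bcz + caz + abz
        N[f, 0] = Nx; N[f, 1] = Ny; N[f, 2] = Nz
        Nn[f] = np.sqrt(Nx * Nx + Ny * Ny + Nz * Nz)
        Vf = (ax * bcx + ay * bcy + az * bcz) / 6.0
        Vt += Vf
        dV = Vf - V0
        UV += 0.5 * KV * dV * dV
        coef = (KV * dV + P) / 6.0
        F_out[a, 0] -= coef * bcx; F_out[a, 1] -= coef * bcy; F_out[a, 2] -= coef * bcz
        F_out[b, 0] -= coef * cax; F_out[b, 1] -= coef * cay; F_out[b, 2] -= coef * caz
        F_out[c, 0] -= coef * abx; F_out[c, 1] -= coef * aby; F_out[c, 2] -= coef * abz
        cg = KV * dV / 6.0
        Gx += cg * Nx; Gy += cg * Ny; Gz += cg * Nz

    Gx /= nV; Gy /= nV; Gz /= nV
    for i in range(nV):
        F_out[i, 0] += Gx; F_out[i, 1] += Gy; F_out[i, 2] += Gz

    Ue = 0.0
    fmemb = 0.0
    for e in range(nE):
        i = edges[e, 0]; j = edges[e, 1]
        dx = pos[i, 0] - pos[j, 0]; dy = pos[i, 1] - pos[j, 1]; dz = pos[i, 2] - pos[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        ext = l - l0
        Ue += 0.5 * Ke * ext * ext
        fmemb += Ke * ext
        g = Ke * ext / l
        F_out[i, 0] -= g * dx; F_out[i, 1] -= g * dy; F_out[i, 2] -= g * dz
        F_out[j, 0] += g * dx; F_out[j, 1] += g * dy; F_out[j, 2] += g * dz
    fmemb /= nE

    Ub = 0.0
    for e in range(nE):
        f1 = edge_faces[e, 0]; f2 = edge_faces[e, 1]
        n1x, n1y, n1z = N[f1, 0], N[f1, 1], N[f1, 2]
        n2x, n2y, n2z = N[f2, 0], N[f2, 1], N[f2, 2]
        m1 = Nn[f1]; m2 = Nn[f2]
        c = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
        Ub += Kb * (1.0 - c)
        # d(n1hat . n2hat)/dN1 = (n2hat - c*n1hat)/|N1|; force = -Kb * (-that)
        w1x = Kb * (n2x / m2 - c * n1x / m1) / m1
        w1y = Kb * (n2y / m2 - c * n1y / m1) / m1
        w1z = Kb * (n2z / m2 - c * n1z / m1) / m1
        w2x = Kb * (n1x / m1 - c * n2x / m2) / m2
        w2y = Kb * (n1y / m1 - c * n2y / m2) / m2
        w2z = Kb * (n1z / m1 - c * n2z / m2) / m2
        for k in range(2):
            if k == 0:
                f = f1; wx = w1x; wy = w1y; wz = w1z
            else:
                f = f2; wx = w2x; wy = w2y; wz = w2z
            a = faces[f, 0]; b = faces[f, 1]; cc = faces[f, 2]
            ux = pos[b, 0] - pos[cc, 0]; uy = pos[b, 1] - pos[cc, 1]; uz = pos[b, 2] - pos[cc, 2]
            F_out[a, 0] += uy * wz - uz * wy; F_out[a, 1] += uz * wx - ux * wz; F_out[a, 2] += ux * wy - uy * wx
            ux = pos[cc, 0] - pos[a, 0]; uy = pos[cc, 1] - pos[a, 1]; uz = pos[cc, 2] - pos[a, 2]
            F_out[b, 0] += uy * wz - uz * wy; F_out[b, 1] += uz * wx - ux * wz; F_out[b, 2] += ux * wy - uy * wx
            ux = pos[a, 0] - pos[b, 0]; uy = pos[a, 1] - pos[b, 1]; uz = pos[a, 2] - pos[b, 2]
            F_out[cc, 0] += uy * wz - uz * wy; F_out[cc, 1] += uz * wx - ux * wz; F_out[cc, 2] += ux * wy - uy * wx

    # 6-12 repulsion between close non-bonded vertex pairs, with the pair
    # potential shifted to zero at the threshold distance D
    Urep = 0.0
    min_d = np.inf
    phiD = Kr * (0.1 * D**-10 - 0.25 * D**-4)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]; j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]; dy = pos[i, 1] - pos[j, 1]; dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        d = np.sqrt(d2)
        if d < min_d:
            min_d = d
        if d >= D:
            continue
        inv2 = 1.0 / d2
        inv6 = inv2 * inv2 * inv2
        g = Kr * (inv6 * inv6 - inv6)          # force = g * (ri - rj)
        Urep += Kr * (0.1 * inv6 * inv6 * d2 - 0.25 * inv2 * inv2 * d2) - phiD
        F_out[i, 0] += g * dx; F_out[i, 1] += g * dy; F_out[i, 2] += g * dz
        F_out[j, 0] -= g * dx; F_out[j, 1] -= g * dy; F_out[j, 2] -= g * dz

    L = Ue + Ub + UV + Urep + P * (Vt - Vref)
    return L, Vt, Ue, Ub, UV, Urep, fmemb, min_d


@njit(cache=True)
def build_pairs(pos, cutoff, bonded_keys):
    """All non-bonded vertex pairs closer than ``cutoff``, via a uniform grid.

    ``bonded_keys`` is a sorted int64 array of i * n + j keys (i < j) for
    edge-sharing pairs, which are excluded.
    """
    n = pos.shape[0]
    inv = 1.0 / cutoff
    xmin = pos[:, 0].min(); ymin = pos[:, 1].min(); zmin = pos[:, 2].min()
    nx = int((pos[:, 0].max() - xmin) * inv) + 1
    ny = int((pos[:, 1].max() - ymin) * inv) + 1
    nz = int((pos[:, 2].max() - zmin) * inv) + 1
    cell = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) * inv)
        cy = int((pos[i, 1] - ymin) * inv)
        cz = int((pos[i, 2] - zmin) * inv)
        cell[i] = (cx * ny + cy) * nz + cz
    order = np.argsort(cell)
    sorted_cells = cell[order]
    c2 = cutoff * cutoff

    # two passes: count then fill
    out = np.empty((n * 32, 2), dtype=np.int64)  # grown on demand
    m = 0
    for i in range(n):
        ci = cell[i]
        czi = ci % nz
        cyi = (ci // nz) % ny
        cxi = ci // (nz * ny)
        for ox in range(-1, 2):
            cx = cxi + ox
            if cx < 0 or cx >= nx:
                continue
            for oy in range(-1, 2):
                cy = cyi + oy
                if cy < 0 or cy >= ny:
                    continue
                for oz in range(-1, 2):
                    cz = czi + oz
                    if cz < 0 or cz >= nz:
                        continue
                    target = (cx * ny + cy) * nz + cz
                    lo = np.searchsorted(sorted_cells, target)
                    hi = np.searchsorted(sorted_cells, target + 1)
                    for k in range(lo, hi):
                        j = order[k]
                        if j <= i:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz >= c2:
                            continue
                        key = i * n + j
                        lo2 = np.searchsorted(bonded_keys, key)
                        if lo2 < len(bonded_keys) and bonded_keys[lo2] == key:
                            continue
                        if m >= out.shape[0]:
                            bigger = np.empty((out.shape[0] * 2, 2), dtype=np.int64)
                            bigger[: out.shape[0]] = out
                            out = bigger
                        out[m, 0] = i
                        out[m, 1] = j
                        m += 1
    return out[:m].copy()


@njit(cache=True)
def integrate(pos, F, faces, edges, edge_faces, bonded_keys, pairs, ref_pos,
              l0, V0, Ke, Kb, KV, Kr, D, P, eta, Vref,
              contact_dist, cutoff, skin,
              t, t_target, dt_try, dt_max, E, disp_acc, hard_core_dist):
    """Advance the damped gradient flow from ``t`` to ``t_target``.

    ``pos``, ``F`` and ``ref_pos`` are modified in place; ``pairs`` may be
    replaced (it is returned).  Returns
    (t, dt_try, E, disp_acc, status, n_sub, n_rej, pairs, Vt, fmemb, min_d).
    """
    n_sub = 0
    n_rej = 0
    status = OK
    trial = np.empty_like(pos)
    F_new = np.empty_like(F)
    Vt = 0.0
    fmemb = 0.0
    min_d = np.inf
    inv_eta = 1.0 / eta

    while t < t_target:
        dt = dt_try
        if t + dt > t_target:
            dt = t_target - t
        s = dt * inv_eta
        max_step = 0.0
        for i in range(pos.shape[0]):
            sx = s * F[i, 0]; sy = s * F[i, 1]; sz = s * F[i, 2]
            trial[i, 0] = pos[i, 0] + sx
            trial[i, 1] = pos[i, 1] + sy
            trial[i, 2] = pos[i, 2] + sz
            a = abs(sx)
            if abs(sy) > a:
                a = abs(sy)
            if abs(sz) > a:
                a = abs(sz)
            if a > max_step:
                max_step = a
        if disp_acc + max_step > 0.5 * skin:
            # pair list may go stale during this step: rebuild from current pos
            pairs = build_pairs(pos, cutoff + skin, bonded_keys)
            ref_pos[:] = pos
            disp_acc = 0.0
        En, Vtn, Ue, Ub, UV, Urep, fmembn, mind = forces_energy(
            trial, faces, edges, edge_faces, pairs,
            l0, V0, Ke, Kb, KV, Kr, D, P, Vref, F_new)
        tol = 1e-12 * (1.0 + abs(E))
        if np.isfinite(En) and En <= E + tol:
            pos[:] = trial
            F[:] = F_new
            E = En
            Vt = Vtn
            fmemb = fmembn
            min_d = mind
            t += dt
            disp_acc += max_step
            n_sub += 1
            dt_try = min(dt_try * _GROW, dt_max)
            if mind < hard_core_dist:
                status = HARD_CORE
                break
            if mind < contact_dist:
                status = BREAKDOWN
                break
        else:
            n_rej += 1
            dt_try *= _SHRINK
            if dt_try < _DT_MIN:
                status = STEP_COLLAPSE
                break
    return t, dt_try, E, disp_acc, status, n_sub, n_rej, pairs, Vt, fmemb, min_d
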