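"""Numba kernels for the inner loops.

Everything here is plain float64/int64 array code so the Monte Carlo
engines stay fast at desk scale.  Python-level modules own all bookkeeping
and validation; kernels assume well-formed inputs.
"""

import numpy as np
from numba import njit

# Overlap guard: pair distances below this (squared) raise upstream.
R2_OVERLAP = 1e-16


@njit(cache=True)
def lj_pair(r2, eps, sig2):
    if r2 < R2_OVERLAP:  # overlap: huge finite repulsion, caller raises
        return 1e300
    s = sig2 / r2
    s6 = s * s * s
    return 4.0 * eps * (s6 * s6 - s6)


@njit(cache=True)
def total_energy_cluster(pos, n, eps, sig2):
    """All-pairs LJ energy, no cutoff. Returns (energy, min_r2)."""
    e = 0.0
    mr2 = 1e300
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < mr2:
                mr2 = r2
            e += lj_pair(r2, eps, sig2)
    return e, mr2


@njit(cache=True)
def particle_energy_cluster(pos, n, skip, x, y, z, eps, sig2):
    """Energy of a test point against all active particles except `skip`."""
    e = 0.0
    for j in range(n):
        if j == skip:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        r2 = dx * dx + dy * dy + dz * dz
        e += lj_pair(r2, eps, sig2)
    return e


@njit(cache=True)
def total_energy_bulk(pos, n, box, rc2, eps, sig2):
    """Minimum-image pair energy with spherical cutoff. Returns (E, min_r2)."""
    e = 0.0
    mr2 = 1e300
    ibox = 1.0 / box
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx * ibox)
            dy -= box * np.rint(dy * ibox)
            dz -= box * np.rint(dz * ibox)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < mr2:
                mr2 = r2
            if r2 < rc2:
                e += lj_pair(r2, eps, sig2)
    return e, mr2


@njit(cache=True)
def translate_delta_bulk(pos, n, i, xn, yn, zn, box, rc2, eps, sig2):
    """Energy change of moving particle i to (xn, yn, zn), one fused pass."""
    xo = pos[i, 0]
    yo = pos[i, 1]
    zo = pos[i, 2]
    ibox = 1.0 / box
    de = 0.0
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - xo
        dy = pos[j, 1] - yo
        dz = pos[j, 2] - zo
        dx -= box * np.rint(dx * ibox)
        dy -= box * np.rint(dy * ibox)
        dz -= box * np.rint(dz * ibox)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            de -= lj_pair(r2, eps, sig2)
        dx = pos[j, 0] - xn
        dy = pos[j, 1] - yn
        dz = pos[j, 2] - zn
        dx -= box * np.rint(dx * ibox)
        dy -= box * np.rint(dy * ibox)
        dz -= box * np.rint(dz * ibox)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            de += lj_pair(r2, eps, sig2)
    return de


@njit(cache=True)
def particle_energy_bulk(pos, n, skip, x, y, z, box, rc2, eps, sig2):
    e = 0.0
    ibox = 1.0 / box
    for j in range(n):
        if j == skip:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        dx -= box * np.rint(dx * ibox)
        dy -= box * np.rint(dy * ibox)
        dz -= box * np.rint(dz * ibox)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            e += lj_pair(r2, eps, sig2)
    return e


@njit(cache=True)
def virial_bulk(pos, n, box, rc2, eps, sig2):
    """Pair virial sum W = sum_ij r du/dr * (-1) = sum 48 eps [s12 - s6/2]."""
    w = 0.0
    ibox = 1.0 / box
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx * ibox)
            dy -= box * np.rint(dy * ibox)
            dz -= box * np.rint(dz * ibox)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2:
                s = sig2 / r2
                s6 = s * s * s
                w += 48.0 * eps * (s6 * s6 - 0.5 * s6)
    return w


@njit(cache=True)
def tail_energy_total(n, vol, rc, eps, sig):
    """Total mean-field tail correction to the energy (bulk, r > rc)."""
    rho = n / vol
    sr3 = (sig / rc) ** 3
    sr9 = sr3 ** 3
    per = (8.0 / 3.0) * np.pi * rho * eps * sig ** 3 * (sr9 / 3.0 - sr3)
    return n * per


@njit(cache=True)
def count_within(pos, n, skip, x, y, z, r2max):
    """Number of particles (excluding `skip`) within sqrt(r2max) of a point."""
    c = 0
    for j in range(n):
        if j == skip:
            continue
        dx = pos[j, 0] - x
        dy = pos[j, 1] - y
        dz = pos[j, 2] - z
        if dx * dx + dy * dy + dz * dz < r2max:
            c += 1
    return c


# ---------------------------------------------------------------------------
# connectivity (BFS)
# ---------------------------------------------------------------------------

@njit(cache=True)
def liquid_connected(pos, n, skip, r2max):
    """True iff particles [0,n) minus `skip` form one Stillinger cluster.

    Edges are pair distances < sqrt(r2max); open space (no images).
    """
    m = 0
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        if i != skip:
            idx[m] = i
            m += 1
    if m <= 1:
        return True
    visited = np.zeros(m, dtype=np.uint8)
    stack = np.empty(m, dtype=np.int64)
    stack[0] = 0
    visited[0] = 1
    top = 1
    count = 1
    while top > 0:
        top -= 1
        a = idx[stack[top]]
        for jj in range(m):
            if visited[jj]:
                continue
            b = idx[jj]
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            if dx * dx + dy * dy + dz * dz < r2max:
                visited[jj] = 1
                stack[top] = jj
                top += 1
                count += 1
    return count == m


@njit(cache=True)
def solid_connected(keys_sorted, deltas):
    """True iff the occupied-site graph is connected.

    `keys_sorted` are packed (i,j,k) site keys in ascending order; `deltas`
    are the 12 packed FCC nearest-neighbor offsets (addition-safe packing).
    """
    m = keys_sorted.shape[0]
    if m <= 1:
        return True
    visited = np.zeros(m, dtype=np.uint8)
    stack = np.empty(m, dtype=np.int64)
    stack[0] = 0
    visited[0] = 1
    top = 1
    count = 1
    while top > 0:
        top -= 1
        k = keys_sorted[stack[top]]
        for d in range(12):
            t = k + deltas[d]
            lo = np.searchsorted(keys_sorted, t)
            if lo < m and keys_sorted[lo] == t and not visited[lo]:
                visited[lo] = 1
                stack[top] = lo
                top += 1
                count += 1
    return count == m


# ---------------------------------------------------------------------------
# bulk NPT driver
# ---------------------------------------------------------------------------

@njit(cache=True)
def rsa_fill(n, box, min_dist, seed, max_trials):
    """Random sequential insertion of n points with a hard minimum distance."""
    np.random.seed(seed)
    pos = np.empty((n, 3))
    d2 = min_dist * min_dist
    placed = 0
    trials = 0
    while placed < n and trials < max_trials:
        trials += 1
        x = np.random.random() * box
        y = np.random.random() * box
        z = np.random.random() * box
        ok = True
        for j in range(placed):
            dx = pos[j, 0] - x
            dy = pos[j, 1] - y
            dz = pos[j, 2] - z
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            if dx * dx + dy * dy + dz * dz < d2:
                ok = False
                break
        if ok:
            pos[placed, 0] = x
            pos[placed, 1] = y
            pos[placed, 2] = z
            placed += 1
    return pos, placed


@njit(cache=True)
def run_npt(pos, box0, T, P, rc, tail_on, n_sweeps, max_disp, max_dlnv,
            nvol_per_sweep, seed, sample_every, eps):
    """Metropolis NPT: single-particle translations + ln-V volume moves.

    Returns (rho_samples, upair_samples, vol_samples,
             acc_tr, att_tr, acc_v, att_v, box, status)
    status 0 = ok, 1 = box shrank below 2*rc (aborted).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    box = box0
    sig2 = 1.0
    beta = 1.0 / T
    rc2 = rc * rc
    upair, _ = total_energy_bulk(pos, n, box, rc2, eps, sig2)
    utail = tail_energy_total(n, box ** 3, rc, eps, 1.0) if tail_on else 0.0

    nsamp = n_sweeps // sample_every + 1
    rho_s = np.empty(nsamp)
    u_s = np.empty(nsamp)
    v_s = np.empty(nsamp)
    w_s = np.empty(nsamp)
    ns = 0
    acc_tr = 0
    att_tr = 0
    acc_v = 0
    att_v = 0
    status = 0

    for sweep in range(n_sweeps):
        for _ in range(n):
            att_tr += 1
            i = int(np.random.random() * n)
            xo = pos[i, 0]
            yo = pos[i, 1]
            zo = pos[i, 2]
            xn = (xo + (np.random.random() - 0.5) * 2.0 * max_disp) % box
            yn = (yo + (np.random.random() - 0.5) * 2.0 * max_disp) % box
            zn = (zo + (np.random.random() - 0.5) * 2.0 * max_disp) % box
            de = translate_delta_bulk(pos, n, i, xn, yn, zn, box, rc2, eps, sig2)
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                pos[i, 0] = xn
                pos[i, 1] = yn
                pos[i, 2] = zn
                upair += de
                acc_tr += 1
        for _ in range(nvol_per_sweep):
            att_v += 1
            v_old = box ** 3
            lnv_new = np.log(v_old) + (np.random.random() - 0.5) * 2.0 * max_dlnv
            v_new = np.exp(lnv_new)
            box_new = v_new ** (1.0 / 3.0)
            scale = box_new / box
            pos_new = pos * scale
            u_new, _ = total_energy_bulk(pos_new, n, box_new, rc2, eps, sig2)
            ut_new = tail_energy_total(n, v_new, rc, eps, 1.0) if tail_on else 0.0
            du = (u_new + ut_new) - (upair + utail)
            arg = -beta * (du + P * (v_new - v_old)) + (n + 1) * np.log(v_new / v_old)
            if arg >= 0.0 or np.random.random() < np.exp(arg):
                pos[:, :] = pos_new
                box = box_new
                upair = u_new
                utail = ut_new
                acc_v += 1
            if box < 2.0 * rc:
                status = 1
                break
        if status == 1:
            break
        if (sweep + 1) % 20 == 0:  # bound float drift on the running energy
            upair, _ = total_energy_bulk(pos, n, box, rc2, eps, sig2)
        if (sweep + 1) % sample_every == 0:
            rho_s[ns] = n / box ** 3
            u_s[ns] = upair + utail
            v_s[ns] = box ** 3
            w_s[ns] = virial_bulk(pos, n, box, rc2, eps, sig2)
            ns += 1

    return (rho_s[:ns], u_s[:ns], v_s[:ns], w_s[:ns],
            acc_tr, att_tr, acc_v, att_v, box, status)
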