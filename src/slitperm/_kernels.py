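"""Numba kernels: exhaustive depth-first enumeration and flatPERM growth.

Both kernels share one geometry.  Monomer 0 sits at the centre of a
``(2 Nm + 1)^3`` occupancy grid (a chain of Nm monomers can never leave it),
and slit confinement is enforced through the *running z-extent*: a partial
chain is allowed iff it occupies at most ``slit_h`` planes.  The back-fold
(bending angle pi) never needs an explicit rule — the previous-but-one site
is occupied, so self-avoidance removes it.

Contacts are counted incrementally: placing a monomer adds (occupied
neighbours of the new site) - 1 contacts, the -1 being the bond to its
predecessor.  A joint is a right angle iff the new step differs from the
previous one (the reversal being impossible).
"""

import numpy as np
from numba import njit

_MOVES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

_NEG_INF = -np.inf


@njit(cache=True, inline="always")
def _logaddexp(a, b):
    if a < b:
        a, b = b, a
    if b == _NEG_INF:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def enumerate_kernel(n_mono, slit_h, nc_cap):
    """Exact joint counts of shapes by (contact number, right-angle joints).

    Returns an int64 matrix ``counts[nc, bends]`` over all self-avoiding
    chains of ``n_mono`` monomers whose z-extent fits in ``slit_h`` planes,
    each shape counted once (first monomer pinned, all orientations kept).
    """
    moves = _MOVES
    L = 2 * n_mono + 1
    c0 = n_mono
    occ = np.zeros((L, L, L), dtype=np.uint8)
    n_bend_bins = n_mono - 1 if n_mono >= 2 else 1
    counts = np.zeros((nc_cap + 1, n_bend_bins), dtype=np.int64)

    px = np.zeros(n_mono, dtype=np.int64)
    py = np.zeros(n_mono, dtype=np.int64)
    pz = np.zeros(n_mono, dtype=np.int64)
    dird = np.zeros(n_mono, dtype=np.int64)
    trial = np.zeros(n_mono, dtype=np.int64)
    ccum = np.zeros(n_mono, dtype=np.int64)
    bcum = np.zeros(n_mono, dtype=np.int64)
    zlo = np.zeros(n_mono, dtype=np.int64)
    zhi = np.zeros(n_mono, dtype=np.int64)

    px[0] = c0
    py[0] = c0
    pz[0] = c0
    zlo[0] = c0
    zhi[0] = c0
    occ[c0, c0, c0] = 1
    if n_mono == 1:
        counts[0, 0] = 1
        occ[c0, c0, c0] = 0
        return counts

    d = 1
    trial[1] = 0
    while d >= 1:
        placed = False
        while trial[d] < 6:
            mv = trial[d]
            trial[d] += 1
            nx = px[d - 1] + moves[mv, 0]
            ny = py[d - 1] + moves[mv, 1]
            nz = pz[d - 1] + moves[mv, 2]
            if occ[nx, ny, nz] == 1:
                continue
            nzlo = zlo[d - 1] if zlo[d - 1] < nz else nz
            nzhi = zhi[d - 1] if zhi[d - 1] > nz else nz
            if nzhi - nzlo >= slit_h:
                continue
            k = -1
            for m6 in range(6):
                if occ[nx + moves[m6, 0], ny + moves[m6, 1], nz + moves[m6, 2]] == 1:
                    k += 1
            nc = ccum[d - 1] + k
            nb = bcum[d - 1]
            if d >= 2 and mv != dird[d - 1]:
                nb += 1
            if d == n_mono - 1:
                counts[nc, nb] += 1
                continue
            occ[nx, ny, nz] = 1
            px[d] = nx
            py[d] = ny
            pz[d] = nz
            dird[d] = mv
            ccum[d] = nc
            bcum[d] = nb
            zlo[d] = nzlo
            zhi[d] = nzhi
            d += 1
            trial[d] = 0
            placed = True
            break
        if not placed:
            d -= 1
            if d >= 1:
                occ[px[d], py[d], pz[d]] = 0
    occ[c0, c0, c0] = 0
    return counts


@njit(cache=True)
def flatperm_kernel(n_mono, slit_h, nc_cap, eps_bend, n_tours, seed, bias):
    """Flat-histogram PERM estimate of the (n, Nc)-resolved growth weights.

    Chains grow monomer by monomer.  At each arrival at ``(n, Nc)`` the
    running weight sum ``W[n, Nc]`` (log-space) and visit histogram are
    updated; the ratio of the current weight to the per-tour-normalized
    estimate then drives enrichment (``ceil(r)`` copies, capped at the
    atmosphere size, each carrying ``w / copies``) or pruning (survive with
    probability ``r``, weight promoted to the estimate).  Unvisited bins act
    as infinitely attractive (ratio -> cap), which is what flattens the
    exploration.  With ``bias`` the continuation is drawn proportionally to
    its bending weight and the weight multiplies by the atmosphere total;
    otherwise the draw is uniform and the weight multiplies by
    ``(atmosphere size) * (chosen bending weight)``.  Both are unbiased.

    Returns ``(logW, visits, touched, total_steps, dead_ends)`` where
    ``touched`` counts distinct tours per bin; the density of states
    estimate is ``logW[n_mono] - log(n_tours)``.
    """
    np.random.seed(seed)
    moves = _MOVES
    L = 2 * n_mono + 1
    c0 = n_mono
    occ = np.zeros((L, L, L), dtype=np.uint8)
    logW = np.full((n_mono + 1, nc_cap + 1), _NEG_INF)
    visits = np.zeros((n_mono + 1, nc_cap + 1), dtype=np.int64)
    # distinct tours touching each bin: visits within one tour are strongly
    # correlated (enrichment copies), so this is the effective sample count
    touched = np.zeros((n_mono + 1, nc_cap + 1), dtype=np.int64)
    last_tour = np.full((n_mono + 1, nc_cap + 1), -1, dtype=np.int64)
    wb = np.exp(-eps_bend)

    px = np.zeros(n_mono, dtype=np.int64)
    py = np.zeros(n_mono, dtype=np.int64)
    pz = np.zeros(n_mono, dtype=np.int64)
    dird = np.zeros(n_mono, dtype=np.int64)
    ccum = np.zeros(n_mono, dtype=np.int64)
    zlo = np.zeros(n_mono, dtype=np.int64)
    zhi = np.zeros(n_mono, dtype=np.int64)

    # one frame per chain length n = 1 .. n_mono-1 (branch points)
    copies = np.zeros(n_mono, dtype=np.int64)
    fr_logw = np.zeros(n_mono)
    atm_cnt = np.zeros(n_mono, dtype=np.int64)
    atm_dir = np.zeros((n_mono, 6), dtype=np.int64)
    atm_wt = np.zeros((n_mono, 6))
    atm_usum = np.zeros(n_mono)
    atm_logu = np.zeros(n_mono)

    total_steps = 0
    dead_ends = 0

    px[0] = c0
    py[0] = c0
    pz[0] = c0

    for tour in range(n_tours):
        log_s = np.log(tour + 1.0)
        occ[c0, c0, c0] = 1
        ccum[0] = 0
        zlo[0] = c0
        zhi[0] = c0
        logW[1, 0] = _logaddexp(logW[1, 0], 0.0)
        visits[1, 0] += 1
        if last_tour[1, 0] != tour:
            last_tour[1, 0] = tour
            touched[1, 0] += 1
        if n_mono == 1:
            occ[c0, c0, c0] = 0
            continue

        # atmosphere of the single-monomer chain: no joint, all weights 1
        na = 0
        usum = 0.0
        for mvi in range(6):
            nz = c0 + moves[mvi, 2]
            if slit_h <= 1 and nz != c0:
                continue
            atm_dir[1, na] = mvi
            atm_wt[1, na] = 1.0
            usum += 1.0
            na += 1
        atm_cnt[1] = na
        atm_usum[1] = usum
        atm_logu[1] = np.log(usum)

        # prune/enrich decision at (1, 0); current log-weight is 0
        log_est = logW[1, 0] - log_s
        log_r = 0.0 - log_est
        if log_r <= 0.0:
            if np.log(np.random.random()) < log_r:
                copies[1] = 1
                fr_logw[1] = log_est
            else:
                occ[c0, c0, c0] = 0
                continue
        else:
            lna = np.log(float(na))
            if log_r >= lna:
                cc = na
            else:
                cc = int(np.ceil(np.exp(log_r)))
                if cc > na:
                    cc = na
            if cc < 1:
                cc = 1
            copies[1] = cc
            fr_logw[1] = -np.log(float(cc))

        d = 1
        while d >= 1:
            if copies[d] == 0:
                if d == 1:
                    break
                occ[px[d - 1], py[d - 1], pz[d - 1]] = 0
                d -= 1
                continue
            copies[d] -= 1
            total_steps += 1

            na = atm_cnt[d]
            if bias:
                r = np.random.random() * atm_usum[d]
                i = na - 1
                acc = 0.0
                for j in range(na):
                    acc += atm_wt[d, j]
                    if r < acc:
                        i = j
                        break
                lw = fr_logw[d] + atm_logu[d]
            else:
                i = int(np.random.random() * na)
                if i >= na:
                    i = na - 1
                lw = fr_logw[d] + np.log(na * atm_wt[d, i])
            mv = atm_dir[d, i]
            nx = px[d - 1] + moves[mv, 0]
            ny = py[d - 1] + moves[mv, 1]
            nz = pz[d - 1] + moves[mv, 2]
            k = -1
            for m6 in range(6):
                if occ[nx + moves[m6, 0], ny + moves[m6, 1], nz + moves[m6, 2]] == 1:
                    k += 1
            m = ccum[d - 1] + k
            occ[nx, ny, nz] = 1
            px[d] = nx
            py[d] = ny
            pz[d] = nz
            dird[d] = mv
            ccum[d] = m
            zlo[d] = zlo[d - 1] if zlo[d - 1] < nz else nz
            zhi[d] = zhi[d - 1] if zhi[d - 1] > nz else nz

            n_new = d + 1
            logW[n_new, m] = _logaddexp(logW[n_new, m], lw)
            visits[n_new, m] += 1
            if last_tour[n_new, m] != tour:
                last_tour[n_new, m] = tour
                touched[n_new, m] += 1
            if n_new == n_mono:
                occ[nx, ny, nz] = 0
                continue

            # atmosphere of the extended chain
            na2 = 0
            usum = 0.0
            for mvi in range(6):
                tx = nx + moves[mvi, 0]
                ty = ny + moves[mvi, 1]
                tz = nz + moves[mvi, 2]
                if occ[tx, ty, tz] == 1:
                    continue
                tlo = zlo[d] if zlo[d] < tz else tz
                thi = zhi[d] if zhi[d] > tz else tz
                if thi - tlo >= slit_h:
                    continue
                w = 1.0 if mvi == mv else wb
                atm_dir[n_new, na2] = mvi
                atm_wt[n_new, na2] = w
                usum += w
                na2 += 1
            if na2 == 0:
                dead_ends += 1
                occ[nx, ny, nz] = 0
                continue
            atm_cnt[n_new] = na2
            atm_usum[n_new] = usum
            atm_logu[n_new] = np.log(usum)

            log_est = logW[n_new, m] - log_s
            log_r = lw - log_est
            if log_r <= 0.0:
                if np.log(np.random.random()) < log_r:
                    copies[n_new] = 1
                    fr_logw[n_new] = log_est
                else:
                    occ[nx, ny, nz] = 0
                    continue
            else:
                lna = np.log(float(na2))
                if log_r >= lna:
                    cc = na2
                else:
                    cc = int(np.ceil(np.exp(log_r)))
                    if cc > na2:
                        cc = na2
                if cc < 1:
                    cc = 1
                copies[n_new] = cc
                fr_logw[n_new] = lw - np.log(float(cc))
            d = n_new
        occ[c0, c0, c0] = 0

    return logW, visits, touched, total_steps, dead_ends
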