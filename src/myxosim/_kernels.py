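"""Jitted engine kernels: one simulation chunk in compiled code.

Numerically equivalent to the reference implementations in ``mechanics``,
``adhesion`` and ``slime``, restructured over flat arrays for speed.  All
kernels are single-threaded and branch-deterministic, so a run is
bit-for-bit reproducible for a given (config, seed).

Layout: M agents × N nodes flattened to Mn = M·N rows; agent of global
node g is g // N, local index g % N.  Agent chains are kept geometrically
contiguous (no per-node wrap); the whole chain is re-centred by ±L_sim
when its first node leaves the box, and every inter-agent displacement is
taken minimum-image.
"""

from __future__ import annotations

import numpy as np
from numba import njit as _njit

_FASTMATH = {"nsz", "arcp", "contract", "afn", "reassoc"}


def njit(*args, **kwargs):
    kwargs.setdefault("fastmath", _FASTMATH)
    return _njit(*args, **kwargs)

# status codes returned by run_chunk
OK = 0
ERR_PAIR_OVERFLOW = 1
ERR_BOND_OVERFLOW = 2
ERR_NONFINITE = 3
ERR_BREAK_OVERFLOW = 4

BOND_EE = 0
BOND_LAT = 1

_PAIR_CUTOFF_FACTOR = 1.0  # pair cutoff = d_thr_ee + segment length (covers repulsion too)


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _turn_sign_draw(seed, agent, counter):
    """Deterministic ±1 from a counter-based hash: sub-stream per agent so
    ablations elsewhere do not shift the draw sequence."""
    h = _splitmix64(np.uint64(seed) ^ (np.uint64(agent) * np.uint64(0x632BE59BD9B4E019))
                    ^ (np.uint64(counter) * np.uint64(0x9E3779B97F4A7C15)))
    return 1 if (h & np.uint64(1)) == np.uint64(0) else -1


@njit(cache=True, inline="always")
def _min_image(d, box):
    return d - box * np.rint(d / box)


@njit(cache=True)
def _recenter(pos, anchors, M, N, box):
    """Translate each chain (and its anchors) so node 0 lies in [0, box)."""
    for a in range(M):
        base = a * N
        for k in range(2):
            shift = box * np.floor(pos[base, k] / box)
            if shift != 0.0:
                for li in range(N):
                    pos[base + li, k] -= shift
                    anchors[base + li, k] -= shift


@njit(cache=True)
def _build_cells(pos, posw, Mn, box, cell_size, ncells, cell_of, cell_count,
                 cell_start, cell_order):
    """Counting-sort nodes into a periodic uniform grid of ncells² cells;
    also caches per-node wrapped coordinates in ``posw``."""
    for c in range(ncells * ncells):
        cell_count[c] = 0
    for g in range(Mn):
        x = pos[g, 0] - box * np.floor(pos[g, 0] / box)
        y = pos[g, 1] - box * np.floor(pos[g, 1] / box)
        posw[g, 0] = x
        posw[g, 1] = y
        ci = int(x / cell_size)
        cj = int(y / cell_size)
        if ci >= ncells:
            ci = ncells - 1
        if cj >= ncells:
            cj = ncells - 1
        c = ci * ncells + cj
        cell_of[g] = c
        cell_count[c] += 1
    s = 0
    for c in range(ncells * ncells):
        cell_start[c] = s
        s += cell_count[c]
        cell_count[c] = 0
    for g in range(Mn):
        c = cell_of[g]
        cell_order[cell_start[c] + cell_count[c]] = g
        cell_count[c] += 1


@njit(cache=True)
def _find_pairs(posw, Mn, N, box, cutoff, ncells, cell_of, cell_start,
                cell_count, cell_order, pair_i, pair_j, pair_dx, pair_dy, pair_d):
    """Candidate node pairs of distinct agents within ``cutoff`` (min-image).

    Works on cached wrapped coordinates; the periodic wrap of each
    neighbour cell contributes a known ±box offset, so the inner loop is
    free of divisions.  Returns the pair count, or −1 on workspace
    overflow.  Each unordered pair appears once (i < j by global index).
    """
    cap = pair_i.shape[0]
    npairs = 0
    cut2 = cutoff * cutoff
    for g in range(Mn):
        cg = cell_of[g]
        ci = cg // ncells
        cj = cg % ncells
        ag = g // N
        xg = posw[g, 0]
        yg = posw[g, 1]
        for di in range(-1, 2):
            ii = ci + di
            ox = 0.0
            if ii < 0:
                ii += ncells
                ox = -box
            elif ii >= ncells:
                ii -= ncells
                ox = box
            for dj in range(-1, 2):
                jj = cj + dj
                oy = 0.0
                if jj < 0:
                    jj += ncells
                    oy = -box
                elif jj >= ncells:
                    jj -= ncells
                    oy = box
                c = ii * ncells + jj
                st = cell_start[c]
                for kk in range(cell_count[c]):
                    h = cell_order[st + kk]
                    if h <= g:
                        continue
                    if h // N == ag:
                        continue
                    dx = posw[h, 0] + ox - xg
                    dy = posw[h, 1] + oy - yg
                    d2 = dx * dx + dy * dy
                    if d2 <= cut2:
                        if npairs >= cap:
                            return -1
                        pair_i[npairs] = g
                        pair_j[npairs] = h
                        pair_dx[npairs] = dx
                        pair_dy[npairs] = dy
                        pair_d[npairs] = np.sqrt(d2)
                        npairs += 1
    return npairs


@njit(cache=True, inline="always")
def _segments_beyond(pos, g, h, ox, oy, reach):
    """Cheap axis-aligned bounding-box reject for a segment pair."""
    alo = min(pos[g, 0], pos[g + 1, 0])
    ahi = max(pos[g, 0], pos[g + 1, 0])
    blo = min(pos[h, 0], pos[h + 1, 0]) + ox
    bhi = max(pos[h, 0], pos[h + 1, 0]) + ox
    if blo - ahi > reach or alo - bhi > reach:
        return True
    alo = min(pos[g, 1], pos[g + 1, 1])
    ahi = max(pos[g, 1], pos[g + 1, 1])
    blo = min(pos[h, 1], pos[h + 1, 1]) + oy
    bhi = max(pos[h, 1], pos[h + 1, 1]) + oy
    return blo - ahi > reach or alo - bhi > reach


@njit(cache=True)
def _split_pair_lists(pos, N, box, npairs, pair_i, pair_j, pair_dx, pair_dy,
                      pair_d, strain, allele, adh_enabled, k_wt, k_oe,
                      seg_reach, bond_reach,
                      seg_i, seg_j, bnd_i, bnd_j, counts):
    """Split the Verlet node-pair list into (a) segment pairs whose capsule
    axes approach within ``seg_reach`` (repulsion candidates) and (b) node
    pairs that can adhere at all (adhesion candidates).  ``bond_reach`` is
    (end-end reach, lateral reach): only pairs of two end nodes can ever
    form an end-end bond (head/tail roles live on the chain ends however
    polarity flips), so pairs involving an interior node are kept only to
    the shorter lateral reach.  Both lists remain valid supersets until
    the next rebuild.  Returns 0, or −1 on overflow."""
    n_seg = 0
    n_bnd = 0
    cap_seg = seg_i.shape[0]
    cap_bnd = bnd_i.shape[0]
    reach_ee, reach_lat = bond_reach
    for p in range(npairs):
        g = pair_i[p]
        h = pair_j[p]
        d = pair_d[p]
        lg = g % N
        lh = h % N
        ends = (lg == 0 or lg == N - 1) and (lh == 0 or lh == N - 1)
        if d <= (reach_ee if ends else reach_lat):
            ag = g // N
            ah = h // N
            if _pair_kadh(strain[ag], allele[ag], strain[ah], allele[ah],
                          adh_enabled, k_wt, k_oe) > 0.0:
                if n_bnd >= cap_bnd:
                    return -1
                bnd_i[n_bnd] = g
                bnd_j[n_bnd] = h
                n_bnd += 1
        if (g % N) < N - 1 and (h % N) < N - 1:
            # pair_dx is the min-image delta, so the box offset falls out
            ox = pair_dx[p] - (pos[h, 0] - pos[g, 0])
            oy = pair_dy[p] - (pos[h, 1] - pos[g, 1])
            if _segments_beyond(pos, g, h, ox, oy, seg_reach):
                continue
            dist, s, t, nx, ny = _segment_closest(
                pos[g, 0], pos[g, 1], pos[g + 1, 0], pos[g + 1, 1],
                pos[h, 0] + ox, pos[h, 1] + oy,
                pos[h + 1, 0] + ox, pos[h + 1, 1] + oy,
            )
            if dist <= seg_reach:
                if n_seg >= cap_seg:
                    return -1
                seg_i[n_seg] = g
                seg_j[n_seg] = h
                n_seg += 1
    counts[0] = n_seg
    counts[1] = n_bnd
    return 0


@njit(cache=True)
def _sort_bond_pairs(n_bnd, bnd_i, bnd_j):
    """Order the bond-candidate list by packed key so per-step candidate
    collection emits keys in sorted order (merge needs no per-step sort)."""
    keys = np.empty(n_bnd, dtype=np.int64)
    for p in range(n_bnd):
        keys[p] = bnd_i[p] * np.int64(1 << 31) + bnd_j[p]
    order = np.argsort(keys)
    tmp_i = bnd_i[:n_bnd].copy()
    tmp_j = bnd_j[:n_bnd].copy()
    for p in range(n_bnd):
        bnd_i[p] = tmp_i[order[p]]
        bnd_j[p] = tmp_j[order[p]]


@njit(cache=True, inline="always")
def _segment_closest(p0x, p0y, p1x, p1y, q0x, q0y, q1x, q1y):
    """Closest approach of two segments; returns (dist, s, t, nx, ny) with
    (nx, ny) the unit vector from the point on p toward the point on q."""
    ux = p1x - p0x
    uy = p1y - p0y
    vx = q1x - q0x
    vy = q1y - q0y
    w0x = p0x - q0x
    w0y = p0y - q0y
    a = ux * ux + uy * uy
    b = ux * vx + uy * vy
    c = vx * vx + vy * vy
    d = ux * w0x + uy * w0y
    e = vx * w0x + vy * w0y
    denom = a * c - b * b
    if denom > 1e-12:
        s = (b * e - c * d) / denom
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    else:
        s = 0.0
    if c > 1e-12:
        t = (b * s + e) / c
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    if a > 1e-12:
        s = (b * t - d) / a
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    cpx = p0x + s * ux
    cpy = p0y + s * uy
    cqx = q0x + t * vx
    cqy = q0y + t * vy
    dx = cqx - cpx
    dy = cqy - cpy
    dist = np.sqrt(dx * dx + dy * dy)
    if dist > 1e-12:
        return dist, s, t, dx / dist, dy / dist
    return dist, s, t, 0.0, 0.0


@njit(cache=True, inline="always")
def _pair_kadh(strain_i, allele_i, strain_j, allele_j, adh_enabled, k_wt, k_oe):
    if not adh_enabled:
        return 0.0
    if allele_i != allele_j:
        return 0.0
    if strain_i == 1 and strain_j == 1:  # both OE
        return k_oe
    return k_wt


@njit(cache=True)
def _bending(pos, M, N, k_b, forces):
    for a in range(M):
        base = a * N
        for li in range(1, N - 1):
            i = base + li
            ax = pos[i, 0] - pos[i - 1, 0]
            ay = pos[i, 1] - pos[i - 1, 1]
            bx = pos[i + 1, 0] - pos[i, 0]
            by = pos[i + 1, 1] - pos[i, 1]
            la2 = ax * ax + ay * ay
            lb2 = bx * bx + by * by
            if la2 < 1e-18 or lb2 < 1e-18:
                continue
            phi = np.arctan2(ax * by - ay * bx, ax * bx + ay * by)
            gax = -ay / la2
            gay = ax / la2
            gbx = -by / lb2
            gby = bx / lb2
            kphi = k_b * phi
            forces[i - 1, 0] += -kphi * gax
            forces[i - 1, 1] += -kphi * gay
            forces[i + 1, 0] += -kphi * gbx
            forces[i + 1, 1] += -kphi * gby
            forces[i, 0] += kphi * (gax + gbx)
            forces[i, 1] += kphi * (gay + gby)


@njit(cache=True)
def _substrate(pos, anchors, M, N, head, k_a, d_a_max, forces):
    """Transverse-only focal-adhesion springs; detached anchors re-form at
    the node's position with zero force this step.

    The head node's adhesion complex is freshly assembled at its current
    position every step (focal adhesions are built at the leading pole and
    stay substrate-fixed as the body glides over them), so the head feels
    no restoring force and steering acts on a mechanically free tip."""
    for a in range(M):
        base = a * N
        h = head[a]
        for li in range(N):
            i = base + li
            if li == h:
                anchors[i, 0] = pos[i, 0]
                anchors[i, 1] = pos[i, 1]
                continue
            dx = pos[i, 0] - anchors[i, 0]
            dy = pos[i, 1] - anchors[i, 1]
            if dx * dx + dy * dy >= d_a_max * d_a_max:
                anchors[i, 0] = pos[i, 0]
                anchors[i, 1] = pos[i, 1]
                continue
            # local body axis: central difference for interior nodes
            if li == 0:
                tx = pos[i + 1, 0] - pos[i, 0]
                ty = pos[i + 1, 1] - pos[i, 1]
            elif li == N - 1:
                tx = pos[i, 0] - pos[i - 1, 0]
                ty = pos[i, 1] - pos[i - 1, 1]
            else:
                tx = pos[i + 1, 0] - pos[i - 1, 0]
                ty = pos[i + 1, 1] - pos[i - 1, 1]
            tn = np.sqrt(tx * tx + ty * ty)
            if tn < 1e-12:
                continue
            tx /= tn
            ty /= tn
            proj = dx * tx + dy * ty
            ex = dx - proj * tx
            ey = dy - proj * ty
            forces[i, 0] += -k_a * ex
            forces[i, 1] += -k_a * ey


@njit(cache=True)
def _propulsion(pos, M, N, head, turn_remaining, turn_sign, f_node,
                slime_orient, slime_time, slime_n, slime_cell, box,
                slime_on, omega_dt, t, slime_decay, forces):
    """Distributed propulsion with turn/slime-adjusted head direction.
    Trail cells older than ``slime_decay`` are treated as empty."""
    for a in range(M):
        base = a * N
        h = head[a]
        tail = N - 1 - h
        step = -1 if h == 0 else 1  # local offset toward the head
        # head heading from the neck node
        neck = h - step
        hx = pos[base + h, 0] - pos[base + neck, 0]
        hy = pos[base + h, 1] - pos[base + neck, 1]
        hn = np.sqrt(hx * hx + hy * hy)
        if hn < 1e-12:
            continue
        psi = np.arctan2(hy / hn, hx / hn)
        if turn_remaining[a] > 0.0 and turn_sign[a] != 0:
            # active 90° turn overrides slime steering
            psi = psi + turn_sign[a] * (np.pi / 2.0)
        elif slime_on:
            gx = pos[base + h, 0] - box * np.floor(pos[base + h, 0] / box)
            gy = pos[base + h, 1] - box * np.floor(pos[base + h, 1] / box)
            ci = int(gx / slime_cell)
            cj = int(gy / slime_cell)
            if ci >= slime_n:
                ci = slime_n - 1
            if cj >= slime_n:
                cj = slime_n - 1
            theta = slime_orient[ci, cj]
            if theta >= 0.0 and t - slime_time[ci, cj] <= slime_decay:
                delta = (theta - psi + np.pi / 2.0) % np.pi - np.pi / 2.0
                if delta > omega_dt:
                    delta = omega_dt
                elif delta < -omega_dt:
                    delta = -omega_dt
                psi = psi + delta
        forces[base + h, 0] += f_node * np.cos(psi)
        forces[base + h, 1] += f_node * np.sin(psi)
        for li in range(N):
            if li == h or li == tail:
                continue
            fwd = li + step
            dx = pos[base + fwd, 0] - pos[base + li, 0]
            dy = pos[base + fwd, 1] - pos[base + li, 1]
            dn = np.sqrt(dx * dx + dy * dy)
            if dn < 1e-12:
                continue
            forces[base + li, 0] += f_node * dx / dn
            forces[base + li, 1] += f_node * dy / dn


@njit(cache=True)
def _repulsion_from_pairs(pos, N, box, w, k_rep, npairs,
                          pair_i, pair_j, forces):
    """Capsule-capsule penalty repulsion over candidate segment pairs
    (identified by their lower-index owner nodes)."""
    for p in range(npairs):
        g = pair_i[p]
        h = pair_j[p]
        # offset agent-h segment next to agent-g segment (minimum image)
        ox = _min_image(pos[h, 0] - pos[g, 0], box) - (pos[h, 0] - pos[g, 0])
        oy = _min_image(pos[h, 1] - pos[g, 1], box) - (pos[h, 1] - pos[g, 1])
        if _segments_beyond(pos, g, h, ox, oy, w):
            continue
        dist, s, t, nx, ny = _segment_closest(
            pos[g, 0], pos[g, 1], pos[g + 1, 0], pos[g + 1, 1],
            pos[h, 0] + ox, pos[h, 1] + oy, pos[h + 1, 0] + ox, pos[h + 1, 1] + oy,
        )
        if dist >= w or dist <= 1e-12:
            continue
        fmag = k_rep * (w - dist)
        fx = fmag * nx  # pushes h away from g
        fy = fmag * ny
        forces[g, 0] += -fx * (1.0 - s)
        forces[g, 1] += -fy * (1.0 - s)
        forces[g + 1, 0] += -fx * s
        forces[g + 1, 1] += -fy * s
        forces[h, 0] += fx * (1.0 - t)
        forces[h, 1] += fy * (1.0 - t)
        forces[h + 1, 0] += fx * t
        forces[h + 1, 1] += fy * t


@njit(cache=True)
def _collect_bond_candidates(pos, N, box, head, strain, allele,
                             adh_enabled, k_wt, k_oe, d_thr_ee, d_thr_lat,
                             npairs, pair_i, pair_j,
                             cand_key, cand_type, cand_d):
    """Current-step candidate bonds among the bond-pair list (distances
    recomputed from live positions); returns count or −1."""
    cap = cand_key.shape[0]
    n = 0
    for p in range(npairs):
        g = pair_i[p]
        h = pair_j[p]
        dx = _min_image(pos[h, 0] - pos[g, 0], box)
        dy = _min_image(pos[h, 1] - pos[g, 1], box)
        d = np.sqrt(dx * dx + dy * dy)
        if d > d_thr_ee:
            continue
        ag = g // N
        ah = h // N
        k = _pair_kadh(strain[ag], allele[ag], strain[ah], allele[ah],
                       adh_enabled, k_wt, k_oe)
        if k == 0.0:
            continue
        lg = g % N
        lh = h % N
        hg = head[ag]
        hh = head[ah]
        is_ee = (lg == hg and lh == N - 1 - hh) or (lg == N - 1 - hg and lh == hh)
        if is_ee:
            btype = BOND_EE
        else:
            if d > d_thr_lat:
                continue
            btype = BOND_LAT
        if n >= cap:
            return -1
        cand_key[n] = np.int64(g) * np.int64(1 << 31) + np.int64(h)
        cand_type[n] = btype
        cand_d[n] = d
        n += 1
    return n


@njit(cache=True)
def _merge_bonds(t, n_prev, prev_key, prev_formed, prev_type,
                 n_cand, cand_key, cand_type, cand_d,
                 new_key, new_formed, new_type, new_d,
                 break_type, break_formed, break_broke, n_break_io):
    """Carry bond ages across steps: candidates present before keep their
    formation time; vanished bonds are logged as breaks; type changes
    (e.g. after a reversal re-labels head/tail) break and re-form.
    Both key lists are sorted ascending.  Returns new count or −1."""
    cap_break = break_type.shape[0]
    nb = n_break_io[0]
    i = 0
    j = 0
    n_new = 0
    while j < n_cand:
        ck = cand_key[j]
        while i < n_prev and prev_key[i] < ck:
            if nb >= cap_break:
                return -1
            break_type[nb] = prev_type[i]
            break_formed[nb] = prev_formed[i]
            break_broke[nb] = t
            nb += 1
            i += 1
        new_key[n_new] = ck
        new_type[n_new] = cand_type[j]
        new_d[n_new] = cand_d[j]
        if i < n_prev and prev_key[i] == ck:
            if prev_type[i] == cand_type[j]:
                new_formed[n_new] = prev_formed[i]
            else:
                if nb >= cap_break:
                    return -1
                break_type[nb] = prev_type[i]
                break_formed[nb] = prev_formed[i]
                break_broke[nb] = t
                nb += 1
                new_formed[n_new] = t
            i += 1
        else:
            new_formed[n_new] = t
        n_new += 1
        j += 1
    while i < n_prev:
        if nb >= cap_break:
            return -1
        break_type[nb] = prev_type[i]
        break_formed[nb] = prev_formed[i]
        break_broke[nb] = t
        nb += 1
        i += 1
    n_break_io[0] = nb
    return n_new


@njit(cache=True)
def _bond_forces_and_counts(pos, M, N, box, t, w, F_T,
                            adh_enabled, k_wt, k_oe, tau_thr,
                            strain, allele, per_agent_pair,
                            n_bonds, bond_key, bond_formed, bond_type, bond_d,
                            forces, ee_active, lat_active, pairseen_key):
    """Adhesion forces plus per-agent counts of suppression-active bonds.

    With ``per_agent_pair`` set, at most one active bond per (agent pair,
    type) is counted, using the sorted bond order for dedup."""
    for a in range(M):
        ee_active[a] = 0
        lat_active[a] = 0
    n_seen = 0
    for b in range(n_bonds):
        key = bond_key[b]
        g = np.int64(key) // np.int64(1 << 31)
        h = np.int64(key) % np.int64(1 << 31)
        ag = g // N
        ah = h // N
        d = bond_d[b]
        if d > w:
            k = _pair_kadh(strain[ag], allele[ag], strain[ah], allele[ah],
                           adh_enabled, k_wt, k_oe)
            fmag = k * (d - w) / w * F_T
            dx = _min_image(pos[h, 0] - pos[g, 0], box)
            dy = _min_image(pos[h, 1] - pos[g, 1], box)
            dn = np.sqrt(dx * dx + dy * dy)
            if dn > 1e-12:
                fx = fmag * dx / dn
                fy = fmag * dy / dn
                forces[g, 0] += fx
                forces[g, 1] += fy
                forces[h, 0] += -fx
                forces[h, 1] += -fy
        if t - bond_formed[b] > tau_thr:
            if per_agent_pair:
                pk = (np.int64(ag) * np.int64(1 << 24) + np.int64(ah)) * np.int64(2) \
                    + np.int64(bond_type[b])
                dup = False
                for q in range(n_seen):
                    if pairseen_key[q] == pk:
                        dup = True
                        break
                if dup:
                    continue
                if n_seen < pairseen_key.shape[0]:
                    pairseen_key[n_seen] = pk
                    n_seen += 1
            if bond_type[b] == BOND_EE:
                ee_active[ag] += 1
                ee_active[ah] += 1
            else:
                lat_active[ag] += 1
                lat_active[ah] += 1


@njit(cache=True)
def _integrate_project(pos, M, N, dt, c, seg_len, forces, n_project, max_step):
    """Overdamped update x += (F/c)·dt, then constraint projection of the
    chain spacings (symmetric pair moves preserve the centroid).

    Per-node displacement is capped at ``max_step`` (the overdamped
    analogue of a physics engine's maximum-velocity clamp): only nodes
    under extreme transient crowd pressure are affected.  Returns
    (bad, max_disp): the global index of a non-finite node (−1 if all
    finite) and the largest per-node displacement this step (for the
    Verlet-list skin accounting; the projection moves nodes by far less
    than the integration step, so the integration displacement bounds it
    up to the projection correction, which is added conservatively)."""
    Mn = M * N
    inv_c = 1.0 / c
    max_d2 = 0.0
    cap2 = max_step * max_step
    for g in range(Mn):
        ddx = forces[g, 0] * inv_c * dt
        ddy = forces[g, 1] * inv_c * dt
        d2 = ddx * ddx + ddy * ddy
        if d2 > cap2:
            scale = max_step / np.sqrt(d2)
            ddx *= scale
            ddy *= scale
            d2 = cap2
        pos[g, 0] += ddx
        pos[g, 1] += ddy
        if d2 > max_d2:
            max_d2 = d2
        if not (np.isfinite(pos[g, 0]) and np.isfinite(pos[g, 1])):
            return g, 0.0
    max_corr = 0.0
    for a in range(M):
        base = a * N
        for _ in range(n_project):
            for li in range(N - 1):
                i = base + li
                dx = pos[i + 1, 0] - pos[i, 0]
                dy = pos[i + 1, 1] - pos[i, 1]
                dist = np.sqrt(dx * dx + dy * dy)
                if dist < 1e-12:
                    continue
                corr = 0.5 * (dist - seg_len) / dist
                cx = corr * dx
                cy = corr * dy
                pos[i, 0] += cx
                pos[i, 1] += cy
                pos[i + 1, 0] -= cx
                pos[i + 1, 1] -= cy
                c2 = cx * cx + cy * cy
                if c2 > max_corr:
                    max_corr = c2
    return -1, np.sqrt(max_d2) + 2.0 * np.sqrt(max_corr)


@njit(cache=True)
def _deposit_slime(pos, M, N, head, box, slime_cell, slime_n, t,
                   slime_orient, slime_time):
    """Tail node writes the tail segment's apolar orientation; latest wins."""
    for a in range(M):
        base = a * N
        tail = N - 1 - head[a]
        nxt = tail + (1 if head[a] == N - 1 else -1)  # neighbour toward the head
        dx = pos[base + nxt, 0] - pos[base + tail, 0]
        dy = pos[base + nxt, 1] - pos[base + tail, 1]
        if dx * dx + dy * dy < 1e-18:
            continue
        theta = np.arctan2(dy, dx) % np.pi
        gx = pos[base + tail, 0] - box * np.floor(pos[base + tail, 0] / box)
        gy = pos[base + tail, 1] - box * np.floor(pos[base + tail, 1] / box)
        ci = int(gx / slime_cell)
        cj = int(gy / slime_cell)
        if ci >= slime_n:
            ci = slime_n - 1
        if cj >= slime_n:
            cj = slime_n - 1
        slime_orient[ci, cj] = theta
        slime_time[ci, cj] = t


@njit(cache=True)
def _clocks_and_events(M, t, dt, tau_r, tau_t, turn_duration,
                       delta_R_e, delta_R_l, seed,
                       strain, head, N, r, ee_active, lat_active,
                       turn_sign, turn_remaining, turn_timer, turn_count,
                       rev_agent, rev_time, n_rev_io):
    """Reversal clocks (contact-gated) and the random-turn scheduler."""
    cap = rev_agent.shape[0]
    n_rev = n_rev_io[0]
    for a in range(M):
        if strain[a] == 2:  # nonreversing: clock pinned at zero
            r[a] = 0.0
        else:
            rate = 1.0 - ee_active[a] * delta_R_e - lat_active[a] * delta_R_l
            rn = r[a] + dt * rate
            if rn < 0.0:
                rn = 0.0
            # fire on crossing the period, so the isolated-agent interval
            # is exactly tau_r quantised to one step
            if rn >= tau_r:
                rn = 0.0
                head[a] = N - 1 - head[a]
                if n_rev < cap:
                    rev_agent[n_rev] = a
                    rev_time[n_rev] = t
                    n_rev += 1
            r[a] = rn
        # turn scheduling
        if turn_remaining[a] > 0.0:
            turn_remaining[a] -= dt
            if turn_remaining[a] <= 0.0:
                turn_remaining[a] = 0.0
                turn_sign[a] = 0
        turn_timer[a] += dt
        if turn_timer[a] >= tau_t:
            turn_timer[a] -= tau_t
            turn_sign[a] = _turn_sign_draw(seed, a, turn_count[a])
            turn_count[a] += 1
            turn_remaining[a] = turn_duration
    n_rev_io[0] = n_rev


@njit(cache=True)
def run_chunk(pos, anchors, M, N, box,
              head, strain, allele, r,
              turn_sign, turn_remaining, turn_timer, turn_count,
              slime_orient, slime_time, slime_n, slime_cell, slime_on,
              bond_key, bond_formed, bond_type, bond_d, n_bonds_io,
              # parameters
              dt, t0, n_steps, seed,
              F_T, c, k_b, k_a, d_a_max, k_rep, w, seg_len,
              adh_enabled, k_wt, k_oe, d_thr_ee, d_thr_lat, tau_thr,
              per_agent_pair, delta_R_e, delta_R_l, tau_r, tau_t, turn_duration,
              omega_dt, slime_decay, n_project, max_step,
              # workspaces
              ncells, posw, cell_of, cell_count, cell_start, cell_order,
              pair_i, pair_j, pair_dx, pair_dy, pair_d,
              seg_i, seg_j, bnd_i, bnd_j, list_counts, verlet_acc, skin,
              cand_key, cand_type, cand_d,
              new_key, new_formed, new_type,
              forces, ee_active, lat_active, pairseen_key,
              # event logs
              rev_agent, rev_time, n_rev_io,
              break_type, break_formed, break_broke, n_break_io):
    """Advance ``n_steps`` integration steps from simulated time ``t0``.

    Per step: neighbour-list maintenance → bond update → force assembly
    (propulsion with turn/slime steering, bending, substrate springs,
    repulsion, adhesion) → overdamped update + length projection →
    re-centre → slime deposition → clock updates and reversal/turn events.

    Neighbour search uses a Verlet list with a skin margin: the node-pair
    list (cutoff + skin) is rebuilt only once accumulated displacement
    could let an unseen pair reach the cutoff, and is split into segment
    (repulsion) and node (adhesion) candidate sublists; distances are
    recomputed from live positions every step, so forces and bond logic
    are identical to a fresh search.  Returns a status code (OK or an
    overflow/non-finite error; on error the offending global node index
    is stored in n_rev_io[1]).
    """
    Mn = M * N
    f_node = F_T / (N - 1)
    cutoff = d_thr_ee + seg_len  # covers adhesion reach and capsule contacts
    for k in range(n_steps):
        t = t0 + k * dt
        _recenter(pos, anchors, M, N, box)
        if list_counts[2] == 0 or 2.0 * verlet_acc[0] >= 0.9 * skin:
            _build_cells(pos, posw, Mn, box, box / ncells, ncells,
                         cell_of, cell_count, cell_start, cell_order)
            npairs = _find_pairs(posw, Mn, N, box, cutoff + skin, ncells,
                                 cell_of, cell_start, cell_count, cell_order,
                                 pair_i, pair_j, pair_dx, pair_dy, pair_d)
            if npairs < 0:
                return ERR_PAIR_OVERFLOW
            ok = _split_pair_lists(pos, N, box, npairs, pair_i, pair_j,
                                   pair_dx, pair_dy, pair_d,
                                   strain, allele, adh_enabled, k_wt, k_oe,
                                   w + skin, (d_thr_ee + skin, d_thr_lat + skin),
                                   seg_i, seg_j, bnd_i, bnd_j, list_counts)
            if ok < 0:
                return ERR_PAIR_OVERFLOW
            _sort_bond_pairs(list_counts[1], bnd_i, bnd_j)
            list_counts[2] = 1
            verlet_acc[0] = 0.0
        # ---- bonds ----
        n_cand = _collect_bond_candidates(pos, N, box, head, strain, allele,
                                          adh_enabled, k_wt, k_oe,
                                          d_thr_ee, d_thr_lat,
                                          list_counts[1], bnd_i, bnd_j,
                                          cand_key, cand_type, cand_d)
        if n_cand < 0:
            return ERR_BOND_OVERFLOW
        n_new = _merge_bonds(t, n_bonds_io[0], bond_key, bond_formed, bond_type,
                             n_cand, cand_key, cand_type, cand_d,
                             new_key, new_formed, new_type, bond_d,
                             break_type, break_formed, break_broke, n_break_io)
        if n_new < 0:
            return ERR_BREAK_OVERFLOW
        n_bonds_io[0] = n_new
        for b in range(n_new):
            bond_key[b] = new_key[b]
            bond_formed[b] = new_formed[b]
            bond_type[b] = new_type[b]
        # ---- forces ----
        for g in range(Mn):
            forces[g, 0] = 0.0
            forces[g, 1] = 0.0
        _propulsion(pos, M, N, head, turn_remaining, turn_sign, f_node,
                    slime_orient, slime_time, slime_n, slime_cell, box,
                    slime_on, omega_dt, t, slime_decay, forces)
        _bending(pos, M, N, k_b, forces)
        _substrate(pos, anchors, M, N, head, k_a, d_a_max, forces)
        _repulsion_from_pairs(pos, N, box, w, k_rep, list_counts[0],
                              seg_i, seg_j, forces)
        _bond_forces_and_counts(pos, M, N, box, t, w, F_T,
                                adh_enabled, k_wt, k_oe, tau_thr,
                                strain, allele, per_agent_pair,
                                n_new, bond_key, bond_formed, bond_type, bond_d,
                                forces, ee_active, lat_active, pairseen_key)
        bad, max_disp = _integrate_project(pos, M, N, dt, c, seg_len, forces,
                                           n_project, max_step)
        if bad >= 0:
            n_rev_io[1] = bad
            return ERR_NONFINITE
        verlet_acc[0] += max_disp
        _deposit_slime(pos, M, N, head, box, slime_cell, slime_n, t + dt,
                       slime_orient, slime_time)
        _clocks_and_events(M, t + dt, dt, tau_r, tau_t, turn_duration,
                           delta_R_e, delta_R_l, seed,
                           strain, head, N, r, ee_active, lat_active,
                           turn_sign, turn_remaining, turn_timer, turn_count,
                           rev_agent, rev_time, n_rev_io)
    return OK
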