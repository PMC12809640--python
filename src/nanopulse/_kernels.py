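"""Compiled per-sample kernels for the TSW detector.

The detector state machine runs sample-by-sample; at 500 kHz this loop is the
throughput bottleneck, so it is compiled with numba. State lives in plain
numpy arrays owned by the Python wrapper (:class:`nanopulse.detector.
TSWDetector`) and is passed in on every chunk call, which makes streaming,
chunked and single-sample replay bit-identical.

The w1 sliding median uses two binary heaps with lazy deletion: heap entries
are (value, sequence-number) pairs; because w1 is a FIFO, an entry is dead
exactly when its sequence number is below the eviction counter. Dead entries
are dropped when they surface at a heap top, and a heap is compacted in place
when more than half of it is dead. Amortized cost per sample: O(log w1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# istate slots
MODE = 0
W1_COUNT = 1
W1_HEAD = 2
LOW_N = 3
HIGH_N = 4
LOW_LIVE = 5
HIGH_LIVE = 6
PUSHED = 7
EVICTED = 8
W2_COUNT = 9
W2_HEAD = 10
SAMPLE_IDX = 11
EV_CROSS = 12
EV_COUNT = 13
ARMED = 14
N1_FROZEN = 15
ISTATE_LEN = 16

# fstate slots
W1_MEAN = 0
W1_M2 = 1
W2_SUM = 2
W2_SUMSQ = 3
I0_FROZEN = 4
SIG_FROZEN = 5
MEAN1_FROZEN = 6
FSTATE_LEN = 7

# event flags
FLAG_OK = 0
FLAG_CLOG = 1


@njit(cache=True)
def _less(v1, s1, v2, s2):
    return v1 < v2 or (v1 == v2 and s1 < s2)


@njit(cache=True)
def _sift_down(kv, ks, n, i):
    while True:
        left = 2 * i + 1
        if left >= n:
            return
        small = left
        right = left + 1
        if right < n and _less(kv[right], ks[right], kv[left], ks[left]):
            small = right
        if _less(kv[small], ks[small], kv[i], ks[i]):
            kv[i], kv[small] = kv[small], kv[i]
            ks[i], ks[small] = ks[small], ks[i]
            i = small
        else:
            return


@njit(cache=True)
def _hpush(kv, ks, n, v, s):
    kv[n] = v
    ks[n] = s
    i = n
    while i > 0:
        parent = (i - 1) // 2
        if _less(kv[i], ks[i], kv[parent], ks[parent]):
            kv[i], kv[parent] = kv[parent], kv[i]
            ks[i], ks[parent] = ks[parent], ks[i]
            i = parent
        else:
            break
    return n + 1


@njit(cache=True)
def _hpop(kv, ks, n):
    n -= 1
    kv[0] = kv[n]
    ks[0] = ks[n]
    _sift_down(kv, ks, n, 0)
    return n


@njit(cache=True)
def _compact(kv, ks, n, evicted, negated):
    m = 0
    for i in range(n):
        seq = -ks[i] if negated else ks[i]
        if seq >= evicted:
            kv[m] = kv[i]
            ks[m] = ks[i]
            m += 1
    for i in range(m // 2 - 1, -1, -1):
        _sift_down(kv, ks, m, i)
    return m


@njit(cache=True)
def _purge(kv, ks, n, evicted, negated):
    while n > 0:
        seq = -ks[0] if negated else ks[0]
        if seq < evicted:
            n = _hpop(kv, ks, n)
        else:
            break
    return n


@njit(cache=True)
def _w1_push(x, istate, fstate, w1_ring, low_v, low_s, high_v, high_s, n1_init):
    """Push x into w1 (ring + heaps + Welford), evicting the oldest if full."""
    count = istate[W1_COUNT]
    head = istate[W1_HEAD]
    if count == n1_init:
        # evict the oldest FIFO element
        v_old = w1_ring[head]
        s_old = istate[EVICTED]
        istate[LOW_N] = _purge(low_v, low_s, istate[LOW_N], s_old, True)
        in_low = False
        if istate[LOW_LIVE] > 0 and istate[LOW_N] > 0:
            lv = -low_v[0]
            ls = -low_s[0]
            if v_old < lv or (v_old == lv and s_old <= ls):
                in_low = True
        if in_low:
            istate[LOW_LIVE] -= 1
        else:
            istate[HIGH_LIVE] -= 1
        istate[EVICTED] = s_old + 1
        # Welford downdate
        n = count
        mean_prev = (n * fstate[W1_MEAN] - v_old) / (n - 1)
        fstate[W1_M2] -= (v_old - mean_prev) * (v_old - fstate[W1_MEAN])
        if fstate[W1_M2] < 0.0:
            fstate[W1_M2] = 0.0
        fstate[W1_MEAN] = mean_prev
        count -= 1
        w1_ring[head] = x
        istate[W1_HEAD] = (head + 1) % n1_init
    else:
        w1_ring[(head + count) % n1_init] = x
    # Welford update
    count += 1
    delta = x - fstate[W1_MEAN]
    fstate[W1_MEAN] += delta / count
    fstate[W1_M2] += delta * (x - fstate[W1_MEAN])
    istate[W1_COUNT] = count
    # heap insert
    seq = istate[PUSHED]
    istate[PUSHED] = seq + 1
    istate[LOW_N] = _purge(low_v, low_s, istate[LOW_N], istate[EVICTED], True)
    to_low = True
    if istate[LOW_LIVE] > 0 and istate[LOW_N] > 0:
        lv = -low_v[0]
        ls = -low_s[0]
        if x > lv or (x == lv and seq > ls):
            to_low = False
    elif istate[LOW_LIVE] > 0:
        to_low = False
    if to_low:
        istate[LOW_N] = _hpush(low_v, low_s, istate[LOW_N], -x, -seq)
        istate[LOW_LIVE] += 1
    else:
        istate[HIGH_N] = _hpush(high_v, high_s, istate[HIGH_N], x, seq)
        istate[HIGH_LIVE] += 1
    # rebalance: low_live == high_live or high_live + 1
    while istate[LOW_LIVE] > istate[HIGH_LIVE] + 1:
        istate[LOW_N] = _purge(low_v, low_s, istate[LOW_N], istate[EVICTED], True)
        v = -low_v[0]
        s = -low_s[0]
        istate[LOW_N] = _hpop(low_v, low_s, istate[LOW_N])
        istate[HIGH_N] = _hpush(high_v, high_s, istate[HIGH_N], v, s)
        istate[LOW_LIVE] -= 1
        istate[HIGH_LIVE] += 1
    while istate[HIGH_LIVE] > istate[LOW_LIVE]:
        istate[HIGH_N] = _purge(high_v, high_s, istate[HIGH_N], istate[EVICTED], False)
        v = high_v[0]
        s = high_s[0]
        istate[HIGH_N] = _hpop(high_v, high_s, istate[HIGH_N])
        istate[LOW_N] = _hpush(low_v, low_s, istate[LOW_N], -v, -s)
        istate[HIGH_LIVE] -= 1
        istate[LOW_LIVE] += 1
    # compaction when mostly dead, or nearly out of room
    cap = low_v.shape[0]
    if istate[LOW_N] > 2 * istate[LOW_LIVE] + 16 or istate[LOW_N] >= cap - 2:
        istate[LOW_N] = _compact(low_v, low_s, istate[LOW_N], istate[EVICTED], True)
    if istate[HIGH_N] > 2 * istate[HIGH_LIVE] + 16 or istate[HIGH_N] >= cap - 2:
        istate[HIGH_N] = _compact(high_v, high_s, istate[HIGH_N], istate[EVICTED], False)


@njit(cache=True)
def _w1_median(istate, low_v, low_s, high_v, high_s):
    istate[LOW_N] = _purge(low_v, low_s, istate[LOW_N], istate[EVICTED], True)
    lo = -low_v[0]
    if (istate[LOW_LIVE] + istate[HIGH_LIVE]) % 2 == 1:
        return lo
    istate[HIGH_N] = _purge(high_v, high_s, istate[HIGH_N], istate[EVICTED], False)
    return 0.5 * (lo + high_v[0])


@njit(cache=True)
def _w2_push(x, istate, fstate, w2_ring, n2):
    count = istate[W2_COUNT]
    head = istate[W2_HEAD]
    if count == n2:
        old = w2_ring[head]
        fstate[W2_SUM] -= old
        fstate[W2_SUMSQ] -= old * old
        w2_ring[head] = x
        istate[W2_HEAD] = (head + 1) % n2
    else:
        w2_ring[(head + count) % n2] = x
        istate[W2_COUNT] = count + 1
    fstate[W2_SUM] += x
    fstate[W2_SUMSQ] += x * x


@njit(cache=True)
def _reset_windows(istate, fstate):
    istate[MODE] = 0
    istate[W1_COUNT] = 0
    istate[W1_HEAD] = 0
    istate[LOW_N] = 0
    istate[HIGH_N] = 0
    istate[LOW_LIVE] = 0
    istate[HIGH_LIVE] = 0
    istate[PUSHED] = 0
    istate[EVICTED] = 0
    istate[W2_COUNT] = 0
    istate[W2_HEAD] = 0
    istate[EV_COUNT] = 0
    istate[ARMED] = 0
    fstate[W1_MEAN] = 0.0
    fstate[W1_M2] = 0.0
    fstate[W2_SUM] = 0.0
    fstate[W2_SUMSQ] = 0.0


@njit(cache=True)
def run_chunk(
    chunk,
    istate,
    fstate,
    w1_ring,
    low_v,
    low_s,
    high_v,
    high_s,
    w2_ring,
    n1_init,
    n2,
    sigma_start,
    z_end,
    baseline_mode,  # 0 = median, 1 = mean
    polarity,  # 0 = both, -1 = negative-going, +1 = positive-going
    clamp_enabled,
    max_event_samples,
    ev_cross,
    ev_fire,
    ev_i0,
    ev_sigma,
    ev_flag,
    i0_out,
    emit_i0,
):
    """Advance the detector over ``chunk``; returns number of emitted events.

    Emitted events are raw (crossing index, z-fire index, frozen baseline and
    sigma); edge refinement happens in the Python wrapper.
    """
    n_ev = 0
    for k in range(chunk.shape[0]):
        x = chunk[k]
        idx = istate[SAMPLE_IDX]
        istate[SAMPLE_IDX] = idx + 1
        if istate[MODE] == 0:  # BASELINE
            ready = istate[W1_COUNT] >= n2 and istate[W1_COUNT] >= 2
            i0 = np.nan
            sigma1 = 0.0
            if ready:
                if baseline_mode == 0:
                    i0 = _w1_median(istate, low_v, low_s, high_v, high_s)
                else:
                    i0 = fstate[W1_MEAN]
                sigma1 = np.sqrt(fstate[W1_M2] / (istate[W1_COUNT] - 1))
            if emit_i0 != 0:
                i0_out[k] = i0
            if ready and sigma1 > 0.0:
                dev = x - i0
                trig = abs(dev) > sigma_start * sigma1
                if polarity < 0:
                    trig = trig and dev < 0.0
                elif polarity > 0:
                    trig = trig and dev > 0.0
                if trig:
                    istate[MODE] = 1
                    istate[EV_CROSS] = idx
                    istate[EV_COUNT] = 0
                    istate[ARMED] = 0
                    istate[N1_FROZEN] = istate[W1_COUNT]
                    fstate[I0_FROZEN] = i0
                    fstate[SIG_FROZEN] = sigma1
                    fstate[MEAN1_FROZEN] = fstate[W1_MEAN]
                    xc = x
                    if clamp_enabled != 0:
                        lo = i0 - 5.0 * sigma1
                        hi = i0 + 5.0 * sigma1
                        xc = min(max(x, lo), hi)
                    _w2_push(xc, istate, fstate, w2_ring, n2)
                    continue
            _w1_push(x, istate, fstate, w1_ring, low_v, low_s, high_v, high_s, n1_init)
            xc = x
            if ready and clamp_enabled != 0 and sigma1 > 0.0:
                lo = i0 - 5.0 * sigma1
                hi = i0 + 5.0 * sigma1
                xc = min(max(x, lo), hi)
            _w2_push(xc, istate, fstate, w2_ring, n2)
        else:  # IN_EVENT
            if emit_i0 != 0:
                i0_out[k] = fstate[I0_FROZEN]
            istate[EV_COUNT] += 1
            i0 = fstate[I0_FROZEN]
            sigma1 = fstate[SIG_FROZEN]
            xc = x
            if clamp_enabled != 0:
                lo = i0 - 5.0 * sigma1
                hi = i0 + 5.0 * sigma1
                xc = min(max(x, lo), hi)
            _w2_push(xc, istate, fstate, w2_ring, n2)
            cnt2 = istate[W2_COUNT]
            mean2 = fstate[W2_SUM] / cnt2
            var2 = 0.0
            if cnt2 >= 2:
                var2 = (fstate[W2_SUMSQ] - fstate[W2_SUM] * fstate[W2_SUM] / cnt2) / (
                    cnt2 - 1
                )
                if var2 < 0.0:
                    var2 = 0.0
            n1 = istate[N1_FROZEN]
            denom = np.sqrt(sigma1 * sigma1 / n1 + var2 / cnt2)
            if denom > 0.0:
                z = (fstate[MEAN1_FROZEN] - mean2) / denom
            else:
                z = np.inf
            if istate[ARMED] == 0 and (abs(z) >= z_end or istate[EV_COUNT] >= n2):
                istate[ARMED] = 1
            if istate[ARMED] == 1 and abs(z) < z_end:
                ev_cross[n_ev] = istate[EV_CROSS]
                ev_fire[n_ev] = idx
                ev_i0[n_ev] = i0
                ev_sigma[n_ev] = sigma1
                ev_flag[n_ev] = FLAG_OK
                n_ev += 1
                istate[MODE] = 0
                istate[EV_COUNT] = 0
                istate[ARMED] = 0
            elif istate[EV_COUNT] >= max_event_samples:
                # runaway event: likely pore clog -- abandon and flush
                ev_cross[n_ev] = istate[EV_CROSS]
                ev_fire[n_ev] = idx
                ev_i0[n_ev] = i0
                ev_sigma[n_ev] = sigma1
                ev_flag[n_ev] = FLAG_CLOG
                n_ev += 1
                _reset_windows(istate, fstate)
    return n_ev


@njit(cache=True)
def orientation_walk_kernel(u, kicks, theta):
    """Rotational Brownian walk on the unit sphere.

    ``u`` is the (3,) starting axis (unit norm, modified in place), ``kicks``
    the (n, 2) Gaussian tangential displacements; fills ``theta`` with the
    polar angle after each step.
    """
    n = kicks.shape[0]
    for i in range(n):
        # orthonormal tangent basis at u
        if abs(u[2]) > 0.9:
            rx, ry, rz = 1.0, 0.0, 0.0
        else:
            rx, ry, rz = 0.0, 0.0, 1.0
        t1x = u[1] * rz - u[2] * ry
        t1y = u[2] * rx - u[0] * rz
        t1z = u[0] * ry - u[1] * rx
        norm1 = np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
        t1x /= norm1
        t1y /= norm1
        t1z /= norm1
        t2x = u[1] * t1z - u[2] * t1y
        t2y = u[2] * t1x - u[0] * t1z
        t2z = u[0] * t1y - u[1] * t1x
        k1 = kicks[i, 0]
        k2 = kicks[i, 1]
        ux = u[0] + k1 * t1x + k2 * t2x
        uy = u[1] + k1 * t1y + k2 * t2y
        uz = u[2] + k1 * t1z + k2 * t2z
        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
        u[0] = ux / norm
        u[1] = uy / norm
        u[2] = uz / norm
        c = u[2]
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta[i] = np.arccos(c)
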