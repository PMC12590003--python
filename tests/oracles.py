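"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the NB fit oracle
is an exhaustive nested grid search over the exact likelihood, the BH oracle
is the textbook step-up recursion, and the zone oracle classifies each frame
with plain point-in-rectangle tests.
"""

import math

import numpy as np
from scipy import stats as sps


def nb_nll(k, mu, alpha):
    r = 1.0 / alpha
    return -sps.nbinom.logpmf(k, r, r / (r + mu)).sum()


def grid_search_mle(k_num, k_den, s_num, s_den, alpha, span=8.0):
    """Nested grid search over (log2 baseline, log2FC) of the two-group NB model."""
    q0 = np.log2(max(k_den.sum() / s_den.sum(), 1e-3))
    l0 = 0.0
    width = span
    for _ in range(8):
        qs = np.linspace(q0 - width, q0 + width, 41)
        ls = np.linspace(l0 - width, l0 + width, 41)
        best = (np.inf, q0, l0)
        for q in qs:
            mu_d = 2.0**q * s_den
            nll_d = nb_nll(k_den, mu_d, alpha)
            for L in ls:
                mu_n = 2.0 ** (q + L) * s_num
                nll = nll_d + nb_nll(k_num, mu_n, alpha)
                if nll < best[0]:
                    best = (nll, q, L)
        _, q0, l0 = best
        width /= 4.0
    return q0, l0


def textbook_bh(p):
    """Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def oracle_zone_of_frame(x, y, arena):
    """Zones containing the point, by independent point-in-rectangle tests."""
    w, h, sw = arena.width, arena.height, arena.strip_width

    def in_rect(x0, y0, x1, y1, closed=True):
        if closed:
            return x0 <= x <= x1 and y0 <= y <= y1
        return x0 < x < x1 and y0 < y < y1

    zones = set()
    inside1 = in_rect(sw, sw, w - sw, h - sw, closed=False)
    inside2 = in_rect(2 * sw, 2 * sw, w - 2 * sw, h - 2 * sw, closed=False)
    inside3 = in_rect(3 * sw, 3 * sw, w - 3 * sw, h - 3 * sw, closed=False)
    if not inside1:
        zones.add("strip1")
    elif not inside2:
        zones.add("strip2")
    elif not inside3:
        zones.add("strip3")
    else:
        zones.add("interior")
    cs = arena.center_size / 2.0
    if in_rect(w / 2 - cs, h / 2 - cs, w / 2 + cs, h / 2 + cs, closed=False):
        zones.add("center")
    k = arena.corner_size
    for x0, y0 in ((0, 0), (w - k, 0), (0, h - k), (w - k, h - k)):
        if in_rect(x0, y0, x0 + k, y0 + k, closed=True):
            zones.add("corners")
    return zones


def oracle_zone_metrics(traj, arena):
    """Per-frame replay of time/distance/entries for every zone."""
    t, x, y = traj.t, traj.x, traj.y
    dts = list(np.diff(t)) + [float(np.median(np.diff(t)))]
    zones = ("strip1", "strip2", "strip3", "interior", "center", "corners")
    time_s = dict.fromkeys(zones, 0.0)
    dist = dict.fromkeys(zones, 0.0)
    entries = dict.fromkeys(zones, 0)
    prev = set()
    for i in range(len(t)):
        here = oracle_zone_of_frame(x[i], y[i], arena)
        for z in here:
            time_s[z] += dts[i]
            if z not in prev:
                entries[z] += 1
            if i + 1 < len(t):
                dist[z] += math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
        prev = here
    return time_s, dist, entries
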