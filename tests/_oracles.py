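"""Independent brute-force oracles used by the test suite.

These re-derive results from first principles without sharing code
paths with the package: ROI containment by explicit shift-and-AND of
mask slices, disc means by shift-and-add, Fisher's two-sided p by full
enumeration of tables with fixed margins, and the product-limit
estimator by a hand-rolled event-by-event table.
"""

from __future__ import annotations

import math

import numpy as np


def _shift2d(arr: np.ndarray, dr: int, dc: int, fill):
    """Value at (r+dr, c+dc) moved to (r, c); out-of-grid -> fill."""
    out = np.full_like(arr, fill)
    nr, nc = arr.shape
    src_r = slice(max(0, dr), min(nr, nr + dr))
    dst_r = slice(max(0, -dr), min(nr, nr - dr))
    src_c = slice(max(0, dc), min(nc, nc + dc))
    dst_c = slice(max(0, -dc), min(nc, nc - dc))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def disc_offsets(spacing_rc, diameter):
    """In-plane integer offsets whose centers lie within diameter/2."""
    r = diameter / 2.0
    nr = int(math.floor(r / spacing_rc[0]))
    nc = int(math.floor(r / spacing_rc[1]))
    return [
        (dr, dc)
        for dr in range(-nr, nr + 1)
        for dc in range(-nc, nc + 1)
        if (dr * spacing_rc[0]) ** 2 + (dc * spacing_rc[1]) ** 2 <= r**2 + 1e-12
    ]


def brute_placement_count(mask, spacing, diameter, planes="all"):
    """Count fully-contained disc placements by explicit looping."""
    count = 0
    plane_axes = (0,) if planes == "axial" else (0, 1, 2)
    for plane_axis in plane_axes:
        r_ax, c_ax = [a for a in range(3) if a != plane_axis]
        offs = disc_offsets((spacing[r_ax], spacing[c_ax]), diameter)
        m = np.moveaxis(mask, plane_axis, 0)
        nsl, nr, nc = m.shape
        for s in range(nsl):
            for r in range(nr):
                for c in range(nc):
                    ok = True
                    for dr, dc in offs:
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < nr and 0 <= cc < nc and m[s, rr, cc]):
                            ok = False
                            break
                    count += ok
    return count


def brute_best_wi(pre, early, delay, mask, spacing, diameter, planes="all"):
    """Exhaustive max-WI over all disc placements; returns (wi, n_placements).

    Vectorised per slice with explicit shifts; placements whose
    pre-contrast mean is non-positive are skipped, mirroring the
    analysis convention.
    """
    best = -np.inf
    n_placements = 0
    plane_axes = (0,) if planes == "axial" else (0, 1, 2)
    for plane_axis in plane_axes:
        r_ax, c_ax = [a for a in range(3) if a != plane_axis]
        offs = disc_offsets((spacing[r_ax], spacing[c_ax]), diameter)
        m = np.moveaxis(mask, plane_axis, 0)
        vols = [np.moveaxis(v, plane_axis, 0) for v in (pre, early, delay)]
        for s in range(m.shape[0]):
            msl = m[s]
            ok = np.ones_like(msl, dtype=bool)
            sums = [np.zeros(msl.shape), np.zeros(msl.shape), np.zeros(msl.shape)]
            for dr, dc in offs:
                ok &= _shift2d(msl, dr, dc, False)
                for i in range(3):
                    sums[i] = sums[i] + _shift2d(vols[i][s], dr, dc, 0.0)
            n_placements += int(ok.sum())
            if not ok.any():
                continue
            s_pre = sums[0][ok]
            s_early = sums[1][ok]
            s_delay = sums[2][ok]
            usable = s_pre > 0
            if usable.any():
                wi = (s_early[usable] - s_delay[usable]) / s_pre[usable] * 100.0
                best = max(best, float(wi.max()))
    return best, n_placements


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_hyper(x):
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    p_obs = math.exp(log_hyper(a))
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = math.exp(log_hyper(x))
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def km_by_hand(times, events):
    """Product-limit table computed event-by-event, returning (t, S(t))."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out_t, out_s = [], []
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        d = 0
        at_risk = n - i
        while i < n and times[i] == t:
            d += int(events[i])
            i += 1
        if d:
            s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
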