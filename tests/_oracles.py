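"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive expected values by naive exhaustive methods
(linear programming, full pair enumeration) so the package's optimised
implementations are checked against something that shares none of their
code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# Dip statistic: minimax distance to the nearest unimodal CDF, solved as a
# family of linear programs, one per candidate mode point.
# ---------------------------------------------------------------------------

def dip_brute_force(sample) -> float:
    """Exact dip by LP minimisation over all unimodal CDF placements.

    A unimodal CDF G is convex left of its mode, concave right of it, and
    may jump only at the mode.  The sup-distance between G and the ECDF
    depends only on G's values and left limits at the distinct data
    points, and any feasible set of such values extends to a genuine
    unimodal CDF, so for a fixed mode point the minimal sup-distance is a
    linear program.  A mode placed strictly between data points (or
    outside the data range) is always dominated by a mode placed at an
    adjacent data point with an atom allowed, so minimising over the
    point placements is exact.  Intended for small n.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    xs, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n               # F at each distinct point
    lo_f = np.concatenate(([0.0], cum[:-1]))  # F left-limit
    best = np.inf
    for m in range(xs.size):
        best = min(best, _dip_lp_mode_at(xs, cum, lo_f, m))
    return float(best)


def _dip_lp_mode_at(xs, cum, lo_f, m):
    """Minimal sup-deviation with the mode (and possible atom) at xs[m].

    Variables: v[0..g-1] are G at the points, except v[m] is G's left
    limit at the mode; v[g] is G's value at the mode; v[g+1] is t.
    """
    g = xs.size
    vm = g
    t = g + 1
    nvar = g + 2
    A_ub, b_ub = [], []

    def row(coefs, rhs=0.0):
        r = np.zeros(nvar)
        for idx, c in coefs:
            r[idx] += c
        A_ub.append(r)
        b_ub.append(rhs)

    def val_idx(i):  # index of G(xs[i])
        return vm if i == m else i

    # |G - F| <= t at left limits and values
    for i in range(g):
        row([(i, 1.0), (t, -1.0)], lo_f[i])      # v_i >= lo_f - t ... both:
        row([(i, -1.0), (t, -1.0)], -lo_f[i])
        vi = val_idx(i)
        row([(vi, 1.0), (t, -1.0)], cum[i])
        row([(vi, -1.0), (t, -1.0)], -cum[i])

    # monotone: ... v[m-1] <= v[m] (left limit) <= v[vm] <= v[m+1] ...
    chain = list(range(m + 1)) + [vm] + list(range(m + 1, g))
    chain_x = [xs[i] for i in range(m + 1)] + [xs[m]] + \
              [xs[i] for i in range(m + 1, g)]
    for a, b in zip(chain[:-1], chain[1:]):
        row([(a, 1.0), (b, -1.0)])

    # convex slopes on the left chain 0..m (ending at the left limit)
    left = chain[: m + 1]
    left_x = chain_x[: m + 1]
    for (a, xa), (b, xb), (c, xc) in zip(
        zip(left[:-2], left_x[:-2]), zip(left[1:-1], left_x[1:-1]),
        zip(left[2:], left_x[2:])
    ):
        # (v_b - v_a)/(xb-xa) <= (v_c - v_b)/(xc-xb)
        row([(b, (xc - xb) + (xb - xa)), (a, -(xc - xb)), (c, -(xb - xa))])

    # concave slopes on the right chain vm, m+1 .. g-1
    right = chain[m + 1:]
    right_x = chain_x[m + 1:]
    for (a, xa), (b, xb), (c, xc) in zip(
        zip(right[:-2], right_x[:-2]), zip(right[1:-1], right_x[1:-1]),
        zip(right[2:], right_x[2:])
    ):
        # (v_b - v_a)/(xb-xa) >= (v_c - v_b)/(xc-xb)
        row([(a, (xc - xb)), (c, (xb - xa)), (b, -((xc - xb) + (xb - xa)))])

    c_obj = np.zeros(nvar)
    c_obj[t] = 1.0
    bounds = [(0.0, 1.0)] * (g + 1) + [(0.0, 0.5)]
    res = linprog(c_obj, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    return res.fun if res.success else np.inf


# ---------------------------------------------------------------------------
# Marker detection: exhaustive pair-scan oracle.
# ---------------------------------------------------------------------------

def markers_brute_force(spectrum, config):
    """Marker wavelengths by full enumeration of grid-point pairs.

    Works on the same smoothed curve and extrema segmentation as the
    implementation (those stages have their own oracles) but replaces the
    within-segment search by brute force: every pair (i, j) inside a
    segment with width < max_span is examined; qualifying pairs are
    ranked by (span, -|change|, start); the winner is extended while the
    curve keeps changing strictly in its direction, and the half-height
    crossing is located by an independent scan.
    """
    from floracue.markers import (_extrema_indices, _segment_bounds,
                                  smooth_spectrum)
    from floracue.spectra import to_canonical

    spectrum = to_canonical(spectrum)
    sm = smooth_spectrum(spectrum, config.smoothing_window)
    y, w = sm.reflectance, sm.wavelengths
    extrema = _extrema_indices(y, config.lookahead,
                               config.effective_min_delta)
    found = []
    for a, b in _segment_bounds(y.size, extrema):
        cands = []
        for i in range(a, b + 1):
            for j in range(i + 1, b + 1):
                if w[j] - w[i] >= config.max_span:
                    continue
                d = y[j] - y[i]
                ok = (d >= config.threshold and "rise" in config.directions) \
                    or (-d >= config.threshold and "fall" in config.directions)
                if ok:
                    cands.append((w[j] - w[i], -abs(d), i, j, d))
        if not cands:
            continue
        cands.sort()
        _, _, i, j, d = cands[0]
        sign = 1.0 if d > 0 else -1.0
        while i > a and sign * (y[i] - y[i - 1]) > 0:
            i -= 1
        while j < b and sign * (y[j + 1] - y[j]) > 0:
            j += 1
        mid = 0.5 * (y[i] + y[j])
        pos = None
        for t in range(i, j):
            lo, hi = sorted((y[t], y[t + 1]))
            if lo <= mid <= hi:
                if y[t + 1] == y[t]:
                    pos = w[t]
                else:
                    pos = w[t] + (mid - y[t]) / (y[t + 1] - y[t]) \
                        * (w[t + 1] - w[t])
                break
        found.append((float(pos), "rise" if sign > 0 else "fall",
                      float(abs(y[j] - y[i])), float(w[j] - w[i])))
    return found


def local_extrema_exhaustive(y, lookahead):
    """Interior strict local extrema by direct neighbourhood comparison
    (for smooth curves without plateaus)."""
    out = []
    n = len(y)
    for i in range(1, n - 1):
        lo = max(0, i - lookahead)
        hi = min(n, i + lookahead + 1)
        window = y[lo:hi]
        if y[i] == window.max() and y[i] > y[i - 1] and y[i] > y[i + 1]:
            out.append((i, "max"))
        elif y[i] == window.min() and y[i] < y[i - 1] and y[i] < y[i + 1]:
            out.append((i, "min"))
    return out
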