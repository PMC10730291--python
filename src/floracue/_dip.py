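"""Hartigan–Hartigan dip statistic for unimodality.

The dip of a sample is the smallest, over all unimodal distribution
functions G, of the largest absolute deviation between the empirical CDF
and G.  It is computed exactly for the given sample with the classic
greatest-convex-minorant / least-concave-majorant sweep: the candidate
modal interval [low, high] is shrunk iteratively while tracking the
largest deviation of the ECDF above the convex minorant (left of the
modal interval) and below the concave majorant (right of it).

Internally deviations are kept in count units (n times probability) and
the final statistic is ``max_deviation / (2 n)``.  For a sample of n
distinct values the dip is at least ``1 / (2 n)``; the supremum over all
samples is 0.25, approached by two equal point masses far apart.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(sample) -> float:
    """Exact dip statistic of a 1-D sample.

    Parameters
    ----------
    sample : array-like
        Observations; need not be sorted. ``n >= 4`` is required (the
        statistic is degenerate below that).

    Returns
    -------
    float
        The dip ``D``, with ``1/(2n) <= D <= 0.25`` for samples of
        distinct values (0.0 for an all-equal sample).
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic requires n >= 4, got n={n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if x[0] == x[-1]:
        return 0.0
    return _dip_sorted(x)


def _dip_sorted(xs: np.ndarray) -> float:
    """Dip of a sorted sample (1-based work arrays, count units)."""
    n = xs.size
    # 1-based padding keeps the index arithmetic identical to the
    # published algorithm.
    x = np.empty(n + 1)
    x[1:] = xs

    # mn[j]: previous touch index of the convex minorant fitted up to j.
    mn = np.empty(n + 1, dtype=np.intp)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 1:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj

    # mj[k]: next touch index of the concave majorant fitted down to k.
    mj = np.empty(n + 1, dtype=np.intp)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; the floor 1/(2n) after rescaling

    gcm = np.empty(n + 2, dtype=np.intp)
    lcm = np.empty(n + 2, dtype=np.intp)

    for _ in range(4 * n + 16):  # modal interval strictly shrinks
        # Touch points of the hulls on [low, high].  gcm runs high..low,
        # lcm runs low..high.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i
        ig = l_gcm
        ix = l_gcm - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i
        ih = l_lcm
        iv = 2

        # Largest gap between the concave majorant and convex minorant,
        # evaluated at the touch points of the opposite hull.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # gap at the lcm touch point lcmiv
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # gap at the gcm touch point gcmix
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d <= dip:
            break

        # Largest deviation of the ECDF above the convex minorant between
        # low and the left end of the candidate modal interval.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Largest deviation of the ECDF below the concave majorant between
        # the right end of the candidate modal interval and high.
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]
    else:  # pragma: no cover - defensive
        raise RuntimeError("dip computation failed to converge")

    return dip / (2.0 * n)
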