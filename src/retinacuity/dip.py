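"""Hartigan's dip statistic and a bootstrap test of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF ``F_n`` and the class of unimodal distribution functions (convex up to
some mode, concave after it, with an atom permitted only at the mode).

The computation follows the classical iterative scheme: maintain a candidate
modal interval ``[x_low, x_high]``; compute the greatest convex minorant
(GCM) and least concave majorant (LCM) of ``F_n`` on it; the largest
GCM-LCM crossing distance bounds what any unimodal fit must absorb inside
the interval, while the deviations of ``F_n`` from the GCM left of the
modal interval and from the LCM right of it bound the one-sided fit errors;
the interval is then shrunk to the crossing location and the process
repeats until no larger deviation can be found.  The dip is half the
largest deviation encountered (in units of ``1/n``), with ``1/(2n)`` as the
floor attained by perfectly unimodal samples.

``tests/test_dip.py`` checks this implementation against an independent
linear-programming oracle that solves the defining minimax problem on a
fine x-grid, where the unimodal shape constraints are plain linear
inequalities on slopes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _gcm_predecessors(x: np.ndarray) -> np.ndarray:
    """mn[j]: previous touch point of the greatest convex minorant at j."""
    n = x.size
    mn = np.empty(n, dtype=np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    return mn


def _lcm_successors(x: np.ndarray) -> np.ndarray:
    """mj[k]: next touch point of the least concave majorant at k."""
    n = x.size
    mj = np.empty(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a one-dimensional sample.

    Degenerate samples (fewer than 2 values, or all values equal) return 0;
    any sample of 2 or 3 values attains the unimodal floor ``1/(2n)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if n < 4:
        return 1.0 / (2 * n)

    mn = _gcm_predecessors(x)
    mj = _lcm_successors(x)
    low, high = 0, n - 1
    dip = 1.0  # in count units; /(2n) on return

    while True:
        # GCM touch points high -> low, LCM touch points low -> high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_gcm = len(gcm) - 1
        l_lcm = len(lcm) - 1

        # largest crossing distance between the two envelopes
        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 1, 1
        d = 0.0
        if l_gcm != 1 or l_lcm != 1:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # LCM touch point inside a GCM segment
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # GCM touch point inside an LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # one-sided deviations outside the new modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0  # a segment always costs at least one count
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    max_t = max(max_t, t)
            dip_l = max(dip_l, max_t)
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    max_t = max(max_t, t)
            dip_u = max(dip_u, max_t)

        dip = max(dip, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2 * n)


@lru_cache(maxsize=32)
def _null_dips(n: int, n_bootstrap: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(0.0, 1.0, n)) for _ in range(n_bootstrap))


def dip_test(x, n_bootstrap: int = 500, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value under the uniform null.

    The null distribution of the dip depends on the sample size only; it is
    estimated from ``n_bootstrap`` uniform samples of the same size (cached
    per size/seed).  Returns ``(dip, p_value)`` where the p-value is the
    fraction of null dips at least as large as the observed one.
    """
    x = np.asarray(x, dtype=float)
    stat = dip_statistic(x)
    null = np.array(_null_dips(int(x.size), n_bootstrap, seed))
    p = float((null >= stat).mean())
    return stat, p
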