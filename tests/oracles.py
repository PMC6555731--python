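"""Independent reference computations used only by the tests.

These deliberately avoid the code paths they check: the period oracle uses
autocorrelation instead of the FFT spectrum, and the rank-sum oracle
enumerates subsets by brute force instead of the package's DP recursion.
"""

from __future__ import annotations

import itertools

import numpy as np


def autocorr_period(profile, min_period_um: float = 1.6, max_period_um: float = 3.4):
    """Period = lag of the highest in-band autocorrelation maximum, refined by
    parabolic interpolation over lags.  Returns None if the band holds no lag."""
    y = profile.intensities - profile.intensities.mean()
    ac = np.correlate(y, y, mode="full")[y.size - 1 :]
    dx = profile.pixel_size_um
    lmin = int(np.ceil(min_period_um / dx))
    lmax = min(int(np.floor(max_period_um / dx)), ac.size - 2)
    if lmax < lmin:
        return None
    k = lmin + int(np.argmax(ac[lmin : lmax + 1]))
    a, b, c = ac[k - 1], ac[k], ac[k + 1]
    denom = a - 2 * b + c
    delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    return (k + float(np.clip(delta, -0.5, 0.5))) * dx


def brute_force_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by enumerating every subset of ranks.

    Only feasible for tiny samples; assumes no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    order = np.argsort(combined)
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, combined.size + 1)
    w_obs = ranks[: x.size].sum()
    n, total = x.size, combined.size
    ws = np.array([sum(c) for c in itertools.combinations(range(1, total + 1), n)])
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
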