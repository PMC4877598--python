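"""Independent reference implementations used only by the tests.

These deliberately take the slow, direct route (explicit two-sample t
statistics, numerical quadrature, exhaustive alignment recursion) so they
share no code path with the package internals they check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy.special import betaln


def beta_survival_quadrature(a: float, b: float, theta: float) -> float:
    """Pr(X >= theta) for X ~ Beta(a, b) by adaptive quadrature of the
    density over [theta, 1]."""

    def pdf(x: float) -> float:
        return np.exp((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b))

    val, _err = integrate.quad(pdf, theta, 1.0, epsabs=1e-12, epsrel=1e-12, limit=500)
    return val


def _max_arc_t(seg: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best circular arc (i, j] by the two-sample t statistic, exhaustively.

    Returns (t^2, i, j); ties resolved to the smallest i then j. Arcs that
    wrap the circle are the complements of non-wrapping arcs and give the
    same statistic, so enumerating i < j covers everything.
    """
    n = len(seg)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    q = np.concatenate(([0.0], np.cumsum(seg**2)))
    best = (-np.inf, 0, n)
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            m = j - i
            if m > n - min_width:
                continue
            arc_sum = s[j] - s[i]
            comp_sum = s[n] - arc_sum
            ma, mc = arc_sum / m, comp_sum / (n - m)
            ss_within = (q[j] - q[i] - m * ma**2) + (q[n] - (q[j] - q[i]) - (n - m) * mc**2)
            d = ma - mc
            if ss_within <= 0:
                t2 = np.inf if d != 0 else 0.0
            else:
                s2 = ss_within / (n - 2)
                t2 = d * d / (s2 * (1 / m + 1 / (n - m)))
            if t2 > best[0]:
                best = (t2, i, j)
    return best


def cbs_boundaries(
    values: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_width: int = 2,
) -> list[int]:
    """Segment start indices from an exhaustive-arc CBS with the same
    permutation protocol as the package (child generator [seed, k] per test
    in depth-first order; permutations via argsort of rng.random(n))."""
    x = np.asarray(values, dtype=float)
    counter = {"k": 0}
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        test_seed = counter["k"]
        counter["k"] += 1
        if n >= 2 * min_width:
            ss_tot = float(np.sum((seg - seg.mean()) ** 2))
            t2_obs, i, j = _max_arc_t(seg, min_width)
            if ss_tot > 0 and t2_obs > 0:
                rng = np.random.default_rng([seed, test_seed])
                count = 0
                for _ in range(n_perm):
                    xp = seg[np.argsort(rng.random(n))]
                    if _max_arc_t(xp, min_width)[0] >= t2_obs:
                        count += 1
                if count / n_perm < alpha:
                    cuts = [c for c in (i, j) if 0 < c < n]
                    if cuts:
                        prev = lo
                        for c in cuts:
                            recurse(prev, lo + c)
                            prev = lo + c
                        recurse(prev, hi)
                        return
        breaks.append(lo)

    recurse(0, len(x))
    return sorted(breaks)


def global_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal global alignment score by exhaustive recursion over the three
    moves at every cell (memoized); N scores 0 against anything."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            if "N" in (a[i], b[j]):
                s = 0.0
            else:
                s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)
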