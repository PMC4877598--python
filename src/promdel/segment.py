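"""Circular binary segmentation of binned depth log-ratios and
heterozygous-deletion calling.

The input track holds log2(observed / expected diploid) depth per bin; a
heterozygous deletion shows as a step to about -1. Segmentation treats the
current interval as a circle, finds the arc whose mean differs most from its
complement (two-sample t statistic), judges the split by a permutation test,
and recurses on the resulting pieces until nothing significant remains. The
emitted segments partition the track exactly.

Implementation note: at fixed total sum of squares the squared t statistic is
a strictly increasing function of the between-group sum of squares
B = m(n-m)/n * (mean_arc - mean_rest)^2, and permuting the bin values leaves
the total SS unchanged; the search and the permutation test therefore
maximise/compare B, which reduces the inner loop to prefix-sum arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import InputError


@dataclass
class RatioTrack:
    """Binned log2 depth ratios with 1-based inclusive bin coordinates."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise InputError("starts, ends and values must have equal length")
        if np.any(self.ends < self.starts):
            raise InputError("bins must satisfy start <= end")
        if np.any(self.starts[1:] <= self.ends[:-1]):
            raise InputError("bins must be sorted and non-overlapping")
        if not np.all(np.isfinite(self.values)):
            raise InputError("ratio values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CopySegment:
    chrom: str
    start_bin: int  # inclusive bin indices into the track
    end_bin: int
    start: int  # genomic bp, 1-based inclusive
    end: int
    mean_value: float
    n_bins: int
    state: str  # diploid | het-loss | other


@dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    length: int
    mean_log2: float
    resolution: int  # +/- bp, one bin


def compute_ratios(
    depth: pd.DataFrame,
    expected: float | pd.DataFrame,
    pseudocount: float = 0.5,
) -> RatioTrack:
    """log2((depth + c) / (expected + c)) per bin against a scalar diploid
    expectation or a bin-matched control profile."""
    d = depth["depth"].to_numpy(dtype=float)
    if isinstance(expected, pd.DataFrame):
        if len(expected) != len(depth) or not (
            np.array_equal(expected["start"].to_numpy(), depth["start"].to_numpy())
            and np.array_equal(expected["end"].to_numpy(), depth["end"].to_numpy())
        ):
            raise InputError("case and control depth profiles have mismatched bins")
        e = expected["depth"].to_numpy(dtype=float)
    else:
        e = float(expected)
        if e <= 0:
            raise InputError("expected depth must be positive")
        e = np.full_like(d, e)
    values = np.log2((d + pseudocount) / (e + pseudocount))
    return RatioTrack(
        chrom=str(depth["chrom"].iloc[0]),
        starts=depth["start"].to_numpy(),
        ends=depth["end"].to_numpy(),
        values=values,
    )


def _arc_pairs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) prefix-boundary pairs whose arc (i, j] and complement both
    span at least min_width bins."""
    i, j = np.triu_indices(n + 1, k=min_width)
    keep = (j - i) <= n - min_width
    return i[keep], j[keep]


def _max_arc(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Between-SS statistic of the best arc and its boundaries (i, j]."""
    n = len(x)
    ii, jj = _arc_pairs(n, min_width)
    if len(ii) == 0:
        return 0.0, 0, n
    s = np.concatenate(([0.0], np.cumsum(x)))
    m = (jj - ii).astype(float)
    mu = s[-1] / n
    b = (s[jj] - s[ii] - m * mu) ** 2 / (m * (n - m))
    k = int(np.argmax(b))  # ties: smallest i, then smallest j (row-major order)
    return float(b[k]), int(ii[k]), int(jj[k])


def _perm_pvalue(
    x: np.ndarray,
    b_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float,
    min_width: int,
    chunk: int = 64,
) -> float:
    """Permutation p-value of the observed max-B statistic.

    Permutations come from argsort of rng.random((n_perm, n)), drawn in
    chunks (identical stream to drawing rows one at a time). Once the
    exceedance count already implies p >= alpha, remaining permutations
    cannot change the split decision and are skipped; the returned p is then
    the conservative count/n_done.
    """
    n = len(x)
    ii, jj = _arc_pairs(n, min_width)
    m = (jj - ii).astype(float)
    w = m * (n - m)
    mu = float(np.sum(x)) / n
    stop_at = int(np.ceil(alpha * n_perm))  # count >= stop_at => p >= alpha
    count = 0
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        xp = x[order]
        s = np.concatenate((np.zeros((k, 1)), np.cumsum(xp, axis=1)), axis=1)
        b = (s[:, jj] - s[:, ii] - m * mu) ** 2 / w
        count += int(np.sum(b.max(axis=1) >= b_obs))
        done += k
        if count >= stop_at:
            break
    return count / done


def cbs_segment(
    track: RatioTrack,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_width: int = 2,
    het_loss_max: float = -0.6,
    neutral_band: float = 0.3,
) -> list[CopySegment]:
    """Recursive circular binary segmentation of *track*.

    Each candidate split is kept when its permutation p-value is strictly
    below ``alpha``; each segment test uses an independent generator seeded
    ``[seed, k]`` with k the depth-first test counter, so results are
    reproducible and unaffected by early stopping elsewhere. Segment ``state``
    is het-loss when the mean is <= ``het_loss_max``, diploid when within
    ``neutral_band`` of zero, otherwise "other".
    """
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must lie in (0, 1)")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-values; 1000 is the default",
            stacklevel=2,
        )
    if len(track) < 2:
        raise InputError("need at least 2 bins to segment")

    x = track.values
    counter = {"k": 0}
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        test_seed = counter["k"]
        counter["k"] += 1
        if n >= 2 * min_width:
            b_obs, i, j = _max_arc(seg, min_width)
            ss_tot = float(np.sum((seg - seg.mean()) ** 2))
            if ss_tot > 0 and b_obs > 0:
                rng = np.random.default_rng([seed, test_seed])
                p = _perm_pvalue(seg, b_obs, n_perm, rng, alpha, min_width)
                if p < alpha:
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
    bounds = sorted(breaks) + [len(x)]
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mean = float(np.mean(x[lo:hi]))
        if mean <= het_loss_max:
            state = "het-loss"
        elif abs(mean) <= neutral_band:
            state = "diploid"
        else:
            state = "other"
        segments.append(
            CopySegment(
                chrom=track.chrom,
                start_bin=lo,
                end_bin=hi - 1,
                start=int(track.starts[lo]),
                end=int(track.ends[hi - 1]),
                mean_value=mean,
                n_bins=hi - lo,
                state=state,
            )
        )
    return segments


def detect_deletion(
    segments: list[CopySegment],
    het_loss_max: float = -0.6,
    min_bins: int = 3,
) -> list[DeletionCall]:
    """Turn qualifying low segments into deletion calls.

    A segment qualifies when its mean log2 ratio is <= ``het_loss_max`` and it
    spans at least ``min_bins`` bins; adjacent qualifying segments merge into
    one call. Breakpoint resolution is one bin.
    """
    calls: list[DeletionCall] = []
    run: list[CopySegment] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0].start, run[-1].end
        n = sum(s.n_bins for s in run)
        mean = sum(s.mean_value * s.n_bins for s in run) / n
        bin_size = run[0].end - run[0].start + 1 if run[0].n_bins == 1 else (
            (run[0].end - run[0].start + 1) // run[0].n_bins
        )
        calls.append(
            DeletionCall(
                chrom=run[0].chrom,
                start=start,
                end=end,
                length=deletion_length(start, end),
                mean_log2=mean,
                resolution=bin_size,
            )
        )
        run.clear()

    prev: CopySegment | None = None
    for seg in segments:
        ok = seg.mean_value <= het_loss_max and seg.n_bins >= min_bins
        adjacent = prev is not None and seg.start_bin == prev.end_bin + 1
        if ok:
            if run and not adjacent:
                flush()
            run.append(seg)
        else:
            flush()
        prev = seg
    flush()
    return calls


def deletion_length(start: int, end: int) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    if start > end:
        raise InputError(f"start {start} exceeds end {end}")
    return end - start + 1
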