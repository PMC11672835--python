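"""Interspecies physiological synchrony on mid-interaction RE slices.

For each interaction subsession an 18-epoch (3 min) slice of the 10 Hz RE
series is taken from the subsession's temporal center, torso devices only
(human chest, canine harness).  Two complementary couplings are computed
per metric (HR, SDNN, RMSSD, IMA): the lockstep Pearson correlation, and
the dynamic-time-warping cumulative path distance, which tolerates
temporal asynchrony between the two members.  DTW runs on raw metric
units by default (a species heart-rate offset then dominates the HR path
distance, as expected); a z-scored mode removes level and scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .preprocess import normalize
from .session import Subsession, ValidationError
from .metrics import ReSeries

SYNC_METRICS = ("HR", "SDNN", "RMSSD", "IMA")
SLICE_EPOCHS = 18          # 3 min at 10 s epochs
SLICE_SECONDS = 180.0
MAX_MISSING_FRAC = 0.05


class SliceUnavailableError(ValidationError):
    """The subsession cannot provide a valid 18-epoch slice."""


@dataclass
class SyncSlice:
    metric: str
    subsession: str
    t: np.ndarray
    human: np.ndarray
    canine: np.ndarray


def extract_slice(re_human: ReSeries, re_canine: ReSeries,
                  subsession: Subsession,
                  max_missing_frac: float = MAX_MISSING_FRAC) -> SyncSlice:
    """Centered [mid - 90 s, mid + 90 s) slice of an RE pair.

    Edge-flagged ticks never enter a slice; up to ``max_missing_frac`` of
    missing ticks per side are linearly interpolated, more invalidates
    the slice.
    """
    if subsession.duration < SLICE_SECONDS:
        raise SliceUnavailableError(
            f"{subsession.label}: {subsession.duration:.0f} s < "
            f"{SLICE_SECONDS:.0f} s slice"
        )
    mid = subsession.midpoint
    w0, w1 = mid - SLICE_SECONDS / 2, mid + SLICE_SECONDS / 2
    segs = []
    for re in (re_human, re_canine):
        sel = (re.t >= w0 - 1e-9) & (re.t < w1 - 1e-9)
        if re.edge[sel].any():
            raise SliceUnavailableError(
                f"{subsession.label}/{re.metric}: slice touches edge-flagged ticks"
            )
        v = re.values[sel].astype(float)
        n_exp = int(round(SLICE_SECONDS * re.fs_out))
        if len(v) != n_exp:
            raise SliceUnavailableError(
                f"{subsession.label}/{re.metric}: {len(v)} ticks, expected {n_exp}"
            )
        miss = ~np.isfinite(v)
        if miss.mean() > max_missing_frac:
            raise SliceUnavailableError(
                f"{subsession.label}/{re.metric}: {miss.mean():.1%} missing ticks"
            )
        if miss.any():
            idx = np.arange(len(v))
            v[miss] = np.interp(idx[miss], idx[~miss], v[~miss])
        segs.append(v)
    t = re_human.t[(re_human.t >= w0 - 1e-9) & (re_human.t < w1 - 1e-9)]
    return SyncSlice(re_human.metric, subsession.label, t, segs[0], segs[1])


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("pearson_r needs equal-length inputs, n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


@njit(cache=False)
def _dtw_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D


def dtw_distance(x, y, return_path: bool = False, z_normalize: bool = False):
    """Classic dynamic-time-warping distance with L1 local cost.

    Full cost matrix (no window constraint), steps {(1,0), (0,1), (1,1)},
    boundary-anchored.  ``z_normalize`` z-scores both inputs first (the
    scale-free mode).  Returns the cumulative path distance, and the warp
    path as (i, j) index pairs when ``return_path``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("dtw_distance needs non-empty sequences")
    if z_normalize:
        x = normalize(x)
        y = normalize(y)
    D = _dtw_matrix(x, y)
    dist = float(D[len(x), len(y)])
    if not return_path:
        return dist
    path = [(len(x) - 1, len(y) - 1)]
    i, j = len(x), len(y)
    while (i, j) != (1, 1):
        steps = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min((s for s in steps if s[0] >= 1 and s[1] >= 1),
                   key=lambda s: D[s])
        path.append((i - 1, j - 1))
    return dist, path[::-1]


def synchrony_table(re_pairs: dict, timeline) -> pd.DataFrame:
    """Pearson r and DTW distance per (interaction subsession, metric).

    ``re_pairs`` maps metric -> (human ReSeries, canine ReSeries); torso
    placements are the caller's responsibility.  Metrics whose slice is
    unavailable propagate as missing rows.
    """
    rows = []
    for sub in timeline.interactions():
        for metric in SYNC_METRICS:
            if metric not in re_pairs:
                continue
            re_h, re_c = re_pairs[metric]
            try:
                sl = extract_slice(re_h, re_c, sub)
                r = pearson_r(sl.human, sl.canine)
                d = dtw_distance(sl.human, sl.canine)
            except (SliceUnavailableError, ValidationError):
                r, d = np.nan, np.nan
            rows.append((sub.label, metric, r, d))
    return pd.DataFrame(rows, columns=["subsession", "metric",
                                       "pearson_r", "dtw_distance"])
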