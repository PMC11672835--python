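"""Psychophysiological state assignment (PPSA) and its dyadic statistics.

Raters label each second of video as positive (+1), neutral (0), negative
(-1) or offscreen.  Epoch coding takes the strict majority of the
determinate seconds in each 10 s epoch with a deliberate neutral bias: any
tie — including a 5/5 split of neutral with another state, or a
positive/negative tie — codes neutral.  Epochs with at least half their
seconds offscreen are indeterminate and excluded from every statistic.
Dyadic behavioral synchrony is the XNOR percentage: the share of jointly
determinate epochs in which both members carry the identical code.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import BehaviorStream, EpochGrid, ValidationError

POSITIVE, NEUTRAL, NEGATIVE = 1, 0, -1
_STATES = (NEGATIVE, NEUTRAL, POSITIVE)


@dataclass
class BehaviorCodeSeries:
    """Per-epoch PPSA codes for one (subject, rater); NaN = indeterminate."""

    subject_id: str
    rater: str
    epochs: np.ndarray  # global epoch indices
    codes: np.ndarray   # float, in {-1, 0, 1, NaN}


def ppsa_code(stream: BehaviorStream, grid: EpochGrid) -> BehaviorCodeSeries:
    """Code each epoch from the per-second labels of one rater.

    Offscreen seconds are excluded from the majority count; an epoch with
    at least half its seconds offscreen is indeterminate.
    """
    labels = stream.codes
    epoch_len = int(round(grid.epoch_len))
    codes = np.empty(len(grid.frame))
    for k, (t0, t1) in enumerate(grid.frame[["t0", "t1"]].itertuples(index=False)):
        a = int(round(t0 - stream.origin))
        b = int(round(t1 - stream.origin))
        if b > len(labels):
            raise ValidationError(
                f"behavior stream of {stream.subject_id}/{stream.rater} ends at "
                f"second {len(labels)} but the epoch grid needs {b}"
            )
        sec = labels[a:b]
        codes[k] = _code_epoch(sec, epoch_len)
    return BehaviorCodeSeries(stream.subject_id, stream.rater,
                              grid.frame["epoch"].to_numpy(), codes)


def _code_epoch(seconds: np.ndarray, epoch_len: int) -> float:
    off = np.isnan(seconds)
    if off.sum() * 2 >= epoch_len:
        return float("nan")
    det = seconds[~off]
    counts = {s: int((det == s).sum()) for s in _STATES}
    best = max(counts.values())
    winners = [s for s, c in counts.items() if c == best]
    return float(winners[0]) if len(winners) == 1 else float(NEUTRAL)


def state_percentages(codes: np.ndarray) -> tuple[float, float, float]:
    """(pos %, neu %, neg %) over determinate epochs; they sum to 100."""
    codes = np.asarray(codes, dtype=float)
    det = codes[~np.isnan(codes)]
    if len(det) == 0:
        raise ValidationError("no determinate epochs")
    n = len(det)
    return (100.0 * (det == POSITIVE).sum() / n,
            100.0 * (det == NEUTRAL).sum() / n,
            100.0 * (det == NEGATIVE).sum() / n)


def same_state_pct(a: np.ndarray, b: np.ndarray) -> float:
    """XNOR synchrony: % of jointly determinate epochs with identical codes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("code series must share the epoch grid")
    joint = ~np.isnan(a) & ~np.isnan(b)
    if not joint.any():
        raise ValidationError("no jointly determinate epochs")
    return float(100.0 * (a[joint] == b[joint]).mean())


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Unweighted Cohen's kappa over jointly determinate epochs.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    raters' marginal code frequencies on the 3-category nominal scale.
    Returns NaN when p_e = 1 (both raters constant on the same category).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    joint = ~np.isnan(a) & ~np.isnan(b)
    if not joint.any():
        raise ValidationError("no jointly determinate epochs")
    aj, bj = a[joint], b[joint]
    n = len(aj)
    p_o = float((aj == bj).mean())
    p_e = sum(float((aj == s).mean()) * float((bj == s).mean())
              for s in _STATES)
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def mean_pairwise_kappa(series: list[BehaviorCodeSeries]) -> float:
    """Multi-rater report: mean of all pairwise kappas."""
    if len(series) < 2:
        raise ValidationError("need at least two raters")
    ks = []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            ks.append(cohens_kappa(series[i].codes, series[j].codes))
    return float(np.nanmean(ks))
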