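"""Survey scoring and session-type statistics.

Scales: SAM valence/arousal on a 1-5 manikin (with this protocol's
orientation: larger valence = more unhappiness, larger arousal = more
calmness), PANAS-SF positive/negative affect as sums of ten 1-5 items
each, and the MDORS dog-owner relationship total (lower = stronger bond,
consumed as a provided total).  Session-type comparisons use the Wilcoxon
signed-rank test — exact tie-aware enumeration of all 2^n sign assignments
for small n, a continuity-corrected normal approximation otherwise — with
a two-sided 0.05 significance threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import INTERACTION_LABELS, NEUTRAL_TYPE, ValidationError

#: Classic 20-item PANAS positions (1-based) of the positive-affect items.
PANAS_POSITIVE_POSITIONS = (1, 3, 5, 9, 10, 12, 14, 16, 17, 19)

SCALES = ("SAM_V", "SAM_A", "PANAS_PA", "PANAS_NA")

#: Exact enumeration is used up to this many nonzero differences.
EXACT_N = 12


def score_panas(items, positive_positions=PANAS_POSITIVE_POSITIONS
                ) -> tuple[int, int]:
    """(PA, NA) sums from 20 item responses, each an integer in 1-5."""
    items = np.asarray(items)
    if items.shape != (20,):
        raise ValidationError("PANAS needs exactly 20 item responses")
    if not np.isin(items, (1, 2, 3, 4, 5)).all():
        bad = items[~np.isin(items, (1, 2, 3, 4, 5))][0]
        raise ValidationError(f"PANAS item response {bad!r} outside 1-5")
    pos = np.zeros(20, dtype=bool)
    pos[[p - 1 for p in positive_positions]] = True
    return int(items[pos].sum()), int(items[~pos].sum())


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int            # nonzero differences used
    exact: bool


def wilcoxon_signed_rank(x, y=None, exact_n: int = EXACT_N) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped (Wilcoxon's original procedure); ties
    among |d| get midranks.  For n <= ``exact_n`` the p-value enumerates
    all 2^n sign assignments of the observed (possibly tied) ranks:
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).  Larger n uses the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if n <= exact_n:
        bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1)
        sums = bits @ ranks
        p_le = float((sums <= w + 1e-9).mean())
        p_ge = float((sums >= w - 1e-9).mean())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w, p, n, True)

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts ** 3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    cc = 0.5 * np.sign(w - mu)
    z = (w - mu - cc) / sigma if sigma > 0 else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w, p, n, False)


def summarize_by_subsession(records: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD per scale per subsession label, plus pooled ALL_NEU/ALL_INT.

    ``records`` columns: subject, timepoint (``post_<LABEL>``), scale,
    value.  ALL_NEU pools BASE, NEU and POST records; ALL_INT pools INT1
    and INT2.  Cells with a single record report SD as missing.
    """
    df = records[records["scale"].isin(SCALES)].copy()
    df["label"] = df["timepoint"].str.replace("post_", "", regex=False)
    rows = []
    labels = [lb for lb in
              ("BASE", "INT1", "NEU1", "INT2", "NEU2", "POST")
              if lb in set(df["label"])]
    groups = [(lb, (lb,)) for lb in labels]
    groups += [("ALL_NEU", NEUTRAL_TYPE), ("ALL_INT", INTERACTION_LABELS)]
    for name, members in groups:
        sel = df[df["label"].isin(members)]
        for scale in SCALES:
            v = sel.loc[sel["scale"] == scale, "value"].astype(float)
            mean = v.mean() if len(v) else float("nan")
            sd = v.std(ddof=1) if len(v) >= 2 else float("nan")
            rows.append((name, scale, mean, sd, len(v)))
    return pd.DataFrame(rows, columns=["subsession", "scale", "mean", "sd", "n"])


def compare_session_types(records: pd.DataFrame, value_col: str = "value",
                          scale_col: str = "scale", label_col: str = "label",
                          pair_col: str = "session") -> pd.DataFrame:
    """Paired neutral-type vs interaction-type comparison per scale/metric.

    For each pairing unit (default: one session-day) the observations are
    the unit's mean over neutral-type labels and its mean over interaction
    labels; one Wilcoxon signed-rank p-value is reported per scale.  Rows
    with fewer than 2 usable pairs report a missing p.
    """
    df = records.copy()
    if label_col not in df.columns and "timepoint" in df.columns:
        df[label_col] = df["timepoint"].str.replace("post_", "", regex=False)
    rows = []
    for scale, sub in df.groupby(scale_col):
        neu = sub[sub[label_col].isin(NEUTRAL_TYPE)]
        inter = sub[sub[label_col].isin(INTERACTION_LABELS)]
        neu_m = neu.groupby(pair_col)[value_col].mean()
        int_m = inter.groupby(pair_col)[value_col].mean()
        pairs = pd.concat([neu_m, int_m], axis=1, join="inner").dropna()
        pairs.columns = ["neu", "int"]
        if len(pairs) < 2:
            rows.append((scale, pairs["neu"].mean() if len(pairs) else np.nan,
                         pairs["int"].mean() if len(pairs) else np.nan,
                         len(pairs), np.nan, np.nan))
            continue
        try:
            res = wilcoxon_signed_rank(pairs["neu"].to_numpy(),
                                       pairs["int"].to_numpy())
            w, p = res.statistic, res.p_value
        except ValidationError:
            w, p = np.nan, np.nan
        rows.append((scale, float(pairs["neu"].mean()),
                     float(pairs["int"].mean()), len(pairs), w, p))
    return pd.DataFrame(rows, columns=["scale", "mean_neu", "mean_int",
                                       "n_pairs", "W", "p"])
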