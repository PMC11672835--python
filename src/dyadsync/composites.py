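"""Composite multimodal representations of a dyadic session.

Three views summarize a session beyond single-metric tables: a directional
subsession heatmap (epoch-to-epoch increase/decrease of every mapped
metric, composed with its psychophysiological orientation and grouped into
a valence/stress block and an arousal block, humans above canines),
a combined pair table joining physiological synchrony, behavior-coded
percentages and surveys per interaction subsession, and a session-level
correlation matrix over middle-minute metric means, behavior codes and
post-interaction survey scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .session import EpochGrid, SessionBundle, ValidationError  # noqa: E402

VALENCE, AROUSAL = "valence_stress", "arousal"

#: metric -> (dimension, orientation).  With a *direct* orientation an
#: increase renders as a positive contribution to the dimension: rising
#: HR/EDA/ST/IMA read as more arousal; rising SDNN/RMSSD read as less
#: stress, i.e. a positive valence contribution.  EDA/ST rows exist for
#: the human only (no canine EDA/ST channel).
DEFAULT_DIRECTION_MAP = {
    "HR": (AROUSAL, "direct"),
    "EDA_mean": (AROUSAL, "direct"),
    "EDA_max": (AROUSAL, "direct"),
    "EDA_peak_ct": (AROUSAL, "direct"),
    "ST": (AROUSAL, "direct"),
    "IMA": (AROUSAL, "direct"),
    "SDNN": (VALENCE, "direct"),
    "RMSSD": (VALENCE, "direct"),
}


def epoch_deltas(me: pd.DataFrame) -> pd.DataFrame:
    """Sign of the epoch-to-epoch difference per (subject, placement, metric).

    Returns tidy rows (subsession, epoch, subject, placement, metric,
    delta, tie) where delta is +1/-1 and the first epoch of each
    subsession carries no delta.  Ties render as decrease (-1) — the
    two-state visual contract — but are reported via the tie flag.
    """
    rows = []
    for (subj, plc, metric), g in me.groupby(["subject", "placement",
                                              "metric"]):
        g = g.sort_values("epoch")
        for sub, gg in g.groupby("subsession", sort=False):
            v = gg["value"].to_numpy(float)
            ep = gg["epoch"].to_numpy()
            for k in range(1, len(v)):
                if not (np.isfinite(v[k]) and np.isfinite(v[k - 1])):
                    continue
                diff = v[k] - v[k - 1]
                delta = 1.0 if diff > 0 else -1.0
                rows.append((sub, ep[k], subj, plc, metric, delta,
                             diff == 0.0))
    return pd.DataFrame(rows, columns=["subsession", "epoch", "subject",
                                       "placement", "metric", "delta", "tie"])


@dataclass
class HeatmapMatrix:
    """Directional heatmap over one 18-epoch (3 min) segment.

    ``frame`` is indexed by (dimension, species, subject, metric) rows and
    epoch columns; cells are +1 (solid: state increase along the
    dimension), -1 (off-tint: decrease) or NaN (missing).  Survey
    annotations flank the segment.
    """

    subsession: str
    epochs: np.ndarray
    frame: pd.DataFrame
    annotations: dict = field(default_factory=dict)
    tie_count: int = 0

    def coherence(self, epoch, dimension) -> float:
        """max(share of increases, share of decreases) among the defined
        cells of one epoch column within a dimension block."""
        col = self.frame.loc[self.frame.index.get_level_values("dimension")
                             == dimension, epoch]
        col = col.dropna()
        if len(col) < 2:
            return float("nan")
        up = float((col > 0).mean())
        return max(up, 1.0 - up)


def build_heatmap(deltas: pd.DataFrame, segment_epochs,
                  subsession: str,
                  direction_map: dict | None = None,
                  surveys: pd.DataFrame | None = None,
                  species_of: dict | None = None) -> HeatmapMatrix:
    """Compose deltas with metric orientations over an 18-epoch segment.

    ``segment_epochs`` are the global epoch indices of the segment;
    ``species_of`` maps subject id -> species for the human-above-canine
    row ordering.  Metrics present in the deltas but absent from the map
    raise a configuration error; unmapped metrics must be filtered first.
    """
    dmap = DEFAULT_DIRECTION_MAP if direction_map is None else direction_map
    segment_epochs = np.asarray(list(segment_epochs))
    d = deltas[deltas["epoch"].isin(segment_epochs)
               & (deltas["subsession"] == subsession)]
    unmapped = set(d["metric"]) - set(dmap)
    if unmapped:
        raise ValidationError(f"metrics without direction mapping: {unmapped}")
    species_of = species_of or {}

    cells = {}
    for (subj, metric), g in d.groupby(["subject", "metric"]):
        dim, orient = dmap[metric]
        sign = 1.0 if orient == "direct" else -1.0
        sp = species_of.get(subj, "human")
        key = (dim, sp, subj, metric)
        row = pd.Series(np.nan, index=segment_epochs)
        row.loc[g["epoch"].to_numpy()] = sign * g["delta"].to_numpy()
        cells[key] = row
    if not cells:
        frame = pd.DataFrame(columns=segment_epochs)
        frame.index = pd.MultiIndex.from_tuples([], names=["dimension",
                                                           "species",
                                                           "subject", "metric"])
    else:
        frame = pd.DataFrame(cells).T
        frame.index.names = ["dimension", "species", "subject", "metric"]
        dim_order = {VALENCE: 0, AROUSAL: 1}
        sp_order = {"human": 0, "canine": 1}
        frame = frame.iloc[sorted(
            range(len(frame)),
            key=lambda i: (dim_order.get(frame.index[i][0], 9),
                           sp_order.get(frame.index[i][1], 9),
                           frame.index[i][2], frame.index[i][3]))]
    ann = {}
    if surveys is not None:
        for _, r in surveys.iterrows():
            ann.setdefault(r["timepoint"], {})[r["scale"]] = r["value"]
    ties = int(d["tie"].sum())
    return HeatmapMatrix(subsession, segment_epochs, frame, ann, ties)


def coherence(heatmap: HeatmapMatrix, epoch, dimension) -> float:
    return heatmap.coherence(epoch, dimension)


def middle_epochs(grid: EpochGrid, label: str, n: int = 6) -> np.ndarray:
    """Global indices of the n central epochs of a subsession (the
    'middle minute' is 6 epochs)."""
    eps = grid.epochs_of(label)["epoch"].to_numpy()
    if len(eps) < n:
        raise ValidationError(f"{label}: fewer than {n} epochs")
    start = (len(eps) - n) // 2
    return eps[start:start + n]


def correlation_matrix(features: pd.DataFrame,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Pearson matrix over interaction sessions.

    ``features``: one row per interaction session, one column per variable
    (middle-minute metric means, behavior codes, post-interaction survey
    scores).  Pairwise-complete observations; cells with fewer than
    ``min_pairs`` complete pairs are missing; diagonal is 1.
    """
    if len(features) < min_pairs:
        raise ValidationError(
            f"need >= {min_pairs} interaction sessions, got {len(features)}")
    cols = list(features.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            x = features[a].to_numpy(float)
            y = features[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs:
                continue
            if i == j:
                r = 1.0
            else:
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = float(np.corrcoef(xs, ys)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def combined_pair_table(sync: pd.DataFrame | None,
                        behavior_pct: pd.DataFrame | None,
                        surveys: pd.DataFrame | None,
                        pair: str, subsession: str) -> pd.DataFrame:
    """One combined block for a (human, canine, INT subsession).

    Rows: Pearson r and DTW per metric, same-state %, per-species state
    percentages, pre/post survey scores and the MDORS total.  Missing
    components render as missing cells, never as errors.
    """
    rows = []
    if sync is not None:
        s = sync[sync["subsession"] == subsession]
        for _, r in s.iterrows():
            rows.append((pair, subsession, "Pcorr", r["metric"],
                         r["pearson_r"]))
            rows.append((pair, subsession, "DTW", r["metric"],
                         r["dtw_distance"]))
    if behavior_pct is not None:
        for _, r in behavior_pct.iterrows():
            rows.append((pair, subsession, f"becode_{r['subject']}",
                         r["stat"], r["value"]))
    if surveys is not None:
        for _, r in surveys.iterrows():
            rows.append((pair, subsession, f"survey_{r['timepoint']}",
                         r["scale"], r["value"]))
    return pd.DataFrame(rows, columns=["pair", "subsession", "block",
                                       "item", "value"])


# ---------------------------------------------------------------------------
# plotting (thin layers over the data-first structures above)
# ---------------------------------------------------------------------------

def plot_heatmap(hm: HeatmapMatrix, path) -> None:
    fig, axes = plt.subplots(2, 1, figsize=(10, 6), constrained_layout=True)
    for ax, dim, cmap in zip(axes, (VALENCE, AROUSAL), ("Blues", "Reds")):
        blk = hm.frame[hm.frame.index.get_level_values("dimension") == dim]
        if blk.empty:
            ax.set_axis_off()
            continue
        ax.imshow(blk.to_numpy(float), aspect="auto", cmap=cmap,
                  vmin=-1, vmax=1, interpolation="nearest")
        ax.set_yticks(range(len(blk)))
        ax.set_yticklabels([f"{'h' if sp == 'human' else 'c'}_{m}"
                            for (_, sp, _, m) in blk.index], fontsize=7)
        ax.set_title(f"{hm.subsession} — {dim}")
        n_h = int((blk.index.get_level_values("species") == "human").sum())
        if 0 < n_h < len(blk):
            ax.axhline(n_h - 0.5, color="k", ls="--", lw=1)
    axes[-1].set_xlabel("epoch")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_matrix(cm: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(0.5 * len(cm) + 3,) * 2)
    im = ax.imshow(cm.to_numpy(float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm)))
    ax.set_xticklabels(cm.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm)))
    ax.set_yticklabels(cm.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_raw_snapshot(ecg_human, ecg_canine, annotations=None, path=None,
                      window: tuple[float, float] | None = None):
    """Dual-trace raw ECG snapshot with optional highlighted event spans.

    ``annotations``: list of (t_start, t_end, label); spans outside the
    plotted range are skipped with a warning.
    """
    import warnings

    fig, axes = plt.subplots(2, 1, figsize=(12, 5), sharex=True,
                             constrained_layout=True)
    for ax, ch, name in ((axes[0], ecg_human, "human"),
                         (axes[1], ecg_canine, "canine")):
        t, v = ch.t, ch.values
        if window is not None:
            sel = (t >= window[0]) & (t < window[1])
            t, v = t[sel], v[sel]
        ax.plot(t, v, lw=0.5)
        ax.set_ylabel(f"{name} ECG (mV)")
        for a, b, label in (annotations or []):
            if b < t[0] or a > t[-1]:
                warnings.warn(f"annotation {label!r} outside plotted range; "
                              "skipped", stacklevel=2)
                continue
            ax.axvspan(max(a, t[0]), min(b, t[-1]), alpha=0.2, color="orange")
    axes[-1].set_xlabel("time (s)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
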