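"""Per-epoch (ME) and rolling-window (RE) physiological metric extraction.

ME averages each metric over the shared non-overlapping 10 s epochs; RE
evaluates the same metric over a centered 60 s rolling window at a 10 Hz
output rate (the form used for synchrony analysis).  ECG metrics derive
from R peaks via a Pan-Tompkins-style detector; HRV is time-domain only
(SDNN, RMSSD and their quotient).  EDA is split into a tonic level (rolling
median) and a phasic component whose skin-conductance-response (SCR) peaks
are counted per epoch; activity yields per-axis statistics, per-axis mean
amplitude deviation (MAD), and the time-normalized integral of the L1
modulus of dynamic acceleration (IMA).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .preprocess import IBI_BOUNDS_MS, FilterSpec
from .session import Channel, EpochGrid, SessionBundle, ValidationError

#: Pan-Tompkins bands and refractory periods per species.  The canine heart
#: is faster with narrower complexes, so its band is wider and refractory
#: shorter.
_PT_BAND = {"human": (5.0, 15.0), "canine": (5.0, 25.0)}
_PT_REFRACTORY = {"human": 0.200, "canine": 0.150}

ME_COLUMNS = ["subsession", "epoch", "subject", "placement", "metric", "value"]

#: Minimum SCR onset-to-peak rise (uS) within 5 s to count a phasic peak.
SCR_MIN_RISE = 0.03
#: Tonic estimator window (s): rolling median.
TONIC_WINDOW_S = 8.0


@dataclass
class BeatSeries:
    """R-peak times (s) with derived interbeat intervals (ms).

    ``ibi[i] = 1000 * (t[i+1] - t[i])``; ``valid[i]`` marks IBIs that pass
    species plausibility bounds and the local-median artifact test
    (a "normal sinus beats" proxy — no morphology beat typing).
    """

    subject_id: str
    t: np.ndarray
    ibi: np.ndarray
    valid: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.t)


def detect_r_peaks(channel: Channel, species: str) -> BeatSeries:
    """Pan-Tompkins-style R-peak detection on a (filtered) ECG channel.

    Band-pass -> derivative -> squaring -> 150 ms moving integration ->
    adaptive signal/noise thresholds with search-back, followed by R-wave
    localization on the band-passed waveform.
    """
    fs = channel.fs
    x = channel.values.astype(float)
    fin = np.isfinite(x)
    if fin.sum() < int(2 * fs):
        return _empty_beats(channel.subject_id)
    xf = np.where(fin, x, 0.0)

    lo, hi = _PT_BAND[species]
    sos = signal.butter(2, [lo / (fs / 2), hi / (fs / 2)], btype="band",
                        output="sos")
    y = signal.sosfiltfilt(sos, xf)
    y[~fin] = 0.0
    deriv = np.gradient(y) * fs
    integ = ndimage.uniform_filter1d(deriv ** 2, max(1, int(0.150 * fs)))

    refractory = _PT_REFRACTORY[species]
    min_dist = max(1, int(refractory * fs))
    cand, _ = signal.find_peaks(integ, distance=min_dist)
    if len(cand) == 0:
        return _empty_beats(channel.subject_id)

    accepted = _adaptive_threshold(integ, cand, fs)
    if len(accepted) == 0:
        return _empty_beats(channel.subject_id)

    # localize R on the band-passed waveform around each integrated peak
    half = int(0.120 * fs)
    r_idx = []
    for i in accepted:
        a, b = max(0, i - half), min(len(y), i + half + 1)
        r_idx.append(a + int(np.argmax(y[a:b])))
    r_idx = np.unique(r_idx)
    # enforce refractory: drop the smaller of any too-close pair
    keep = []
    for i in r_idx:
        if keep and (i - keep[-1]) < min_dist:
            if y[i] > y[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
    r_idx = np.asarray(keep, dtype=int)
    r_idx = r_idx[fin[r_idx]]

    t = channel.t[r_idx]
    ibi = np.diff(t) * 1000.0
    return BeatSeries(channel.subject_id, t, ibi,
                      ibi_artifact_mask(ibi, species))


def _empty_beats(subject_id: str) -> BeatSeries:
    return BeatSeries(subject_id, np.empty(0), np.empty(0),
                      np.empty(0, dtype=bool))


def _adaptive_threshold(integ: np.ndarray, cand: np.ndarray,
                        fs: float) -> np.ndarray:
    """Classic running signal/noise level discrimination with search-back."""
    warm = integ[: int(2 * fs)]
    spki = 0.25 * warm.max() if len(warm) else integ.max() * 0.25
    npki = 0.5 * warm.mean() if len(warm) else 0.0
    accepted: list[int] = []
    rr: list[float] = []
    pending: list[int] = []
    for i in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[i] > thr:
            if accepted and rr:
                gap = (i - accepted[-1]) / fs
                avg_rr = float(np.mean(rr[-8:]))
                if gap > 1.66 * avg_rr and pending:
                    # search-back at half threshold
                    back = [j for j in pending if integ[j] > 0.5 * thr]
                    if back:
                        j = max(back, key=lambda k: integ[k])
                        accepted.append(j)
                        rr.append(gap)
                        accepted.sort()
            spki = 0.125 * integ[i] + 0.875 * spki
            if accepted:
                rr.append((i - accepted[-1]) / fs)
            accepted.append(i)
            pending = []
        else:
            npki = 0.125 * integ[i] + 0.875 * npki
            pending.append(i)
    return np.asarray(sorted(set(accepted)), dtype=int)


def ibi_artifact_mask(ibi: np.ndarray, species: str,
                      rel_tol: float = 0.30) -> np.ndarray:
    """Valid = inside species bounds and within 30% of the median of the
    5 surrounding IBIs."""
    ibi = np.asarray(ibi, dtype=float)
    if len(ibi) == 0:
        return np.empty(0, dtype=bool)
    lo, hi = IBI_BOUNDS_MS[species]
    ok = (ibi >= lo) & (ibi <= hi)
    if len(ibi) >= 3:
        local = ndimage.median_filter(ibi, size=min(5, len(ibi) | 1),
                                      mode="nearest")
        ok &= np.abs(ibi - local) <= rel_tol * local
    return ok


def hrv_time_domain(ibi, valid=None) -> tuple[float, float, float]:
    """(SDNN, RMSSD, SDNN/RMSSD) over a window of IBIs, ms.

    SDNN is the sample SD (n-1 denominator) of valid IBIs (>= 2 required);
    RMSSD the root mean square of successive differences over valid
    adjacent pairs (>= 1 pair, i.e. >= 3 beats).  The quotient is missing
    (NaN) when RMSSD is 0.
    """
    ibi = np.asarray(ibi, dtype=float)
    valid = np.ones(len(ibi), dtype=bool) if valid is None \
        else np.asarray(valid, dtype=bool)
    v = ibi[valid]
    sdnn = float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
    pair_ok = valid[1:] & valid[:-1]
    diffs = np.diff(ibi)[pair_ok]
    rmssd = float(np.sqrt(np.mean(diffs ** 2))) if len(diffs) >= 1 \
        else float("nan")
    if np.isnan(sdnn) or np.isnan(rmssd) or rmssd == 0.0:
        quotient = float("nan")
    else:
        quotient = sdnn / rmssd
    return sdnn, rmssd, quotient


def mad_ima(values: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Per-axis mean amplitude deviation and the IMA of a dynamic
    (gravity-free) tri-axial window.

    MAD_axis = mean |a_i - a_bar|; IMA = (sum_i (|ax|+|ay|+|az|) * dt) / T,
    i.e. the time-average of the L1 modulus (units m/s^2), which makes 10 s
    epochs and 60 s windows directly comparable.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValidationError("mad_ima expects an (n, 3) window")
    fin = np.isfinite(v).all(axis=1)
    v = v[fin]
    if len(v) == 0:
        return np.full(3, np.nan), float("nan")
    mad = np.abs(v - v.mean(axis=0)).mean(axis=0)
    ima = float(np.abs(v).sum(axis=1).mean())
    return mad, ima


def eda_decompose_and_peaks(channel: Channel
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split EDA into tonic level and phasic component; detect SCR peaks.

    Tonic = rolling median (8 s); phasic = signal - tonic.  An SCR peak is
    a local phasic maximum with an onset-to-peak rise of at least
    ``SCR_MIN_RISE`` uS within the preceding 5 s.  Returns
    (tonic, phasic, peak_times).
    """
    x = channel.values.astype(float)
    fin = np.isfinite(x)
    if fin.sum() < 3:
        return np.full_like(x, np.nan), np.full_like(x, np.nan), np.empty(0)
    xf = x.copy()
    if not fin.all():
        xf[~fin] = np.interp(channel.t[~fin], channel.t[fin], x[fin])
    win = max(3, int(round(TONIC_WINDOW_S * channel.fs)) | 1)
    tonic = ndimage.median_filter(xf, size=win, mode="nearest")
    phasic = xf - tonic
    peaks, _ = signal.find_peaks(phasic, distance=max(1, int(channel.fs)))
    look = int(5.0 * channel.fs)
    keep = []
    for p in peaks:
        a = max(0, p - look)
        onset = phasic[a:p + 1].min() if p > a else phasic[p]
        if phasic[p] - onset >= SCR_MIN_RISE and fin[p]:
            keep.append(p)
    tonic[~fin] = np.nan
    phasic[~fin] = np.nan
    return tonic, phasic, channel.t[np.asarray(keep, dtype=int)]


# ---------------------------------------------------------------------------
# ME: average metric by epoch
# ---------------------------------------------------------------------------

def epoch_me(bundle: SessionBundle, grid: EpochGrid,
             beats_cache: dict | None = None) -> pd.DataFrame:
    """Tidy per-epoch metric table over every channel of a preprocessed
    bundle (columns: subsession, epoch, subject, placement, metric, value).

    ECG epochs use the beats whose R peak falls in the epoch; sample-based
    channels average in-epoch samples and are missing when more than half
    the epoch's samples are masked.
    """
    rows: list[tuple] = []
    g = grid.frame
    for ch in bundle.channels:
        species = bundle.subject(ch.subject_id).species
        if ch.kind == "ECG":
            beats = detect_r_peaks(ch, species)
            if beats_cache is not None:
                beats_cache[(ch.subject_id, ch.placement)] = beats
            _ecg_epoch_rows(beats, g, ch.placement, rows)
        elif ch.kind == "EDA":
            tonic, phasic, peak_t = eda_decompose_and_peaks(ch)
            _sample_epoch_rows(ch, g, rows, extra_peaks=peak_t)
        elif ch.kind == "ST":
            _sample_epoch_rows(ch, g, rows)
        elif ch.kind == "ACC3":
            _acc_epoch_rows(ch, g, rows)
    return pd.DataFrame(rows, columns=ME_COLUMNS)


def _ecg_epoch_rows(beats: BeatSeries, g: pd.DataFrame, placement: str,
                    rows: list) -> None:
    # IBIs are attributed to the epoch containing their closing R peak
    close_t = beats.t[1:] if beats.n_beats else np.empty(0)
    for sub, ep, t0, t1 in g[["subsession", "epoch", "t0", "t1"]].itertuples(
            index=False):
        sel = (close_t >= t0) & (close_t < t1)
        ibi = beats.ibi[sel]
        val = beats.valid[sel]
        v = ibi[val]
        mean_ibi = float(v.mean()) if len(v) else float("nan")
        hr = 60000.0 / mean_ibi if len(v) else float("nan")
        sdnn, rmssd, quot = hrv_time_domain(ibi, val)
        for metric, value in (("HR", hr), ("IBI", mean_ibi), ("SDNN", sdnn),
                              ("RMSSD", rmssd), ("SDNN_RMSSD", quot)):
            rows.append((sub, ep, beats.subject_id, placement, metric, value))


def _sample_epoch_rows(ch: Channel, g: pd.DataFrame, rows: list,
                       extra_peaks: np.ndarray | None = None) -> None:
    name = "ST" if ch.kind == "ST" else None
    for sub, ep, t0, t1 in g[["subsession", "epoch", "t0", "t1"]].itertuples(
            index=False):
        i0, i1 = np.searchsorted(ch.t, (t0, t1))
        seg = ch.values[i0:i1]
        fin = np.isfinite(seg)
        missing = len(seg) == 0 or fin.mean() < 0.5
        if ch.kind == "ST":
            v = float(seg[fin].mean()) if not missing else float("nan")
            rows.append((sub, ep, ch.subject_id, ch.placement, "ST", v))
        else:  # EDA
            mean = float(seg[fin].mean()) if not missing else float("nan")
            mx = float(seg[fin].max()) if not missing else float("nan")
            if missing:
                ct = float("nan")
            else:
                ct = float(((extra_peaks >= t0) & (extra_peaks < t1)).sum())
            rows.append((sub, ep, ch.subject_id, ch.placement, "EDA_mean", mean))
            rows.append((sub, ep, ch.subject_id, ch.placement, "EDA_max", mx))
            rows.append((sub, ep, ch.subject_id, ch.placement, "EDA_peak_ct", ct))


def _acc_epoch_rows(ch: Channel, g: pd.DataFrame, rows: list) -> None:
    axes = "xyz"
    for sub, ep, t0, t1 in g[["subsession", "epoch", "t0", "t1"]].itertuples(
            index=False):
        i0, i1 = np.searchsorted(ch.t, (t0, t1))
        seg = ch.values[i0:i1]
        fin = np.isfinite(seg).all(axis=1) if len(seg) else np.empty(0, bool)
        missing = len(seg) == 0 or fin.mean() < 0.5
        if missing:
            for ax in axes:
                for stat in ("mean", "min", "max"):
                    rows.append((sub, ep, ch.subject_id, ch.placement,
                                 f"ACC_{stat}_{ax}", float("nan")))
                rows.append((sub, ep, ch.subject_id, ch.placement,
                             f"MAD_{ax}", float("nan")))
            rows.append((sub, ep, ch.subject_id, ch.placement, "IMA",
                         float("nan")))
            continue
        v = seg[fin]
        mad, ima = mad_ima(v, ch.fs)
        for j, ax in enumerate(axes):
            rows.append((sub, ep, ch.subject_id, ch.placement,
                         f"ACC_mean_{ax}", float(v[:, j].mean())))
            rows.append((sub, ep, ch.subject_id, ch.placement,
                         f"ACC_min_{ax}", float(v[:, j].min())))
            rows.append((sub, ep, ch.subject_id, ch.placement,
                         f"ACC_max_{ax}", float(v[:, j].max())))
            rows.append((sub, ep, ch.subject_id, ch.placement,
                         f"MAD_{ax}", float(mad[j])))
        rows.append((sub, ep, ch.subject_id, ch.placement, "IMA", ima))


# ---------------------------------------------------------------------------
# RE: centered 60 s rolling window at 10 Hz
# ---------------------------------------------------------------------------

@dataclass
class ReSeries:
    """Rolling-window metric series at the RE output rate.

    The value at tick t uses only beats/samples in [t - w/2, t + w/2);
    ticks whose window is truncated by the record edges are computed but
    flagged ``edge`` and excluded from synchrony slices.
    """

    metric: str
    subject_id: str
    t: np.ndarray
    values: np.ndarray
    edge: np.ndarray
    window_s: float = 60.0
    fs_out: float = 10.0


BEAT_METRICS = ("HR", "IBI", "SDNN", "RMSSD")


def rolling_re(source, metric: str, t_start: float, t_end: float,
               window_s: float = 60.0, fs_out: float = 10.0) -> ReSeries:
    """Compute an RE series for one metric.

    ``source`` is a :class:`BeatSeries` for beat metrics (HR, IBI, SDNN,
    RMSSD) or a :class:`Channel` for sample metrics (IMA on a dynamic ACC3
    channel, EDA_mean, ST).
    """
    half = window_s / 2.0
    k0 = int(np.ceil(t_start * fs_out - 1e-9))
    k1 = int(np.floor(t_end * fs_out + 1e-9))
    t = np.arange(k0, k1 + 1) / fs_out
    edge = (t - half < t_start - 1e-9) | (t + half > t_end + 1e-9)

    if metric in BEAT_METRICS:
        if not isinstance(source, BeatSeries):
            raise ValidationError(f"metric {metric} needs a BeatSeries")
        values = _re_beats(source, metric, t, half)
    elif metric in ("IMA", "EDA_mean", "ST"):
        if not isinstance(source, Channel):
            raise ValidationError(f"metric {metric} needs a Channel")
        values = _re_samples(source, metric, t, half)
    else:
        raise ValidationError(f"unknown RE metric {metric!r}")
    return ReSeries(metric, getattr(source, "subject_id", ""), t, values,
                    edge, window_s, fs_out)


def _re_beats(beats: BeatSeries, metric: str, t: np.ndarray,
              half: float) -> np.ndarray:
    att = beats.t[1:]  # IBI attachment times (closing peak)
    ibi = np.where(beats.valid, beats.ibi, 0.0)
    cnt = beats.valid.astype(float)
    s1 = np.concatenate([[0.0], np.cumsum(ibi)])
    s2 = np.concatenate([[0.0], np.cumsum(ibi ** 2)])
    c = np.concatenate([[0.0], np.cumsum(cnt)])
    pair_ok = (beats.valid[1:] & beats.valid[:-1]).astype(float)
    d2 = np.diff(beats.ibi) ** 2 * pair_ok
    sd2 = np.concatenate([[0.0], np.cumsum(d2)])
    cd = np.concatenate([[0.0], np.cumsum(pair_ok)])

    lo = np.searchsorted(att, t - half, side="left")
    hi = np.searchsorted(att, t + half, side="left")
    n = c[hi] - c[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, (s1[hi] - s1[lo]) / np.maximum(n, 1), np.nan)
        if metric == "IBI":
            out = np.where(n >= 1, mean, np.nan)
        elif metric == "HR":
            out = np.where(n >= 1, 60000.0 / mean, np.nan)
        elif metric == "SDNN":
            var = (s2[hi] - s2[lo] - n * mean ** 2) / np.maximum(n - 1, 1)
            out = np.where(n >= 2, np.sqrt(np.maximum(var, 0.0)), np.nan)
        else:  # RMSSD over diffs attached at the later closing peak
            lo_d = np.searchsorted(att[1:], t - half, side="left")
            hi_d = np.searchsorted(att[1:], t + half, side="left")
            nd = cd[hi_d] - cd[lo_d]
            out = np.where(nd >= 1,
                           np.sqrt((sd2[hi_d] - sd2[lo_d])
                                   / np.maximum(nd, 1)), np.nan)
    return out


def _re_samples(ch: Channel, metric: str, t: np.ndarray,
                half: float) -> np.ndarray:
    if metric == "IMA":
        x = np.abs(ch.values).sum(axis=1)
    else:
        x = ch.values.astype(float)
    fin = np.isfinite(x)
    xs = np.where(fin, x, 0.0)
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    c = np.concatenate([[0.0], np.cumsum(fin.astype(float))])
    lo = np.searchsorted(ch.t, t - half, side="left")
    hi = np.searchsorted(ch.t, t + half, side="left")
    n = c[hi] - c[lo]
    expected = np.maximum(hi - lo, 1)
    with np.errstate(invalid="ignore"):
        out = np.where((n > 0) & (n / expected >= 0.5),
                       (s1[hi] - s1[lo]) / np.maximum(n, 1), np.nan)
    return out


def write_me_table(me: pd.DataFrame, path) -> None:
    me.to_csv(path, index=False)
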