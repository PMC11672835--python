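"""Preprocessing chain: data check / outlier masking, Butterworth band-pass
filtering, and normalization.

Artifacts are masked (NaN), never interpolated, so downstream epoch metrics
can apply their own missing-data rules.  Filtering is zero-phase by default
(forward-backward) so epoch alignment is not phase-shifted.  Metrics are
computed on filtered physical-unit signals; z-score normalization is
reserved for visualization and the optional normalized DTW mode.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .session import Channel, SubsessionTimeline, ValidationError

#: Physical plausibility bounds per channel kind (values outside are masked).
PLAUSIBILITY_BOUNDS = {
    "ECG": (-10.0, 10.0),        # mV
    "EDA": (0.01, 60.0),         # uS
    "ST": (20.0, 42.0),          # degC
    "ACC3": (-78.48, 78.48),     # m/s^2 (|a| <= 8 g per axis)
}

#: Species-specific IBI plausibility bounds, ms (used by beat artifact rejection).
IBI_BOUNDS_MS = {"human": (300.0, 2000.0), "canine": (250.0, 1500.0)}

#: Hampel absolute-deviation floors so genuine transients (SCRs, activity
#: bursts) are never flagged; the MAD test targets gross spikes only.
_HAMPEL_FLOOR = {"EDA": 0.5, "ST": 0.5, "ACC3": 5.0}
#: Kinds screened by the Hampel window test.  ECG is excluded: every QRS
#: complex is a >5 MAD excursion from the 1 s local median by construction.
_HAMPEL_KINDS = ("EDA", "ST", "ACC3")


class QualityError(ValidationError):
    """Too large a fraction of a channel is masked within a subsession."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter; ``low=None`` gives a low-pass, ``high=None`` a
    high-pass, both set gives a band-pass."""

    order: int
    low: float | None
    high: float | None
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.low is not None and not 0 < self.low < nyq:
            raise ValidationError(f"low cutoff {self.low} Hz outside (0, {nyq})")
        if self.high is not None and not 0 < self.high < nyq:
            raise ValidationError(f"high cutoff {self.high} Hz outside (0, {nyq})")
        if self.low is not None and self.high is not None \
                and not self.low < self.high:
            raise ValidationError("low cutoff must be below high cutoff")

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        nyq = fs / 2.0
        if self.low is not None and self.high is not None:
            return signal.butter(self.order, [self.low / nyq, self.high / nyq],
                                 btype="band", output="sos")
        if self.low is not None:
            return signal.butter(self.order, self.low / nyq, btype="high",
                                 output="sos")
        return signal.butter(self.order, self.high / nyq, btype="low",
                             output="sos")


def default_filter(kind: str, fs: float) -> FilterSpec:
    """Per-kind default bands (standard physiological choices; the source
    protocol does not pin them, so they are configurable here)."""
    if kind == "ECG":
        return FilterSpec(order=4, low=0.5, high=40.0)
    if kind == "ACC3":  # dynamic (gravity-free) component
        return FilterSpec(order=4, low=0.1, high=0.4 * fs)
    if kind == "EDA":
        return FilterSpec(order=2, low=None, high=1.0)
    if kind == "ST":
        return FilterSpec(order=2, low=None, high=0.01)
    raise ValidationError(f"no default filter for kind {kind!r}")


def remove_outliers(channel: Channel,
                    timeline: SubsessionTimeline | None = None,
                    hampel_window_s: float = 1.0,
                    n_mad: float = 5.0,
                    max_masked_frac: float = 0.5,
                    ) -> tuple[Channel, dict]:
    """Mask implausible samples; returns (masked channel, report).

    Two screens are applied: fixed physical plausibility bounds per kind,
    and — for slow channels — a Hampel test against the ``hampel_window_s``
    rolling median at ``n_mad`` scaled MADs (with a per-kind absolute floor).
    Masking is idempotent.  If more than ``max_masked_frac`` of a subsession
    is newly masked (excluding subsessions that are entirely absent by
    design), a :class:`QualityError` is raised.
    """
    vals = channel.values.reshape(len(channel.t), -1).copy()
    pre_missing = ~np.isfinite(vals).all(axis=1)

    lo, hi = PLAUSIBILITY_BOUNDS[channel.kind]
    with np.errstate(invalid="ignore"):
        bad = (vals < lo) | (vals > hi)

    if channel.kind in _HAMPEL_KINDS:
        win = max(3, int(round(hampel_window_s * channel.fs)) | 1)
        floor = _HAMPEL_FLOOR[channel.kind]
        for j in range(vals.shape[1]):
            x = vals[:, j]
            fin = np.isfinite(x)
            if fin.sum() < win:
                continue
            xf = np.where(fin, x, np.nanmedian(x[fin]))
            med = ndimage.median_filter(xf, size=win, mode="nearest")
            mad = ndimage.median_filter(np.abs(xf - med), size=win,
                                        mode="nearest")
            thresh = np.maximum(n_mad * 1.4826 * mad, floor)
            bad[:, j] |= fin & (np.abs(x - med) > thresh)

    bad_row = bad.any(axis=1)
    vals[bad_row] = np.nan
    newly = bad_row & ~pre_missing

    report = {"masked_fraction": float(newly.mean()), "n_masked": int(newly.sum())}
    if timeline is not None:
        per_sub = {}
        missing_after = ~np.isfinite(vals).all(axis=1)
        for sub in timeline:
            sel = (channel.t >= sub.t_start) & (channel.t < sub.t_end)
            if not sel.any():
                continue
            if pre_missing[sel].all():
                continue  # absent by design, not an artifact
            frac = float(missing_after[sel].mean())
            per_sub[sub.label] = frac
            if frac > max_masked_frac:
                raise QualityError(
                    f"{channel.kind}@{channel.placement} of {channel.subject_id}: "
                    f"{frac:.0%} masked in subsession {sub.label}"
                )
        report["masked_fraction_by_subsession"] = per_sub

    values = vals[:, 0] if channel.values.ndim == 1 else vals
    return channel.copy_with(values=values), report


def bandpass(channel: Channel, spec: FilterSpec | None = None) -> Channel:
    """Apply a (zero-phase) Butterworth filter; NaN spans are bridged by
    linear interpolation for the filter pass and re-masked afterwards."""
    if spec is None:
        spec = default_filter(channel.kind, channel.fs)
    sos = spec.sos(channel.fs)
    vals = channel.values.reshape(len(channel.t), -1)
    out = np.empty_like(vals, dtype=float)
    for j in range(vals.shape[1]):
        x = vals[:, j]
        fin = np.isfinite(x)
        if fin.sum() < 2:
            out[:, j] = np.nan
            continue
        xf = x.copy()
        if not fin.all():
            xf[~fin] = np.interp(channel.t[~fin], channel.t[fin], x[fin])
        if spec.zero_phase:
            y = signal.sosfiltfilt(sos, xf)
        else:
            y = signal.sosfilt(sos, xf)
        y[~fin] = np.nan
        out[:, j] = y
    values = out[:, 0] if channel.values.ndim == 1 else out
    return channel.copy_with(values=values)


def normalize(x: np.ndarray) -> np.ndarray:
    """Z-score over finite samples (mean 0, sample SD 1); NaNs pass through.

    Raises on constant input or fewer than two finite values.
    """
    x = np.asarray(x, dtype=float)
    fin = np.isfinite(x)
    if fin.sum() < 2:
        raise ValidationError("normalize needs at least 2 finite values")
    mu = x[fin].mean()
    sd = x[fin].std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot normalize a constant series")
    return (x - mu) / sd


def preprocess_bundle(bundle, timeline_check: bool = True):
    """Convenience pass: outlier-mask then band-pass every channel.

    ECG and ACC3 are replaced by their filtered versions (ACC3 keeps the raw
    values too; see :mod:`dyadsync.metrics` which refilters as needed); EDA
    and ST get their smoothing low-passes.  Returns a new bundle; reports
    are attached as ``bundle.preprocess_reports``.
    """
    from .session import SessionBundle

    channels = []
    reports = {}
    for ch in bundle.channels:
        masked, rep = remove_outliers(
            ch, bundle.timeline if timeline_check else None)
        filtered = bandpass(masked)
        channels.append(filtered)
        reports[(ch.subject_id, ch.kind, ch.placement)] = rep
    out = SessionBundle(bundle.session_id, bundle.subjects, bundle.timeline,
                        channels, bundle.behavior, bundle.surveys)
    out.preprocess_reports = reports
    return out
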