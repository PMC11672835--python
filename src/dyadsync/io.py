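"""On-disk session layout and channel synchronization.

Session directory layout::

    manifest.yaml                 subjects, timeline, channel registry, units, fs
    <subject>_<kind>_<placement>.csv   header time_s,value  (or time_s,ax,ay,az)
    behavior_<rater>_<subject>.csv     header second,code   (code in {-1,0,1,offscreen})
    surveys.csv                        subject,timepoint,scale,value
    ground_truth.json                  optional simulator truth (tests only)

Write -> read round-trips losslessly for values and metadata.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .session import (
    KIND_NCOLS,
    KIND_UNITS,
    BehaviorStream,
    Channel,
    SessionBundle,
    Subject,
    Subsession,
    SubsessionTimeline,
    ValidationError,
)

_OFFSCREEN = "offscreen"


def _channel_filename(ch: Channel) -> str:
    return f"{ch.subject_id}_{ch.kind}_{ch.placement}.csv"


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session directory; returns the directory path."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "session_id": bundle.session_id,
        "subjects": [
            {"id": s.id, "species": s.species,
             **({"role": s.role} if s.role else {})}
            for s in bundle.subjects
        ],
        "timeline": [
            {"label": s.label, "t_start": float(s.t_start),
             "t_end": float(s.t_end)}
            for s in bundle.timeline
        ],
        "channels": [
            {"subject": c.subject_id, "kind": c.kind, "placement": c.placement,
             "fs": float(c.fs), "units": KIND_UNITS[c.kind],
             "file": _channel_filename(c)}
            for c in bundle.channels
        ],
        "behavior": [
            {"rater": b.rater, "subject": b.subject_id,
             "origin": float(b.origin),
             "file": f"behavior_{b.rater}_{b.subject_id}.csv"}
            for b in bundle.behavior
        ],
    }
    if bundle.surveys is not None:
        manifest["surveys"] = "surveys.csv"
        bundle.surveys.to_csv(root / "surveys.csv", index=False)
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    for c in bundle.channels:
        if KIND_NCOLS[c.kind] == 1:
            df = pd.DataFrame({"time_s": c.t, "value": c.values})
        else:
            df = pd.DataFrame({"time_s": c.t, "ax": c.values[:, 0],
                               "ay": c.values[:, 1], "az": c.values[:, 2]})
        df.to_csv(root / _channel_filename(c), index=False, float_format="%.17g")

    for b in bundle.behavior:
        codes = [(_OFFSCREEN if np.isnan(v) else int(v)) for v in b.codes]
        pd.DataFrame({"second": np.arange(len(codes)), "code": codes}).to_csv(
            root / f"behavior_{b.rater}_{b.subject_id}.csv", index=False)
    return root


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`."""
    root = Path(path)
    mf_path = root / "manifest.yaml"
    if not mf_path.exists():
        raise ValidationError(f"missing manifest: {mf_path}")
    manifest = yaml.safe_load(mf_path.read_text())

    subjects = [Subject(d["id"], d["species"], d.get("role"))
                for d in manifest["subjects"]]
    timeline = SubsessionTimeline(
        [Subsession(d["label"], float(d["t_start"]), float(d["t_end"]))
         for d in manifest["timeline"]]
    )

    channels = []
    for d in manifest.get("channels", []):
        f = root / d["file"]
        if not f.exists():
            raise ValidationError(f"missing channel file: {f}")
        expected_units = KIND_UNITS[d["kind"]]
        if d.get("units", expected_units) != expected_units:
            raise ValidationError(
                f"unit mismatch for {d['kind']}: manifest says {d['units']!r}, "
                f"expected {expected_units!r}"
            )
        df = pd.read_csv(f, float_precision="round_trip")
        t = df["time_s"].to_numpy(float)
        if KIND_NCOLS[d["kind"]] == 1:
            values = df["value"].to_numpy(float)
        else:
            values = df[["ax", "ay", "az"]].to_numpy(float)
        channels.append(Channel(d["subject"], d["kind"], d["placement"],
                                float(d["fs"]), t, values))

    behavior = []
    for d in manifest.get("behavior", []):
        f = root / d["file"]
        if not f.exists():
            raise ValidationError(f"missing behavior file: {f}")
        df = pd.read_csv(f)
        codes = np.array([np.nan if str(v) == _OFFSCREEN else float(v)
                          for v in df["code"]])
        behavior.append(BehaviorStream(d["rater"], d["subject"], codes,
                                       origin=float(d.get("origin", 0.0))))

    surveys = None
    if "surveys" in manifest:
        f = root / manifest["surveys"]
        if not f.exists():
            raise ValidationError(f"missing survey file: {f}")
        surveys = pd.read_csv(f)

    bundle = SessionBundle(manifest.get("session_id", root.name), subjects,
                           timeline, channels, behavior, surveys)
    bundle.validate()
    return bundle


def synchronize(bundle: SessionBundle, max_gap_s: float = 2.0) -> SessionBundle:
    """Resample every channel onto a uniform per-kind grid on the master clock.

    Target grids are anchored at the timeline origin with the channel's own
    nominal rate, so the maximum induced timing shift is 0.5/fs.  Linear
    interpolation bridges short irregularities; any sample gap longer than
    ``max_gap_s`` (device dropout, canine absence) is flagged missing (NaN),
    never interpolated.  Applying the operation twice equals applying it once.
    """
    origin = bundle.timeline.origin
    channels = [_resample(ch, origin, max_gap_s) for ch in bundle.channels]
    return SessionBundle(bundle.session_id, bundle.subjects, bundle.timeline,
                         channels, bundle.behavior, bundle.surveys)


def _resample(ch: Channel, origin: float, max_gap_s: float) -> Channel:
    if len(ch.t) < 2:
        return ch.copy_with()
    dt = 1.0 / ch.fs
    k0 = int(np.ceil((ch.t[0] - origin) / dt - 1e-9))
    k1 = int(np.floor((ch.t[-1] - origin) / dt + 1e-9))
    tt = origin + np.arange(k0, k1 + 1) * dt

    vals2d = ch.values.reshape(len(ch.t), -1)
    out = np.empty((len(tt), vals2d.shape[1]))
    finite_rows = np.isfinite(vals2d).all(axis=1)
    tf = ch.t[finite_rows]
    if len(tf) < 2:
        out[:] = np.nan
    else:
        vf = vals2d[finite_rows]
        for j in range(vals2d.shape[1]):
            out[:, j] = np.interp(tt, tf, vf[:, j])
        # mask target times falling in a gap between finite source samples;
        # ticks coinciding (within half a sample) with a finite source
        # sample are supported and stay, keeping the operation idempotent
        idx = np.searchsorted(tf, tt, side="right")
        left = tf[np.clip(idx - 1, 0, len(tf) - 1)]
        right = tf[np.clip(idx, 0, len(tf) - 1)]
        gap = right - left
        tol = 0.5 * dt
        in_gap = ((idx > 0) & (idx < len(tf)) & (gap > max_gap_s)
                  & (tt - left > tol) & (right - tt > tol))
        outside = (tt < tf[0] - tol) | (tt > tf[-1] + tol)
        out[in_gap | outside] = np.nan
    values = out[:, 0] if ch.values.ndim == 1 else out
    return Channel(ch.subject_id, ch.kind, ch.placement, ch.fs, tt, values)
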