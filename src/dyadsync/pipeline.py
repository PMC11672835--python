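"""End-to-end session and study drivers.

Glue over the analysis modules: preprocess a session bundle, extract ME/RE
metrics, code behavior, score surveys, compute synchrony, and build the
composite representations; at study level, pool sessions for the
session-type comparisons and the interaction correlation matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bh
from . import composites as cp
from . import metrics as mx
from . import surveys as sv
from . import synchrony as sy
from .preprocess import preprocess_bundle
from .session import EpochGrid, SessionBundle, build_epoch_grid
from .simulate import SimConfig, simulate_session

TORSO = {"human": "chest", "canine": "harness"}


@dataclass
class SessionResult:
    session_id: str
    grid: EpochGrid
    me: pd.DataFrame
    sync: pd.DataFrame
    codes: dict                 # (subject_id, rater) -> BehaviorCodeSeries
    kappa: dict                 # subject_id -> mean pairwise kappa
    state_pct: pd.DataFrame     # per (subsession, subject): pos/neu/neg %
    same_state: pd.DataFrame    # per interaction subsession: XNOR %
    survey_summary: pd.DataFrame
    heatmaps: dict = field(default_factory=dict)  # label -> HeatmapMatrix


def analyze_session(bundle: SessionBundle, rater: str | None = None
                    ) -> SessionResult:
    """Run the full single-session chain on a raw bundle."""
    pre = preprocess_bundle(bundle)
    grid = build_epoch_grid(bundle.timeline)
    beats = {}
    me = mx.epoch_me(pre, grid, beats_cache=beats)

    # --- synchrony on torso RE series ---
    t0, t1 = bundle.timeline.origin, bundle.timeline.t_end
    re_pairs = {}
    sp_subj = {s.species: s.id for s in bundle.subjects}
    for metric in sy.SYNC_METRICS:
        pair = []
        for species in ("human", "canine"):
            sid = sp_subj[species]
            if metric == "IMA":
                src = pre.channel(sid, "ACC3", TORSO[species])
            else:
                src = beats.get((sid, TORSO[species]))
                if src is None:
                    ch = pre.channel(sid, "ECG", TORSO[species])
                    src = mx.detect_r_peaks(ch, species)
            pair.append(mx.rolling_re(src, metric, t0, t1))
        re_pairs[metric] = tuple(pair)
    sync = sy.synchrony_table(re_pairs, bundle.timeline)

    # --- behavior coding ---
    codes = {}
    for stream in bundle.behavior:
        codes[(stream.subject_id, stream.rater)] = bh.ppsa_code(stream, grid)
    raters = sorted({r for (_, r) in codes})
    use_rater = rater or (raters[0] if raters else None)
    kappa = {}
    for sid in {s for (s, _) in codes}:
        series = [codes[(sid, r)] for r in raters if (sid, r) in codes]
        if len(series) >= 2:
            kappa[sid] = bh.mean_pairwise_kappa(series)

    pct_rows, same_rows = [], []
    if use_rater is not None:
        for sub in bundle.timeline.interactions():
            eps = grid.epochs_of(sub.label)["epoch"].to_numpy()
            per_subject = {}
            for sid in sorted({s for (s, _) in codes}):
                cs = codes[(sid, use_rater)]
                sel = np.isin(cs.epochs, eps)
                per_subject[sid] = cs.codes[sel]
                try:
                    pos, neu, neg = bh.state_percentages(cs.codes[sel])
                    pct_rows.append((sub.label, sid, pos, neu, neg))
                except Exception:
                    pct_rows.append((sub.label, sid, np.nan, np.nan, np.nan))
            if len(per_subject) == 2:
                a, b = per_subject.values()
                try:
                    same_rows.append((sub.label, bh.same_state_pct(a, b)))
                except Exception:
                    same_rows.append((sub.label, np.nan))
    state_pct = pd.DataFrame(pct_rows, columns=["subsession", "subject",
                                                "pos_pct", "neu_pct",
                                                "neg_pct"])
    same_state = pd.DataFrame(same_rows, columns=["subsession",
                                                  "same_state_pct"])

    survey_summary = (sv.summarize_by_subsession(bundle.surveys)
                      if bundle.surveys is not None else pd.DataFrame())

    # --- directional heatmaps on the central 3 min of each interaction ---
    deltas = cp.epoch_deltas(me[me["metric"].isin(cp.DEFAULT_DIRECTION_MAP)])
    species_of = {s.id: s.species for s in bundle.subjects}
    heatmaps = {}
    for sub in bundle.timeline.interactions():
        eps = grid.epochs_of(sub.label)["epoch"].to_numpy()
        if len(eps) < 18:
            continue
        start = (len(eps) - 18) // 2
        seg = eps[start:start + 18]
        heatmaps[sub.label] = cp.build_heatmap(
            deltas, seg, sub.label, surveys=bundle.surveys,
            species_of=species_of)

    return SessionResult(bundle.session_id, grid, me, sync, codes, kappa,
                         state_pct, same_state, survey_summary, heatmaps)


@dataclass
class StudyResult:
    sessions: list
    survey_records: pd.DataFrame
    survey_comparison: pd.DataFrame
    me_comparison: pd.DataFrame
    features: pd.DataFrame
    corr: pd.DataFrame


def run_study(n_sessions: int = 22, seed: int = 0,
              config_factory=None) -> StudyResult:
    """Simulate and analyze a whole multi-session synthetic study.

    Each session draws its own seed from ``seed``; ``config_factory(k,
    session_seed)`` may customize per-session conditions (bond levels
    etc.).  Returns pooled session-type comparisons (surveys and ME
    metrics) and the interaction correlation matrix.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_sessions)]
    results, bundles = [], []
    for k, s in enumerate(seeds):
        if config_factory is not None:
            cfg = config_factory(k, s)
        else:
            cfg = SimConfig(seed=s)
        bundle, _ = simulate_session(cfg)
        bundle.session_id = f"S{k:02d}"
        results.append(analyze_session(bundle))
        bundles.append(bundle)

    survey_records = pd.concat(
        [b.surveys.assign(session=r.session_id)
         for b, r in zip(bundles, results) if b.surveys is not None],
        ignore_index=True)
    survey_comparison = sv.compare_session_types(survey_records)

    me_all = pd.concat([r.me.assign(session=r.session_id) for r in results],
                       ignore_index=True)
    me_sess = (me_all.groupby(["session", "subsession", "subject",
                               "placement", "metric"])["value"]
               .mean().reset_index())
    me_sess["scale"] = (me_sess["subject"] + "_" + me_sess["placement"]
                        + "_" + me_sess["metric"])
    me_comparison = sv.compare_session_types(
        me_sess.rename(columns={"subsession": "label"}))

    features = build_interaction_features(results, bundles)
    corr = cp.correlation_matrix(features)
    return StudyResult(results, survey_records, survey_comparison,
                       me_comparison, features, corr)


def coupling_recovery(levels=(0.0, 0.3, 0.6, 0.9), n_seeds: int = 30,
                      seed: int = 0) -> pd.DataFrame:
    """Recover the dyadic coupling from simulated sessions.

    For each coupling level, simulates dyads (two 10-min interaction
    subsessions each), runs the full ECG -> R peaks -> RE -> mid-slice
    chain and averages the HR-slice Pearson r and the z-scored DTW
    distance over all interaction slices of all seeds.
    """
    plan = (("INT1", 600.0), ("NEU1", 60.0), ("INT2", 600.0))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in ss.spawn(n_seeds)]
    rows = []
    for rho in levels:
        rs, dzs = [], []
        for s in seeds:
            cfg = SimConfig(seed=s, coupling_rho=rho, subsession_plan=plan)
            bundle, _ = simulate_session(cfg)
            pre = preprocess_bundle(bundle)
            t0, t1 = bundle.timeline.origin, bundle.timeline.t_end
            res = {}
            for species in ("human", "canine"):
                sid = {s_.species: s_.id for s_ in bundle.subjects}[species]
                ch = pre.channel(sid, "ECG", TORSO[species])
                beats = mx.detect_r_peaks(ch, species)
                res[species] = mx.rolling_re(beats, "HR", t0, t1)
            for sub in bundle.timeline.interactions():
                sl = sy.extract_slice(res["human"], res["canine"], sub)
                rs.append(sy.pearson_r(sl.human, sl.canine))
                dzs.append(sy.dtw_distance(sl.human, sl.canine,
                                           z_normalize=True))
        rows.append((rho, float(np.mean(rs)), float(np.std(rs)),
                     float(np.mean(dzs)), len(rs)))
    return pd.DataFrame(rows, columns=["coupling_rho", "mean_r", "sd_r",
                                       "mean_dtw_z", "n_slices"])


def beat_recovery(n_seeds: int = 20, seed: int = 0, fs: float = 250.0,
                  duration: float = 300.0, noise_sd: float = 0.05
                  ) -> pd.DataFrame:
    """Detector fidelity on clean synthetic ECG for both species.

    Per seed and species: R-peak sensitivity within +-20 ms of truth,
    mean absolute per-epoch heart-rate error, and the relative SDNN
    recovery error against the generator target.
    """
    from .session import Channel, SubsessionTimeline, build_epoch_grid

    conditions = {"human": (75.0, 50.0, 40.0), "canine": (95.0, 60.0, 55.0)}
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in ss.spawn(2 * n_seeds)]
    rows = []
    for i in range(n_seeds):
        for j, (species, (hr, sdnn, rmssd)) in enumerate(conditions.items()):
            s = seeds[2 * i + j]
            from .simulate import render_ecg, simulate_ibi_series

            ibi = simulate_ibi_series(hr, sdnn, rmssd, duration, seed=s)
            t, ecg, r_true = render_ecg(ibi, fs, seed=s + 1,
                                        noise_sd=noise_sd)
            ch = Channel("X", "ECG", "chest", fs, t, ecg)
            beats = mx.detect_r_peaks(ch, species)
            # sensitivity: fraction of true peaks with a detection in +-20 ms
            if beats.n_beats == 0:
                sensitivity = 0.0
            else:
                idx = np.searchsorted(beats.t, r_true)
                near = np.minimum(
                    np.abs(beats.t[np.clip(idx, 0, beats.n_beats - 1)] - r_true),
                    np.abs(beats.t[np.clip(idx - 1, 0, beats.n_beats - 1)]
                           - r_true))
                sensitivity = float((near < 0.020).mean())
            # per-epoch HR error against truth beats
            tl = SubsessionTimeline.from_plan([("BASE", t[-1] + 1.0 / fs)])
            grid = build_epoch_grid(tl)
            errs = []
            true_ibi = np.diff(r_true) * 1000.0
            for _, _, t0, t1 in grid.frame[
                    ["subsession", "epoch", "t0", "t1"]].itertuples(index=False):
                sel_t = (r_true[1:] >= t0) & (r_true[1:] < t1)
                sel_d = (beats.t[1:] >= t0) & (beats.t[1:] < t1) \
                    if beats.n_beats > 1 else np.empty(0, bool)
                if sel_t.sum() < 2 or sel_d.sum() < 2:
                    continue
                hr_t = 60000.0 / true_ibi[sel_t].mean()
                hr_d = 60000.0 / beats.ibi[sel_d][beats.valid[sel_d]].mean()
                errs.append(abs(hr_t - hr_d))
            sdnn_est, _, _ = mx.hrv_time_domain(beats.ibi, beats.valid)
            rows.append((species, sensitivity,
                         float(np.mean(errs)) if errs else np.nan,
                         abs(sdnn_est - sdnn) / sdnn))
    return pd.DataFrame(rows, columns=["species", "sensitivity",
                                       "epoch_hr_mae", "sdnn_rel_err"])


def wilcoxon_type1(n_replicates: int = 1000, n_pairs: int = 12,
                   seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the signed-rank test under a true null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(size=n_pairs)
        y = rng.normal(size=n_pairs)
        res = sv.wilcoxon_signed_rank(x, y)
        rejections += res.p_value < alpha
    return rejections / n_replicates


def build_interaction_features(results, bundles) -> pd.DataFrame:
    """One row per interaction subsession: middle-minute (6 central epochs)
    metric means, mean behavior code, and post-interaction survey scores."""
    rows = []
    for res, bundle in zip(results, bundles):
        species_of = {s.id: s.species for s in bundle.subjects}
        raters = sorted({r for (_, r) in res.codes})
        for sub in bundle.timeline.interactions():
            try:
                mid = cp.middle_epochs(res.grid, sub.label, 6)
            except Exception:
                continue
            feat = {}
            me = res.me[res.me["epoch"].isin(mid)]
            for (sid, metric), g in me.groupby(["subject", "metric"]):
                prefix = "h" if species_of[sid] == "human" else "c"
                if metric in ("HR", "SDNN", "RMSSD", "IMA", "ST", "EDA_mean",
                              "EDA_max", "EDA_peak_ct"):
                    feat[f"{prefix}_{metric}"] = g["value"].mean()
            for sid in species_of:
                if raters:
                    cs = res.codes[(sid, raters[0])]
                    sel = np.isin(cs.epochs, mid)
                    det = cs.codes[sel]
                    det = det[~np.isnan(det)]
                    prefix = "h" if species_of[sid] == "human" else "c"
                    feat[f"{prefix}_becode"] = det.mean() if len(det) else np.nan
            if bundle.surveys is not None:
                post = bundle.surveys[bundle.surveys["timepoint"]
                                      == f"post_{sub.label}"]
                for _, r in post.iterrows():
                    feat[r["scale"]] = float(r["value"])
            rows.append(feat)
    return pd.DataFrame(rows)
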