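"""Synthetic canine-assisted-interaction (CAI) dyad sessions with known truth.

The generator emits a complete session — coupled human/canine interbeat
processes rendered to raw ECG, tri-axial activity with scheduled bouts,
tonic+phasic electrodermal activity, slow skin-temperature drift, coupled
three-state behavior label streams from multiple raters, and interstitial
survey scores — together with a :class:`GroundTruth` container so every
downstream estimate can be checked against what was injected.

Interbeat intervals use a two-timescale construction.  A slow modulation
(per-second AR(1), time constant ~20 s) carries the dyadic coupling: during
interaction subsessions both subjects load a shared latent driver with
weight sqrt(coupling_rho), which makes the expected Pearson correlation of
their slow heart-rate modulation equal coupling_rho.  A fast beat-to-beat
AR(1) supplies the remaining variance, with its lag-1 autocorrelation
solved from the identity RMSSD^2 = 2*Var*(1-phi) so that one
(SDNN, RMSSD) pair is targeted exactly in expectation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .session import (
    BehaviorStream,
    Channel,
    SessionBundle,
    Subject,
    SubsessionTimeline,
    ValidationError,
)

#: Standard protocol: interaction periods couched in neutral periods.
DEFAULT_PLAN = (
    ("BASE", 300.0),
    ("INT1", 600.0),
    ("NEU1", 300.0),
    ("INT2", 600.0),
    ("POST", 300.0),
)

#: Fraction of IBI variance carried by the slow (coupled) modulation.
SLOW_FRAC = 0.6
#: Per-second autocorrelation of the slow modulation (time constant ~20 s).
PHI_SLOW = 0.95

STATES = (-1, 0, 1)
#: Neutral-heavy state dynamics (interaction time is mostly neutral, positive
#: displays are bout-like, negative ones rare).
DEFAULT_TRANSITION = np.array([
    [0.50, 0.45, 0.05],   # from negative
    [0.01, 0.93, 0.06],   # from neutral
    [0.01, 0.25, 0.74],   # from positive
])

_ECG_R_AMP = 1.0      # mV
_ECG_R_SIGMA = 0.005  # s  (~12 ms FWHM R wave)
_ECG_P_AMP = 0.15
_ECG_P_SIGMA = 0.020
_ECG_T_AMP = 0.30
_ECG_T_SIGMA = 0.040

_SCR_TAU_RISE = 0.75  # s
_SCR_TAU_DECAY = 4.0  # s


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Heart-rate and HRV targets follow typical human resting values and a
    faster canine heart; the canine SDNN/RMSSD defaults are plausible
    placeholders, not population claims about dogs.
    """

    seed: int = 0
    subsession_plan: tuple = DEFAULT_PLAN
    human_hr_mean: float = 75.0    # beats/min
    canine_hr_mean: float = 95.0   # beats/min
    sdnn_target: dict = field(default_factory=lambda: {"human": 50.0, "canine": 60.0})
    rmssd_target: dict = field(default_factory=lambda: {"human": 40.0, "canine": 55.0})
    coupling_rho: float = 0.6      # dyadic physiological coupling, [0, 1]
    copy_prob_kappa: float = 0.6   # behavior-state coupling, [0, 1]
    scr_rate: float = 4.0          # SCR events/min (neutral periods)
    scr_amp_mean: float = 0.5      # uS
    activity_bout_schedule: dict | None = None  # species -> [(start, end, amp)]
    st_baseline: float = 30.0      # degC
    st_drift: float = 0.1          # degC/min
    eda_tonic: float = 1.5         # uS
    eda_drift: float = 0.02        # uS/min
    ecg_fs: float = 200.0
    acc_fs: float = 32.0
    eda_fs: float = 4.0
    st_fs: float = 4.0
    ecg_noise_sd: float = 0.02     # mV
    n_raters: int = 2
    rater_error_prob: float = 0.05
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy())

    def __post_init__(self) -> None:
        for label, dur in self.subsession_plan:
            if dur <= 0:
                raise ValidationError(f"subsession {label}: duration {dur} <= 0")
        for hr in (self.human_hr_mean, self.canine_hr_mean):
            if not 20.0 < hr < 300.0:
                raise ValidationError(f"heart rate {hr} outside (20, 300) beats/min")
        for name, v in (("coupling_rho", self.coupling_rho),
                        ("copy_prob_kappa", self.copy_prob_kappa)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for sp in ("human", "canine"):
            sdnn, rmssd = self.sdnn_target[sp], self.rmssd_target[sp]
            _check_ar1_feasible(sdnn * np.sqrt(1.0 - SLOW_FRAC), rmssd,
                                context=f"{sp} fast component")

    @property
    def hr_mean(self) -> dict:
        return {"human": self.human_hr_mean, "canine": self.canine_hr_mean}


@dataclass
class GroundTruth:
    """What the simulator injected, for recovery tests."""

    r_peak_times: dict          # subject_id -> np.ndarray of seconds
    scr_times: dict             # subject_id -> np.ndarray of seconds
    state_sequence: dict        # subject_id -> per-second int array (-1/0/+1)
    realized_coupling: float
    bout_schedule: dict         # subject_id -> list of (start, end, amp)

    def to_json(self, path: str | Path) -> None:
        d = {
            "r_peak_times": {k: list(map(float, v))
                             for k, v in self.r_peak_times.items()},
            "scr_times": {k: list(map(float, v))
                          for k, v in self.scr_times.items()},
            "state_sequence": {k: list(map(int, v))
                               for k, v in self.state_sequence.items()},
            "realized_coupling": float(self.realized_coupling),
            "bout_schedule": {k: [list(map(float, b)) for b in v]
                              for k, v in self.bout_schedule.items()},
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            {k: np.asarray(v, float) for k, v in d["r_peak_times"].items()},
            {k: np.asarray(v, float) for k, v in d["scr_times"].items()},
            {k: np.asarray(v, int) for k, v in d["state_sequence"].items()},
            d["realized_coupling"],
            {k: [tuple(b) for b in v] for k, v in d["bout_schedule"].items()},
        )


def _check_ar1_feasible(sdnn: float, rmssd: float, context: str = "") -> float:
    """phi = 1 - rmssd^2 / (2 sdnn^2) must be a valid AR(1) autocorrelation."""
    if sdnn < 0 or rmssd < 0:
        raise ValidationError("sdnn and rmssd must be non-negative")
    if sdnn == 0:
        if rmssd != 0:
            raise ValidationError("rmssd must be 0 when sdnn is 0")
        return 0.0
    phi = 1.0 - rmssd ** 2 / (2.0 * sdnn ** 2)
    if not -1.0 < phi < 1.0:
        raise ValidationError(
            f"infeasible (sdnn={sdnn}, rmssd={rmssd})"
            f"{' for ' + context if context else ''}: AR(1) lag-1 "
            f"autocorrelation phi={phi:.3f} outside (-1, 1); require "
            "0 < rmssd < 2*sdnn"
        )
    return phi


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_ibi_series(mean_hr: float, sdnn: float, rmssd: float,
                        duration: float, seed=0) -> np.ndarray:
    """Stationary AR(1) interbeat-interval sequence (ms).

    Marginal mean 60000/mean_hr, marginal SD ``sdnn`` and expected RMSSD
    ``rmssd`` via phi = 1 - rmssd^2/(2 sdnn^2).  The cumulative sum of the
    returned sequence covers at least ``duration`` seconds.
    """
    if not 20.0 < mean_hr < 300.0:
        raise ValidationError(f"mean_hr {mean_hr} outside (20, 300)")
    phi = _check_ar1_feasible(sdnn, rmssd)
    mu = 60000.0 / mean_hr
    rng = _rng(seed)
    n = int(np.ceil(duration * 1000.0 / mu * 1.2)) + 20
    out = np.empty(0)
    x = rng.normal(0.0, sdnn) if sdnn > 0 else 0.0
    while out.sum() < duration * 1000.0:
        eps = rng.normal(0.0, 1.0, size=n)
        seg = np.empty(n)
        innov_sd = sdnn * np.sqrt(1.0 - phi ** 2)
        for i in range(n):
            x = phi * x + innov_sd * eps[i]
            seg[i] = x
        out = np.concatenate([out, np.clip(mu + seg, 0.3 * mu, 2.5 * mu)])
    return out


def render_ecg(ibi: np.ndarray, fs: float, seed=0, noise_sd: float = 0.02,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render raw ECG (mV) from an IBI sequence.

    Returns ``(t, ecg, r_times)``: a uniform time base starting at 0, the
    waveform (three Gaussian bumps per beat: P, R, T; R amplitude 1 mV),
    and the R-peak times.  Beat times are snapped to the sample grid so the
    recorded truth index is exactly the noiseless argmax.
    """
    if fs < 100.0:
        raise ValidationError(f"fs={fs} Hz too low to resolve QRS (need >= 100)")
    ibi = np.asarray(ibi, dtype=float)
    if len(ibi) == 0:
        raise ValidationError("empty IBI sequence")
    r_times = 0.3 + np.concatenate([[0.0], np.cumsum(ibi[:-1])]) / 1000.0
    r_times = np.round(r_times * fs) / fs
    duration = r_times[-1] + 0.5
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    _add_beat_bumps(ecg, fs, r_times, ibi)
    rng = _rng(seed)
    if noise_sd > 0:
        ecg += rng.normal(0.0, noise_sd, size=n)
    return t, ecg, r_times


def _add_beat_bumps(out: np.ndarray, fs: float, r_times: np.ndarray,
                    ibi_ms: np.ndarray, t0: float = 0.0) -> None:
    """Add P/QRS/T Gaussian bumps for each beat to a preallocated signal."""
    n = len(out)
    local = np.concatenate([ibi_ms, [ibi_ms[-1]]])[:len(r_times)] / 1000.0
    for r, ib in zip(r_times, local):
        p_t = r - 0.18 * ib
        t_t = r + 0.30 * ib
        lo = max(0, int((p_t - 5 * _ECG_P_SIGMA - t0) * fs))
        hi = min(n, int((t_t + 5 * _ECG_T_SIGMA - t0) * fs) + 1)
        if hi <= lo:
            continue
        tt = t0 + np.arange(lo, hi) / fs
        out[lo:hi] += (
            _ECG_P_AMP * np.exp(-0.5 * ((tt - p_t) / _ECG_P_SIGMA) ** 2)
            + _ECG_R_AMP * np.exp(-0.5 * ((tt - r) / _ECG_R_SIGMA) ** 2)
            + _ECG_T_AMP * np.exp(-0.5 * ((tt - t_t) / _ECG_T_SIGMA) ** 2)
        )


def scr_kernel(t: np.ndarray) -> np.ndarray:
    """Bi-exponential (Bateman) SCR shape, normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0,
                 np.exp(-np.clip(t, 0, None) / _SCR_TAU_DECAY)
                 - np.exp(-np.clip(t, 0, None) / _SCR_TAU_RISE), 0.0)
    t_peak = (np.log(_SCR_TAU_DECAY / _SCR_TAU_RISE)
              * _SCR_TAU_RISE * _SCR_TAU_DECAY / (_SCR_TAU_DECAY - _SCR_TAU_RISE))
    peak = (np.exp(-t_peak / _SCR_TAU_DECAY) - np.exp(-t_peak / _SCR_TAU_RISE))
    return h / peak


def simulate_eda(duration: float, fs: float, scr_times, scr_amplitudes,
                 tonic_level: float, drift: float = 0.0, seed=0,
                 noise_sd: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Tonic ramp + Bateman SCR bumps + Gaussian noise.

    ``drift`` is in uS/min.  Returns ``(t, eda)``.
    """
    scr_times = np.asarray(scr_times, dtype=float)
    scr_amplitudes = np.asarray(scr_amplitudes, dtype=float)
    if (scr_amplitudes < 0).any():
        raise ValidationError("SCR amplitudes must be non-negative")
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    x = tonic_level + drift * t / 60.0
    for ts, amp in zip(scr_times, scr_amplitudes):
        x += amp * scr_kernel(t - ts)
    if noise_sd > 0:
        x = x + _rng(seed).normal(0.0, noise_sd, size=n)
    return t, x


def simulate_accelerometer(duration: float, fs: float, schedule, seed=0,
                           noise_floor: float = 0.03, gravity: float = 9.81,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Gravity on z + band-limited dynamic noise bursts during bouts.

    ``schedule`` is a list of (start_s, end_s, amplitude m/s^2); intervals
    must be disjoint and inside [0, duration].  Returns ``(t, values)`` with
    values shaped (n, 3).
    """
    sched = sorted((float(a), float(b), float(amp)) for a, b, amp in schedule)
    for (a, b, _) in sched:
        if a < 0 or b > duration + 1e-9 or b <= a:
            raise ValidationError(f"bout ({a}, {b}) outside [0, {duration}]")
    for (a1, b1, _), (a2, b2, _) in zip(sched, sched[1:]):
        if a2 < b1:
            raise ValidationError(f"overlapping bouts ({a1},{b1}) and ({a2},{b2})")
    rng = _rng(seed)
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    env = np.zeros(n)
    ramp = max(1, int(fs))  # 1 s raised-cosine edges
    for a, b, amp in sched:
        i0, i1 = int(a * fs), min(n, int(b * fs))
        seg = np.full(i1 - i0, 1.0)
        m = min(ramp, len(seg) // 2)
        if m > 0:
            w = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
            seg[:m] *= w
            seg[len(seg) - m:] *= w[::-1]
        env[i0:i1] = np.maximum(env[i0:i1], amp * seg)
    sos = sp_signal.butter(2, [0.3 / (fs / 2), min(8.0, 0.45 * fs) / (fs / 2)],
                           btype="band", output="sos")
    vals = np.empty((n, 3))
    for j in range(3):
        w = sp_signal.sosfilt(sos, rng.normal(0.0, 1.0, size=n))
        sd = w.std() or 1.0
        vals[:, j] = env / np.sqrt(3.0) * (w / sd) \
            + rng.normal(0.0, noise_floor, size=n)
    vals[:, 2] += gravity
    return t, vals


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def _markov_chain(n: int, transition: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    pi = stationary_distribution(transition)
    cum = np.cumsum(transition, axis=1)
    u = rng.random(n)
    s = np.empty(n, dtype=int)
    s[0] = rng.choice(3, p=pi)
    for k in range(1, n):
        s[k] = np.searchsorted(cum[s[k - 1]], u[k])
    return s


def simulate_behavior_codes(n_seconds: int, transition_matrix: np.ndarray,
                            copy_prob_kappa: float, seed=0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Coupled per-second state streams (values in {-1, 0, +1}).

    The human stream is a 3-state Markov chain; each second the canine
    emits the human's current state with probability kappa and otherwise
    its own independent chain's state, so the expected same-state fraction
    is kappa + (1 - kappa) * chance agreement >= kappa.
    """
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.shape != (3, 3) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("transition_matrix rows must sum to 1 (+-1e-9)")
    if not 0.0 <= copy_prob_kappa <= 1.0:
        raise ValidationError("copy_prob_kappa outside [0, 1]")
    rng = _rng(seed)
    states = np.array(STATES)
    human = states[_markov_chain(n_seconds, tm, rng)]
    own = states[_markov_chain(n_seconds, tm, rng)]
    copy = rng.random(n_seconds) < copy_prob_kappa
    canine = np.where(copy, human, own)
    return human, canine


#: Bias constant of the slice-Pearson estimator for this pipeline geometry:
#: a 180 s slice of 60 s moving-average-smoothed series has few effective
#: degrees of freedom, so E[sample r] ~= x - c * x * (1 - x^2) when the
#: underlying modulation correlation is x.  The constant matches the
#: closed latent model across the whole [0, 1] range.
_SLICE_R_BIAS = 0.30
#: Multiplicative dilution of the slice correlation by the rest of the
#: chain (beat-to-beat HRV noise surviving the 60 s window, detection and
#: quantization noise), from the variance budget of the two-timescale
#: construction.
_CHAIN_DILUTION = 0.95


def _latent_coupling(rho: float) -> float:
    """Latent cross-correlation that delivers an expected mid-interaction
    slice Pearson r equal to the nominal ``coupling_rho``.

    ``coupling_rho`` is defined as the target slice correlation of the two
    subjects' smoothed heart-rate modulation; the latent loading is the
    internal knob, solved by inverting the estimator-bias relation above.
    """
    if rho <= 0.0:
        return 0.0
    if rho >= 1.0:
        return 1.0

    def delivered(x: float) -> float:
        return _CHAIN_DILUTION * (x - _SLICE_R_BIAS * x * (1.0 - x * x))

    if delivered(1.0) <= rho:
        return 1.0
    lo, hi = rho, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if delivered(mid) < rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ar1_path(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-marginal-variance AR(1) sample path of length n."""
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n) * np.sqrt(1.0 - phi ** 2)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k]
    return x


def _presence_blocks(timeline: SubsessionTimeline, species: str
                     ) -> list[tuple[float, float]]:
    """Contiguous spans a subject is in the room (dog out during NEU)."""
    blocks: list[list[float]] = []
    for sub in timeline:
        if species == "canine" and sub.label.startswith("NEU"):
            continue
        if blocks and abs(blocks[-1][1] - sub.t_start) < 1e-9:
            blocks[-1][1] = sub.t_end
        else:
            blocks.append([sub.t_start, sub.t_end])
    return [(a, b) for a, b in blocks]


def _coupled_beats(config: SimConfig, timeline: SubsessionTimeline,
                   rng_pool: dict) -> dict:
    """Beat times per subject with shared slow modulation during INT."""
    total = timeline.duration
    lat_t = timeline.origin + np.arange(int(np.ceil(total)) + 2)
    rho = _latent_coupling(config.coupling_rho)
    rng = rng_pool["latent"]
    z = _ar1_path(len(lat_t), PHI_SLOW, rng)
    e = {"human": _ar1_path(len(lat_t), PHI_SLOW, rng),
         "canine": _ar1_path(len(lat_t), PHI_SLOW, rng)}
    int_mask = np.zeros(len(lat_t), dtype=bool)
    for sub in timeline.interactions():
        int_mask |= (lat_t >= sub.t_start) & (lat_t < sub.t_end)

    u = {}
    for sp in ("human", "canine"):
        u[sp] = np.where(int_mask,
                         np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e[sp],
                         e[sp])

    beats = {}
    for sp in ("human", "canine"):
        mu = 60000.0 / config.hr_mean[sp]
        sdnn = config.sdnn_target[sp]
        rmssd = config.rmssd_target[sp]
        slow_sd = sdnn * np.sqrt(SLOW_FRAC)
        fast_sd = sdnn * np.sqrt(1.0 - SLOW_FRAC)
        # subtract the slow component's contribution to successive diffs
        slow_dvar = 2.0 * slow_sd ** 2 * (1.0 - PHI_SLOW ** (mu / 1000.0))
        fast_dvar = max(rmssd ** 2 - slow_dvar, 0.0)
        phi_f = 1.0 - fast_dvar / (2.0 * fast_sd ** 2) if fast_sd > 0 else 0.0
        phi_f = float(np.clip(phi_f, -0.999, 0.999))
        rng_b = rng_pool[f"beats_{sp}"]
        times: list[float] = []
        x = rng_b.normal(0.0, fast_sd) if fast_sd > 0 else 0.0
        innov_sd = fast_sd * np.sqrt(1.0 - phi_f ** 2)
        for t0, t1 in _presence_blocks(timeline, sp):
            t = t0 + rng_b.uniform(0.05, 0.3)
            while True:
                times.append(t)
                slow = slow_sd * np.interp(t, lat_t, u[sp])
                x = phi_f * x + innov_sd * rng_b.normal()
                ibi = float(np.clip(mu + slow + x, 0.4 * mu, 2.5 * mu))
                t = t + ibi / 1000.0
                if t >= t1 - 0.05:
                    break
        beats[sp] = np.asarray(times)

    int_sec = int_mask
    realized = float(np.corrcoef(u["human"][int_sec], u["canine"][int_sec])[0, 1]) \
        if int_sec.sum() > 2 else float("nan")
    return {"beats": beats, "realized_coupling": realized}


def _auto_bout_schedule(timeline: SubsessionTimeline, species: str,
                        rng: np.random.Generator) -> list[tuple[float, float, float]]:
    sched = []
    for sub in timeline:
        if species == "canine" and sub.label.startswith("NEU"):
            continue
        n = rng.poisson(3.0 if sub.is_interaction else 1.0)
        lo, hi = ((1.0, 2.5) if sub.is_interaction else (0.3, 0.8))
        tries = 0
        while n > 0 and tries < 50:
            tries += 1
            dur = rng.uniform(15.0, 45.0)
            if dur >= sub.duration:
                continue
            a = rng.uniform(sub.t_start, sub.t_end - dur)
            b = a + dur
            if any(a < b0 and a0 < b for a0, b0, _ in sched):
                continue
            sched.append((a, b, rng.uniform(lo, hi)))
            n -= 1
    return sorted(sched)


def simulate_session(config: SimConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate one full synthetic session and its ground truth."""
    timeline = SubsessionTimeline.from_plan(config.subsession_plan)
    ss = np.random.SeedSequence(config.seed)
    names = ["latent", "beats_human", "beats_canine", "ecg_human", "ecg_canine",
             "eda", "st", "acc_human", "acc_canine", "behavior", "raters",
             "surveys", "schedule"]
    rng_pool = {nm: np.random.default_rng(s)
                for nm, s in zip(names, ss.spawn(len(names)))}

    human = Subject("H1", "human", "owner")
    canine = Subject("C1", "canine")
    sub_of = {"human": human, "canine": canine}

    res = _coupled_beats(config, timeline, rng_pool)
    beats = res["beats"]
    total = timeline.duration
    origin = timeline.origin

    channels = []
    # --- ECG ---
    ecg_placement = {"human": "chest", "canine": "harness"}
    r_truth = {}
    for sp in ("human", "canine"):
        fs = config.ecg_fs
        n = int(np.round(total * fs))
        t = origin + np.arange(n) / fs
        x = np.full(n, np.nan)
        bt = np.round((beats[sp] - origin) * fs) / fs + origin
        ibi_ms = np.diff(bt) * 1000.0
        rng = rng_pool[f"ecg_{sp}"]
        blocks = _presence_blocks(timeline, sp)
        for (a, b) in blocks:
            i0 = int(np.ceil((a - origin) * fs - 1e-9))
            i1 = min(n, int(np.floor((b - origin) * fs + 1e-9)))
            seg = rng.normal(0.0, config.ecg_noise_sd, size=i1 - i0) \
                if config.ecg_noise_sd > 0 else np.zeros(i1 - i0)
            in_block = (bt >= a) & (bt < b)
            bts = bt[in_block]
            if len(bts) >= 2:
                local_ibi = np.diff(bts) * 1000.0
                _add_beat_bumps(seg, fs, bts - (origin + i0 / fs), local_ibi,
                                t0=0.0)
            x[i0:i1] = seg
        channels.append(Channel(sub_of[sp].id, "ECG", ecg_placement[sp],
                                fs, t, x))
        r_truth[sub_of[sp].id] = bt

    # --- accelerometers ---
    if config.activity_bout_schedule is not None:
        sched = {sp: list(config.activity_bout_schedule.get(sp, []))
                 for sp in ("human", "canine")}
    else:
        sched = {sp: _auto_bout_schedule(timeline, sp, rng_pool["schedule"])
                 for sp in ("human", "canine")}
    acc_placement = {"human": "chest", "canine": "harness"}
    for sp in ("human", "canine"):
        rel = [(a - origin, b - origin, amp) for a, b, amp in sched[sp]]
        t, vals = simulate_accelerometer(total, config.acc_fs, rel,
                                         seed=rng_pool[f"acc_{sp}"])
        t = t + origin
        for (a, b) in _absence_spans(timeline, sp):
            vals[(t >= a) & (t < b)] = np.nan
        channels.append(Channel(sub_of[sp].id, "ACC3", acc_placement[sp],
                                config.acc_fs, t, vals))

    # --- EDA + ST (human wrist only; no canine EDA/ST channel exists) ---
    rng = rng_pool["eda"]
    sec = np.arange(int(np.ceil(total)))
    int_ind = np.zeros(len(sec))
    for sub in timeline.interactions():
        int_ind[(origin + sec >= sub.t_start) & (origin + sec < sub.t_end)] = 1.0
    rate = config.scr_rate * (1.0 + 0.5 * int_ind) / 60.0  # events/s
    scr_mask = rng.random(len(sec)) < rate
    scr_times_rel = sec[scr_mask] + rng.uniform(0, 1, size=scr_mask.sum())
    amps = rng.gamma(4.0, config.scr_amp_mean / 4.0, size=len(scr_times_rel))
    t, eda = simulate_eda(total, config.eda_fs, scr_times_rel, amps,
                          config.eda_tonic, config.eda_drift, seed=rng)
    arousal = 0.6 * gaussian_filter1d(int_ind, 20.0)
    eda = eda + np.interp(t, sec + 0.5, arousal)
    channels.append(Channel(human.id, "EDA", "left_wrist", config.eda_fs,
                            t + origin, eda))

    rng = rng_pool["st"]
    n_st = int(np.round(total * config.st_fs))
    t_st = np.arange(n_st) / config.st_fs
    st = np.clip(config.st_baseline + config.st_drift * t_st / 60.0, None, 41.0) \
        + rng.normal(0.0, 0.02, size=n_st)
    channels.append(Channel(human.id, "ST", "left_wrist", config.st_fs,
                            t_st + origin, st))

    # --- behavior states, raters ---
    n_sec = int(np.ceil(total))
    h_states, c_states = simulate_behavior_codes(
        n_sec, config.transition_matrix, config.copy_prob_kappa,
        seed=rng_pool["behavior"])
    sec_abs = origin + np.arange(n_sec)
    non_int = np.ones(n_sec, dtype=bool)
    for sub in timeline.interactions():
        non_int &= ~((sec_abs >= sub.t_start) & (sec_abs < sub.t_end))
    h_states = np.where(non_int, 0, h_states)   # humans sit quietly off-interaction

    offscreen = {"H1": np.zeros(n_sec, dtype=bool),
                 "C1": np.zeros(n_sec, dtype=bool)}
    for (a, b) in _absence_spans(timeline, "canine"):
        offscreen["C1"][(sec_abs >= a) & (sec_abs < b)] = True
    rng = rng_pool["raters"]
    for sid, rate_pm in (("C1", 0.2), ("H1", 0.05)):
        starts = np.nonzero(rng.random(n_sec) < rate_pm / 60.0)[0]
        for s0 in starts:
            offscreen[sid][s0:s0 + int(rng.exponential(8.0)) + 1] = True

    states_by_id = {"H1": h_states, "C1": c_states}
    behavior = []
    for r in range(config.n_raters):
        for sid in ("H1", "C1"):
            truth_codes = states_by_id[sid].astype(float)
            flip = rng.random(n_sec) < config.rater_error_prob
            alt = np.array(STATES)[rng.integers(0, 3, size=n_sec)]
            codes = np.where(flip, alt, truth_codes).astype(float)
            codes[offscreen[sid]] = np.nan
            behavior.append(BehaviorStream(f"r{r + 1}", sid, codes,
                                           origin=origin))

    surveys = _simulate_surveys(config, timeline, rng_pool["surveys"])

    bundle = SessionBundle(f"session_{config.seed}", [human, canine], timeline,
                           channels, behavior, surveys)
    truth = GroundTruth(
        r_peak_times=r_truth,
        scr_times={"H1": np.asarray(scr_times_rel) + origin},
        state_sequence={"H1": h_states.astype(int), "C1": c_states.astype(int)},
        realized_coupling=res["realized_coupling"],
        bout_schedule={sub_of[sp].id: sched[sp] for sp in ("human", "canine")},
    )
    return bundle, truth


def _absence_spans(timeline: SubsessionTimeline, species: str
                   ) -> list[tuple[float, float]]:
    if species == "human":
        return []
    return [(s.t_start, s.t_end) for s in timeline
            if s.label.startswith("NEU")]


def _simulate_surveys(config: SimConfig, timeline: SubsessionTimeline,
                      rng: np.random.Generator):
    """Interstitial SAM/PANAS after every subsession (none before baseline)
    plus one session-level MDORS total.

    Interaction subsessions shift arousal (lower SAM-A = less calm) and
    positive affect, scaled by the dyadic bonding level; means follow the
    magnitudes a short CAI protocol typically produces.
    """
    import pandas as pd

    bond = 0.5 * (config.coupling_rho + config.copy_prob_kappa)
    rows = []
    for sub in timeline:
        tp = f"post_{sub.label}"
        is_int = sub.is_interaction
        sam_v = int(np.clip(round(rng.normal(2.3 - 0.15 * bond * is_int, 0.6)),
                            1, 5))
        sam_a_mean = 3.8 - (0.6 + 0.4 * bond) * is_int
        sam_a = int(np.clip(round(rng.normal(sam_a_mean, 0.9)), 1, 5))
        pa_mean = 19.6 + (0.8 + 1.2 * bond) * is_int
        pa = int(np.clip(round(rng.normal(pa_mean, 5.0)), 10, 50))
        na = int(np.clip(round(rng.normal(11.2 - 0.4 * bond * is_int, 2.0)),
                         10, 50))
        rows += [("H1", tp, "SAM_V", sam_v), ("H1", tp, "SAM_A", sam_a),
                 ("H1", tp, "PANAS_PA", pa), ("H1", tp, "PANAS_NA", na)]
    mdors = int(np.clip(round(140.0 - 55.0 * bond + rng.normal(0.0, 6.0)),
                        28, 144))
    rows.append(("H1", "session", "MDORS", mdors))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "scale", "value"])
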