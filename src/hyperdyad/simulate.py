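"""Synthetic dyad-cohort generator.

Emulates a competitive button-pressing hyperscanning session: the task
timeline (30 s rest / 20-trial block / 30 s rest / 20-trial block /
30 s rest), trial-level response times whose dyad-mean difference (DRT)
follows a group x block schedule, and two participants' hemodynamic
signals with physiological noise, motion artifacts, and a band-limited
inter-brain coupling component whose amplitude follows a group x block
schedule.

Hemodynamics are built directly as HbO/HbR series (micromolar) and then
forward-projected to dual-wavelength intensity through the same modified
Beer-Lambert relation the preprocessing module inverts, which closes the
generator -> pipeline testing loop.  All randomness flows from an
explicit integer seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import (
    BehavioralTrials,
    DyadSession,
    ParticipantRecording,
    ProbeLayout,
    Segment,
    TaskTimeline,
    Trial,
    ValidationError,
    default_layout,
)

__all__ = [
    "CouplingSpec",
    "NoiseSpec",
    "BehaviorSpec",
    "gen_timeline",
    "gen_behavior",
    "gen_dyad_signals",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# specs

def _default_amplitudes() -> dict:
    # uM amplitude (sd) of the shared band-limited component, per
    # (group, block): couples ramp up across blocks, controls ramp down --
    # the qualitative interaction pattern the analysis is meant to recover.
    return {
        ("couple", 1): 0.025,
        ("couple", 2): 0.045,
        ("control", 1): 0.040,
        ("control", 2): 0.018,
    }


@dataclass
class CouplingSpec:
    """Shared narrow-band oscillation injected into one inter-brain
    channel pair.  ``lag_s`` > 0 means the female member's component
    trails the male member's by that many seconds.  ``lag_s`` may also be
    a per-block mapping ``{block: lag}``."""

    channel_pair: tuple[int, int] = (3, 6)  # (male ch, female ch)
    band_hz: tuple[float, float] = (0.11, 0.14)
    amplitude_by_group_block: dict = field(default_factory=_default_amplitudes)
    lag_s: float | dict = 0.0
    active_during: str = "blocks_only"  # or "all"

    def validate(self, analysis_hz: float) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValidationError(f"coupling band {self.band_hz} invalid")
        if hi >= analysis_hz / 2:
            raise ValidationError(
                f"coupling band {self.band_hz} at/above the analysis Nyquist "
                f"({analysis_hz / 2} Hz)")
        if any(a < 0 or not np.isfinite(a)
               for a in self.amplitude_by_group_block.values()):
            raise ValidationError("coupling amplitudes must be finite and >= 0")

    def lag_for_block(self, block: int) -> float:
        if isinstance(self.lag_s, dict):
            return float(self.lag_s.get(block, 0.0))
        return float(self.lag_s)


@dataclass
class NoiseSpec:
    """Physiological and instrumental noise (uM units on HbO).

    The oscillatory components are stochastic narrow-band processes (not
    pure sinusoids) generated once per participant and mixed into every
    channel with a random gain, so they are spatially global within a
    participant but independent between participants.
    """

    mayer_hz: float = 0.10
    mayer_amp: float = 0.08
    respiration_hz: float = 0.25
    respiration_amp: float = 0.05
    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.04
    drift_amp: float = 0.10          # global very-low-frequency drift
    channel_drift_amp: float = 0.02  # independent per-channel drift
    white_sd: float = 0.03
    artifact_rate_per_min: float = 0.5
    spike_amp: float = 0.5           # 1-sample motion spikes
    step_amp: float = 0.2            # baseline shifts
    hrf_amplitude: float = 0.02      # event-locked double-gamma response

    def validate(self) -> None:
        for name in ("mayer_amp", "respiration_amp", "cardiac_amp", "drift_amp",
                     "channel_drift_amp", "white_sd", "artifact_rate_per_min",
                     "spike_amp", "step_amp", "hrf_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _default_drt_targets() -> dict:
    # block-mean DRT targets (ms) per (group, block): controls' gap widens
    # across blocks while couples hold a roughly constant gap.
    return {
        ("couple", 1): 87.02,
        ("couple", 2): 96.90,
        ("control", 1): 73.21,
        ("control", 2): 103.26,
    }


@dataclass
class BehaviorSpec:
    rt_mean_ms: float = 450.0
    rt_sd_ms: float = 80.0
    drt_target_ms: dict = field(default_factory=_default_drt_targets)
    dyad_target_rel_sd: float = 0.25  # dyad-level multiplicative target jitter
    outlier_rate: float = 0.008       # fraction of RTs pushed beyond 1500 ms

    def validate(self) -> None:
        if self.rt_mean_ms <= 0:
            raise ValidationError("rt_mean_ms must be positive")
        if any(v < 0 for v in self.drt_target_ms.values()):
            raise ValidationError("drt_target_ms values must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValidationError("outlier_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# timeline

def gen_timeline(seed: int = 0, *, trials_per_block: int = 20, n_blocks: int = 2,
                 rest_s: float = 30.0, cue_range_s: tuple[float, float] = (0.6, 1.5),
                 response_window_s: float = 1.5, feedback_s: float = 4.0,
                 blank_s: float = 2.0) -> TaskTimeline:
    """Draw a task timeline: rest / block / rest / ... / rest, with
    per-trial cue durations uniform on ``cue_range_s`` and the fixed
    cue -> go -> response window -> feedback -> blank trial structure."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    segments: list[Segment] = []
    trials: list[Trial] = []
    t = 0.0
    segments.append(Segment("rest", t, rest_s))
    t += rest_s
    for b in range(1, n_blocks + 1):
        block_start = t
        for i in range(1, trials_per_block + 1):
            cue = float(rng.uniform(*cue_range_s))
            go = t + cue
            fb = go + response_window_s
            blank = fb + feedback_s
            trials.append(Trial(b, i, t, go, response_window_s, fb, blank))
            t = blank + blank_s
        segments.append(Segment("block", block_start, t - block_start, b))
        segments.append(Segment("rest", t, rest_s))
        t += rest_s
    timeline = TaskTimeline(tuple(segments), tuple(trials))
    timeline.validate()
    return timeline


# ---------------------------------------------------------------------------
# behavior

def gen_behavior(timeline: TaskTimeline, spec: BehaviorSpec, seed: int, *,
                 group: str = "couple", dyad_id: str = "dyad") -> BehavioralTrials:
    """Per-trial RT pairs whose within-block mean absolute difference is
    centred on the spec's (group, block) DRT target.

    The member difference on each trial is a sign-flipped half-normal
    scaled so its expected magnitude equals the dyad's (jittered) block
    target; with a zero target and zero RT spread both members respond
    identically.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks = sorted({tr.block_index for tr in timeline.trials})
    # dyad-level multiplicative jitter shared across blocks
    jit = max(0.0, 1.0 + rng.normal(0.0, spec.dyad_target_rel_sd))
    target = {b: spec.drt_target_ms.get((group, b), 0.0) * jit for b in blocks}

    n = timeline.n_trials
    block_index = np.array([tr.block_index for tr in timeline.trials])
    trial_index = np.array([tr.trial_index for tr in timeline.trials])
    rt1 = np.maximum(150.0, rng.normal(spec.rt_mean_ms, spec.rt_sd_ms, size=n))
    sigma = np.array([target[b] for b in block_index]) * np.sqrt(np.pi / 2.0)
    diff = rng.choice([-1.0, 1.0], size=n) * np.abs(rng.normal(0.0, 1.0, size=n)) * sigma
    rt2 = np.maximum(150.0, rt1 + diff)
    for rt in (rt1, rt2):
        out = rng.random(n) < spec.outlier_rate
        rt[out] = rng.uniform(1550.0, 2500.0, size=out.sum())
    winner = np.where(rt1 < rt2, 1, np.where(rt2 < rt1, 2, 0))
    points = np.where(winner == 1, 2, np.where(winner == 2, -2, 0))
    beh = BehavioralTrials(dyad_id, block_index, trial_index, rt1, rt2, winner, points)
    beh.validate()
    return beh


# ---------------------------------------------------------------------------
# signals

def _narrowband(rng, n, fs, f0, frac_bw=0.5):
    """Unit-sd stochastic oscillation: white noise band-passed around f0."""
    lo = f0 * (1 - frac_bw / 2)
    hi = min(f0 * (1 + frac_bw / 2), 0.49 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited(rng, n, fs, band):
    """Unit-sd Gaussian process band-limited to ``band`` (Hz)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _drift(rng, n, fs, cutoff_hz=0.01):
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _double_gamma_hrf(fs, duration_s=30.0, peak_s=6.0, under_s=16.0, ratio=6.0):
    t = np.arange(0, duration_s, 1.0 / fs)
    from scipy.stats import gamma as gamma_dist
    h = gamma_dist.pdf(t, peak_s, scale=1.0) - gamma_dist.pdf(t, under_s, scale=1.0) / ratio
    peak = h.max()
    return h / peak if peak > 0 else h


def _fractional_shift(x, shift_samples):
    """Delay ``x`` by a (possibly fractional) number of samples via
    linear interpolation; edges are padded with the end values."""
    n = len(x)
    idx = np.arange(n) - shift_samples
    return np.interp(idx, np.arange(n), x)


def _member_hbo(rng, timeline, layout, fs, noise, n_t, go_onsets):
    """One participant's HbO matrix (n_ch, n_t): global systemic noise with
    per-channel gains, per-channel white noise and drift, an event-locked
    hemodynamic response, and Poisson-timed motion artifacts."""
    n_ch = layout.n_channels
    comps = []
    for f0, amp in ((noise.mayer_hz, noise.mayer_amp),
                    (noise.respiration_hz, noise.respiration_amp),
                    (noise.cardiac_hz, noise.cardiac_amp)):
        if amp > 0 and f0 < 0.49 * fs:  # skip oscillators above Nyquist
            comps.append(amp * _narrowband(rng, n_t, fs, f0))
    if noise.drift_amp > 0:
        comps.append(noise.drift_amp * _drift(rng, n_t, fs))
    systemic = np.sum(comps, axis=0) if comps else np.zeros(n_t)

    gains = rng.uniform(0.6, 1.4, size=n_ch)
    hbo = gains[:, None] * systemic[None, :]
    hbo += noise.white_sd * rng.standard_normal((n_ch, n_t))
    if noise.channel_drift_amp > 0:
        for c in range(n_ch):
            hbo[c] += noise.channel_drift_amp * _drift(rng, n_t, fs)

    if noise.hrf_amplitude > 0 and len(go_onsets):
        stick = np.zeros(n_t)
        idx = np.clip(np.round(np.asarray(go_onsets) * fs).astype(int), 0, n_t - 1)
        stick[idx] = 1.0
        h = _double_gamma_hrf(fs)
        evoked = sps.fftconvolve(stick, h)[:n_t]
        amps = noise.hrf_amplitude * rng.uniform(0.5, 1.5, size=n_ch)
        hbo += amps[:, None] * evoked[None, :]

    # motion artifacts: spikes (single sample) and baseline steps
    rate = noise.artifact_rate_per_min / 60.0  # events per second per channel
    n_events = rng.poisson(rate * n_t / fs, size=n_ch)
    for c in range(n_ch):
        for _ in range(n_events[c]):
            pos = rng.integers(0, n_t)
            if rng.random() < 0.5:
                hbo[c, pos] += rng.choice([-1, 1]) * noise.spike_amp
            else:
                hbo[c, pos:] += rng.normal(0.0, noise.step_amp)
    return hbo


# extinction coefficients (1 / (cm * M)) for (HbO, HbR) at 760 and 830 nm,
# from the standard compiled hemoglobin spectra; DPF applied separately.
EXTINCTION = {
    760.0: (1486.5865, 3843.707),
    830.0: (2321.40, 1791.734),
}


def forward_project(hbo, hbr, wavelengths_nm, distance_cm, dpf, rng=None,
                    base_intensity=1000.0):
    """Project HbO/HbR (uM) to dual-wavelength raw intensity via the
    modified Beer-Lambert relation: OD_l = (e_HbO,l * HbO + e_HbR,l * HbR)
    * 1e-6 * d * DPF_l and I_l = I0 * exp(-OD_l)."""
    n_ch, n_t = hbo.shape
    out = np.empty((n_ch, 2, n_t))
    for w, wl in enumerate(wavelengths_nm):
        e_o, e_r = EXTINCTION[float(wl)]
        od = (e_o * hbo + e_r * hbr) * 1e-6 * distance_cm * dpf[w]
        i0 = base_intensity if rng is None else base_intensity * rng.uniform(0.5, 2.0, size=(n_ch, 1))
        out[:, w, :] = i0 * np.exp(-od)
    return out


def gen_dyad_signals(timeline: TaskTimeline, coupling: CouplingSpec,
                     noise: NoiseSpec, layout: ProbeLayout, fs_hz: float,
                     seed: int, *, group: str = "couple", emit: str = "intensity",
                     analysis_hz: float = 1.0, dpf: tuple[float, float] = (6.0, 6.0),
                     distance_cm: float = 3.0, participant_ids=("m", "f"),
                     return_components: bool = False):
    """Generate the two members' recordings for one dyad.

    A shared band-limited Gaussian process, scaled by the (group, block)
    amplitude schedule and phase-lagged between members by ``lag_s``, is
    injected into the configured channel pair only; everything else is
    independent noise.  ``emit`` selects dual-wavelength ``intensity``
    (the full-chain input) or direct ``hbo`` series (fast path for
    simulation studies at the analysis rate).
    """
    coupling.validate(analysis_hz)
    noise.validate()
    ch_m, ch_f = coupling.channel_pair
    if not (1 <= ch_m <= layout.n_channels and 1 <= ch_f <= layout.n_channels):
        raise ValidationError("coupling channel pair outside the layout")
    ss = np.random.SeedSequence(seed)
    rng_shared, rng_m, rng_f = (np.random.default_rng(s) for s in ss.spawn(3))
    n_t = int(round(timeline.duration_s * fs_hz))
    go_onsets = [tr.go_onset_s for tr in timeline.trials]

    hbo_m = _member_hbo(rng_m, timeline, layout, fs_hz, noise, n_t, go_onsets)
    hbo_f = _member_hbo(rng_f, timeline, layout, fs_hz, noise, n_t, go_onsets)

    # shared coupling component with per-segment amplitude envelope
    z = _bandlimited(rng_shared, n_t, fs_hz, coupling.band_hz)
    env_m = np.zeros(n_t)
    comp_f = np.zeros(n_t)
    blocks = sorted({s.block_index for s in timeline.segments_of("block")})
    block_amps = [coupling.amplitude_by_group_block.get((group, b), 0.0) for b in blocks]
    for b, amp in zip(blocks, block_amps):
        mask = timeline.sample_mask(fs_hz, n_t, "block", b)
        env_m[mask] = amp
        lag = coupling.lag_for_block(b)
        zb = _fractional_shift(z, lag * fs_hz) if lag != 0.0 else z
        comp_f[mask] = amp * zb[mask]
    if coupling.active_during == "all" and block_amps:
        amp = float(np.mean(block_amps))
        mask = timeline.sample_mask(fs_hz, n_t, "rest")
        env_m[mask] = amp
        comp_f[mask] = amp * z[mask]
    comp_m = env_m * z
    hbo_m[ch_m - 1] += comp_m
    hbo_f[ch_f - 1] += comp_f

    hbr_m = -0.33 * hbo_m + 0.01 * rng_m.standard_normal(hbo_m.shape)
    hbr_f = -0.33 * hbo_f + 0.01 * rng_f.standard_normal(hbo_f.shape)

    def _make(pid, sex, hbo, hbr, rng):
        if emit == "hbo":
            return ParticipantRecording(pid, sex, fs_hz, hbo=hbo, hbr=hbr,
                                        source_detector_distance_cm=distance_cm)
        inten = forward_project(hbo, hbr, (760.0, 830.0), distance_cm, dpf, rng)
        return ParticipantRecording(pid, sex, fs_hz, intensity=inten,
                                    source_detector_distance_cm=distance_cm)

    rec_m = _make(participant_ids[0], "M", hbo_m, hbr_m, rng_m)
    rec_f = _make(participant_ids[1], "F", hbo_f, hbr_f, rng_f)
    if return_components:
        return rec_m, rec_f, {"shared": z, "male": comp_m, "female": comp_f}
    return rec_m, rec_f


# ---------------------------------------------------------------------------
# cohort

_AGE = {  # mean, sd, (low, high) truncation, per group
    "couple": (67.44, 5.15, (62.0, 78.0)),
    "control": (65.94, 5.05, (58.0, 80.0)),
}


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def gen_cohort(n_couples: int = 17, n_controls: int = 18, *,
               coupling: CouplingSpec | None = None,
               noise: NoiseSpec | None = None,
               behavior: BehaviorSpec | None = None,
               layout: ProbeLayout | None = None,
               fs_hz: float = 7.81, emit: str = "intensity",
               analysis_hz: float = 1.0, seed: int = 0) -> list[DyadSession]:
    """Generate a full cohort of dyad sessions (default 17 couples and
    18 unacquainted cross-sex control dyads), with ages drawn from the
    group-specific truncated normals and group-specific coupling and
    behavior schedules applied."""
    if n_couples < 0 or n_controls < 0:
        raise ValidationError("cohort sizes must be >= 0")
    coupling = coupling or CouplingSpec()
    noise = noise or NoiseSpec()
    behavior = behavior or BehaviorSpec()
    layout = layout or default_layout()
    ss = np.random.SeedSequence(seed)
    rng_meta = np.random.default_rng(ss.spawn(1)[0])
    sessions: list[DyadSession] = []
    plan = [("couple", i) for i in range(n_couples)] + \
           [("control", i) for i in range(n_controls)]
    child_seeds = ss.spawn(len(plan))
    for (group, i), child in zip(plan, child_seeds):
        dyad_id = f"{group}{i + 1:02d}"
        s_tl, s_beh, s_sig = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3))
        timeline = gen_timeline(s_tl)
        beh = gen_behavior(timeline, behavior, s_beh, group=group, dyad_id=dyad_id)
        rec_m, rec_f = gen_dyad_signals(
            timeline, coupling, noise, layout, fs_hz, s_sig, group=group,
            emit=emit, analysis_hz=analysis_hz,
            participant_ids=(f"{dyad_id}_m", f"{dyad_id}_f"))
        mean, sd, (lo, hi) = _AGE[group]
        covs = {"age_m": round(_truncated_normal(rng_meta, mean, sd, lo, hi), 1),
                "age_f": round(_truncated_normal(rng_meta, mean, sd, lo, hi), 1)}
        session = DyadSession(dyad_id, group, rec_m, rec_f, timeline, beh,
                              layout, covs)
        session.validate()
        sessions.append(session)
    return sessions
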