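"""Synthetic fatiguing-contraction trials with ground-truth labels.

The generator emulates an isometric biceps hold at 40% load: stationary
band-limited sEMG whose median frequency compresses downward and whose
amplitude grows as fatigue develops, and an elbow angle held near 90 degrees
that develops oscillation at the transition to fatigue and then drops below
86.5 degrees at fatigue onset.

Construction, per channel: Gaussian noise shaped second-by-second by a
4th-order Butterworth band-pass of fixed width re-centred on the target
median frequency (piecewise-stationary), scaled by a linear amplitude ramp.
During the transition phase a slow multiplicative burst process modulates
the amplitude: the kinematic instability of a struggling muscle couples into
the sEMG envelope, which is what makes the variability-based features spike
at the transition and settle again once fatigue is established.

All randomness derives from one integer seed via counter-based
``SeedSequence`` keys (subject, trial, stream), so cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .core import FatigueClass, LabelSeries, Trial, ValidationError

__all__ = ["SyntheticConfig", "generate_trial", "generate_cohort"]

# stream indices for counter-based seed derivation
_STREAM_EMG1, _STREAM_EMG2, _STREAM_BURST, _STREAM_OSC, _STREAM_SENSOR = range(5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic trial. Durations are whole seconds."""

    duration_s: int = 180
    t_tf: int = 100          # transition-to-fatigue onset, s
    t_f: int = 150           # fatigue onset, s
    mdf_start: float = 95.0  # initial median frequency, Hz
    mdf_end: float = 55.0    # final median frequency, Hz
    amp_gain: float = 1.6    # relative amplitude growth at end of trial
    angle_hold: float = 90.0
    angle_end: float = 84.0
    osc_sd_nf: float = 0.2   # angular oscillation SD before t_tf, deg
    osc_sd_tf: float = 1.0   # angular oscillation SD from t_tf on, deg
    noise_sd: float = 0.05   # additive goniometer sensor noise, deg
    seed: int = 0
    # generator details (not part of the phase phenomenology itself)
    fs: float = 2000.0
    base_amp_mv: float = 0.5
    band_width_hz: float = 60.0
    decline_s: float = 2.0       # seconds the angle takes to fall to angle_end
    burst_sd_nf: float = 0.0     # relative sEMG envelope burst SD per phase
    burst_sd_tf: float = 0.6
    burst_sd_f: float = 0.05

    def validate(self) -> None:
        problems = []
        for name in ("duration_s", "t_tf", "t_f"):
            if not float(getattr(self, name)).is_integer():
                problems.append(f"{name} must be a whole number of seconds")
        if not 0 < self.t_tf < self.t_f < self.duration_s:
            problems.append("need 0 < t_tf < t_f < duration_s")
        if not self.mdf_end < self.mdf_start:
            problems.append("need mdf_end < mdf_start")
        if not self.angle_end < 86.5 < self.angle_hold:
            problems.append("need angle_end < 86.5 < angle_hold")
        if not self.osc_sd_nf < 0.6 < self.osc_sd_tf:
            problems.append("need osc_sd_nf < 0.6 < osc_sd_tf")
        if self.fs <= 0 or self.base_amp_mv <= 0 or self.band_width_hz <= 0:
            problems.append("fs, base_amp_mv and band_width_hz must be positive")
        if self.mdf_end - self.band_width_hz / 2 <= 0:
            problems.append("mdf_end must exceed half the shaping bandwidth")
        if self.mdf_start + self.band_width_hz / 2 >= self.fs / 2:
            problems.append("mdf_start band edge must stay below Nyquist")
        if self.noise_sd < 0 or self.decline_s <= 0:
            problems.append("noise_sd must be >= 0 and decline_s > 0")
        if min(self.burst_sd_nf, self.burst_sd_tf, self.burst_sd_f) < 0:
            problems.append("burst SDs must be non-negative")
        if problems:
            raise ValidationError("; ".join(problems))


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0xFFFFFFFF, stream]))


def _mdf_schedule(config: SyntheticConfig, t: float) -> float:
    """Target median frequency at time t: flat, linear decline, flat."""
    if t <= config.t_tf:
        return config.mdf_start
    if t >= config.t_f:
        return config.mdf_end
    frac = (t - config.t_tf) / (config.t_f - config.t_tf)
    return config.mdf_start + frac * (config.mdf_end - config.mdf_start)


def _slow_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    """Low-pass-filtered unit-SD Gaussian noise (zero mean over the trace)."""
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    sd = x.std(ddof=1)
    return x / sd if sd > 0 else x


def _phase_of_samples(config: SyntheticConfig, n: int) -> np.ndarray:
    """0 = NF, 1 = TF, 2 = F for each sample index."""
    t = np.arange(n) / config.fs
    return np.select([t < config.t_tf, t < config.t_f], [0, 1], default=2)


def _emg_channel(config: SyntheticConfig, rng: np.random.Generator,
                 burst_mult: np.ndarray) -> np.ndarray:
    spp = int(round(config.fs))  # samples per 1-s chunk
    n_sec = int(config.duration_s)
    half = config.band_width_hz / 2.0
    chunks = []
    for s in range(n_sec):
        m = _mdf_schedule(config, s + 0.5)
        sos = sps.butter(4, [m - half, m + half], btype="bandpass",
                         fs=config.fs, output="sos")
        chunk = sps.sosfiltfilt(sos, rng.standard_normal(spp))
        chunk /= chunk.std(ddof=1)
        amp = 1.0 + (config.amp_gain - 1.0) * (s + 0.5) / config.duration_s
        chunks.append(config.base_amp_mv * amp * chunk)
    x = np.concatenate(chunks)
    return x * burst_mult


def generate_trial(config: SyntheticConfig) -> tuple[Trial, LabelSeries]:
    """Generate one trial and its ground-truth per-second labels.

    Deterministic given ``config.seed``.  Ground truth: NF on ``[0, t_tf)``,
    TF on ``[t_tf, t_f)``, F on ``[t_f, duration_s)``.
    """
    config.validate()
    fs = config.fs
    n = int(round(config.duration_s * fs))
    phase = _phase_of_samples(config, n)

    # sEMG: shared slow burst envelope (phase-scaled), two independent channels
    burst_sd = np.array([config.burst_sd_nf, config.burst_sd_tf, config.burst_sd_f])
    burst = _slow_noise(_rng(config, _STREAM_BURST), n, fs, cutoff_hz=1.5)
    burst_mult = np.clip(1.0 + burst_sd[phase] * burst, 0.05, None)
    # normalize to unit mean square within each phase so expected window power
    # follows the linear amplitude ramp; bursts redistribute power in time
    # without shifting the phase's mean power
    for k in range(3):
        sel = phase == k
        if np.any(sel):
            burst_mult[sel] /= np.sqrt(np.mean(burst_mult[sel] ** 2))
    emg = np.vstack([
        _emg_channel(config, _rng(config, _STREAM_EMG1), burst_mult),
        _emg_channel(config, _rng(config, _STREAM_EMG2), burst_mult),
    ])

    # goniometer: hold + per-phase oscillation + fatigue decline + sensor noise
    osc = _slow_noise(_rng(config, _STREAM_OSC), n, fs, cutoff_hz=5.0)
    n_nf = int(round(config.t_tf * fs))
    osc_scaled = np.empty(n)
    for sl, sd in ((slice(0, n_nf), config.osc_sd_nf),
                   (slice(n_nf, n), config.osc_sd_tf)):
        seg = osc[sl] - osc[sl].mean()
        seg_sd = seg.std(ddof=1)
        osc_scaled[sl] = sd * (seg / seg_sd if seg_sd > 0 else seg)
    t = np.arange(n) / fs
    base = np.interp(t, [config.t_f, config.t_f + config.decline_s],
                     [config.angle_hold, config.angle_end])
    angle = base + osc_scaled
    if config.noise_sd > 0:
        angle = angle + config.noise_sd * _rng(config, _STREAM_SENSOR).standard_normal(n)
    angle = np.clip(angle, 0.0, 180.0)

    labels = (
        [FatigueClass.NON_FATIGUE] * config.t_tf
        + [FatigueClass.TRANSITION_TO_FATIGUE] * (config.t_f - config.t_tf)
        + [FatigueClass.FATIGUE] * (config.duration_s - config.t_f)
    )
    trial = Trial(emg=emg, gonio_angle=angle, fs_emg=fs, fs_gonio=fs)
    return trial, LabelSeries(labels=labels)


def _jittered(base: SyntheticConfig, rng: np.random.Generator,
              jitter: float, seed: int) -> SyntheticConfig:
    """Perturb the phase/shape parameters within +-jitter relative, then clip
    back into the config's validity region."""
    def u() -> float:
        return 1.0 + rng.uniform(-jitter, jitter)

    # floors keep every phase >= 4 s without altering an already-valid base
    t_tf = max(4, int(round(base.t_tf * u())))
    t_f = max(t_tf + 4, int(round(base.t_f * u())))
    duration = max(t_f + 4, int(round(base.duration_s * u())))
    mdf_end = min(base.mdf_end * u(), base.mdf_start - 10.0)
    cfg = replace(
        base,
        duration_s=duration,
        t_tf=t_tf,
        t_f=t_f,
        mdf_start=base.mdf_start * u(),
        mdf_end=mdf_end,
        amp_gain=max(1.05, base.amp_gain * u()),
        angle_end=min(base.angle_end * u(), 86.0),
        osc_sd_nf=min(base.osc_sd_nf * u(), 0.55),
        osc_sd_tf=max(base.osc_sd_tf * u(), 0.65),
        burst_sd_tf=base.burst_sd_tf * u(),
        seed=seed,
    )
    cfg.validate()
    return cfg


def generate_cohort(
    n_subjects: int,
    trials_per_subject: int,
    base: SyntheticConfig | None = None,
    jitter: float = 0.1,
    seed: int = 0,
) -> list[tuple[Trial, LabelSeries]]:
    """Generate a cohort of labeled trials.

    Subject parameters are drawn once per subject by perturbing ``base``
    within +-jitter relative; per-trial seeds are derived deterministically
    from ``seed``.  Subject/trial ids are assigned as S01..Snn / T1..Tm.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValidationError("counts must be >= 1")
    if not 0 <= jitter < 0.5:
        raise ValidationError("jitter must lie in [0, 0.5)")
    base = base or SyntheticConfig()
    out: list[tuple[Trial, LabelSeries]] = []
    for i in range(n_subjects):
        subj_rng = np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, 1000 + i]))
        subj_cfg = _jittered(base, subj_rng, jitter, seed=0)
        for j in range(trials_per_subject):
            trial_seed = int(
                np.random.SeedSequence([seed & 0xFFFFFFFF, i, j]).generate_state(1)[0]
            )
            trial, labels = generate_trial(replace(subj_cfg, seed=trial_seed))
            trial.subject_id = f"S{i + 1:02d}"
            trial.trial_id = f"T{j + 1}"
            out.append((trial, labels))
    return out
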