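"""Synthetic multi-channel surface-EMG generator.

Emulates the study conditions of a lower-limb walking protocol: four muscle
channels sampled at 1000 Hz, burst-modulated band-limited activity in the
20-460 Hz hardware band, and the three canonical contaminants (additive
white Gaussian sensor noise, 50 Hz power-line interference, <5 Hz baseline
wander).  Class imbalance arises from recording *duration*: knee-abnormal
subjects take longer to complete walking tasks, so their recordings -- and
hence their window counts -- are longer by a configurable ratio (default
4.48:1, which reproduces the ~4.5:1 window imbalance of the study data).

The clean activity model is Gaussian white noise band-passed to the
configured band by a zero-phase filter, then amplitude-modulated by a
raised-cosine burst envelope (one burst per gait cycle) riding on a small
tonic floor.  Gait is non-stationary the way real walking is: each
recording starts at a random cycle phase and successive cycle durations
jitter (stride-time variability), and the mains phase wanders slowly.
Contaminant amplitudes are tied to the *process* scale of the clean signal
(filter noise gain x analytic envelope RMS), not to each recording's
realized RMS, so no recording carries an amplitude fingerprint beyond its
class.  The abnormal class differs by per-channel amplitude scaling and a
lengthened burst duty (prolonged muscle activation), both proportional to
``class_effect``; with ``class_effect = 0`` the two classes are
distributionally identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_io import DEFAULT_CHANNELS, Recording

#: Relative per-channel activation change applied to the abnormal class
#: (scaled by ``class_effect``): quadriceps/hamstring imbalance pattern.
ABNORMAL_CHANNEL_WEIGHTS = np.array([0.8, -0.4, 0.5, -0.6])


@dataclass
class NoiseConfig:
    """Contaminant mix, each scaled relative to the clean-signal RMS.

    ``wgn_snr_db=None`` (or ``inf``) disables sensor noise; amplitudes of 0
    disable the other contaminants.
    """

    wgn_snr_db: float | None = 15.0
    pli_amplitude: float = 0.2      # RMS of the 50 Hz tone, x clean RMS
    baseline_amplitude: float = 0.3  # RMS of the <5 Hz wander, x clean RMS
    pli_freq: float = 50.0
    pli_phase_wander: float = 0.05  # mains phase drift, cycles/sqrt(s)
    baseline_cutoff: float = 4.0


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic dataset."""

    sampling_rate: float = 1000.0
    healthy_duration_s: float = 6.1
    duration_ratio: float = 4.48     # abnormal : healthy recording length
    n_subjects: int = 11             # per class
    burst_rate: float = 1.1          # gait cycles per second
    burst_duty: float = 0.4          # active fraction of each cycle
    tonic_floor: float = 0.1         # baseline muscle tone in the envelope
    cadence_jitter: float = 0.05     # stride-time variability (CV of cycle length)
    band: tuple[float, float] = (20.0, 460.0)
    class_effect: float = 0.4
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def validate(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError(f"invalid band {self.band} for fs={self.sampling_rate}")
        if not (0 < self.burst_duty < 1):
            raise ValueError("burst_duty must lie in (0, 1)")
        if self.healthy_duration_s * 1000.0 <= 256.0:
            raise ValueError("durations must exceed the 256 ms analysis window")
        if self.duration_ratio <= 0 or self.n_subjects < 1:
            raise ValueError("duration_ratio must be > 0 and n_subjects >= 1")
        if not (0 <= self.tonic_floor < 1):
            raise ValueError("tonic_floor must lie in [0, 1)")

    def duration_s(self, label: str) -> float:
        return self.healthy_duration_s * (
            self.duration_ratio if label == "abnormal" else 1.0
        )


def _burst_envelope(
    n: int,
    fs: float,
    rate: float,
    duty: float,
    floor: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raised-cosine burst train on a tonic floor, in [floor, 1].

    Starts at a random cycle phase; successive cycle durations carry
    stride-time variability (coefficient of variation ``jitter``)."""
    mean_cycle = 1.0 / rate
    t_end = n / fs
    starts = [-rng.uniform(0.0, mean_cycle)]  # random initial gait phase
    durations = []
    while starts[-1] < t_end:
        d = mean_cycle * max(0.5, 1.0 + jitter * rng.standard_normal())
        durations.append(d)
        starts.append(starts[-1] + d)
    starts_arr = np.array(starts)
    dur_arr = np.array(durations)
    t = np.arange(n) / fs
    ci = np.searchsorted(starts_arr, t, side="right") - 1
    cycle_pos = (t - starts_arr[ci]) / dur_arr[ci]
    bump = np.where(
        cycle_pos < duty, 0.5 * (1.0 - np.cos(2.0 * np.pi * cycle_pos / duty)), 0.0
    )
    return floor + (1.0 - floor) * bump


def _envelope_rms(duty: float, floor: float) -> float:
    """Analytic RMS of the burst envelope over one cycle:
    E[env^2] = F^2 + F(1-F)d + (3/8)(1-F)^2 d  for a Hann bump of duty d
    on floor F."""
    f = floor
    e2 = f * f + f * (1 - f) * duty + 0.375 * (1 - f) ** 2 * duty
    return float(np.sqrt(e2))


def _filter_noise_gain(sos, n_ref: int) -> float:
    """Std of unit white noise after zero-phase filtering: the energy of
    the combined forward-backward impulse response."""
    impulse = np.zeros(n_ref)
    impulse[n_ref // 2] = 1.0
    h = sosfiltfilt(sos, impulse)
    return float(np.sqrt(np.sum(h**2)))


def gen_components(cfg: SynthConfig, label: str, seed) -> dict[str, np.ndarray]:
    """Generate the additive parts of one recording separately.

    Returns a dict with keys ``clean``, ``wgn``, ``pli``, ``baseline``,
    each of shape ``(n_samples, n_channels)``.  Summing them gives the
    recording samples.  Exposed so tests can check spectral and energy
    properties of each part in isolation.
    """
    cfg.validate()
    if label not in ("healthy", "abnormal"):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.duration_s(label) * fs))
    n_ch = len(cfg.channel_names)
    t = np.arange(n) / fs

    # band-limited innovation process, zero-phase filtered (no group delay)
    sos = butter(4, cfg.band, btype="bandpass", fs=fs, output="sos")
    activity = sosfiltfilt(sos, rng.standard_normal((n, n_ch)), axis=0)

    duty = cfg.burst_duty
    amp = np.ones(n_ch)
    if label == "abnormal" and cfg.class_effect != 0.0:
        # prolonged activation and redistributed muscle amplitudes
        duty = min(0.95, duty * (1.0 + 0.2 * cfg.class_effect))
        w = ABNORMAL_CHANNEL_WEIGHTS[:n_ch]
        amp = np.clip(1.0 + cfg.class_effect * w, 0.1, None)
    env = _burst_envelope(
        n, fs, cfg.burst_rate, duty, cfg.tonic_floor, cfg.cadence_jitter, rng
    )
    clean = activity * env[:, None] * amp[None, :]

    # process-scale reference RMS per channel (analytic, not realized, so
    # contaminant levels carry no per-recording fingerprint)
    n_ref = max(n, int(8 * fs))
    bp_gain = _filter_noise_gain(sos, n_ref)
    ref_rms = bp_gain * _envelope_rms(duty, cfg.tonic_floor) * amp

    nz = cfg.noise
    wgn = np.zeros_like(clean)
    if nz.wgn_snr_db is not None and np.isfinite(nz.wgn_snr_db):
        noise_std = ref_rms * 10.0 ** (-nz.wgn_snr_db / 20.0)
        wgn = rng.standard_normal((n, n_ch)) * noise_std[None, :]

    pli = np.zeros_like(clean)
    if nz.pli_amplitude > 0:
        phase0 = rng.uniform(0, 2 * np.pi, n_ch)
        # slow mains phase wander (Wiener process) on top of the carrier
        wander = np.cumsum(
            rng.standard_normal((n, n_ch))
            * (2 * np.pi * nz.pli_phase_wander / np.sqrt(fs)),
            axis=0,
        )
        # sinusoid of RMS = pli_amplitude * ref RMS  =>  peak = sqrt(2) * RMS
        peak = np.sqrt(2.0) * nz.pli_amplitude * ref_rms
        pli = peak[None, :] * np.sin(
            2 * np.pi * nz.pli_freq * t[:, None] + phase0[None, :] + wander
        )

    baseline = np.zeros_like(clean)
    if nz.baseline_amplitude > 0:
        sos_lp = butter(4, nz.baseline_cutoff, btype="lowpass", fs=fs, output="sos")
        drift = sosfiltfilt(sos_lp, rng.standard_normal((n, n_ch)), axis=0)
        # scaled by the filter's noise gain, not the realisation's RMS:
        # per-recording energy normalisation would imprint the recording
        # length on window-level statistics (short recordings get squeezed
        # harder), which must not distinguish the classes under a null effect
        lp_gain = _filter_noise_gain(sos_lp, n_ref)
        baseline = drift * (nz.baseline_amplitude * ref_rms / lp_gain)[None, :]

    return {"clean": clean, "wgn": wgn, "pli": pli, "baseline": baseline}


def gen_recording(
    cfg: SynthConfig, label: str, seed, subject_id: str | None = None
) -> Recording:
    """Generate one labelled recording; fully reproducible from ``seed``."""
    parts = gen_components(cfg, label, seed)
    samples = parts["clean"] + parts["wgn"] + parts["pli"] + parts["baseline"]
    return Recording(
        samples=samples,
        sampling_rate=cfg.sampling_rate,
        channel_names=cfg.channel_names,
        label=label,
        subject_id=subject_id or f"{label}_{seed}",
    )


def gen_dataset(cfg: SynthConfig) -> list[Recording]:
    """Generate ``n_subjects`` recordings per class with unique subject ids.

    Abnormal recordings are longer by ``cfg.duration_ratio``, so downstream
    windowing produces a duration-driven class imbalance (the default
    configuration yields an abnormal:healthy window ratio of ~4.5:1).
    """
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_subjects)
    recs = []
    k = 0
    for label in ("healthy", "abnormal"):
        for i in range(cfg.n_subjects):
            recs.append(
                gen_recording(
                    cfg, label, int(seeds[k]), subject_id=f"{label}_{i + 1:02d}"
                )
            )
            k += 1
    return recs


def null_config(cfg: SynthConfig | None = None) -> SynthConfig:
    """A copy of ``cfg`` with zero class effect (distributionally identical
    classes) -- the null-separability condition used in sanity checks."""
    return replace(cfg or SynthConfig(), class_effect=0.0)
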