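"""Seeded synthetic auscultation audio and synthetic patient cohorts.

No swallowing-sound recordings or patient-level data are distributed with
the method, so every test runs on synthetic material produced here:

* **Crackle bursts** — exponentially damped sinusoids
  ``a * exp(-t/tau) * sin(2 pi f t)``, the standard parsimonious
  fine-crackle surrogate (default 650 Hz centre, 4 ms damping, 10 ms
  duration), standing in for the transient sound of water entering the
  oesophagus.
* **Recordings** — white Gaussian background noise with bursts placed by a
  homogeneous Poisson process inside a swallow window, scaled to a target
  SNR; ground-truth frame labels mark every frame overlapping a burst.
* **Teacher sets** — labelled clips (bursts-in-noise positives, noise-only
  negatives) emulating the 50-clip curated training collections used for
  crackle discriminators.
* **Cohorts** — patient tables whose swallowing sound index depends
  linearly on clinical covariates plus Gaussian noise, with covariate
  distributions shaped like an ALS clinic population (ALSFRS-R totals and
  bulbar sub-scores, %VC, tongue pressure, MASA scores).

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import DEFAULT_EDGE_S, AudioRecording, CANONICAL_RATE, section_of, trim_auscultation
from .classifier import TeacherClip, TeacherSet
from .features import FeatureExtractor, make_grid


class SynthesisError(ValueError):
    """Raised for infeasible synthesis specifications."""


# ---------------------------------------------------------------------------
# crackle bursts


@dataclass(frozen=True)
class CrackleSpec:
    """Damped-sinusoid burst parameters."""

    center_freq: float = 650.0  # Hz
    damping_tau: float = 0.004  # s
    burst_dur: float = 0.010  # s
    amplitude: float = 0.5  # relative, (0, 1]

    def __post_init__(self) -> None:
        if min(self.center_freq, self.damping_tau, self.burst_dur) <= 0:
            raise SynthesisError("all burst parameters must be positive")
        if self.burst_dur < self.damping_tau:
            raise SynthesisError("burst_dur must be >= damping_tau")
        if not (0 <= self.amplitude <= 1):
            raise SynthesisError("amplitude must be in [0, 1]")


def synth_crackle(spec: CrackleSpec, rate: int = CANONICAL_RATE) -> np.ndarray:
    """One burst waveform, length ``round(burst_dur * rate)`` samples."""
    if rate <= 2 * spec.center_freq:
        raise SynthesisError(
            f"rate {rate} Hz too low for a {spec.center_freq} Hz burst (aliasing)"
        )
    n = int(round(spec.burst_dur * rate))
    t = np.arange(n) / rate
    return spec.amplitude * np.exp(-t / spec.damping_tau) * np.sin(
        2 * np.pi * spec.center_freq * t
    )


def _pink(white: np.ndarray, target_rms: float) -> np.ndarray:
    """Shape white noise to a 1/f amplitude spectrum at the given RMS."""
    from scipy.fft import irfft as _irfft, rfft as _rfft

    spec = _rfft(white)
    scale = np.ones(spec.shape[0])
    scale[1:] = 1.0 / np.sqrt(np.arange(1, spec.shape[0]))
    out = _irfft(spec * scale, n=white.shape[0])
    return out * (target_rms / max(np.sqrt(np.mean(out ** 2)), 1e-12))


# ---------------------------------------------------------------------------
# recordings


@dataclass(frozen=True)
class SwallowScenario:
    """One simulated water-swallow trial.

    The swallow window must sit inside the trimmed region
    ``[edge, duration - edge]`` so the bursts survive edge exclusion.
    ``burst_rate`` is the Poisson rate of crackle bursts per second within
    the window; ``snr_db`` is the target ratio of burst power (over the
    burst support) to background-noise power.
    """

    duration_s: float = 5.0
    burst_rate: float = 8.0  # bursts / s during the swallow
    swallow_window: tuple[float, float] = (1.0, 4.0)
    noise_rms: float = 0.02
    snr_db: float = 10.0
    noise_color: str = "white"  # "white" or "pink" (1/f) background
    seed: int = 0
    edge_s: float = DEFAULT_EDGE_S

    def __post_init__(self) -> None:
        if self.noise_color not in ("white", "pink"):
            raise SynthesisError(f"unknown noise color {self.noise_color!r}")
        lo, hi = self.swallow_window
        if not (self.edge_s <= lo < hi <= self.duration_s - self.edge_s):
            raise SynthesisError(
                f"swallow window {self.swallow_window} must lie within "
                f"[{self.edge_s}, {self.duration_s - self.edge_s}]"
            )
        if self.burst_rate < 0 or self.noise_rms < 0:
            raise SynthesisError("burst_rate and noise_rms must be non-negative")
        if self.noise_rms == 0 and self.burst_rate > 0:
            raise SynthesisError("target SNR undefined with zero noise")


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated trial with its ground truth.

    ``signal`` and ``noise`` are the separately-kept components
    (``recording.samples = signal + noise``) so the realised SNR can be
    recomputed; ``burst_intervals`` are (start_s, end_s) pairs.
    """

    recording: AudioRecording
    signal: np.ndarray
    noise: np.ndarray
    burst_intervals: tuple[tuple[float, float], ...]

    def frame_labels(self, extractor: FeatureExtractor | None = None,
                     edge_s: float = DEFAULT_EDGE_S) -> np.ndarray:
        """Per-frame ground truth on the trimmed section's grid.

        A frame is positive iff its sample interval overlaps any burst.
        """
        extractor = extractor or FeatureExtractor()
        section = (trim_auscultation(self.recording, edge_s) if edge_s > 0
                   else section_of(self.recording))
        grid = make_grid(section, extractor.hop_s, extractor.window_s)
        starts = section.start_s + grid.frame_start_times()
        ends = starts + grid.window_samples / grid.rate
        labels = np.zeros(grid.n_frames, dtype=np.int8)
        for b0, b1 in self.burst_intervals:
            labels |= ((starts < b1) & (ends > b0)).astype(np.int8)
        return labels

    def realized_snr_db(self) -> float:
        active = self.signal != 0
        if not active.any():
            return -np.inf
        p_sig = float(np.mean(self.signal[active] ** 2))
        p_noise = float(np.mean(self.noise ** 2))
        return 10.0 * np.log10(p_sig / p_noise)


def synth_recording(
    scenario: SwallowScenario,
    spec: CrackleSpec = CrackleSpec(),
    rate: int = CANONICAL_RATE,
) -> SyntheticRecording:
    """Generate one trial: noise + Poisson-timed bursts at the target SNR.

    Burst count ~ Poisson(rate x window length); burst starts are uniform
    in the window, clipped so no burst crosses the window end.  The summed
    burst component is rescaled so its power over the burst support sits
    ``snr_db`` above the noise power.  Same seed, same output, bitwise.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_s * rate))
    if scenario.noise_rms > 0:
        noise = rng.normal(0.0, scenario.noise_rms, size=n)
        if scenario.noise_color == "pink":
            noise = _pink(noise, scenario.noise_rms)
    else:
        noise = np.zeros(n)

    lo, hi = scenario.swallow_window
    burst_len = int(round(spec.burst_dur * rate))
    signal = np.zeros(n)
    intervals: list[tuple[float, float]] = []
    n_bursts = rng.poisson(scenario.burst_rate * (hi - lo))
    starts_s = np.sort(rng.uniform(lo, hi - spec.burst_dur, size=n_bursts))
    burst = synth_crackle(spec, rate)
    for s in starts_s:
        i0 = int(round(s * rate))
        signal[i0 : i0 + burst_len] += burst
        intervals.append((i0 / rate, (i0 + burst_len) / rate))

    active = signal != 0
    if active.any() and scenario.noise_rms > 0:
        p_sig = np.mean(signal[active] ** 2)
        target = scenario.noise_rms ** 2 * 10.0 ** (scenario.snr_db / 10.0)
        signal *= np.sqrt(target / p_sig)

    samples = np.clip(signal + noise, -1.0, 1.0)
    return SyntheticRecording(
        recording=AudioRecording(samples=samples, rate=rate),
        signal=signal,
        noise=noise,
        burst_intervals=tuple(intervals),
    )


# ---------------------------------------------------------------------------
# teacher sets


def synth_teacher_set(
    n_clips: int = 50,
    pos_fraction: float = 0.5,
    spec: CrackleSpec = CrackleSpec(),
    seed: int = 0,
    clip_dur_s: float = 1.0,
    snr_db: float = 10.0,
    noise_rms: float = 0.02,
    bursts_per_clip: tuple[int, int] = (2, 5),
    rate: int = CANONICAL_RATE,
    extractor: FeatureExtractor | None = None,
) -> TeacherSet:
    """Labelled clips: bursts-in-noise positives, noise-only negatives.

    Clip frame labels are exact by construction (computed from the burst
    intervals on the clip's own grid, no edge trimming — curated clips are
    taken whole).  ``pos_fraction`` strictly between 0 and 1 so both
    classes are present.
    """
    if n_clips < 2:
        raise SynthesisError("need at least 2 clips")
    if not (0.0 < pos_fraction < 1.0):
        raise SynthesisError("pos_fraction must be strictly between 0 and 1")
    extractor = extractor or FeatureExtractor()
    n_pos = int(round(n_clips * pos_fraction))
    n_pos = min(max(n_pos, 1), n_clips - 1)
    rng = np.random.default_rng(seed)
    burst = synth_crackle(spec, rate)
    burst_len = burst.shape[0]
    n_samp = int(round(clip_dur_s * rate))

    clips: list[TeacherClip] = []
    for i in range(n_clips):
        positive = i < n_pos
        noise = rng.normal(0.0, noise_rms, size=n_samp)
        signal = np.zeros(n_samp)
        intervals: list[tuple[float, float]] = []
        if positive:
            k = rng.integers(bursts_per_clip[0], bursts_per_clip[1] + 1)
            starts = rng.uniform(0.0, clip_dur_s - spec.burst_dur, size=k)
            for s in starts:
                i0 = int(round(s * rate))
                signal[i0 : i0 + burst_len] += burst
                intervals.append((i0 / rate, (i0 + burst_len) / rate))
            p_sig = np.mean(signal[signal != 0] ** 2)
            signal *= np.sqrt(noise_rms ** 2 * 10.0 ** (snr_db / 10.0) / p_sig)
        rec = AudioRecording(samples=np.clip(signal + noise, -1, 1), rate=rate)
        grid = make_grid(section_of(rec), extractor.hop_s, extractor.window_s)
        starts_t = grid.frame_start_times()
        ends_t = starts_t + grid.window_samples / rate
        labels = np.zeros(grid.n_frames, dtype=np.int8)
        for b0, b1 in intervals:
            labels |= ((starts_t < b1) & (ends_t > b0)).astype(np.int8)
        clips.append(TeacherClip(recording=rec, labels=labels,
                                 clip_id=f"{'pos' if positive else 'neg'}_{i:03d}"))
    return TeacherSet(clips=tuple(clips), extractor=extractor)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated-normal covariate: mean, sd, and the admissible range."""

    mean: float
    sd: float
    lo: float
    hi: float
    integer: bool = False

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        v = rng.normal(self.mean, self.sd, size=n)
        v = np.clip(v, self.lo, self.hi)
        return np.round(v) if self.integer else v


def _default_covariates() -> dict[str, CovariateSpec]:
    # Shaped like an ALS clinic cohort: ALSFRS-R total 0-48 (observed 18-47),
    # bulbar sub-score 0-12 (observed 4-12), %VC ~80 +/- 20, tongue pressure
    # ~28 +/- 16 kPa, MASA total <= 200, MASA pharyngeal-phase items <= 70.
    return {
        "age": CovariateSpec(64.0, 11.8, 30.0, 90.0),
        "bmi": CovariateSpec(21.9, 3.3, 14.0, 35.0),
        "duration_months": CovariateSpec(25.0, 22.0, 4.0, 114.0),
        "alsfrs_r_total": CovariateSpec(39.0, 7.0, 18.0, 47.0, integer=True),
        "alsfrs_r_bulbar": CovariateSpec(10.5, 2.2, 4.0, 12.0, integer=True),
        "albumin": CovariateSpec(4.1, 0.4, 2.5, 5.5),
        "pct_vc": CovariateSpec(80.5, 20.4, 20.0, 130.0),
        "tongue_pressure": CovariateSpec(27.6, 16.2, 1.0, 80.0),
        "masa_total": CovariateSpec(190.0, 12.0, 151.0, 200.0, integer=True),
        "masa_pharyngeal": CovariateSpec(67.0, 3.5, 57.0, 70.0, integer=True),
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort generator: index = beta0 + sum_j beta_j * covariate_j + eps.

    Defaults plant a 0.006 index-unit effect per ALSFRS-R point (the
    magnitude reported for that factor in clinical use of the index) with
    residual sd equal to the 0.06 used in the method's power analysis; the
    intercept puts the mean index near the reported patient mean of ~0.21.
    Generated indices are clipped to [0, 1].
    """

    n_patients: int = 24
    betas: dict = field(default_factory=lambda: {"alsfrs_r_total": 0.006})
    intercept: float = -0.025
    sigma: float = 0.06
    covariates: dict = field(default_factory=_default_covariates)
    female_fraction: float = 0.542
    bulbar_onset_fraction: float = 0.208
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise SynthesisError("need at least 3 patients")
        for name in self.betas:
            if name not in self.covariates and name not in ("sex", "onset_type"):
                raise SynthesisError(f"beta refers to unknown covariate {name!r}")
        for name, cov in self.covariates.items():
            if cov.sd <= 0 or cov.hi <= cov.lo:
                raise SynthesisError(f"degenerate distribution for covariate {name!r}")


def synth_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, dict]:
    """One patient table plus the true generating parameters.

    Returns ``(cohort, truth)`` where ``truth`` holds the planted betas,
    intercept and sigma for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    data: dict[str, np.ndarray] = {"id": np.array([f"P{i:04d}" for i in range(n)])}
    for name, cov in spec.covariates.items():
        data[name] = cov.sample(rng, n)
    data["sex"] = np.where(rng.random(n) < spec.female_fraction, "F", "M")
    data["onset_type"] = np.where(rng.random(n) < spec.bulbar_onset_fraction, "bulbar", "limb")

    index = np.full(n, spec.intercept, dtype=np.float64)
    for name, beta in spec.betas.items():
        if name == "sex":
            index += beta * (data["sex"] == "F").astype(float)
        elif name == "onset_type":
            index += beta * (data["onset_type"] == "bulbar").astype(float)
        else:
            index += beta * data[name]
    index += rng.normal(0.0, spec.sigma, size=n)
    data["index"] = np.clip(index, 0.0, 1.0)

    truth = {"betas": dict(spec.betas), "intercept": spec.intercept, "sigma": spec.sigma}
    return pd.DataFrame(data), truth
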