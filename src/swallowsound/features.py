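"""Frame grid and the 148-dimension per-frame acoustic feature vector.

The discriminator operates on short-time frames placed every 12 ms over
the trimmed auscultation section.  Each frame yields a fixed vector of
148 features covering the techniques the method relies on — band-wise
frequency content, local variance of band envelopes, cepstrum analysis
with low-time liftering — plus a set of classical spectral-shape
descriptors.  The layout is:

==============================  =====  =========================================
group                           count  description
==============================  =====  =========================================
``mel``                            40  log energies of a 40-band mel filter bank
                                       spanning 50 Hz to min(20 kHz, Nyquist)
``cep``                            24  real-cepstrum coefficients c1..c24 of the
                                       frame's log magnitude spectrum; the
                                       low-time lifter keeps quefrencies up to
                                       the configured cutoff (default 24)
``dcep``                           24  within-window delta cepstra: c1..c24 of
                                       the second half-window minus the first
``bandvar``                        40  per mel band, variance of the band
                                       log-energy across 4 sub-blocks of the
                                       window (the local-variance features)
``scalar``                         20  zero-crossing rate, spectral centroid,
                                       bandwidth, 5 rolloff quantiles, flux,
                                       flatness, crest factor, log RMS,
                                       envelope skewness/kurtosis, and 6
                                       high-to-low band energy ratios
==============================  =====  =========================================

All features are deterministic functions of the frame's samples, so the
matrix is bitwise reproducible and time-shift covariant (shifting the
input by one hop shifts the rows by one).  Features are min-max
normalised to [-1, 1] against the training set before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.signal.windows import hann
from scipy.stats import kurtosis, skew

from .audio import AuscultationSection

DEFAULT_HOP_S = 0.012
DEFAULT_WINDOW_S = 0.024
N_FEATURES = 148

_N_MEL = 40
_N_CEPSTRA = 24
_N_SUBBLOCKS = 4
_ROLLOFF_QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)
_RATIO_SPLITS_HZ = (500.0, 1000.0, 2000.0, 4000.0, 8000.0, 16000.0)
_FLOOR_DB = -80.0  # spectral floor relative to full scale; keeps silence finite
_EPS = 1e-12


class FeatureError(ValueError):
    """Raised for grid/layout contract violations."""


@dataclass(frozen=True)
class FrameGrid:
    """Frame placement: frame k covers samples [k*hop, k*hop + window)."""

    hop_samples: int
    window_samples: int
    n_frames: int
    rate: int

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.rate

    @property
    def window_s(self) -> float:
        return self.window_samples / self.rate

    def frame_start_times(self) -> np.ndarray:
        """Start time of each frame in seconds, relative to the section."""
        return np.arange(self.n_frames) * self.hop_samples / self.rate


def make_grid(
    section: AuscultationSection,
    hop_s: float = DEFAULT_HOP_S,
    window_s: float = DEFAULT_WINDOW_S,
) -> FrameGrid:
    """Place the 12-ms frame grid on a section.

    ``n_frames = floor((n_samples - window) / hop) + 1``; a section shorter
    than one analysis window is an error.
    """
    rate = section.rate
    hop = int(round(hop_s * rate))
    window = int(round(window_s * rate))
    if hop <= 0 or window <= 0:
        raise FeatureError(f"hop and window must be positive, got {hop_s}, {window_s}")
    if window < hop:
        raise FeatureError(f"window ({window_s}s) must be >= hop ({hop_s}s)")
    if section.n_samples < window:
        raise FeatureError(
            f"section of {section.n_samples} samples shorter than one "
            f"{window}-sample window"
        )
    n_frames = (section.n_samples - window) // hop + 1
    return FrameGrid(hop_samples=hop, window_samples=window, n_frames=n_frames, rate=rate)


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered names of the 148 features; serialised with any trained model."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_FEATURES:
            raise FeatureError(f"layout must have {N_FEATURES} names, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise FeatureError("feature names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)


def default_layout(
    n_mel: int = _N_MEL,
    n_cepstra: int = _N_CEPSTRA,
) -> FeatureLayout:
    names: list[str] = []
    names += [f"mel_logE_{i:02d}" for i in range(n_mel)]
    names += [f"cep_{i:02d}" for i in range(1, n_cepstra + 1)]
    names += [f"dcep_{i:02d}" for i in range(1, n_cepstra + 1)]
    names += [f"bandvar_{i:02d}" for i in range(n_mel)]
    names += [
        "zcr",
        "spectral_centroid",
        "spectral_bandwidth",
    ]
    names += [f"rolloff_q{int(q * 100):02d}" for q in _ROLLOFF_QUANTILES]
    names += [
        "spectral_flux",
        "spectral_flatness",
        "crest_factor",
        "log_rms",
        "envelope_skewness",
        "envelope_kurtosis",
    ]
    names += [f"hi_lo_ratio_{int(f):d}Hz" for f in _RATIO_SPLITS_HZ]
    return FeatureLayout(names=tuple(names))


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame normalised feature vectors over a section's grid."""

    grid: FrameGrid
    values: np.ndarray  # (n_frames, 148), each entry in [-1, 1]
    layout: FeatureLayout

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_frames, self.layout.n):
            raise FeatureError(
                f"matrix shape {self.values.shape} inconsistent with grid/"
                f"layout ({self.grid.n_frames}, {self.layout.n})"
            )


# ---------------------------------------------------------------------------
# mel filter bank


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mel: int, n_fft: int, rate: int, fmin: float = 50.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filters, shape (n_mel, n_fft//2 + 1)."""
    if fmax is None:
        fmax = min(20_000.0, rate / 2.0)
    fmax = min(fmax, rate / 2.0)
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mel + 2))
    freqs = rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mel, freqs.size))
    for i in range(n_mel):
        lo, center, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        rising = (freqs - lo) / max(center - lo, _EPS)
        falling = (hi - freqs) / max(hi - center, _EPS)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


# ---------------------------------------------------------------------------
# extractor


@dataclass
class FeatureExtractor:
    """Computes the raw (unnormalised) 148-feature matrix for a section.

    ``lifter_cutoff`` is the low-time lifter length in quefrency samples:
    cepstral coefficients above the cutoff are zeroed before the first
    ``n_cepstra`` are taken, isolating spectral-envelope structure.
    """

    hop_s: float = DEFAULT_HOP_S
    window_s: float = DEFAULT_WINDOW_S
    n_mel: int = _N_MEL
    n_cepstra: int = _N_CEPSTRA
    lifter_cutoff: int = _N_CEPSTRA
    floor_db: float = _FLOOR_DB
    layout: FeatureLayout = field(default_factory=default_layout)

    def make_grid(self, section: AuscultationSection) -> FrameGrid:
        return make_grid(section, self.hop_s, self.window_s)

    def extract_raw(
        self, section: AuscultationSection, grid: FrameGrid | None = None
    ) -> tuple[FrameGrid, np.ndarray]:
        """Raw feature matrix, shape (n_frames, 148)."""
        if grid is None:
            grid = self.make_grid(section)
        samples = np.asarray(section.samples, dtype=np.float64)
        if not np.all(np.isfinite(samples)):
            raise FeatureError("section contains non-finite samples")

        win = grid.window_samples
        hop = grid.hop_samples
        idx = np.arange(win)[None, :] + hop * np.arange(grid.n_frames)[:, None]
        frames = samples[idx]  # (n_frames, win)

        floor_lin = 10.0 ** (self.floor_db / 10.0)
        rate = grid.rate
        taper = hann(win, sym=False)
        spec = rfft(frames * taper, axis=1)
        power = np.abs(spec) ** 2
        freqs = rfftfreq(win, d=1.0 / rate)

        cols: list[np.ndarray] = []

        # 40 mel log-energies
        fb = mel_filterbank(self.n_mel, win, rate)
        mel_energy = power @ fb.T
        mel_logE = 10.0 * np.log10(np.maximum(mel_energy, floor_lin))
        cols.append(mel_logE)

        # 24 liftered cepstral coefficients c1..c24
        log_mag = np.log(np.maximum(np.abs(spec), np.sqrt(floor_lin)))
        ceps = irfft(log_mag, n=win, axis=1)
        lifter = np.zeros(win)
        lifter[: self.lifter_cutoff + 1] = 1.0
        ceps_lift = ceps * lifter[None, :]
        cols.append(ceps_lift[:, 1 : self.n_cepstra + 1])

        # 24 delta cepstra from the two half-windows
        hw = win // 2
        half_taper = hann(hw, sym=False)
        halves = np.stack([frames[:, :hw], frames[:, win - hw :]])
        hspec = rfft(halves * half_taper, axis=2)
        hlog = np.log(np.maximum(np.abs(hspec), np.sqrt(floor_lin)))
        hceps = irfft(hlog, n=hw, axis=2)
        n_dc = min(self.n_cepstra, hw - 1)
        dcep = hceps[1, :, 1 : n_dc + 1] - hceps[0, :, 1 : n_dc + 1]
        if n_dc < self.n_cepstra:  # very short windows: pad deterministically
            dcep = np.pad(dcep, ((0, 0), (0, self.n_cepstra - n_dc)))
        cols.append(dcep)

        # 40 local-variance features: band log-energy variance over 4 sub-blocks
        sb = win // _N_SUBBLOCKS
        sub = frames[:, : sb * _N_SUBBLOCKS].reshape(grid.n_frames, _N_SUBBLOCKS, sb)
        sub_spec = rfft(sub * hann(sb, sym=False), axis=2)
        fb_sub = mel_filterbank(self.n_mel, sb, rate)
        sub_mel = np.abs(sub_spec) ** 2 @ fb_sub.T  # (n_frames, 4, n_mel)
        sub_logE = 10.0 * np.log10(np.maximum(sub_mel, floor_lin))
        cols.append(sub_logE.var(axis=1))

        # 20 scalar descriptors
        total_power = power.sum(axis=1)
        safe_total = np.maximum(total_power, _EPS)
        active = total_power > floor_lin  # silence guard for shape statistics

        zcr = np.mean(np.abs(np.diff(np.signbit(frames).astype(np.int8), axis=1)), axis=1)
        centroid = np.where(active, (power * freqs).sum(axis=1) / safe_total, 0.0)
        spread = ((freqs[None, :] - centroid[:, None]) ** 2 * power).sum(axis=1)
        bandwidth = np.where(active, np.sqrt(spread / safe_total), 0.0)

        cum = np.cumsum(power, axis=1)
        rolloffs = []
        for q in _ROLLOFF_QUANTILES:
            k = np.argmax(cum >= q * safe_total[:, None], axis=1)
            rolloffs.append(np.where(active, freqs[k], 0.0))

        hpow = np.abs(hspec) ** 2  # (2, n_frames, hw//2+1)
        p1 = hpow[0] / np.maximum(hpow[0].sum(axis=1, keepdims=True), _EPS)
        p2 = hpow[1] / np.maximum(hpow[1].sum(axis=1, keepdims=True), _EPS)
        flux = np.sqrt(((p2 - p1) ** 2).sum(axis=1))

        flatness = np.exp(np.mean(np.log(np.maximum(power, floor_lin)), axis=1)) / np.maximum(
            power.mean(axis=1), floor_lin
        )
        rms = np.sqrt(np.mean(frames ** 2, axis=1))
        crest = np.abs(frames).max(axis=1) / np.maximum(rms, _EPS)
        log_rms = 20.0 * np.log10(np.maximum(rms, 10.0 ** (self.floor_db / 20.0)))

        env = np.abs(frames)
        env_sd = env.std(axis=1)
        flat_env = env_sd < _EPS
        env_skew = np.where(flat_env, 0.0, skew(env, axis=1))
        env_kurt = np.where(flat_env, 0.0, kurtosis(env, axis=1))

        ratios = []
        for split in _RATIO_SPLITS_HZ:
            hi_mask = freqs > split
            e_hi = power[:, hi_mask].sum(axis=1)
            e_lo = power[:, ~hi_mask].sum(axis=1)
            ratios.append(
                10.0 * (np.log10(np.maximum(e_hi, floor_lin)) - np.log10(np.maximum(e_lo, floor_lin)))
            )

        scalars = np.column_stack(
            [zcr, centroid, bandwidth, *rolloffs, flux, flatness, crest, log_rms,
             env_skew, env_kurt, *ratios]
        )
        cols.append(scalars)

        raw = np.concatenate(cols, axis=1)
        if raw.shape[1] != self.layout.n:
            raise FeatureError(
                f"extractor produced {raw.shape[1]} features, layout has {self.layout.n}"
            )
        if not np.all(np.isfinite(raw)):
            raise FeatureError("non-finite feature values produced")
        return grid, raw

    def config(self) -> dict:
        return {
            "hop_s": self.hop_s,
            "window_s": self.window_s,
            "n_mel": self.n_mel,
            "n_cepstra": self.n_cepstra,
            "lifter_cutoff": self.lifter_cutoff,
            "floor_db": self.floor_db,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FeatureExtractor":
        return cls(**{k: cfg[k] for k in
                      ("hop_s", "window_s", "n_mel", "n_cepstra", "lifter_cutoff", "floor_db")})


# ---------------------------------------------------------------------------
# normalisation


@dataclass(frozen=True)
class FeatureNormalizer:
    """Per-feature affine map onto [-1, 1] fitted on training minima/maxima.

    Min-max with clipping is used (rather than z-scoring) because the
    classifier's contract requires every input component to lie in
    [-1, 1]; values outside the training range clip to the bounds.
    Constant training features map to 0.
    """

    lo: np.ndarray
    hi: np.ndarray
    layout: FeatureLayout

    def transform(self, raw: np.ndarray) -> np.ndarray:
        if raw.shape[-1] != self.layout.n:
            raise FeatureError(
                f"raw matrix has {raw.shape[-1]} features, normalizer expects {self.layout.n}"
            )
        span = self.hi - self.lo
        constant = span <= 0
        scaled = np.where(
            constant[None, :],
            0.0,
            2.0 * (raw - self.lo[None, :]) / np.where(constant, 1.0, span)[None, :] - 1.0,
        )
        return np.clip(scaled, -1.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "layout": list(self.layout.names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        return cls(
            lo=np.asarray(d["lo"], dtype=np.float64),
            hi=np.asarray(d["hi"], dtype=np.float64),
            layout=FeatureLayout(names=tuple(d["layout"])),
        )


def fit_normalizer(raw_matrices: list[np.ndarray], layout: FeatureLayout) -> FeatureNormalizer:
    """Fit the per-feature min/max map from stacked training matrices."""
    if not raw_matrices:
        raise FeatureError("cannot fit a normalizer on an empty training set")
    stacked = np.vstack(raw_matrices)
    if stacked.shape[1] != layout.n:
        raise FeatureError(
            f"training matrices have {stacked.shape[1]} features, layout has {layout.n}"
        )
    return FeatureNormalizer(lo=stacked.min(axis=0), hi=stacked.max(axis=0), layout=layout)


def apply_normalizer(
    grid: FrameGrid, raw: np.ndarray, normalizer: FeatureNormalizer
) -> FeatureMatrix:
    return FeatureMatrix(grid=grid, values=normalizer.transform(raw), layout=normalizer.layout)
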