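"""WAV ingest, validation and auscultation-section trimming.

Cervical auscultation recordings arrive as mono WAV files (the electronic
stethoscope captures roughly 2 Hz-20 kHz and streams to WAV).  This module
reads them into a float representation in [-1, 1], optionally resamples to
the canonical internal rate, and removes a fixed guard interval at both
ends of the recording: the contact sensor that starts/stops the recording
produces handling artifacts, so the 0.2 s immediately before and after the
auscultation are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical internal sampling rate, Hz.  Covers the stethoscope's stated
#: 20 kHz upper band edge; one fixed rate keeps the frame grid and feature
#: layout deterministic across inputs.
CANONICAL_RATE = 44_100

#: Guard interval removed at each end of a recording, seconds.
DEFAULT_EDGE_S = 0.2

_PCM_SCALE = {
    np.dtype(np.int16): 2 ** 15,
    np.dtype(np.int32): 2 ** 31,
    np.dtype(np.uint8): 2 ** 7,  # 8-bit WAV is unsigned, offset binary
}


class AudioError(ValueError):
    """Raised for unreadable, malformed or out-of-contract audio."""


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sampling rate.

    ``samples`` are dimensionless amplitudes nominally in [-1, 1];
    ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioError(f"expected mono audio, got shape {samples.shape}")
        if self.rate <= 0:
            raise AudioError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class AuscultationSection:
    """A contiguous slice of a recording delimited in seconds.

    Construction via :func:`trim_auscultation` guarantees the guard
    intervals have been removed; start/end are stored in whole samples so
    section lengths are exact.
    """

    parent: AudioRecording
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample <= self.parent.n_samples):
            raise AudioError(
                f"invalid section [{self.start_sample}, {self.end_sample}) "
                f"for recording of {self.parent.n_samples} samples"
            )

    @property
    def samples(self) -> np.ndarray:
        return self.parent.samples[self.start_sample : self.end_sample]

    @property
    def rate(self) -> int:
        return self.parent.rate

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    @property
    def start_s(self) -> float:
        return self.start_sample / self.rate

    @property
    def end_s(self) -> float:
        return self.end_sample / self.rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def read_wav(
    path: str | Path,
    *,
    downmix: str = "reject",
    target_rate: int | None = None,
) -> AudioRecording:
    """Read a WAV file into an :class:`AudioRecording`.

    Integer PCM is divided by the type's full scale so samples land in
    [-1, 1] regardless of on-disk bit depth; float WAV is taken as-is.
    ``downmix`` is ``"reject"`` (error on multi-channel input) or
    ``"mean"`` (average channels).  If ``target_rate`` is given and
    differs from the file's rate, polyphase resampling is applied.
    """
    path = Path(path)
    if not path.exists():
        raise AudioError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises plain ValueError on bad RIFF
        raise AudioError(f"cannot read WAV {path}: {exc}") from exc
    if data.size == 0:
        raise AudioError(f"zero-length audio: {path}")
    if data.ndim == 2:
        if downmix == "reject":
            raise AudioError(
                f"{path} has {data.shape[1]} channels; mono required "
                "(set downmix='mean' to average channels)"
            )
        if downmix != "mean":
            raise AudioError(f"unknown downmix policy {downmix!r}")
        data = data.astype(np.float64).mean(axis=1)

    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / scale
        else:
            samples = data.astype(np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioError(f"unsupported WAV sample format {data.dtype} in {path}")

    rec = AudioRecording(samples=samples, rate=int(rate))
    if target_rate is not None and target_rate != rec.rate:
        rec = resample(rec, target_rate)
    return rec


def write_wav(
    rec: AudioRecording,
    path: str | Path,
    *,
    fmt: str = "float32",
    clip: bool = True,
) -> None:
    """Write a recording as WAV (``fmt``: ``"float32"`` or ``"pcm16"``).

    Non-finite samples are always an error.  Out-of-range samples are
    clipped to [-1, 1] when ``clip`` is true, otherwise rejected.
    """
    samples = rec.samples
    if not np.all(np.isfinite(samples)):
        raise AudioError("samples contain NaN or infinity")
    if np.any(np.abs(samples) > 1.0):
        if not clip:
            raise AudioError("samples exceed [-1, 1] and clip=False")
        samples = np.clip(samples, -1.0, 1.0)
    if fmt == "float32":
        wavfile.write(path, rec.rate, samples.astype(np.float32))
    elif fmt == "pcm16":
        # same 2^15 full scale as read_wav so the round trip stays within 1 LSB
        quantized = np.clip(np.round(samples * 2 ** 15), -(2 ** 15), 2 ** 15 - 1).astype(np.int16)
        wavfile.write(path, rec.rate, quantized)
    else:
        raise AudioError(f"unknown WAV format {fmt!r}")


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Polyphase resample to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise AudioError(f"target rate must be positive, got {target_rate}")
    if target_rate == rec.rate:
        return rec
    g = np.gcd(int(target_rate), int(rec.rate))
    up, down = target_rate // g, rec.rate // g
    out = resample_poly(rec.samples, up, down)
    return AudioRecording(samples=out, rate=int(target_rate))


def trim_auscultation(
    rec: AudioRecording, edge_s: float = DEFAULT_EDGE_S
) -> AuscultationSection:
    """Drop ``edge_s`` seconds at each end of the recording.

    Trimming is expressed in whole samples via ``round(edge_s * rate)`` so
    the section length is exactly ``n - 2*round(edge_s*rate)`` samples.
    A recording not strictly longer than ``2 * edge_s`` is rejected as a
    too-short trial.
    """
    if edge_s < 0:
        raise AudioError(f"edge_s must be non-negative, got {edge_s}")
    edge = int(round(edge_s * rec.rate))
    if rec.n_samples <= 2 * edge:
        raise AudioError(
            f"trial too short: {rec.duration_s:.3f} s recording cannot lose "
            f"{edge_s} s at each end"
        )
    return AuscultationSection(parent=rec, start_sample=edge, end_sample=rec.n_samples - edge)


def section_of(rec: AudioRecording) -> AuscultationSection:
    """The whole recording as a section (no trimming)."""
    return AuscultationSection(parent=rec, start_sample=0, end_sample=rec.n_samples)
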