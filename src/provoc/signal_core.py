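"""Audio I/O, analysis windows, and the STFT analysis/synthesis pair.

The short-time Fourier transform here is the frame-wise DFT of the
windowed signal,

    X[u, k] = sum_n h[n] x[tau_u + n] exp(-j 2 pi k n / N),

with frames taken at analysis positions ``tau_u``.  Synthesis is the
inverse DFT per frame followed by windowed overlap-add, normalized by
the summed squared window so that an unmodified spectrogram
reconstructs the input to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import hann

__all__ = [
    "AudioSignal",
    "AnalysisWindow",
    "Spectrogram",
    "load_wav",
    "save_wav",
    "stft",
    "stft_at",
    "istft",
    "default_window",
]


@dataclass
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitude sequence, nominally within [-1, 1].
    rate : int
        Sampling rate in Hz.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"AudioSignal must be mono (1-D); got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    def copy(self) -> "AudioSignal":
        return AudioSignal(self.samples.copy(), self.rate)


@dataclass
class AnalysisWindow:
    """A symmetric, nonnegative analysis window of even length."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.values)
        if n < 4 or n % 2:
            raise ValueError(f"window length must be even and >= 4, got {n}")
        if np.any(self.values < 0):
            raise ValueError("window must be nonnegative")
        # symmetric in the DFT sense: h[n] == h[N-n]
        if not np.allclose(self.values[1:], self.values[1:][::-1]):
            raise ValueError("window must be symmetric")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @classmethod
    def hann(cls, n: int) -> "AnalysisWindow":
        """Periodic Hann window (COLA-compliant at hop n/4)."""
        return cls(hann(n, sym=False))


def default_window(rate: int, target_dur: float = 0.0464) -> AnalysisWindow:
    """Hann window sized to ~46 ms, rounded to the nearest power of two.

    Gives N = 2048 at 44.1 kHz.
    """
    n = 2 ** int(round(np.log2(rate * target_dur)))
    return AnalysisWindow.hann(max(n, 16))


@dataclass
class Spectrogram:
    """Complex STFT coefficient grid with frame-placement metadata.

    ``frame_times`` are the analysis positions tau_u in samples (possibly
    non-uniform).  ``synthesis_times`` — when set — override the uniform
    synthesis grid ``u * synthesis_hop`` during resynthesis.
    """

    coeffs: np.ndarray
    analysis_hop: int
    synthesis_hop: int
    window: AnalysisWindow
    rate: int
    frame_times: np.ndarray
    synthesis_times: np.ndarray | None = None
    orig_length: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.complex128)
        self.frame_times = np.asarray(self.frame_times)
        if self.coeffs.ndim != 2:
            raise ValueError("coeffs must be 2-D (frames x bins)")
        if self.coeffs.shape[1] != self.window.n:
            raise ValueError("number of bins must equal window length")
        if len(self.frame_times) != self.coeffs.shape[0]:
            raise ValueError("frame_times length must match frame count")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def num_frames(self) -> int:
        return self.coeffs.shape[0]

    @property
    def num_bins(self) -> int:
        return self.coeffs.shape[1]


# ---------------------------------------------------------------------------
# WAV I/O


def load_wav(path) -> AudioSignal:
    """Read a mono PCM16 or float32 WAV file, scaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.shape[1]} channels: {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.float32 or data.dtype == np.float64:
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype}; use PCM16 or float32")
    return AudioSignal(samples, int(rate))


def save_wav(signal: AudioSignal, path, subtype: str = "pcm16") -> None:
    """Write a mono WAV file; samples outside [-1, 1] are clipped."""
    samples = signal.samples
    if np.any(np.abs(samples) > 1.0):
        warnings.warn(
            f"samples exceed [-1, 1] (max |x| = {np.max(np.abs(samples)):.3f}); clipping",
            stacklevel=2,
        )
        samples = np.clip(samples, -1.0, 1.0)
    if subtype == "pcm16":
        data = np.round(samples * 32767.0).astype(np.int16)
    elif subtype == "float32":
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(path, signal.rate, data)


# ---------------------------------------------------------------------------
# STFT / iSTFT


def _padded(signal: AudioSignal, half: int, last_center: int) -> np.ndarray:
    """Reflect-pad so that frames centered anywhere in [0, last_center] exist."""
    x = signal.samples
    right = max(last_center + half - len(x) + 1, half)
    if len(x) < 2:
        return np.pad(x, (half, right))
    return np.pad(x, (half, right), mode="reflect")


def stft_at(signal: AudioSignal, window: AnalysisWindow, positions, synthesis_hop: int | None = None) -> Spectrogram:
    """STFT with frames centered at arbitrary sample ``positions``."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("need at least one frame position")
    n = window.n
    half = n // 2
    x = _padded(signal, half, int(positions[-1]))
    frames = np.empty((len(positions), n), dtype=np.float64)
    for u, pos in enumerate(positions):
        frames[u] = x[pos : pos + n]  # pos is center; pad offset cancels half
    coeffs = np.fft.fft(frames * window.values, axis=1)
    hop = int(positions[1] - positions[0]) if len(positions) > 1 else n
    return Spectrogram(
        coeffs=coeffs,
        analysis_hop=hop,
        synthesis_hop=synthesis_hop if synthesis_hop is not None else hop,
        window=window,
        rate=signal.rate,
        frame_times=positions,
        orig_length=len(signal),
    )


def stft(signal: AudioSignal, window: AnalysisWindow, analysis_hop: int) -> Spectrogram:
    """Uniform-hop STFT; frames are centered at tau_u = analysis_hop * u."""
    if analysis_hop < 1:
        raise ValueError(f"analysis hop must be >= 1, got {analysis_hop}")
    if window.n > len(signal) + window.n:  # degenerate; kept for API symmetry
        raise ValueError("window longer than padded signal")
    if len(signal) == 0:
        raise ValueError("empty signal")
    num_frames = int(np.floor((len(signal) - 1) / analysis_hop)) + 1
    positions = analysis_hop * np.arange(num_frames)
    return stft_at(signal, window, positions, synthesis_hop=analysis_hop)


def istft(spec: Spectrogram, out_length: int | None = None) -> AudioSignal:
    """Resynthesize a signal by inverse DFT and windowed overlap-add.

    Overlap-add runs at ``spec.synthesis_times`` (default ``u * R_s``) and is
    normalized by the summed squared window; the result is trimmed or padded
    to ``out_length`` (default: the recorded input length for an identity
    resynthesis, else the extent of the synthesis grid).
    """
    if spec.num_frames == 0:
        raise ValueError("empty spectrogram")
    h = spec.window.values
    n = spec.window.n
    half = n // 2
    if spec.synthesis_times is not None:
        st = np.asarray(spec.synthesis_times, dtype=np.int64)
    else:
        st = spec.synthesis_hop * np.arange(spec.num_frames)
    if len(st) > 1 and np.max(np.diff(st)) >= n:
        raise ValueError("synthesis hop leaves gaps (OLA gain hits zero)")

    frames = np.fft.ifft(spec.coeffs, axis=1).real
    total = int(st[-1]) + n
    y = np.zeros(total)
    wsum = np.zeros(total)
    h2 = h * h
    for u, pos in enumerate(st):
        y[pos : pos + n] += h * frames[u]
        wsum[pos : pos + n] += h2
    core = wsum > 1e-12
    y[core] /= wsum[core]

    if out_length is None:
        if spec.synthesis_times is None and spec.synthesis_hop == spec.analysis_hop:
            out_length = spec.orig_length
        if out_length is None:
            out_length = int(st[-1]) + spec.synthesis_hop if len(st) > 1 else total - n

    # frames were centered at their positions: drop the half-window lead-in
    out = y[half : half + out_length]
    if len(out) < out_length:
        out = np.pad(out, (0, out_length - len(out)))
    return AudioSignal(out, spec.rate)
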