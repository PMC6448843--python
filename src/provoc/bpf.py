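"""Breakpoint functions (BPFs): random generation, evaluation, pitch flattening.

A BPF is a piecewise trajectory of (time, value) pairs controlling a
time-varying transformation parameter.  ``ramp`` BPFs interpolate linearly
between breakpoints; ``square`` BPFs hold a plateau per segment with linear
transitions of width ``transition_time`` centered on segment boundaries.
Values are tagged by dimension: pitch shifts in cents, stretch factors as
ratios, gains in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import AudioSignal

__all__ = [
    "BreakpointFunction",
    "TransformSpec",
    "NEUTRAL",
    "segment_times",
    "sample_truncated_gaussian",
    "generate_random_bpf",
    "evaluate_bpf",
    "estimate_pitch_contour",
    "flatten_pitch_bpf",
]

#: neutral (no-change) breakpoint value per dimension
NEUTRAL = {"pitch": 0.0, "stretch": 1.0, "gain": 0.0}


@dataclass
class BreakpointFunction:
    times: np.ndarray
    values: np.ndarray
    kind: str = "ramp"  # 'ramp' | 'square'
    transition_time: float = 0.02
    dimension: str | None = None  # 'pitch' | 'stretch' | 'gain'

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=np.float64))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValueError("times and values must have equal length >= 1")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("breakpoint times must be >= 0")
        if self.kind not in ("ramp", "square"):
            raise ValueError(f"unknown BPF kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("breakpoint values must be finite")

    def __call__(self, t) -> np.ndarray | float:
        return evaluate_bpf(self, t)

    def _square_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Knot representation of a square BPF as a piecewise-linear curve."""
        tr = max(self.transition_time, 1e-9)
        if len(self.times) == 1:
            return self.times, self.values
        bounds = 0.5 * (self.times[:-1] + self.times[1:])
        kt = np.concatenate([bounds - tr / 2, bounds + tr / 2])
        kv = np.concatenate([self.values[:-1], self.values[1:]])
        order = np.argsort(kt, kind="stable")
        return kt[order], kv[order]

    def save(self, path) -> None:
        """Serialize as a 2-column (time, value) text file."""
        header = f"kind={self.kind} transition_time={self.transition_time} dimension={self.dimension}"
        np.savetxt(path, np.column_stack([self.times, self.values]), header=header)

    @classmethod
    def load(cls, path) -> "BreakpointFunction":
        kind, tr, dim = "ramp", 0.02, None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, val = token.partition("=")
                if key == "kind":
                    kind = val
                elif key == "transition_time":
                    tr = float(val)
                elif key == "dimension" and val != "None":
                    dim = val
        arr = np.loadtxt(path, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], kind=kind, transition_time=tr, dimension=dim)


@dataclass
class TransformSpec:
    """Parameters controlling random BPF generation for one dimension.

    ``winUnit='s'`` segments the sound into fixed-duration windows of
    ``winLen`` seconds (the last may be shorter); ``winUnit='n'`` forces
    ``numWin`` equal segments.  Breakpoint values are drawn from a Gaussian
    centered on the dimension's neutral value with SD ``std``, truncated at
    ``trunc`` multiples of the SD.
    """

    dimension: str
    winLen: float = 0.0
    numWin: int = 0
    winUnit: str = "n"
    std: float = 0.0
    trunc: float = np.inf
    BPFtype: str = "ramp"
    trTime: float = 0.02
    custom_times: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.dimension not in NEUTRAL:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if self.trunc <= 0:
            raise ValueError("trunc must be > 0")
        if self.winUnit not in ("s", "n"):
            raise ValueError(f"winUnit must be 's' or 'n', got {self.winUnit!r}")


def segment_times(duration: float, spec: TransformSpec) -> np.ndarray:
    """Breakpoint times (segment centers) for a sound of ``duration`` seconds.

    numWin == 0 (or winLen == 0) means a static transformation: a single
    breakpoint at the sound's midpoint.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if spec.custom_times is not None:
        return np.asarray(spec.custom_times, dtype=np.float64)
    if spec.winUnit == "n":
        n = spec.numWin
        if n < 0:
            raise ValueError("numWin must be >= 0")
        if n == 0:
            return np.array([duration / 2])
        edges = np.linspace(0.0, duration, n + 1)
    else:
        if spec.winLen < 0:
            raise ValueError("winLen must be >= 0")
        if spec.winLen == 0:
            return np.array([duration / 2])
        n = int(np.ceil(duration / spec.winLen - 1e-12))
        edges = np.minimum(spec.winLen * np.arange(n + 1), duration)
    return 0.5 * (edges[:-1] + edges[1:])


def sample_truncated_gaussian(n, mean, std, trunc, rng) -> np.ndarray:
    """Draw ``n`` Normal(mean, std) values conditioned on |x - mean| <= trunc*std.

    Rejection sampling, so the Gaussian shape is preserved inside the bounds
    (no probability mass piles at the truncation points).
    """
    if std < 0:
        raise ValueError("std must be >= 0")
    if trunc <= 0:
        raise ValueError("trunc must be > 0")
    if std == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, std, size=n)
    if np.isfinite(trunc):
        bad = np.abs(out - mean) > trunc * std
        while np.any(bad):
            out[bad] = rng.normal(mean, std, size=int(bad.sum()))
            bad = np.abs(out - mean) > trunc * std
    return out


def generate_random_bpf(duration: float, spec: TransformSpec, rng) -> BreakpointFunction:
    """Random BPF: breakpoints at segment times, Gaussian values around neutral."""
    times = segment_times(duration, spec)
    mean = NEUTRAL[spec.dimension]
    values = sample_truncated_gaussian(len(times), mean, spec.std, spec.trunc, rng)
    return BreakpointFunction(
        times, values, kind=spec.BPFtype, transition_time=spec.trTime, dimension=spec.dimension
    )


def evaluate_bpf(bpf: BreakpointFunction, t):
    """Evaluate a BPF at time(s) ``t``; clamped to end values outside range."""
    t_arr = np.asarray(t, dtype=np.float64)
    if bpf.kind == "ramp":
        out = np.interp(t_arr, bpf.times, bpf.values)
    else:
        kt, kv = bpf._square_knots()
        out = np.interp(t_arr, kt, kv)
    return float(out) if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# Pitch contour estimation and flattening


def estimate_pitch_contour(
    signal: AudioSignal,
    frame_step: float = 0.02,
    fmin: float = 60.0,
    fmax: float = 500.0,
    voicing_threshold: float = 0.5,
):
    """Autocorrelation-based f0 track.

    Returns an (n, 2) array of (time seconds, f0 Hz) for voiced frames only.
    A frame is voiced when its normalized autocorrelation peak within the
    admissible lag range exceeds ``voicing_threshold`` and it carries energy.

    Raises ``ValueError`` when no voiced frame is found.
    """
    x = signal.samples
    rate = signal.rate
    win = int(round(rate * 2.5 / fmin))  # >= 2.5 periods of the lowest f0
    step = max(int(round(rate * frame_step)), 1)
    lag_min = max(int(np.floor(rate / fmax)), 2)
    lag_max = int(np.ceil(rate / fmin))
    if win + lag_max >= len(x):
        win = max(len(x) - lag_max - 1, lag_max)
    peak_rms = np.sqrt(np.mean(x**2)) if len(x) else 0.0
    contour = []
    pos = 0
    while pos + win + lag_max <= len(x):
        frame = x[pos : pos + win + lag_max]
        frame = frame - frame.mean()
        rms = np.sqrt(np.mean(frame**2))
        if rms > 0.05 * peak_rms:
            # normalized cross-correlation between frame[0:win] and lagged copies
            base = frame[:win]
            nfft = int(2 ** np.ceil(np.log2(win + lag_max + 1)))
            spec_a = np.fft.rfft(base, nfft)
            spec_b = np.fft.rfft(frame, nfft)
            corr = np.fft.irfft(np.conj(spec_a) * spec_b, nfft)[: lag_max + 1]
            e0 = np.dot(base, base)
            lag_energy = np.array(
                [np.dot(frame[k : k + win], frame[k : k + win]) for k in range(lag_max + 1)]
            )
            denom = np.sqrt(e0 * lag_energy)
            denom[denom <= 0] = np.inf
            ncc = corr / denom
            seg = ncc[lag_min : lag_max + 1]
            k = int(np.argmax(seg)) + lag_min
            if ncc[k] > voicing_threshold:
                # parabolic refinement of the peak lag
                if 0 < k < lag_max:
                    a, b, c = ncc[k - 1], ncc[k], ncc[k + 1]
                    denom2 = a - 2 * b + c
                    shift = 0.5 * (a - c) / denom2 if abs(denom2) > 1e-12 else 0.0
                    shift = np.clip(shift, -0.5, 0.5)
                else:
                    shift = 0.0
                f0 = rate / (k + shift)
                if fmin <= f0 <= fmax:
                    contour.append(((pos + win / 2) / rate, f0))
        pos += step
    if not contour:
        raise ValueError("no voiced frames found; cannot estimate pitch contour")
    return np.asarray(contour)


def flatten_pitch_bpf(contour, target="mean") -> BreakpointFunction:
    """Pitch-shift BPF (cents) that moves a contour onto a constant pitch.

    ``target`` is a frequency in Hz, or ``'mean'`` for the geometric mean of
    the voiced f0 values.
    """
    contour = np.asarray(contour, dtype=np.float64)
    if contour.size == 0:
        raise ValueError("empty contour")
    times, f0 = contour[:, 0], contour[:, 1]
    if np.any(f0 <= 0):
        raise ValueError("contour contains nonpositive f0")
    if isinstance(target, str):
        if target != "mean":
            raise ValueError(f"unknown target {target!r}")
        target_hz = float(np.exp(np.mean(np.log(f0))))
    else:
        target_hz = float(target)
        if target_hz <= 0:
            raise ValueError("target frequency must be positive")
    cents = 1200.0 * np.log2(target_hz / f0)
    # collapse duplicate times that parabolic refinement can produce
    times, idx = np.unique(times, return_index=True)
    return BreakpointFunction(times, cents[idx], kind="ramp", dimension="pitch")
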