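"""Phase-vocoder transformations: time stretch, pitch shift, amplitude masks.

Time stretching keeps the synthesis hop R_s constant and varies the analysis
hop per frame (R_a = R_s / t), so a stretch-factor trajectory t(tau) defined
on the input timeline yields an output of duration ~ integral of t.  Phase
coherence across modified hops uses vertical phase synchronization
(phase locking): spectral amplitude peaks are detected per frame, phases are
propagated only at peak bins via their instantaneous frequency, and bins in
each peak's region of influence are rotated rigidly with their peak.

Pitch shifting by a factor p is time stretching by p followed by resampling
by 1/p to restore the original duration; a time-varying p is handled by a
single warped-resampling pass against the cumulative stretch map.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly
from fractions import Fraction

from .signal_core import AnalysisWindow, AudioSignal, Spectrogram, default_window, istft, stft_at
from .bpf import BreakpointFunction, evaluate_bpf

__all__ = [
    "propagate_phases",
    "time_stretch",
    "pitch_shift",
    "apply_gain",
    "resample",
]


def _princarg(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to (-pi, pi]."""
    return phi - 2 * np.pi * np.round(phi / (2 * np.pi))


def _peak_regions(mag: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peak bins and region-of-influence boundaries on a half spectrum.

    A bin is a peak when it strictly exceeds its 2 nearest neighbors on each
    side; regions extend to the midpoint between adjacent peaks.
    Returns (peaks, edges) with region i = [edges[i], edges[i+1]).
    """
    n = len(mag)
    if n < 5:
        peaks = np.array([int(np.argmax(mag))])
    else:
        m = mag
        cand = np.arange(2, n - 2)
        is_peak = (
            (m[cand] > m[cand - 1])
            & (m[cand] > m[cand - 2])
            & (m[cand] > m[cand + 1])
            & (m[cand] > m[cand + 2])
        )
        peaks = cand[is_peak]
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(mag))])
    mid = (peaks[:-1] + peaks[1:] + 1) // 2
    edges = np.concatenate([[0], mid, [n]])
    return peaks, edges


def propagate_phases(spec: Spectrogram, per_frame_hop_ratio) -> Spectrogram:
    """Phase-locked phase propagation for time-shifted STFT frames.

    ``per_frame_hop_ratio[u]`` is the ratio of the synthesis hop to the
    analysis hop leading into frame u (ratio 1 leaves phases untouched up to
    multiples of 2*pi).  Returns a spectrogram with identical amplitudes,
    propagated phases, and ``synthesis_times`` on the rescaled grid.
    """
    ratios = np.atleast_1d(np.asarray(per_frame_hop_ratio, dtype=np.float64))
    if spec.num_frames == 0:
        raise ValueError("empty spectrogram")
    if ratios.size == 1:
        ratios = np.full(spec.num_frames, ratios[0])
    if len(ratios) != spec.num_frames:
        raise ValueError("need one hop ratio per frame")
    if np.any(ratios <= 0):
        raise ValueError("hop ratios must be strictly positive")

    n = spec.num_bins
    half = n // 2 + 1
    omega = 2 * np.pi * np.arange(half) / n

    coeffs = spec.coeffs[:, :half]
    mags = np.abs(coeffs)
    phases = np.angle(coeffs)

    ta = np.asarray(spec.frame_times, dtype=np.float64)
    psi = np.empty_like(phases)
    psi[0] = phases[0]
    ts = np.empty(spec.num_frames)
    ts[0] = 0.0
    # accumulate the phase ROTATION psi - phase_a per bin: for a peak bin,
    # rot_u = rot_{u-1} + omega_inst * (dt_s - dt_a), which is exactly zero
    # for hop ratio 1 and avoids drift from accumulating absolute phases
    rot_prev = np.zeros(half)
    for u in range(1, spec.num_frames):
        dt_a = ta[u] - ta[u - 1]
        dt_s = dt_a * ratios[u]
        ts[u] = ts[u - 1] + dt_s
        peaks, edges = _peak_regions(mags[u])
        # instantaneous frequency at peaks via heterodyned phase increment
        dev = _princarg(phases[u, peaks] - phases[u - 1, peaks] - omega[peaks] * dt_a)
        inst = omega[peaks] + dev / dt_a
        rot_peaks = _princarg(rot_prev[peaks] + inst * (dt_s - dt_a))
        # lock each region rigidly to its peak's phase rotation
        rot_row = np.empty(half)
        for i in range(len(peaks)):
            rot_row[edges[i] : edges[i + 1]] = rot_peaks[i]
        psi[u] = phases[u] + rot_row
        rot_prev = rot_row

    out_half = mags * np.exp(1j * psi)
    # hermitian completion keeps the resynthesized signal real
    out = np.empty_like(spec.coeffs)
    out[:, :half] = out_half
    out[:, half:] = np.conj(out_half[:, 1 : n - half + 1][:, ::-1])
    # DC and Nyquist bins must be real
    out[:, 0] = np.abs(out[:, 0]) * np.where(np.cos(psi[:, 0]) >= 0, 1.0, -1.0)
    if n % 2 == 0:
        k = n // 2
        out[:, k] = np.abs(out[:, k]) * np.where(np.cos(psi[:, k]) >= 0, 1.0, -1.0)

    return Spectrogram(
        coeffs=out,
        analysis_hop=spec.analysis_hop,
        synthesis_hop=spec.synthesis_hop,
        window=spec.window,
        rate=spec.rate,
        frame_times=spec.frame_times,
        synthesis_times=np.round(ts).astype(np.int64),
        orig_length=spec.orig_length,
    )


def _stretch_plan(signal: AudioSignal, bpf: BreakpointFunction, synthesis_hop: int):
    """Analysis frame positions and per-frame hop ratios for a stretch BPF."""
    rate = signal.rate
    positions = [0.0]
    pos = 0.0
    while pos < len(signal):
        t = float(evaluate_bpf(bpf, pos / rate))
        if t <= 0 or not np.isfinite(t):
            raise ValueError(f"stretch factor must be positive, got {t} at {pos / rate:.3f}s")
        pos += synthesis_hop / t
        positions.append(pos)
    if len(positions) > 1 and positions[-1] >= len(signal):
        positions = positions[:-1]
    pos_int = np.round(np.asarray(positions)).astype(np.int64)
    keep = np.concatenate([[True], np.diff(pos_int) > 0])
    pos_int = pos_int[keep]
    ratios = np.empty(len(pos_int))
    ratios[0] = 1.0
    if len(pos_int) > 1:
        ratios[1:] = synthesis_hop / np.diff(pos_int)
    return pos_int, ratios


def time_stretch(
    signal: AudioSignal,
    bpf: BreakpointFunction,
    window: AnalysisWindow | None = None,
) -> AudioSignal:
    """Stretch/compress durations by the factor trajectory in ``bpf``.

    BPF times live on the input timeline; the output duration approximates
    the integral of the stretch factor over the input duration.
    """
    if np.any(bpf.values <= 0):
        raise ValueError("stretch factors must be > 0")
    if window is None:
        window = default_window(signal.rate)
    rs = window.n // 4
    positions, ratios = _stretch_plan(signal, bpf, rs)
    spec = stft_at(signal, window, positions, synthesis_hop=rs)
    shifted = propagate_phases(spec, ratios)
    shifted.synthesis_times = rs * np.arange(len(positions))
    out_len = rs * len(positions)
    return istft(shifted, out_length=out_len)


def pitch_shift(
    signal: AudioSignal,
    bpf: BreakpointFunction,
    window: AnalysisWindow | None = None,
) -> AudioSignal:
    """Shift pitch by the cent trajectory in ``bpf``, preserving duration.

    Internally: time stretch with factor p(tau) = 2**(cents/1200), then a
    warped resampling that maps input time tau to stretched-output position
    integral(p) — restoring the original duration exactly while scaling the
    instantaneous frequency by p(tau).
    """
    if not np.all(np.isfinite(bpf.values)):
        raise ValueError("pitch-shift cents must be finite")
    ratio_bpf = BreakpointFunction(
        bpf.times,
        2.0 ** (bpf.values / 1200.0),
        kind=bpf.kind,
        transition_time=bpf.transition_time,
        dimension="stretch",
    )
    stretched = time_stretch(signal, ratio_bpf, window=window)
    # cumulative stretch map: input sample n -> position in stretched signal
    tau = np.arange(len(signal)) / signal.rate
    p = np.atleast_1d(evaluate_bpf(ratio_bpf, tau))
    pos = np.concatenate([[0.0], np.cumsum(p)[:-1]])
    out = np.interp(pos, np.arange(len(stretched)), stretched.samples)
    return AudioSignal(out, signal.rate)


def apply_gain(
    signal: AudioSignal,
    bpf: BreakpointFunction,
    window: AnalysisWindow | None = None,
) -> AudioSignal:
    """Scale amplitudes by the dB trajectory in ``bpf``; phases untouched."""
    if window is None:
        window = default_window(signal.rate)
    rs = window.n // 4
    num_frames = int(np.floor((len(signal) - 1) / rs)) + 1
    positions = rs * np.arange(num_frames)
    spec = stft_at(signal, window, positions, synthesis_hop=rs)
    gains = 10.0 ** (np.atleast_1d(evaluate_bpf(bpf, positions / signal.rate)) / 20.0)
    spec.coeffs = spec.coeffs * gains[:, None]
    return istft(spec, out_length=len(signal))


def resample(signal: AudioSignal, ratio: float) -> AudioSignal:
    """Band-limited resampling: length scaled by ``ratio``, frequencies by 1/ratio."""
    if ratio <= 0:
        raise ValueError(f"resampling ratio must be positive, got {ratio}")
    if ratio == 1.0:
        return signal.copy()
    frac = Fraction(ratio).limit_denominator(1000)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, signal.rate)
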