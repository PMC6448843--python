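"""Synthetic audio and simulated observers for self-contained validation.

Everything downstream of stimulus generation (kernels, double-pass internal
noise) can be exercised without recordings or human data: tones / glides /
note sequences stand in for speech and song, and a template-matching
two-interval observer with late additive Gaussian noise stands in for the
participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import sawtooth as _sawtooth

from .bpf import TransformSpec, sample_truncated_gaussian
from .signal_core import AudioSignal

__all__ = [
    "make_tone",
    "make_glide",
    "make_note_sequence",
    "ObserverModel",
    "simulate_observer",
    "simulate_experiment",
    "CASE1_NOISE",
    "CASE2_NOISE",
]

#: stimulus-noise specs of the two case studies (pitch cents / stretch ratios)
CASE1_NOISE = TransformSpec(dimension="pitch", numWin=6, winUnit="n",
                            std=70.0, trunc=2.2, BPFtype="ramp")
CASE2_NOISE = TransformSpec(dimension="stretch", numWin=6, winUnit="n",
                            std=0.4, trunc=1.6, BPFtype="square", trTime=0.1)

PEAK = 0.8


def make_tone(freq: float, duration: float, rate: int, shape: str = "sine") -> AudioSignal:
    """Periodic signal at ``freq`` Hz with peak amplitude 0.8."""
    if not 0 < freq < rate / 2:
        raise ValueError(f"frequency {freq} Hz outside (0, Nyquist={rate / 2})")
    t = np.arange(int(round(duration * rate))) / rate
    if shape == "sine":
        x = np.sin(2 * np.pi * freq * t)
    elif shape == "sawtooth":
        x = _sawtooth(2 * np.pi * freq * t)
    elif shape == "harmonic-complex":
        x = np.zeros_like(t)
        k = 1
        while k * freq < rate / 2 and k <= 10:
            x += np.sin(2 * np.pi * k * freq * t) / k
            k += 1
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return AudioSignal(PEAK * x / np.max(np.abs(x)), rate)


def make_glide(f_start: float, f_end: float, duration: float, rate: int) -> AudioSignal:
    """Phase-continuous tone with an exponential f0 trajectory."""
    for f in (f_start, f_end):
        if not 0 < f < rate / 2:
            raise ValueError(f"frequency {f} Hz outside (0, Nyquist={rate / 2})")
    t = np.arange(int(round(duration * rate))) / rate
    if f_start == f_end:
        phase = 2 * np.pi * f_start * t
    else:
        ratio = f_end / f_start
        # integral of f_start * ratio**(t/T)
        phase = 2 * np.pi * f_start * duration / np.log(ratio) * (ratio ** (t / duration) - 1)
    return AudioSignal(PEAK * np.sin(phase), rate)


def make_note_sequence(f0s, durations, rate: int, fade: float = 0.01):
    """Concatenated tones with raised-cosine fades; returns (signal, onsets)."""
    f0s = list(f0s)
    durations = list(durations)
    if len(f0s) != len(durations):
        raise ValueError("f0s and durations must have equal length")
    pieces = []
    onsets = []
    elapsed = 0.0
    for f0, dur in zip(f0s, durations):
        note = make_tone(f0, dur, rate, shape="harmonic-complex").samples
        nf = min(int(fade * rate), len(note) // 2)
        if nf > 0:
            env = 0.5 * (1 - np.cos(np.pi * np.arange(nf) / nf))
            note[:nf] *= env
            note[-nf:] *= env[::-1]
        pieces.append(note)
        onsets.append(elapsed)
        elapsed += len(note) / rate
    return AudioSignal(np.concatenate(pieces), rate), np.asarray(onsets)


@dataclass
class ObserverModel:
    """Template matcher with late additive noise and a decision criterion.

    ``internal_noise_sd`` is expressed in external-noise units: the late
    noise is added to the evidence difference after the per-interval evidence
    (template dot profile) has been normalized to unit variance under the
    stimulus distribution.
    """

    template: np.ndarray
    internal_noise_sd: float = 0.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)
        if not np.all(np.isfinite(self.template)):
            raise ValueError("template must be finite")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be >= 0")


def simulate_observer(model: ObserverModel, profiles_a, profiles_b, rng,
                      scale: float | None = None) -> pd.DataFrame:
    """Run the observer over trial pairs; returns a response table.

    The decision variable is t.(a - b)/scale plus late Gaussian noise of SD
    ``internal_noise_sd``; choose A iff it exceeds ``bias``.  ``scale``
    defaults to the empirical SD of t.profile over the supplied trials (the
    single-interval external-evidence SD), so the noise SD is expressed in
    external-noise units.
    """
    a = np.asarray(profiles_a, dtype=np.float64)
    b = np.asarray(profiles_b, dtype=np.float64)
    if a.shape != b.shape or a.shape[1] != len(model.template):
        raise ValueError("profile shapes must match the template length")
    ev_a = a @ model.template
    ev_b = b @ model.template
    if scale is None:
        scale = float(np.std(np.concatenate([ev_a, ev_b])))
    if scale <= 0:
        raise ValueError("degenerate evidence scale")
    d = (ev_a - ev_b) / scale
    d = d + model.internal_noise_sd * rng.standard_normal(len(d))
    choice = np.where(d > model.bias, "A", "B")
    cols = {"trial": np.arange(len(d))}
    for j in range(a.shape[1]):
        cols[f"A_{j}"] = a[:, j]
    for j in range(b.shape[1]):
        cols[f"B_{j}"] = b[:, j]
    cols["choice"] = choice
    cols["pass_tag"] = "main"
    return pd.DataFrame(cols)


def _draw_profiles(recipe: str, n_trials: int, n_points: int, rng):
    """Per-trial stimulus profiles under a case-study noise spec."""
    if recipe == "case1":
        spec = CASE1_NOISE
        mean = 0.0
    elif recipe == "case2":
        spec = CASE2_NOISE
        mean = 1.0
    else:
        raise ValueError(f"unknown recipe {recipe!r}")
    flat = sample_truncated_gaussian(2 * n_trials * n_points, mean, spec.std, spec.trunc, rng)
    pair = flat.reshape(2, n_trials, n_points)
    return pair[0], pair[1]


def simulate_experiment(recipe: str, observer: ObserverModel, n_trials: int,
                        seed: int, double_pass: int = 33,
                        participant: str = "sim") -> pd.DataFrame:
    """Simulate a full case-study session, including the double-pass block.

    ``n_trials`` distinct trials are drawn with the recipe's noise spec; the
    last ``double_pass`` of them are presented twice (tags 'pass1'/'pass2'),
    as in the melody experiment (280 + 33 repeated = 313 presentations).
    For the stretch recipe the observer operates in the log-ratio domain.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= double_pass <= n_trials:
        raise ValueError("double_pass block must fit within n_trials")
    rng = np.random.default_rng(seed)
    n_points = len(observer.template)
    a, b = _draw_profiles(recipe, n_trials, n_points, rng)
    obs_a, obs_b = (np.log(a), np.log(b)) if recipe == "case2" else (a, b)
    # analytic single-interval evidence scale under the stimulus distribution
    probe = _draw_profiles(recipe, 20_000, n_points,
                           np.random.default_rng(12345))[0]
    if recipe == "case2":
        probe = np.log(probe)
    scale = float(np.std(probe @ observer.template))

    if double_pass:
        obs_a = np.vstack([obs_a, obs_a[-double_pass:]])
        obs_b = np.vstack([obs_b, obs_b[-double_pass:]])
        a = np.vstack([a, a[-double_pass:]])
        b = np.vstack([b, b[-double_pass:]])

    frame = simulate_observer(observer, obs_a, obs_b, rng, scale=scale)
    # store raw (non-log) profiles; the analysis applies its own domain
    for j in range(n_points):
        frame[f"A_{j}"] = a[:, j]
        frame[f"B_{j}"] = b[:, j]
    tags = np.full(len(frame), "main", dtype=object)
    if double_pass:
        tags[n_trials - double_pass : n_trials] = "pass1"
        tags[n_trials:] = "pass2"
    frame["pass_tag"] = tags
    frame["trial"] = np.arange(len(frame))
    frame.insert(0, "participant", participant)
    return frame
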