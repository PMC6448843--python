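"""Config-driven batch generation of randomized stimuli from a base sound.

A batch run loads one base WAV, draws fresh random breakpoint functions per
output file (chained in series, or one independent output per dimension),
writes the transformed WAVs with their BPF logs, and records a manifest CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpf as bpfmod
from .bpf import BreakpointFunction, TransformSpec, estimate_pitch_contour, flatten_pitch_bpf
from .signal_core import AudioSignal, load_wav, save_wav
from .transforms import apply_gain, pitch_shift, time_stretch

__all__ = [
    "BatchConfig",
    "load_config",
    "process_batch",
    "apply_chain",
    "SpeechPitchRecipe",
    "MelodyStretchRecipe",
    "make_case_study_stimulus",
]

logger = logging.getLogger(__name__)

_SPEC_KEYS = ("winLen", "numWin", "winUnit", "std", "trunc", "BPFtype", "trTime")


@dataclass
class BatchConfig:
    numFiles: int
    outPath: str
    transf: list
    chain: bool = True
    seed: int = 0
    specs: dict = field(default_factory=dict)  # dimension -> TransformSpec

    def __post_init__(self) -> None:
        if self.numFiles < 1:
            raise ValueError("numFiles must be >= 1")
        if not self.transf:
            raise ValueError("transf must list at least one transformation")
        for dim in self.transf:
            if dim not in self.specs:
                raise ValueError(f"no TransformSpec provided for {dim!r}")


def load_config(path) -> BatchConfig:
    """Read a YAML batch configuration.

    Top-level keys: numFiles, outPath, chain, transf, seed, plus one mapping
    per listed dimension (pitch / stretch / gain) holding the BPF keys
    winLen, numWin, winUnit, std, trunc, BPFtype, trTime.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    transf = raw.get("transf", [])
    specs = {}
    for dim in transf:
        section = raw.get(dim)
        if section is None:
            raise ValueError(f"config lists transform {dim!r} but has no section for it")
        kwargs = {k: section[k] for k in _SPEC_KEYS if k in section}
        if "trunc" in kwargs and kwargs["trunc"] in (None, 0, "inf"):
            kwargs["trunc"] = np.inf
        specs[dim] = TransformSpec(dimension=dim, **kwargs)
    return BatchConfig(
        numFiles=int(raw.get("numFiles", 1)),
        outPath=str(raw.get("outPath", ".")),
        chain=bool(raw.get("chain", True)),
        transf=list(transf),
        seed=int(raw.get("seed", 0)),
        specs=specs,
    )


def apply_chain(signal: AudioSignal, bpfs) -> AudioSignal:
    """Apply (dimension, BreakpointFunction) pairs in order."""
    out = signal
    for dim, bp in bpfs:
        if dim == "pitch":
            out = pitch_shift(out, bp)
        elif dim == "stretch":
            out = time_stretch(out, bp)
        elif dim == "gain":
            out = apply_gain(out, bp)
        else:
            raise ValueError(f"unknown transformation dimension {dim!r}")
    return out


def process_batch(base, config: BatchConfig) -> pd.DataFrame:
    """Generate ``config.numFiles`` randomized outputs from one base sound.

    Returns the manifest as a DataFrame (one row per written WAV, with its
    BPF log paths and seed) and writes it as ``manifest.csv`` in outPath.
    """
    base_path = Path(base)
    signal = load_wav(base_path)
    out_dir = Path(config.outPath)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    run_id = f"{config.seed:08x}"
    stem = base_path.stem

    logger.info("batch run %s: %d files, transf=%s, chain=%s",
                run_id, config.numFiles, config.transf, config.chain)
    pad = max(len(str(config.numFiles)), 3)
    rows = []
    for index in range(1, config.numFiles + 1):
        if config.chain:
            current = signal
            bpf_paths = []
            for dim in config.transf:
                # chained stretches change the timeline: draw on current duration
                bp = bpfmod.generate_random_bpf(current.duration, config.specs[dim], rng)
                current = apply_chain(current, [(dim, bp)])
                bpf_path = out_dir / f"{stem}.{run_id}.{index:0{pad}d}.{dim}.bpf.txt"
                bp.save(bpf_path)
                bpf_paths.append(str(bpf_path))
            wav_path = out_dir / f"{stem}.{run_id}.{index:0{pad}d}.wav"
            _save_normalized(current, wav_path)
            rows.append({"file": str(wav_path), "seed": config.seed,
                         "transf": "+".join(config.transf),
                         "bpfs": ";".join(bpf_paths)})
        else:
            for dim in config.transf:
                bp = bpfmod.generate_random_bpf(signal.duration, config.specs[dim], rng)
                out = apply_chain(signal, [(dim, bp)])
                wav_path = out_dir / f"{stem}.{run_id}.{index:0{pad}d}.{dim}.wav"
                bpf_path = out_dir / f"{stem}.{run_id}.{index:0{pad}d}.{dim}.bpf.txt"
                bp.save(bpf_path)
                _save_normalized(out, wav_path)
                rows.append({"file": str(wav_path), "seed": config.seed,
                             "transf": dim, "bpfs": str(bpf_path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _save_normalized(signal: AudioSignal, path) -> None:
    """Save, peak-normalizing only on overflow."""
    peak = np.max(np.abs(signal.samples)) if len(signal) else 0.0
    if peak > 1.0:
        signal = AudioSignal(signal.samples / peak, signal.rate)
    save_wav(signal, path)


# ---------------------------------------------------------------------------
# Case-study stimulus recipes


@dataclass
class SpeechPitchRecipe:
    """Flatten pitch, add a constant +-offset, then ramp Gaussian pitch noise."""

    n_points: int = 6
    noise_std: float = 70.0  # cents
    trunc: float = 2.2
    offset_cents: float = 20.0
    offset_sign: int | None = None  # +1 / -1; None draws from rng


@dataclass
class MelodyStretchRecipe:
    """Equalize note durations, then square Gaussian stretch noise per note."""

    onsets: tuple = ()  # note onset times, seconds
    noise_std: float = 0.4
    trunc: float = 1.6
    transition_time: float = 0.1


def make_case_study_stimulus(base: AudioSignal, recipe, rng):
    """Build one randomized stimulus following a case-study recipe.

    Returns ``(signal, profile)`` where ``profile`` is the vector of sampled
    noise values (the quantity entering the response table).
    """
    if isinstance(recipe, SpeechPitchRecipe):
        contour = estimate_pitch_contour(base)
        flat_bpf = flatten_pitch_bpf(contour, target="mean")
        flat = pitch_shift(base, flat_bpf)
        sign = recipe.offset_sign if recipe.offset_sign is not None else int(rng.choice([-1, 1]))
        spec = TransformSpec(dimension="pitch", numWin=recipe.n_points, winUnit="n",
                             std=recipe.noise_std, trunc=recipe.trunc, BPFtype="ramp")
        noise_bpf = bpfmod.generate_random_bpf(flat.duration, spec, rng)
        shifted_bpf = BreakpointFunction(
            noise_bpf.times, noise_bpf.values + sign * recipe.offset_cents,
            kind="ramp", dimension="pitch")
        out = pitch_shift(flat, shifted_bpf)
        return out, noise_bpf.values.copy()

    if isinstance(recipe, MelodyStretchRecipe):
        onsets = np.asarray(recipe.onsets, dtype=np.float64)
        if onsets.size == 0:
            raise ValueError("MelodyStretchRecipe requires note onsets")
        edges = np.concatenate([onsets, [base.duration]])
        durations = np.diff(edges)
        target = durations.mean()
        # piecewise-constant per note, with boundaries exactly at note edges
        # (square BPFs put boundaries midway between breakpoints, which is
        # wrong for unequal notes) -> step-shaped ramp with 1 ms transitions
        eps = 1e-3
        kt = np.ravel(np.column_stack([edges[:-1] + eps, edges[1:] - eps]))
        kv = np.repeat(target / durations, 2)
        eq_bpf = BreakpointFunction(kt, kv, kind="ramp", dimension="stretch")
        equalized = time_stretch(base, eq_bpf)
        n_notes = len(onsets)
        spec = TransformSpec(dimension="stretch", numWin=n_notes, winUnit="n",
                             std=recipe.noise_std, trunc=recipe.trunc,
                             BPFtype="square", trTime=recipe.transition_time)
        noise_bpf = bpfmod.generate_random_bpf(equalized.duration, spec, rng)
        out = time_stretch(equalized, noise_bpf)
        return out, noise_bpf.values.copy()

    raise TypeError(f"unknown recipe type {type(recipe).__name__}")
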