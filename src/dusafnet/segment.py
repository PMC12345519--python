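"""Audio normalization and voiced-segment extraction.

Raw recordings of any rate/channel layout are normalized to 16 kHz mono,
scanned with a two-threshold (hysteresis) energy voice-activity detector,
and tiled into exactly-3-s voiced segments.  A per-species balancing cap
and a stratified 70:30 split produce the train/test corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 16_000

__all__ = [
    "Waveform",
    "VadConfig",
    "Segment",
    "load_wav",
    "resample_mono",
    "frame_energy",
    "vad_regions",
    "regions_to_samples",
    "cut_segments",
    "extract_segments",
    "balance_corpus",
    "split_dataset",
    "stratified_split_counts",
]


@dataclass
class Waveform:
    """Mono samples in [-1, 1] at a known rate."""

    samples: np.ndarray
    rate: int = TARGET_RATE


@dataclass(frozen=True)
class VadConfig:
    """Two-threshold energy VAD parameters.

    ``frame_len``/``hop`` are in samples (25 ms / 10 ms at 16 kHz).  A
    frame with energy above ``t_high`` seeds a voiced region, which is
    extended forward and backward over all connected frames whose energy
    exceeds ``t_low``.  The frame energy is the mean square of the frame
    (``use_rms=True`` takes its square root instead; the thresholds here
    are calibrated for the mean-square convention).
    """

    frame_len: int = 400
    hop: int = 160
    t_high: float = 0.002
    t_low: float = 0.0005
    use_rms: bool = False

    def __post_init__(self):
        if not (0 < self.t_low < self.t_high):
            raise ValueError("need 0 < t_low < t_high")
        if not (self.frame_len > self.hop > 0):
            raise ValueError("need frame_len > hop > 0")


@dataclass(frozen=True)
class Segment:
    """Exactly 3 s of voiced audio with its species label and provenance."""

    samples: np.ndarray
    label: str
    source: str
    offset: int  # start sample in the source waveform

    def __post_init__(self):
        if len(self.samples) != 3 * TARGET_RATE:
            raise ValueError("segment must hold exactly 3 s at 16 kHz")


def load_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file to float64 in [-1, 1] (any rate, any channel count)."""
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"empty audio: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, rate


def resample_mono(audio: np.ndarray, rate: int, target_rate: int = TARGET_RATE) -> Waveform:
    """Channel-mean to mono and polyphase-resample to ``target_rate``.

    Duration is preserved to within one sample.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0:
        raise ValueError("empty audio")
    if audio.ndim == 2:
        audio = audio.mean(axis=1)
    elif audio.ndim != 1:
        raise ValueError("audio must be 1-D or 2-D (samples x channels)")
    if rate != target_rate:
        frac = Fraction(target_rate, rate).limit_denominator(10_000)
        audio = resample_poly(audio, frac.numerator, frac.denominator)
    return Waveform(samples=audio, rate=target_rate)


def frame_energy(wave: Waveform, cfg: VadConfig = VadConfig()) -> np.ndarray:
    """Per-frame energy E(n) = (1/L) * sum x^2 over hop-advanced frames.

    Frames lie fully inside the signal (no padding); a waveform shorter
    than one frame yields an empty sequence.
    """
    x = np.asarray(wave.samples, dtype=np.float64)
    L, hop = cfg.frame_len, cfg.hop
    if len(x) < L:
        return np.empty(0)
    n_frames = 1 + (len(x) - L) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(L)[None, :]
    e = np.mean(x[idx] ** 2, axis=1)
    return np.sqrt(e) if cfg.use_rms else e


def vad_regions(energy: np.ndarray, cfg: VadConfig = VadConfig()) -> list[tuple[int, int]]:
    """Maximal voiced frame intervals ``[start, end)`` from a hysteresis VAD.

    Every returned interval contains at least one frame with
    ``E > t_high`` and consists entirely of frames with ``E > t_low``.
    Intervals are sorted and disjoint; no high-energy frame -> empty list.
    """
    energy = np.asarray(energy)
    if energy.size == 0:
        return []
    above_low = energy > cfg.t_low
    above_high = energy > cfg.t_high
    if not above_high.any():
        return []
    # boundaries of runs of above_low frames
    padded = np.concatenate(([False], above_low, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if above_high[s:e].any()]


def regions_to_samples(
    regions: list[tuple[int, int]], cfg: VadConfig = VadConfig(), n_samples: int | None = None
) -> list[tuple[int, int]]:
    """Map frame intervals to sample intervals ``[start, end)``.

    A frame interval ``[f0, f1)`` covers samples ``[f0*hop,
    (f1-1)*hop + frame_len)``, clipped to the waveform length.
    """
    out = []
    for f0, f1 in regions:
        s0 = f0 * cfg.hop
        s1 = (f1 - 1) * cfg.hop + cfg.frame_len
        if n_samples is not None:
            s1 = min(s1, n_samples)
        out.append((s0, s1))
    return out


def cut_segments(
    wave: Waveform,
    sample_regions: list[tuple[int, int]],
    label: str = "",
    source: str = "",
    window_s: float = 3.0,
) -> list[Segment]:
    """Tile each voiced region with consecutive non-overlapping 3-s windows.

    Windows start at the region start; the trailing remainder (< 3 s) is
    discarded, so regions shorter than 3 s yield nothing.
    """
    win = int(round(window_s * wave.rate))
    segs = []
    for s0, s1 in sample_regions:
        n = (s1 - s0) // win
        for k in range(n):
            a = s0 + k * win
            segs.append(
                Segment(samples=wave.samples[a : a + win].copy(), label=label, source=source, offset=a)
            )
    return segs


def extract_segments(
    path: str | Path, label: str, cfg: VadConfig = VadConfig()
) -> list[Segment]:
    """Full per-file pipeline: load -> 16 kHz mono -> VAD -> 3-s windows."""
    data, rate = load_wav(path)
    wave = resample_mono(data, rate)
    energy = frame_energy(wave, cfg)
    frames = vad_regions(energy, cfg)
    regions = regions_to_samples(frames, cfg, n_samples=len(wave.samples))
    return cut_segments(wave, regions, label=label, source=str(path))


def balance_corpus(segments: list[Segment], cap: int = 1000) -> list[Segment]:
    """Keep at most ``cap`` segments per species, in (source, offset) order."""
    by_label: dict[str, list[Segment]] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg)
    kept = []
    for label in sorted(by_label):
        group = sorted(by_label[label], key=lambda s: (s.source, s.offset))
        kept.extend(group[:cap])
    return kept


def _train_count(n: int, train_frac: float) -> int:
    # round half up on the train side: 804 -> 563, 919 -> 643
    return int(np.floor(n * train_frac + 0.5))


def stratified_split_counts(counts: dict[str, int], train_frac: float = 0.7) -> dict[str, tuple[int, int]]:
    """Per-species (train, test) counts under the round-half-up rule."""
    return {k: (_train_count(n, train_frac), n - _train_count(n, train_frac)) for k, n in counts.items()}


def split_dataset(
    segments: list, train_frac: float = 0.7, seed: int = 1337
) -> tuple[list, list]:
    """Seeded stratified split: per species, ``round_half_up(frac*n)`` go to train.

    Membership is chosen by a seeded shuffle within each species; the two
    returned lists partition the input.  Items need only a ``label``
    attribute.  Species with zero segments are skipped with a warning.
    """
    import warnings

    by_label: dict[str, list] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        if not group:
            warnings.warn(f"species {label!r} has no segments; excluded")
            continue
        order = rng.permutation(len(group))
        n_train = _train_count(len(group), train_frac)
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test
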