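"""Synthetic multi-species call corpora.

Field recordings of bird calls are, to a first approximation, bouts of
tonal syllables -- a fundamental plus a small harmonic stack, often with a
slow linear frequency sweep -- separated by gaps in which only the ambient
noise floor remains.  This module generates WAV corpora with exactly that
structure so the whole pipeline (energy VAD, 3-s windowing, log-Mel
features, the network) can be exercised end to end without any real data.

Species are separable by construction: each species occupies its own
fundamental-frequency band, disjoint from every other species' band.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

SAMPLE_RATE = 16_000
#: clips are peak-normalized to this full-scale fraction before writing so
#: that the absolute VAD thresholds (0.002 / 0.0005) are meaningful.
PEAK_NORM = 0.5

__all__ = ["SyntheticCallSpec", "synth_call", "synth_corpus", "SAMPLE_RATE", "PEAK_NORM"]


@dataclass(frozen=True)
class SyntheticCallSpec:
    """Parameters of one synthetic clip.

    Attributes
    ----------
    species_id : int
        Integer class label.
    f0 : float
        Fundamental frequency in Hz.
    n_harmonics : int
        Number of harmonic partials (>= 1); partial k sits at ``k * f0``
        with amplitude ``1/k``.
    chirp_rate : float
        Linear sweep of the fundamental in Hz/s (0 for a steady tone).
    syllable_dur : float
        Duration of one syllable in seconds.
    gap_dur : float
        Silence (noise-floor only) between consecutive syllables, seconds.
    snr_db : float
        Syllable-to-noise power ratio in dB.
    total_dur : float
        Clip length in seconds.
    sample_rate : int
        Sampling rate in Hz.
    """

    species_id: int
    f0: float
    n_harmonics: int = 2
    chirp_rate: float = 0.0
    syllable_dur: float = 3.5
    gap_dur: float = 1.0
    snr_db: float = 30.0
    total_dur: float = 10.0
    sample_rate: int = SAMPLE_RATE

    def validate(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        top = self.f0 * self.n_harmonics + abs(self.chirp_rate) * self.syllable_dur * self.n_harmonics
        if top >= self.sample_rate / 2:
            raise ValueError(
                f"aliasing: highest partial {top:.0f} Hz >= Nyquist {self.sample_rate / 2:.0f} Hz"
            )
        if self.syllable_dur <= 0:
            raise ValueError("syllable_dur must be > 0")
        if self.total_dur < self.syllable_dur:
            raise ValueError("total_dur must be >= syllable_dur")
        if self.gap_dur < 0:
            raise ValueError("gap_dur must be >= 0")


def _syllable(spec: SyntheticCallSpec, n: int) -> np.ndarray:
    """One harmonic-stack syllable of ``n`` samples, unit peak-ish amplitude."""
    t = np.arange(n) / spec.sample_rate
    # instantaneous phase of the fundamental: f0*t + 0.5*chirp*t^2
    phase0 = spec.f0 * t + 0.5 * spec.chirp_rate * t * t
    sig = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        sig += np.sin(2.0 * np.pi * k * phase0) / k
    # 10 ms cosine ramps to avoid clicks at syllable edges
    ramp = min(int(0.010 * spec.sample_rate), n // 2)
    if ramp > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        sig[:ramp] *= win
        sig[-ramp:] *= win[::-1]
    return sig


def synth_call(spec: SyntheticCallSpec, seed: int) -> np.ndarray:
    """Render one clip: syllables over a stationary white-Gaussian noise floor.

    The clip starts with ``gap_dur`` of noise, then alternates syllable /
    gap; a syllable is emitted only if it fits completely before
    ``total_dur``.  Syllable amplitude is scaled so that the ratio of
    syllable power to noise power equals ``snr_db``.  Deterministic for a
    fixed ``(spec, seed)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_total = int(round(spec.total_dur * spec.sample_rate))
    noise_sigma = 0.01
    out = rng.standard_normal(n_total) * noise_sigma

    n_syl = int(round(spec.syllable_dur * spec.sample_rate))
    n_gap = int(round(spec.gap_dur * spec.sample_rate))
    syl = _syllable(spec, n_syl)
    syl_power = float(np.mean(syl**2))
    if syl_power > 0:
        target = noise_sigma**2 * 10.0 ** (spec.snr_db / 10.0)
        syl = syl * np.sqrt(target / syl_power)

    pos = n_gap
    while pos + n_syl <= n_total:
        out[pos : pos + n_syl] += syl
        pos += n_syl + n_gap
    return out.astype(np.float64)


def _species_specs(n_species: int, rng: np.random.Generator) -> list[dict]:
    """Per-species parameter ranges with disjoint fundamental bands."""
    specs = []
    for i in range(n_species):
        f0 = 700.0 + 550.0 * i
        nh = 2 if 2 * (f0 + 600.0) < SAMPLE_RATE / 2 else 1
        specs.append({"species_id": i, "f0": f0, "n_harmonics": nh})
    return specs


def synth_corpus(
    n_species: int,
    clips_per_species: int,
    out_dir: str | Path,
    seed: int,
    total_dur: float = 10.0,
) -> Path:
    """Write a WAV corpus plus a ``path,species`` CSV manifest.

    Per-clip parameters (chirp, syllable/gap durations, SNR, noise
    realization) are drawn deterministically from ``seed``.  Syllables are
    longer than the 3-s classification window and gap noise falls below
    the low VAD threshold after peak normalization, so every clip contains
    both voiced regions that survive windowing and genuinely silent frames.

    Returns the manifest path.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    species = _species_specs(n_species, master)

    rows = []
    for sp in species:
        sp_dir = out_dir / f"species_{sp['species_id']:02d}"
        sp_dir.mkdir(exist_ok=True)
        for c in range(clips_per_species):
            spec = SyntheticCallSpec(
                species_id=sp["species_id"],
                f0=sp["f0"] + master.uniform(-60.0, 60.0),
                n_harmonics=sp["n_harmonics"],
                chirp_rate=master.uniform(-150.0, 150.0),
                syllable_dur=master.uniform(3.2, 3.8),
                gap_dur=master.uniform(0.8, 1.4),
                snr_db=master.uniform(26.0, 34.0),
                total_dur=total_dur,
            )
            clip_seed = int(master.integers(0, 2**31 - 1))
            wave = synth_call(spec, clip_seed)
            peak = np.max(np.abs(wave))
            if peak > 0:
                wave = wave * (PEAK_NORM / peak)
            path = sp_dir / f"clip_{c:03d}.wav"
            wavfile.write(path, SAMPLE_RATE, (wave * 32767.0).astype(np.int16))
            rows.append((str(path), sp["species_id"]))

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "species"])
        w.writerows(rows)
    return manifest


def corpus_checksum(manifest: str | Path) -> str:
    """SHA-256 over the manifest and every referenced WAV (determinism checks)."""
    h = hashlib.sha256()
    manifest = Path(manifest)
    h.update(manifest.read_bytes())
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            h.update(Path(row["path"]).read_bytes())
    return h.hexdigest()
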