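"""Log-Mel spectrogram images and training-time augmentation.

A 3-s, 16 kHz segment becomes a 128 x 298 log-Mel matrix in dB
(25 ms Hann window, 10 ms hop, 512-point FFT, no centering), which is
min-max rendered to a 224 x 224 8-bit image (low frequencies at the
bottom row).  Training applies SpecAugment (one frequency mask + one time
mask) and image-level rotation / random-resized-crop / horizontal flip,
then per-channel normalization to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import rotate as nd_rotate
from scipy.signal.windows import hann

N_MELS = 128
N_FFT = 512
WIN_LEN = 400
HOP = 160
SEG_SAMPLES = 48_000
N_FRAMES = 1 + (SEG_SAMPLES - WIN_LEN) // HOP  # 298
IMG_SIZE = 224
LOG_EPS = 1e-10
DB_FLOOR = 10.0 * np.log10(LOG_EPS)  # -100 dB

__all__ = [
    "AugmentConfig",
    "stft_power",
    "mel_filterbank",
    "mel_project",
    "log_compress",
    "segment_logmel",
    "render_image",
    "spec_augment",
    "image_augment",
    "segment_to_image",
    "N_MELS",
    "N_FRAMES",
    "DB_FLOOR",
    "IMG_SIZE",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters: mask widths are upper bounds (inclusive)."""

    f_max: int = 16  # max Mel-mask width, bins
    tau_max: int = 20  # max time-mask width, frames
    rot_deg: float = 20.0
    crop_scale: tuple[float, float] = (0.8, 1.0)
    hflip_p: float = 0.5


def stft_power(samples: np.ndarray, sample_rate: int = 16_000) -> np.ndarray:
    """Power spectrogram |X|^2, shape (257, 298) for a 3-s segment.

    Hann window of 400 samples, hop 160, 512-point FFT, frames fully
    inside the segment (no padding).
    """
    x = np.asarray(samples, dtype=np.float64)
    if len(x) != SEG_SAMPLES:
        raise ValueError(f"expected {SEG_SAMPLES} samples, got {len(x)}")
    n_frames = 1 + (len(x) - WIN_LEN) // HOP
    idx = HOP * np.arange(n_frames)[:, None] + np.arange(WIN_LEN)[None, :]
    frames = x[idx] * hann(WIN_LEN, sym=False)[None, :]
    spec = np.fft.rfft(frames, n=N_FFT, axis=1)  # (T, 257)
    return np.abs(spec.T) ** 2  # (F, T)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int = N_MELS,
    n_fft: int = N_FFT,
    sample_rate: int = 16_000,
    f_min: float = 0.0,
    f_max: float | None = None,
) -> np.ndarray:
    """Triangular Mel filterbank, shape (n_mels, n_fft//2 + 1).

    Filter centers are equally spaced on the Mel scale between ``f_min``
    and ``f_max`` (defaults to Nyquist); each filter is a unit-peak
    triangle over the linear-frequency FFT bins.
    """
    if f_max is None:
        f_max = sample_rate / 2.0
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_mels + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(n_mels):
        lo, ctr, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


_FB_CACHE: dict[tuple, np.ndarray] = {}


def mel_project(power: np.ndarray, n_mels: int = N_MELS, sample_rate: int = 16_000) -> np.ndarray:
    """Project a power spectrogram onto the Mel filterbank: S = M @ P."""
    key = (n_mels, power.shape[0], sample_rate)
    if key not in _FB_CACHE:
        _FB_CACHE[key] = mel_filterbank(n_mels, (power.shape[0] - 1) * 2, sample_rate)
    return _FB_CACHE[key] @ power


def log_compress(mel: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    """dB compression: 10*log10(S + eps); zero power maps to -100 dB."""
    return 10.0 * np.log10(np.asarray(mel) + eps)


def segment_logmel(samples: np.ndarray) -> np.ndarray:
    """Segment -> 128 x 298 log-Mel matrix in dB."""
    return log_compress(mel_project(stft_power(samples)))


def render_image(logmel: np.ndarray) -> np.ndarray:
    """Render a log-Mel matrix to a 224 x 224 uint8 image.

    Min-max scaled to [0, 255] (a constant input renders mid-gray),
    flipped so low frequencies sit at the bottom row, and bilinearly
    resized.  PNG round trips of the result are lossless.
    """
    logmel = np.asarray(logmel, dtype=np.float64)
    if not np.isfinite(logmel).all():
        raise ValueError("non-finite log-Mel input")
    lo, hi = logmel.min(), logmel.max()
    if hi - lo < 1e-12:
        scaled = np.full(logmel.shape, 128, dtype=np.uint8)
    else:
        scaled = np.round((logmel - lo) / (hi - lo) * 255.0).astype(np.uint8)
    scaled = scaled[::-1]  # row 0 of the matrix is the lowest Mel band
    img = Image.fromarray(scaled).resize((IMG_SIZE, IMG_SIZE), Image.BILINEAR)
    return np.asarray(img)


def spec_augment(
    spec: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    fill: float | None = None,
) -> np.ndarray:
    """One frequency mask then one time mask on a 2-D representation.

    Mask widths are drawn uniformly from {0..f_max} / {0..tau_max} and
    masked cells are set to the representation's floor (``-100`` dB for a
    log-Mel matrix, ``0`` for an 8-bit image) unless ``fill`` overrides it.
    Works on either the dB matrix or the rendered grayscale image.
    """
    spec = np.asarray(spec)
    M, T = spec.shape
    if cfg.f_max > M or cfg.tau_max > T:
        raise ValueError("mask bounds exceed representation size")
    if fill is None:
        fill = 0 if spec.dtype == np.uint8 else DB_FLOOR
    out = spec.copy()
    f = int(rng.integers(0, cfg.f_max + 1))
    m0 = int(rng.integers(0, M - f + 1))
    out[m0 : m0 + f, :] = fill
    tau = int(rng.integers(0, cfg.tau_max + 1))
    t0 = int(rng.integers(0, T - tau + 1))
    out[:, t0 : t0 + tau] = fill
    return out


def _normalize(img3: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float32 3xHxW in [-1, 1]."""
    x = img3.astype(np.float32) / 255.0 * 2.0 - 1.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def image_augment(
    img: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
    train: bool = False,
) -> np.ndarray:
    """224 x 224 image -> normalized float32 tensor (3, 224, 224) in [-1, 1].

    Training mode: rotation in [-rot_deg, rot_deg] with reflection
    padding, random area crop (scale in ``crop_scale``) resized back to
    224, and horizontal flip with probability ``hflip_p``.  Eval mode:
    resize + normalization only.  A single-channel input is replicated to
    three channels after the geometric transforms.
    """
    img = np.asarray(img)
    if img.ndim == 3:
        gray = img[..., 0]
    else:
        gray = img
    if gray.shape != (IMG_SIZE, IMG_SIZE):
        gray = np.asarray(Image.fromarray(gray).resize((IMG_SIZE, IMG_SIZE), Image.BILINEAR))
    if train:
        if rng is None:
            raise ValueError("training augmentation requires an rng")
        angle = rng.uniform(-cfg.rot_deg, cfg.rot_deg)
        g = nd_rotate(gray.astype(np.float32), angle, reshape=False, mode="reflect", order=1)
        scale = rng.uniform(*cfg.crop_scale)
        side = max(1, int(round(IMG_SIZE * np.sqrt(scale))))
        y0 = int(rng.integers(0, IMG_SIZE - side + 1))
        x0 = int(rng.integers(0, IMG_SIZE - side + 1))
        g = g[y0 : y0 + side, x0 : x0 + side]
        g = np.asarray(
            Image.fromarray(np.clip(g, 0, 255).astype(np.uint8)).resize(
                (IMG_SIZE, IMG_SIZE), Image.BILINEAR
            )
        )
        if rng.random() < cfg.hflip_p:
            g = g[:, ::-1]
        gray = g
    img3 = np.repeat(gray[..., None], 3, axis=2)
    return _normalize(img3)


def segment_to_image(samples: np.ndarray) -> np.ndarray:
    """Segment -> rendered 224 x 224 uint8 spectrogram image (eval chain)."""
    return render_image(segment_logmel(samples))
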