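"""Stimulus preparation: grayscale standardization and Fourier phase-noise corruption.

Images are represented as :class:`GrayImage` objects holding a float grid in
``[0, 1]``.  Noise is injected in the Fourier domain: the magnitude spectrum of
every stimulus is replaced by the average magnitude of the whole image set, and
the phase is a weighted mixture of the original phase and an i.i.d. uniform
random phase field, the weight being the noise level.  This corrupts image
structure while holding low-level spectral statistics fixed across stimuli —
the standard phase-scrambling manipulation of visual psychophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

__all__ = [
    "GrayImage",
    "MagnitudeSpectrum",
    "standardize",
    "average_magnitude",
    "make_phase_noise",
    "random_phase_field",
    "mixed_phase_spectrum",
    "load_image",
    "save_png",
]


@dataclass
class GrayImage:
    """A 2-D grayscale stimulus with intensities in [0, 1]."""

    pixels: np.ndarray
    label: str | None = None
    noise_level: float | None = None
    bit_depth: int = 8
    image_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("GrayImage intensities must be finite")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("GrayImage intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MagnitudeSpectrum:
    """Entrywise-mean 2-D Fourier magnitude of a set of same-shaped images."""

    magnitudes: np.ndarray
    n_images: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.ndim != 2 or np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("magnitudes must be a finite non-negative 2-D grid")
        self.magnitudes = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape


def standardize(
    raw_image: np.ndarray,
    target_height: int = 300,
    target_width: int = 450,
    label: str | None = None,
    image_id: str | None = None,
) -> GrayImage:
    """Collapse to luminance, rescale to [0, 1], resize preserving aspect ratio,
    and zero-pad symmetrically to exactly ``(target_height, target_width)``.
    """
    raw = np.asarray(raw_image)
    if raw.size == 0 or raw.ndim not in (2, 3):
        raise ValueError("raw image must be a non-empty 2-D or 3-D array")
    if target_height <= 0 or target_width <= 0:
        raise ValueError("target dimensions must be positive")
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop alpha
            raw = raw[..., :3]
        gray = rgb2gray(raw)
    else:
        gray = raw.astype(float)
        if np.issubdtype(raw.dtype, np.integer):
            gray = gray / np.iinfo(raw.dtype).max
    gray = np.clip(gray, 0.0, 1.0)

    h, w = gray.shape
    scale = min(target_height / h, target_width / w)
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    content = resize(gray, (new_h, new_w), anti_aliasing=new_h < h, mode="reflect")

    out = np.zeros((target_height, target_width), dtype=float)
    top = (target_height - new_h) // 2
    left = (target_width - new_w) // 2
    out[top : top + new_h, left : left + new_w] = np.clip(content, 0.0, 1.0)
    return GrayImage(out, label=label, image_id=image_id)


def average_magnitude(images: list[GrayImage]) -> MagnitudeSpectrum:
    """Entrywise mean of the 2-D FFT magnitude over a set of images."""
    if not images:
        raise ValueError("need at least one image to average magnitudes")
    shape = images[0].shape
    total = np.zeros(shape, dtype=float)
    for im in images:
        if im.shape != shape:
            raise ValueError(f"shape mismatch: {im.shape} != {shape}")
        total += np.abs(np.fft.fft2(im.pixels))
    return MagnitudeSpectrum(total / len(images), n_images=len(images))


def _self_conjugate_mask(shape: tuple[int, int]) -> np.ndarray:
    """Frequencies that are their own conjugate partner (DC and Nyquist lines)."""
    h, w = shape
    i = np.arange(h)[:, None]
    j = np.arange(w)[None, :]
    return ((-i) % h == i) & ((-j) % w == j)


def random_phase_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform phases on (-pi, pi], made conjugate-antisymmetric.

    Each frequency/its mirror pair shares one uniform draw with opposite signs,
    so a spectrum built from these phases inverts to a real image.
    Self-conjugate frequencies get phase 0.
    """
    h, w = shape
    u = rng.uniform(-np.pi, np.pi, size=shape)
    i = np.arange(h)[:, None] * np.ones((1, w), dtype=int)
    j = np.ones((h, 1), dtype=int) * np.arange(w)[None, :]
    mi, mj = (-i) % h, (-j) % w
    upper = (i < mi) | ((i == mi) & (j < mj))
    phi = np.where(upper, u, -u[mi, mj])
    phi[_self_conjugate_mask(shape)] = 0.0
    return phi


def mixed_phase_spectrum(
    image: GrayImage,
    avg_mag: MagnitudeSpectrum,
    noise_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Complex spectrum with the average magnitude and a noise-mixed phase.

    The noisy phase is the linear combination
    ``(1 - noise_level) * phase(image) + noise_level * random_phase`` wrapped
    back into (-pi, pi].  Self-conjugate frequencies (including DC) keep the
    original phase so mean luminance and realness are preserved.
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError(f"noise_level must be in [0, 1], got {noise_level}")
    if image.shape != avg_mag.shape:
        raise ValueError("image and magnitude spectrum shapes differ")
    spectrum = np.fft.fft2(image.pixels)
    phi = np.angle(spectrum)
    phi_rand = random_phase_field(image.shape, rng)
    mixed = (1.0 - noise_level) * phi + noise_level * phi_rand
    mixed = np.angle(np.exp(1j * mixed))  # wrap into (-pi, pi]
    keep = _self_conjugate_mask(image.shape)
    mixed[keep] = phi[keep]
    return avg_mag.magnitudes * np.exp(1j * mixed)


def make_phase_noise(
    image: GrayImage,
    avg_mag: MagnitudeSpectrum,
    noise_level: float,
    seed: int | np.random.Generator,
) -> GrayImage:
    """Phase-scrambled stimulus at the given noise level.

    Deterministic for a fixed seed; the inverse transform's real part is
    clipped to [0, 1] (8-bit quantization happens only on export).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = mixed_phase_spectrum(image, avg_mag, noise_level, rng)
    out = np.clip(np.fft.ifft2(spec).real, 0.0, 1.0)
    return GrayImage(
        out, label=image.label, noise_level=noise_level, image_id=image.image_id
    )


def load_image(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def save_png(image: GrayImage, path: str | Path) -> None:
    """Quantize to 8-bit grayscale and write a PNG."""
    q = np.round(np.clip(image.pixels, 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(Path(path), q)
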