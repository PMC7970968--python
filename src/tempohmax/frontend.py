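"""V1-like front end: multi-scale Gabor filtering, max pooling, latency coding.

The S1 stage convolves the stimulus, resized to five scales (100, 71, 50, 35,
25 percent), with four 5x5 zero-mean Gabor kernels (wavelength 5, width 2,
orientations 22.5/67.5/112.5/157.5 degrees) and rectifies the responses.  The
C1 stage max-pools each response map over 7x7 windows slid with a one-pixel
overlap (stride 6), shrinking each map to 1/6 of its linear size, then takes
the pixelwise maximum across the four orientations, remembering the winning
orientation.  Each surviving C1 activation v > epsilon emits one spike at
latency 1/v: strong local contrast fires early, weak contrast late.  The
time-sorted events, each tagged with (scale, row, col, orientation), form the
spike train passed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import correlate, maximum_filter
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .stimuli import GrayImage

__all__ = [
    "KernelBank",
    "S1Maps",
    "C1Maps",
    "SpikeTrain",
    "make_s1_kernels",
    "apply_s1",
    "apply_c1",
    "spikes_from_c1",
    "SpikeEncoder",
    "DEFAULT_ORIENTATIONS_DEG",
    "DEFAULT_SCALE_FACTORS",
]

DEFAULT_ORIENTATIONS_DEG = (22.5, 67.5, 112.5, 157.5)
DEFAULT_SCALE_FACTORS = (1.00, 0.71, 0.50, 0.35, 0.25)
POOL_WINDOW = 7
POOL_OVERLAP = 1
POOL_STRIDE = POOL_WINDOW - POOL_OVERLAP


@dataclass
class KernelBank:
    """Oriented zero-mean, unit-norm Gabor kernels."""

    kernels: np.ndarray  # (n_orientations, size, size)
    orientations_deg: tuple[float, ...]
    wavelength: float
    width: float

    @property
    def size(self) -> int:
        return self.kernels.shape[-1]


@dataclass
class S1Maps:
    """Rectified oriented-filter responses; ``maps[s]`` has shape (4, h_s, w_s)."""

    maps: list[np.ndarray]
    scale_factors: tuple[float, ...]
    source_shape: tuple[int, int]

    @property
    def n_maps(self) -> int:
        return sum(m.shape[0] for m in self.maps)


@dataclass
class C1Maps:
    """Pooled maps per scale with the per-position winning orientation.

    ``orientation_maps[s]`` keeps the spatially pooled map of every
    orientation (shape ``(4, oh, ow)``); ``maps[s]`` is their pixelwise
    maximum and ``winners[s]`` the argmax orientation index.
    """

    maps: list[np.ndarray]
    winners: list[np.ndarray]
    orientation_maps: list[np.ndarray]
    pool_window: int = POOL_WINDOW
    pool_overlap: int = POOL_OVERLAP

    @property
    def n_scales(self) -> int:
        return len(self.maps)


@dataclass
class SpikeTrain:
    """Time-sorted spike events tagged with (scale, row, col, orientation)."""

    times: np.ndarray
    scales: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    orientations: np.ndarray
    image_id: str | None = None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "scale": self.scales,
                "row": self.rows,
                "col": self.cols,
                "orientation": self.orientations,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, image_id: str | None = None) -> "SpikeTrain":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(float),
            scales=df["scale"].to_numpy(int),
            rows=df["row"].to_numpy(int),
            cols=df["col"].to_numpy(int),
            orientations=df["orientation"].to_numpy(int),
            image_id=image_id,
        )


def make_s1_kernels(
    wavelength: float = 5.0,
    width: float = 2.0,
    size: int = 5,
    orientations_deg: tuple[float, ...] = DEFAULT_ORIENTATIONS_DEG,
) -> KernelBank:
    """Build one zero-mean, L2-normalized Gabor kernel per orientation.

    A kernel of orientation theta prefers bars elongated along theta: the
    cosine carrier runs perpendicular to the bar axis, inside a circular
    Gaussian envelope of the given width.
    """
    if size <= 0 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    kernels = []
    for deg in orientations_deg:
        theta = np.deg2rad(deg)
        # coordinate across the preferred bar axis
        across = x * np.sin(theta) + y * np.cos(theta)
        envelope = np.exp(-(x**2 + y**2) / (2.0 * width**2))
        g = envelope * np.cos(2.0 * np.pi * across / wavelength)
        g -= g.mean()
        g /= np.linalg.norm(g)
        kernels.append(g)
    return KernelBank(
        kernels=np.stack(kernels),
        orientations_deg=tuple(orientations_deg),
        wavelength=wavelength,
        width=width,
    )


def _as_pixels(image: GrayImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)


def apply_s1(
    image: GrayImage | np.ndarray,
    bank: KernelBank,
    scale_factors: tuple[float, ...] = DEFAULT_SCALE_FACTORS,
) -> S1Maps:
    """Resize to each scale, filter with each kernel, rectify to magnitude."""
    px = _as_pixels(image)
    maps: list[np.ndarray] = []
    for s, factor in enumerate(scale_factors):
        h = int(round(px.shape[0] * factor))
        w = int(round(px.shape[1] * factor))
        if min(h, w) < bank.size:
            raise ValueError(
                f"image too small at scale index {s} (factor {factor}): "
                f"{h}x{w} < kernel {bank.size}x{bank.size}"
            )
        scaled = px if (h, w) == px.shape else resize(px, (h, w), anti_aliasing=True)
        responses = np.stack(
            [np.abs(correlate(scaled, k, mode="constant", cval=0.0)) for k in bank.kernels]
        )
        maps.append(responses)
    return S1Maps(maps=maps, scale_factors=tuple(scale_factors), source_shape=px.shape)


def _pool_map(m: np.ndarray) -> np.ndarray:
    """Max over 7x7 windows, stride 6, output floor(n/6) per dimension.

    Windows start at multiples of the stride; where a window overruns the map
    it reads replicated edge values, which is exactly what
    ``maximum_filter(mode='nearest')`` sampled at window centers computes.
    """
    h, w = m.shape
    oh, ow = h // POOL_STRIDE, w // POOL_STRIDE
    filt = maximum_filter(m, size=POOL_WINDOW, mode="nearest")
    centers_r = np.arange(oh) * POOL_STRIDE + POOL_WINDOW // 2
    centers_c = np.arange(ow) * POOL_STRIDE + POOL_WINDOW // 2
    return filt[np.ix_(centers_r, centers_c)]


def apply_c1(s1: S1Maps) -> C1Maps:
    """Two-stage C1 pooling: spatial 7x7/stride-6 max, then cross-orientation max."""
    maps, winners, orient_maps = [], [], []
    for s, responses in enumerate(s1.maps):
        h, w = responses.shape[1:]
        if min(h, w) < POOL_WINDOW:
            raise ValueError(
                f"S1 map at scale index {s} is {h}x{w}, smaller than the "
                f"{POOL_WINDOW}x{POOL_WINDOW} pooling window"
            )
        pooled = np.stack([_pool_map(responses[o]) for o in range(responses.shape[0])])
        orient_maps.append(pooled)
        winners.append(np.argmax(pooled, axis=0))  # ties -> lowest orientation index
        maps.append(np.max(pooled, axis=0))
    return C1Maps(maps=maps, winners=winners, orientation_maps=orient_maps)


def spikes_from_c1(
    c1: C1Maps, epsilon: float = 1e-6, image_id: str | None = None
) -> SpikeTrain:
    """Latency-code the pooled maps: activation v > epsilon spikes at time 1/v.

    Events are sorted by time; exact ties break by (scale, row, col,
    orientation) for reproducibility.
    """
    times, scales, rows, cols, orients = [], [], [], [], []
    for s, m in enumerate(c1.maps):
        r, c = np.nonzero(m > epsilon)
        if len(r) == 0:
            continue
        times.append(1.0 / m[r, c])
        scales.append(np.full(len(r), s, dtype=int))
        rows.append(r)
        cols.append(c)
        orients.append(c1.winners[s][r, c])
    if not times:
        empty = np.array([], dtype=float)
        z = np.array([], dtype=int)
        return SpikeTrain(empty, z, z, z, z, image_id=image_id)
    t = np.concatenate(times)
    sc = np.concatenate(scales)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    oo = np.concatenate(orients)
    order = np.lexsort((oo, cc, rr, sc, t))
    return SpikeTrain(t[order], sc[order], rr[order], cc[order], oo[order], image_id)


class SpikeEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping grayscale images to latency spike trains.

    Parameters mirror the front-end defaults: 5x5 Gabors of wavelength 5 and
    width 2 at four orientations, five image scales, reciprocal latency coding
    with activation floor ``epsilon``.
    """

    def __init__(
        self,
        wavelength: float = 5.0,
        width: float = 2.0,
        kernel_size: int = 5,
        orientations_deg: tuple[float, ...] = DEFAULT_ORIENTATIONS_DEG,
        scale_factors: tuple[float, ...] = DEFAULT_SCALE_FACTORS,
        epsilon: float = 1e-6,
    ):
        self.wavelength = wavelength
        self.width = width
        self.kernel_size = kernel_size
        self.orientations_deg = orientations_deg
        self.scale_factors = scale_factors
        self.epsilon = epsilon

    def fit(self, X=None, y=None) -> "SpikeEncoder":
        self.kernels_ = make_s1_kernels(
            self.wavelength, self.width, self.kernel_size, self.orientations_deg
        )
        return self

    def encode_one(self, image: GrayImage | np.ndarray) -> SpikeTrain:
        if not hasattr(self, "kernels_"):
            self.fit()
        s1 = apply_s1(image, self.kernels_, self.scale_factors)
        c1 = apply_c1(s1)
        image_id = image.image_id if isinstance(image, GrayImage) else None
        return spikes_from_c1(c1, epsilon=self.epsilon, image_id=image_id)

    def transform(self, X) -> list[SpikeTrain]:
        return [self.encode_one(im) for im in X]

    def c1_shapes(self, image_shape: tuple[int, int]) -> list[tuple[int, int]]:
        """Pooled-map shape per scale for a given input image shape."""
        shapes = []
        for factor in self.scale_factors:
            h = int(round(image_shape[0] * factor))
            w = int(round(image_shape[1] * factor))
            shapes.append((h // POOL_STRIDE, w // POOL_STRIDE))
        return shapes
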