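"""Procedural fixtures: two structured image categories and behavioral RT tables.

The image generator draws stylized, edge-rich "face" (elliptical head outline,
two eye dots, nose and mouth strokes) and "house" (rectangular walls, triangle
roofline, window grid, door) motifs with per-exemplar jitter in position,
scale and stroke intensity, then corrupts them with the same average-magnitude
phase-noise procedure applied to real stimuli.  The behavioral generator draws
per-trial reaction times that increase linearly in noise level with Gaussian
trial-to-trial variability and occasional lapses, emulating the structure of
a two-alternative psychophysics table without emulating any individual human.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse_perimeter, line, rectangle_perimeter

from .decision import BehaviorTable
from .stimuli import GrayImage, MagnitudeSpectrum, average_magnitude, make_phase_noise

__all__ = [
    "FixtureSpec",
    "SyntheticBehaviorSpec",
    "FixtureSet",
    "generate_images",
    "generate_behavior",
    "DEFAULT_NOISE_LEVELS",
]

# ten equally spaced levels, from clean to heavily scrambled
DEFAULT_NOISE_LEVELS = tuple(np.round(np.linspace(0.0, 0.9, 10), 2))


@dataclass
class FixtureSpec:
    categories: tuple[str, str] = ("face", "house")
    image_size: tuple[int, int] = (300, 450)
    n_per_category: int = 10
    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.categories) != 2:
            raise ValueError("exactly two categories required")
        if min(self.image_size) < 35:
            raise ValueError("image size must be at least 35x35")
        if self.n_per_category < 0:
            raise ValueError("n_per_category must be non-negative")


@dataclass
class SyntheticBehaviorSpec:
    base_rt_ms: dict = field(default_factory=lambda: {"face": 550.0, "house": 580.0})
    rt_slope_ms: float = 400.0
    rt_noise_sd: float = 80.0
    lapse_rate: float = 0.05
    n_trials: int = 20
    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    seed: int = 0


@dataclass
class FixtureSet:
    """Generated stimuli: clean motifs plus their phase-noise variants."""

    originals: list[GrayImage]
    noisy: list[GrayImage]
    avg_mag: MagnitudeSpectrum | None
    manifest: pd.DataFrame

    def at_level(self, level: float) -> list[GrayImage]:
        return [im for im in self.noisy if im.noise_level == level]


def _draw_face(canvas: np.ndarray, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    s = int(0.32 * min(h, w) * rng.uniform(0.85, 1.0))
    cy = h // 2 + int(rng.uniform(-0.05, 0.05) * h)
    cx = w // 2 + int(rng.uniform(-0.05, 0.05) * w)
    amp = rng.uniform(0.75, 1.0)
    for dr in (0, 1):  # head outline, two-pixel stroke
        rr, cc = ellipse_perimeter(cy, cx, s + dr, int(0.78 * s) + dr, shape=canvas.shape)
        canvas[rr, cc] = amp
    for side in (-1, 1):  # eyes
        rr, cc = disk((cy - int(0.35 * s), cx + side * int(0.33 * s)),
                      max(2, int(0.13 * s)), shape=canvas.shape)
        canvas[rr, cc] = amp
    rr, cc = line(cy - int(0.15 * s), cx, cy + int(0.25 * s), cx)  # nose
    canvas[rr, cc] = amp
    # mouth: lower arc of a small ellipse
    rr, cc = ellipse_perimeter(cy + int(0.45 * s), cx, int(0.25 * s),
                               int(0.45 * s), shape=canvas.shape)
    keep = rr > cy + int(0.45 * s)
    canvas[rr[keep], cc[keep]] = amp


def _draw_house(canvas: np.ndarray, rng: np.random.Generator) -> None:
    h, w = canvas.shape
    s = int(0.30 * min(h, w) * rng.uniform(0.85, 1.0))
    cy = h // 2 + int(rng.uniform(-0.05, 0.05) * h)
    cx = w // 2 + int(rng.uniform(-0.05, 0.05) * w)
    amp = rng.uniform(0.75, 1.0)
    top, bottom = cy - int(0.4 * s), cy + s
    left, right = cx - int(1.1 * s), cx + int(1.1 * s)
    for d in (0, 1):  # walls
        rr, cc = rectangle_perimeter((top - d, left - d), end=(bottom + d, right + d),
                                     shape=canvas.shape)
        canvas[rr, cc] = amp
    apex = (max(0, top - int(0.8 * s)), cx)
    for d in (0, 1):  # roofline
        rr, cc = line(apex[0] + d, apex[1], top + d, left)
        canvas[rr, cc] = amp
        rr, cc = line(apex[0] + d, apex[1], top + d, right)
        canvas[rr, cc] = amp
    # window grid: one framed window with a cross
    wl, wr = cx - int(0.8 * s), cx - int(0.25 * s)
    wt, wb = cy - int(0.15 * s), cy + int(0.4 * s)
    rr, cc = rectangle_perimeter((wt, wl), end=(wb, wr), shape=canvas.shape)
    canvas[rr, cc] = amp
    rr, cc = line((wt + wb) // 2, wl, (wt + wb) // 2, wr)
    canvas[rr, cc] = amp
    rr, cc = line(wt, (wl + wr) // 2, wb, (wl + wr) // 2)
    canvas[rr, cc] = amp
    # door
    rr, cc = rectangle_perimeter((cy + int(0.2 * s), cx + int(0.35 * s)),
                                 end=(bottom, cx + int(0.8 * s)), shape=canvas.shape)
    canvas[rr, cc] = amp


_MOTIFS = {"face": _draw_face, "house": _draw_house}


def _draw_motif(category_index: int, category: str, shape: tuple[int, int],
                rng: np.random.Generator) -> np.ndarray:
    canvas = np.zeros(shape, dtype=float)
    drawer = _MOTIFS.get(category, None)
    if drawer is None:  # unnamed categories map onto the two motif families
        drawer = _draw_face if category_index == 0 else _draw_house
    drawer(canvas, rng)
    return np.clip(gaussian_filter(canvas, sigma=0.8), 0.0, 1.0)


def generate_images(spec: FixtureSpec) -> FixtureSet:
    """Deterministic labeled image set with phase-noise variants at each level.

    Clean motifs are drawn per category with jittered geometry; the noisy
    variants substitute the set's own average magnitude spectrum and mix the
    phase with uniform noise, exactly as for real stimuli.
    """
    rng = np.random.default_rng(spec.seed)
    originals: list[GrayImage] = []
    rows = []
    for ci, cat in enumerate(spec.categories):
        for i in range(spec.n_per_category):
            image_id = f"{cat}_{i:03d}"
            px = _draw_motif(ci, cat, spec.image_size, rng)
            originals.append(GrayImage(px, label=cat, image_id=image_id))
            rows.append((image_id, cat, np.nan, spec.seed))
    noisy: list[GrayImage] = []
    avg = average_magnitude(originals) if originals else None
    if originals:
        for level in spec.noise_levels:
            for im in originals:
                noisy.append(make_phase_noise(im, avg, float(level), rng))
                rows.append((im.image_id, im.label, float(level), spec.seed))
    manifest = pd.DataFrame(rows, columns=["filename", "label", "noise_level", "seed"])
    return FixtureSet(originals=originals, noisy=noisy, avg_mag=avg, manifest=manifest)


def generate_behavior(spec: SyntheticBehaviorSpec) -> BehaviorTable:
    """Per-trial RT table with mean RT linear in noise level.

    rt ~ base[category] + slope * level + N(0, sd), truncated positive;
    lapse trials flip the recorded choice.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    cats = sorted(spec.base_rt_ms)
    for level in spec.noise_levels:
        for cat in cats:
            mean = spec.base_rt_ms[cat] + spec.rt_slope_ms * float(level)
            for k in range(spec.n_trials):
                rt = rng.normal(mean, spec.rt_noise_sd) if spec.rt_noise_sd > 0 else mean
                while rt <= 0:
                    rt = rng.normal(mean, spec.rt_noise_sd)
                lapse = rng.uniform() < spec.lapse_rate
                other = [c for c in cats if c != cat][0]
                choice = other if lapse else cat
                rows.append(
                    (f"{cat}_{k:03d}", float(level), cat, choice, rt, choice == cat)
                )
    trials = pd.DataFrame(
        rows,
        columns=["image_id", "noise_level", "category", "choice", "rt_ms", "correct"],
    )
    return BehaviorTable.from_trials(trials)
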