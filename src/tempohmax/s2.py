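"""Category-selective integrate-and-fire layer trained with simplified STDP.

Each S2 cell holds one weight per C1 afferent, i.e. per (scale, row, col,
orientation) site.  During training the afferent events of one image are
replayed in latency order; every cell of the trained category integrates the
weight of each arriving afferent, and the first cell to reach its training
threshold fires once (one-winner-take-all per presentation).  The winner's
synapses update by the simplified STDP rule with multiplicative soft bounds:

    causal afferents (spiked at or before the postsynaptic spike):
        w <- w + a_plus  * w * (1 - w)
    all other synapses:
        w <- w - a_minus * w * (1 - w)

so weights stay in [0, 1] and converge toward a binary template of the
earliest, most reliable afferents of the category.

At inference the firing threshold is lowered by ``threshold_factor`` and the
membrane potential resets after every spike, so each cell emits a whole spike
train per image rather than a single spike; there is no competition, and all
cells of both categories respond to every stimulus.  These trains are the
temporal evidence streams consumed by the decision layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .decision import RateSeries
from .frontend import SpikeTrain

__all__ = [
    "S2Population",
    "S2SpikeTrain",
    "init_population",
    "calibrate_thresholds",
    "stdp_train",
    "infer_spikes",
    "base_model_first_spikes",
    "population_rate",
    "STDPLayer",
    "save_population",
    "load_population",
]

_ARCHIVE_VERSION = 1


@dataclass
class S2SpikeTrain:
    """Per-cell output spike times for one stimulus."""

    spike_times: list[np.ndarray]
    categories: list[str]
    image_id: str | None = None

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.spike_times])

    def category_times(self, category: str) -> np.ndarray:
        pooled = [
            t for t, c in zip(self.spike_times, self.categories) if c == category
        ]
        return np.sort(np.concatenate(pooled)) if pooled else np.array([])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (times, cat) in enumerate(zip(self.spike_times, self.categories)):
            for t in times:
                rows.append((i, cat, t))
        return pd.DataFrame(rows, columns=["cell_id", "category", "time"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


class S2Population:
    """A bank of S2 cells with flat per-afferent weight vectors.

    Weights are stored as a ``(n_cells, n_afferents)`` matrix; afferent index
    enumerates (scale, row, col, orientation) sites of the C1 maps.  With
    ``orientation_sensitive=False`` the orientation channel is collapsed and
    all four orientations of a site share one weight.
    """

    def __init__(
        self,
        weights: np.ndarray,
        categories: list[str],
        c1_shapes: list[tuple[int, int]],
        n_orientations: int = 4,
        orientation_sensitive: bool = True,
        theta_train: np.ndarray | None = None,
        threshold_factor: float = 0.5,
    ):
        self.weights = np.asarray(weights, dtype=float)
        self.categories = list(categories)
        self.c1_shapes = [tuple(s) for s in c1_shapes]
        self.n_orientations = n_orientations
        self.orientation_sensitive = orientation_sensitive
        per_site = n_orientations if orientation_sensitive else 1
        self._offsets = np.concatenate(
            [[0], np.cumsum([h * w * per_site for h, w in self.c1_shapes])]
        )
        if self.weights.shape[1] != self._offsets[-1]:
            raise ValueError(
                f"weight width {self.weights.shape[1]} does not match "
                f"C1 shapes (expected {self._offsets[-1]})"
            )
        self.theta_train = (
            np.asarray(theta_train, dtype=float) if theta_train is not None else None
        )
        self.threshold_factor = threshold_factor

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def cell_ids(self, category: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.categories) if c == category])

    def afferent_indices(self, train: SpikeTrain) -> np.ndarray:
        """Flat afferent index of every event in a C1 spike train."""
        widths = np.array([w for _, w in self.c1_shapes])
        site = train.rows * widths[train.scales] + train.cols
        if self.orientation_sensitive:
            idx = site * self.n_orientations + train.orientations
        else:
            idx = site
        return self._offsets[train.scales] + idx

    def copy(self) -> "S2Population":
        return S2Population(
            self.weights.copy(),
            list(self.categories),
            list(self.c1_shapes),
            self.n_orientations,
            self.orientation_sensitive,
            None if self.theta_train is None else self.theta_train.copy(),
            self.threshold_factor,
        )


def init_population(
    n_per_category: int,
    c1_shapes: list[tuple[int, int]],
    seed: int | np.random.Generator,
    categories: tuple[str, ...] = ("face", "house"),
    init_mean: float = 0.8,
    init_sd: float = 0.05,
    n_orientations: int = 4,
    orientation_sensitive: bool = True,
    threshold_factor: float = 0.5,
) -> S2Population:
    """Gaussian-initialized population, ``n_per_category`` cells per label."""
    if n_per_category <= 0:
        raise ValueError("n_per_category must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_site = n_orientations if orientation_sensitive else 1
    total = sum(h * w * per_site for h, w in c1_shapes)
    n_cells = n_per_category * len(categories)
    weights = np.clip(rng.normal(init_mean, init_sd, size=(n_cells, total)), 0.0, 1.0)
    cats = [c for c in categories for _ in range(n_per_category)]
    return S2Population(
        weights,
        cats,
        c1_shapes,
        n_orientations,
        orientation_sensitive,
        threshold_factor=threshold_factor,
    )


def calibrate_thresholds(
    pop: S2Population, trains: list[SpikeTrain], fraction: float = 2.0 / 3.0
) -> np.ndarray:
    """Training threshold per cell: ``fraction`` of its mean total drive.

    The total drive of a cell for one image is the sum of its weights over the
    image's afferent events; averaging over a calibration set anchors the
    threshold to what the cell can actually reach.
    """
    if not trains:
        raise ValueError("calibration needs at least one spike train")
    totals = np.zeros(pop.n_cells)
    for train in trains:
        idx = pop.afferent_indices(train)
        totals += pop.weights[:, idx].sum(axis=1)
    return fraction * totals / len(trains)


def _first_crossings(cum: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-row index of the first cumulative value >= theta, -1 if never."""
    crossed = cum >= theta[:, None]
    any_cross = crossed.any(axis=1)
    first = np.where(any_cross, np.argmax(crossed, axis=1), -1)
    return first


def stdp_train(
    pop: S2Population,
    trains: list[SpikeTrain],
    category: str,
    a_plus: float = 2.0**-5,
    a_minus: float = 0.75 * 2.0**-5,
    epochs: int = 400,
    theta_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator | None = None,
    shuffle: bool = True,
) -> S2Population:
    """Unsupervised STDP over one category's images.

    Only the cells of ``category`` compete; per presentation the first cell to
    reach its training threshold fires and updates (one-winner-take-all).
    Cells are trained on their own category's images only — call once per
    category with that category's spike trains.  Returns a new population;
    thresholds are calibrated on the training set if not already set.
    """
    if not trains:
        raise ValueError("empty training set")
    if a_plus < 0 or a_minus < 0:
        raise ValueError("learning rates must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed if seed is not None else 0)
    )
    out = pop.copy()
    if out.theta_train is None:
        out.theta_train = calibrate_thresholds(out, trains, theta_fraction)
    cells = out.cell_ids(category)
    if len(cells) == 0:
        raise ValueError(f"population has no cells of category {category!r}")
    theta = out.theta_train[cells]
    index_cache = [out.afferent_indices(t) for t in trains]
    n_aff = out.weights.shape[1]
    for _ in range(epochs):
        order = rng.permutation(len(trains)) if shuffle else np.arange(len(trains))
        for ti in order:
            idx = index_cache[ti]
            if len(idx) == 0:
                continue
            drive = out.weights[np.ix_(cells, idx)]
            cum = np.cumsum(drive, axis=1)
            first = _first_crossings(cum, theta)
            live = first >= 0
            if not live.any():
                continue  # no cell reached threshold: no update
            t_cross = np.where(live, first, np.iinfo(int).max)
            earliest = t_cross.min()
            contenders = np.flatnonzero(t_cross == earliest)
            if len(contenders) > 1:  # tie: larger potential, then lower id
                pots = cum[contenders, earliest]
                contenders = contenders[pots == pots.max()]
            winner = cells[contenders[0]]
            causal = idx[: earliest + 1]
            w = out.weights[winner]
            mask = np.zeros(n_aff, dtype=bool)
            mask[causal] = True
            w[mask] += a_plus * w[mask] * (1.0 - w[mask])
            w[~mask] -= a_minus * w[~mask] * (1.0 - w[~mask])
            np.clip(w, 0.0, 1.0, out=w)
    return out


def infer_spikes(
    pop: S2Population,
    train: SpikeTrain,
    threshold_factor: float | None = None,
    max_spikes_per_cell: int | None = None,
) -> S2SpikeTrain:
    """Multi-spike inference: integrate, fire at ``f * theta_train``, reset.

    Every cell of both categories processes every afferent event in time
    order; on each threshold crossing it emits a spike stamped with the
    triggering afferent's time and its potential resets to zero.  There is no
    winner-take-all.  ``max_spikes_per_cell=1`` with ``threshold_factor=1``
    reproduces the single-spike base-model pass (test hook).
    """
    if pop.theta_train is None:
        raise ValueError("population has no training thresholds; train it first")
    f = pop.threshold_factor if threshold_factor is None else threshold_factor
    theta = f * pop.theta_train
    idx = pop.afferent_indices(train)
    n = pop.n_cells
    potentials = np.zeros(n)
    out: list[list[float]] = [[] for _ in range(n)]
    active = np.ones(n, dtype=bool)
    for e, a in enumerate(idx):
        potentials[active] += pop.weights[active, a]
        fired = active & (potentials >= theta)
        if fired.any():
            t = train.times[e]
            for c in np.flatnonzero(fired):
                out[c].append(t)
                if (
                    max_spikes_per_cell is not None
                    and len(out[c]) >= max_spikes_per_cell
                ):
                    active[c] = False
            potentials[fired] = 0.0
    return S2SpikeTrain(
        [np.array(t) for t in out], list(pop.categories), image_id=train.image_id
    )


def base_model_first_spikes(pop: S2Population, train: SpikeTrain) -> np.ndarray:
    """Single-spike pass of the unmodified model: integrate to the full
    training threshold once, no reset.  Returns one first-spike time per cell
    (NaN for silent cells).  Serves as the reference the multi-spike pass must
    reduce to when capped at one spike with threshold_factor 1.
    """
    if pop.theta_train is None:
        raise ValueError("population has no training thresholds; train it first")
    idx = pop.afferent_indices(train)
    first = np.full(pop.n_cells, np.nan)
    potentials = np.zeros(pop.n_cells)
    pending = np.ones(pop.n_cells, dtype=bool)
    for e, a in enumerate(idx):
        potentials[pending] += pop.weights[pending, a]
        fired = pending & (potentials >= pop.theta_train)
        if fired.any():
            first[fired] = train.times[e]
            pending &= ~fired
            if not pending.any():
                break
    return first


def population_rate(
    s2: S2SpikeTrain,
    category: str,
    bin_width: float,
    horizon: float | None = None,
    smooth_bins: int = 1,
) -> RateSeries:
    """Per-bin spike count pooled over one category's cells.

    ``RateSeries.counts`` is the raw per-bin count; a running average firing
    rate is available via :meth:`RateSeries.running` and the cumulative count
    via :meth:`RateSeries.cumulative`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times = s2.category_times(category)
    if horizon is None:
        horizon = float(times.max()) if len(times) else bin_width
    n_bins = max(1, int(np.ceil(horizon / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(times, bins=edges)
    return RateSeries(
        bin_width=bin_width,
        counts=counts.astype(float),
        category=category,
        smooth_bins=smooth_bins,
    )


def save_population(pop: S2Population, path: str | Path, seed: int | None = None,
                    manifest_hash: str | None = None) -> None:
    """Serialize a population to a single .npz archive with a versioned header."""
    meta = {
        "version": _ARCHIVE_VERSION,
        "categories": pop.categories,
        "c1_shapes": [list(s) for s in pop.c1_shapes],
        "n_orientations": pop.n_orientations,
        "orientation_sensitive": pop.orientation_sensitive,
        "threshold_factor": pop.threshold_factor,
        "seed": seed,
        "manifest_hash": manifest_hash,
    }
    np.savez(
        Path(path),
        weights=pop.weights,
        theta_train=(
            pop.theta_train if pop.theta_train is not None else np.array([])
        ),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_population(path: str | Path) -> S2Population:
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        if meta["version"] != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {meta['version']}")
        theta = archive["theta_train"]
        return S2Population(
            archive["weights"],
            meta["categories"],
            [tuple(s) for s in meta["c1_shapes"]],
            meta["n_orientations"],
            meta["orientation_sensitive"],
            theta if theta.size else None,
            meta["threshold_factor"],
        )


class STDPLayer(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper: fit trains one STDP sub-population per label,
    transform maps C1 spike trains to S2 spike trains.

    ``fit(X, y)`` takes a list of C1 :class:`SpikeTrain` and a label per
    train; each label's cells are trained only on that label's trains, as two
    independent unsupervised passes.  Thresholds are calibrated per cell as
    ``theta_fraction`` of mean total drive before training.
    """

    def __init__(
        self,
        n_per_category: int = 10,
        a_plus: float = 2.0**-5,
        a_minus: float = 0.75 * 2.0**-5,
        epochs: int = 400,
        theta_fraction: float = 2.0 / 3.0,
        threshold_factor: float = 0.5,
        init_mean: float = 0.8,
        init_sd: float = 0.05,
        orientation_sensitive: bool = True,
        c1_shapes: list[tuple[int, int]] | None = None,
        random_state: int | None = 0,
    ):
        self.n_per_category = n_per_category
        self.a_plus = a_plus
        self.a_minus = a_minus
        self.epochs = epochs
        self.theta_fraction = theta_fraction
        self.threshold_factor = threshold_factor
        self.init_mean = init_mean
        self.init_sd = init_sd
        self.orientation_sensitive = orientation_sensitive
        self.c1_shapes = c1_shapes
        self.random_state = random_state

    def _resolve_shapes(self, trains: list[SpikeTrain]) -> list[tuple[int, int]]:
        if self.c1_shapes is not None:
            return [tuple(s) for s in self.c1_shapes]
        n_scales = int(max(t.scales.max() for t in trains if len(t))) + 1
        shapes = []
        for s in range(n_scales):
            h = w = 0
            for t in trains:
                m = t.scales == s
                if m.any():
                    h = max(h, int(t.rows[m].max()) + 1)
                    w = max(w, int(t.cols[m].max()) + 1)
            shapes.append((h, w))
        return shapes

    def fit(self, X: list[SpikeTrain], y) -> "STDPLayer":
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("one label per spike train required")
        self.classes_ = np.unique(y)
        shapes = self._resolve_shapes(X)
        rng = np.random.default_rng(self.random_state)
        pop = init_population(
            self.n_per_category,
            shapes,
            rng,
            categories=tuple(str(c) for c in self.classes_),
            init_mean=self.init_mean,
            init_sd=self.init_sd,
            orientation_sensitive=self.orientation_sensitive,
            threshold_factor=self.threshold_factor,
        )
        pop.theta_train = calibrate_thresholds(pop, list(X), self.theta_fraction)
        for label in self.classes_:
            cat_trains = [t for t, lbl in zip(X, y) if lbl == label]
            pop = stdp_train(
                pop,
                cat_trains,
                str(label),
                a_plus=self.a_plus,
                a_minus=self.a_minus,
                epochs=self.epochs,
                seed=rng,
            )
        self.population_ = pop
        return self

    def transform(self, X: list[SpikeTrain]) -> list[S2SpikeTrain]:
        return [infer_spikes(self.population_, t) for t in X]
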