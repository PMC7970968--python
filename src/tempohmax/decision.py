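"""Two-accumulator race decision layer and its fit to behavioral reaction times.

Spikes pooled over the face- and house-selective populations are binned into
rate series v_face(t), v_house(t).  Two accumulators integrate them,

    AC_face(t)  = sum_{t' <= t} [ v_face(t')  - u * v_house(t') ]
    AC_house(t) = sum_{t' <= t} [ v_house(t') - u * v_face(t')  ]

with the opposing-accumulator coefficient u = 0 by default.  The first
accumulator to reach its own bound (TH_face or TH_house) determines the
choice; the crossing time rt (in model time units) maps to a reaction time in
milliseconds through

    RT_model = alpha * rt + RT_motor

where alpha is the model time scale and RT_motor the non-decision time.  The
four free parameters (TH_face, TH_house, alpha, RT_motor) are shared across
all noise levels and are fitted by Nelder-Mead direct search minimizing the
sum over noise levels of the Euclidean distance between the model's and the
observed (face, house) mean-RT pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "RateSeries",
    "DecisionParams",
    "AccumulatorTrace",
    "TrialOutcome",
    "Trial",
    "BehaviorTable",
    "FitResult",
    "accumulate",
    "trace_from_s2",
    "decide",
    "forced_choice",
    "classify",
    "objective",
    "simulate_level_means",
    "fit",
    "RaceModel",
]


@dataclass
class RateSeries:
    """Per-bin spike counts of one population."""

    bin_width: float
    counts: np.ndarray
    category: str = ""
    smooth_bins: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    def running(self, window: int | None = None) -> np.ndarray:
        """Running average firing rate: moving-average smoothed per-bin count."""
        w = window or self.smooth_bins
        if w <= 1:
            return self.counts.copy()
        kernel = np.ones(w) / w
        return np.convolve(self.counts, kernel, mode="same")

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.counts)


@dataclass
class DecisionParams:
    """Free parameters and fixed constants of the race model.

    alpha is in ms per model time unit, rt_motor in ms; u is the opposing
    accumulator coefficient (0 in all reference computations); horizon bounds
    the simulated model time (None: the full trace).
    """

    th_face: float
    th_house: float
    alpha: float
    rt_motor: float
    u: float = 0.0
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.th_face <= 0 or self.th_house <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.rt_motor < 0:
            raise ValueError("rt_motor must be non-negative")
        if self.horizon is not None and self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class AccumulatorTrace:
    """Accumulated evidence per bin for the two populations."""

    times: np.ndarray
    ac_face: np.ndarray
    ac_house: np.ndarray
    bin_width: float
    labels: tuple[str, str] = ("face", "house")


@dataclass
class TrialOutcome:
    choice: str
    decided: bool
    rt_model_units: float | None = None
    rt_ms: float | None = None


@dataclass
class Trial:
    """One stimulus presentation ready for the decision layer."""

    trace: AccumulatorTrace
    noise_level: float
    label: str
    image_id: str | None = None


@dataclass
class FitResult:
    params: DecisionParams
    objective: float
    n_evals: int
    converged: bool
    seed: int | None = None
    empty_levels: list = field(default_factory=list)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "params": {
                "th_face": self.params.th_face,
                "th_house": self.params.th_house,
                "alpha": self.params.alpha,
                "rt_motor": self.params.rt_motor,
                "u": self.params.u,
            },
            "objective": self.objective,
            "n_evals": self.n_evals,
            "converged": self.converged,
            "seed": self.seed,
            "empty_levels": list(self.empty_levels),
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


class BehaviorTable:
    """Per-noise-level mean reaction times per category, plus optional trials.

    ``means`` has columns (noise_level, category, mean_rt_ms, n_trials);
    ``trials`` optionally has (image_id, noise_level, category, choice,
    rt_ms, correct).
    """

    def __init__(self, means: pd.DataFrame, trials: pd.DataFrame | None = None):
        required = {"noise_level", "category", "mean_rt_ms"}
        if not required.issubset(means.columns):
            raise ValueError(f"means frame needs columns {sorted(required)}")
        if (means["mean_rt_ms"] <= 0).any():
            raise ValueError("mean RTs must be positive")
        if means.duplicated(["noise_level", "category"]).any():
            raise ValueError("duplicate (noise_level, category) rows")
        self.means = means.reset_index(drop=True)
        self.trials = trials

    @property
    def levels(self) -> np.ndarray:
        return np.sort(self.means["noise_level"].unique())

    @property
    def categories(self) -> list[str]:
        return sorted(self.means["category"].unique())

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "BehaviorTable":
        g = (
            trials.groupby(["noise_level", "category"])["rt_ms"]
            .agg(mean_rt_ms="mean", n_trials="count")
            .reset_index()
        )
        return cls(g, trials)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.means.to_csv(path, index=False, float_format="%.12g")


def accumulate(
    face_rate: RateSeries, house_rate: RateSeries, u: float = 0.0
) -> AccumulatorTrace:
    """Running evidence sums per bin for the two competing populations."""
    if face_rate.bin_width != house_rate.bin_width:
        raise ValueError("rate series bin widths differ")
    if len(face_rate.counts) != len(house_rate.counts):
        raise ValueError("rate series lengths differ")
    vf, vh = face_rate.counts, house_rate.counts
    times = face_rate.bin_width * np.arange(1, len(vf) + 1)
    return AccumulatorTrace(
        times=times,
        ac_face=np.cumsum(vf - u * vh),
        ac_house=np.cumsum(vh - u * vf),
        bin_width=face_rate.bin_width,
        labels=(face_rate.category or "face", house_rate.category or "house"),
    )


def trace_from_s2(
    s2_train,
    labels: tuple[str, str] = ("face", "house"),
    n_bins: int = 512,
    bin_width: float | None = None,
    horizon: float | None = None,
    u: float = 0.0,
) -> AccumulatorTrace:
    """Bin an S2 spike train into two rate series and accumulate them.

    The default horizon is the last output spike of either population; the
    bin width divides it into ``n_bins`` bins unless given explicitly.
    """
    t_a = s2_train.category_times(labels[0])
    t_b = s2_train.category_times(labels[1])
    if horizon is None:
        last = max(
            float(t_a.max()) if len(t_a) else 0.0,
            float(t_b.max()) if len(t_b) else 0.0,
        )
        horizon = last if last > 0 else 1.0
    if bin_width is None:
        bin_width = horizon / n_bins
    edges = np.arange(int(np.ceil(horizon / bin_width)) + 1) * bin_width
    ca, _ = np.histogram(t_a, bins=edges)
    cb, _ = np.histogram(t_b, bins=edges)
    ra = RateSeries(bin_width, ca.astype(float), labels[0])
    rb = RateSeries(bin_width, cb.astype(float), labels[1])
    return accumulate(ra, rb, u=u)


def _first_crossing(ac: np.ndarray, th: float, monotone: bool) -> int:
    """Index of the first bin with ac >= th, or len(ac) if never."""
    if monotone:
        return int(np.searchsorted(ac, th, side="left"))
    hit = ac >= th
    return int(np.argmax(hit)) if hit.any() else len(ac)


def decide(
    trace: AccumulatorTrace,
    params: DecisionParams,
    rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Race readout: earliest bound crossing determines choice and RT.

    Threshold equality is read as the first bin with AC >= TH (discrete sums
    can jump past the bound).  If both accumulators first cross in the same
    bin, the larger fractional overshoot AC/TH wins; exact ties fall to a
    seeded coin flip.  No crossing within the horizon leaves the trial
    undecided.
    """
    monotone = params.u <= 0
    n = len(trace.times)
    limit = n
    if params.horizon is not None:
        limit = int(np.searchsorted(trace.times, params.horizon, side="right"))
    i_f = _first_crossing(trace.ac_face[:limit], params.th_face, monotone)
    i_h = _first_crossing(trace.ac_house[:limit], params.th_house, monotone)
    if i_f >= limit and i_h >= limit:
        return TrialOutcome(choice="undecided", decided=False)
    if i_f < i_h:
        winner, idx = 0, i_f
    elif i_h < i_f:
        winner, idx = 1, i_h
    else:  # same first-crossing bin
        over_f = trace.ac_face[i_f] / params.th_face
        over_h = trace.ac_house[i_h] / params.th_house
        if over_f > over_h:
            winner, idx = 0, i_f
        elif over_h > over_f:
            winner, idx = 1, i_h
        else:
            rng = rng or np.random.default_rng(0)
            winner, idx = int(rng.integers(2)), i_f
    rt = float(trace.times[idx])
    return TrialOutcome(
        choice=trace.labels[winner],
        decided=True,
        rt_model_units=rt,
        rt_ms=params.alpha * rt + params.rt_motor,
    )


def forced_choice(
    trace: AccumulatorTrace,
    params: DecisionParams,
    deadline: float,
    rng: np.random.Generator | None = None,
) -> str:
    """Deadline readout: the accumulator proportionally closer to its bound wins."""
    idx = int(np.searchsorted(trace.times, deadline, side="right")) - 1
    if idx < 0:
        idx = 0
    prox_f = trace.ac_face[idx] / params.th_face
    prox_h = trace.ac_house[idx] / params.th_house
    if prox_f > prox_h:
        return trace.labels[0]
    if prox_h > prox_f:
        return trace.labels[1]
    rng = rng or np.random.default_rng(0)
    return trace.labels[int(rng.integers(2))]


def classify(
    trace: AccumulatorTrace,
    params: DecisionParams,
    rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Race readout with a forced choice at the end of the trace if undecided."""
    out = decide(trace, params, rng=rng)
    if not out.decided and len(trace.times):
        choice = forced_choice(trace, params, float(trace.times[-1]), rng=rng)
        return TrialOutcome(choice=choice, decided=False)
    return out


def objective(model_means: pd.DataFrame, behavior: BehaviorTable) -> float:
    """Sum over noise levels of the Euclidean distance between the model's and
    the observed (face, house) mean-RT pairs.

    Zero iff the model matches the behavioral means at every level; additive
    across levels.  ``model_means`` needs columns (noise_level, category,
    mean_rt_ms) covering exactly the behavioral levels and categories.
    """
    cats = behavior.categories
    if len(cats) != 2:
        raise ValueError("objective requires exactly two categories")
    b = behavior.means.pivot(index="noise_level", columns="category", values="mean_rt_ms")
    m = model_means.pivot(index="noise_level", columns="category", values="mean_rt_ms")
    if set(m.index) != set(b.index) or not set(cats).issubset(m.columns):
        raise ValueError("model and behavioral level/category sets differ")
    m = m.reindex(index=b.index, columns=cats)
    if m.isna().any().any():
        raise ValueError("model means missing for some (level, category) cell")
    d = m.to_numpy(float) - b[cats].to_numpy(float)
    return float(np.sum(np.sqrt(np.sum(d**2, axis=1))))


def simulate_level_means(
    trials: list[Trial],
    params: DecisionParams,
    rng: np.random.Generator | None = None,
    undecided_penalty_ms: float | None = None,
) -> pd.DataFrame:
    """Per-(level, chosen category) mean model RT in ms.

    A trial contributes to the mean of the category it was *categorized as*,
    whatever its true label.  Undecided trials are excluded unless a fixed
    penalty RT is configured for them.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for tr in trials:
        out = decide(tr.trace, params, rng=rng)
        if out.decided:
            rows.append((tr.noise_level, out.choice, out.rt_ms))
        elif undecided_penalty_ms is not None:
            choice = forced_choice(tr.trace, params, float(tr.trace.times[-1]), rng)
            rows.append((tr.noise_level, choice, undecided_penalty_ms))
    df = pd.DataFrame(rows, columns=["noise_level", "category", "rt_ms"])
    return (
        df.groupby(["noise_level", "category"])["rt_ms"]
        .agg(mean_rt_ms="mean", n_trials="count")
        .reset_index()
    )


class _TrialCache:
    """Precomputed per-trial arrays for fast objective evaluation.

    For fixed u the accumulator traces never change during the fit, so each
    evaluation only needs two sorted-array searches per trial plus a grouped
    mean.  Coin flips for exact ties are pre-drawn per trial so every
    evaluation is deterministic.
    """

    def __init__(self, trials: list[Trial], behavior: BehaviorTable,
                 horizon: float | None, u: float, seed: int):
        self.cats = behavior.categories
        self.levels = list(behavior.levels)
        level_pos = {lv: i for i, lv in enumerate(self.levels)}
        cat_pos = {c: i for i, c in enumerate(self.cats)}
        b = behavior.means.pivot(
            index="noise_level", columns="category", values="mean_rt_ms"
        ).reindex(index=self.levels, columns=self.cats)
        self.b_matrix = b.to_numpy(float)
        self.monotone = u <= 0
        rng = np.random.default_rng(seed)
        self.entries = []
        for t in trials:
            if t.noise_level not in level_pos:
                continue
            limit = len(t.trace.times)
            if horizon is not None:
                limit = int(np.searchsorted(t.trace.times, horizon, side="right"))
            cat_a = cat_pos.get(t.trace.labels[0], 0)
            cat_b = cat_pos.get(t.trace.labels[1], 1)
            self.entries.append(
                (
                    t.trace.ac_face[:limit],
                    t.trace.ac_house[:limit],
                    t.trace.times[:limit],
                    level_pos[t.noise_level],
                    cat_a,
                    cat_b,
                    int(rng.integers(2)),
                )
            )

    def evaluate(self, params: DecisionParams, missing_penalty_ms: float
                 ) -> tuple[float, list]:
        L, C = len(self.levels), len(self.cats)
        sums = np.zeros((L, C))
        counts = np.zeros((L, C))
        thf, thh = params.th_face, params.th_house
        for acf, ach, times, lvl, cat_a, cat_b, coin in self.entries:
            n = len(times)
            i_f = _first_crossing(acf, thf, self.monotone)
            i_h = _first_crossing(ach, thh, self.monotone)
            if i_f >= n and i_h >= n:
                continue
            if i_f < i_h:
                cat, idx = cat_a, i_f
            elif i_h < i_f:
                cat, idx = cat_b, i_h
            else:
                over_f, over_h = acf[i_f] / thf, ach[i_h] / thh
                if over_f > over_h:
                    cat, idx = cat_a, i_f
                elif over_h > over_f:
                    cat, idx = cat_b, i_h
                else:
                    cat, idx = (cat_a, cat_b)[coin], i_f
            sums[lvl, cat] += params.alpha * times[idx] + params.rt_motor
            counts[lvl, cat] += 1.0
        with np.errstate(invalid="ignore"):
            means = sums / counts
        resid = means - self.b_matrix
        missing = counts == 0
        resid = np.where(missing, missing_penalty_ms, resid)
        total = float(np.sum(np.sqrt(np.sum(resid**2, axis=1))))
        empty = [
            (self.levels[i], self.cats[j]) for i, j in zip(*np.nonzero(missing))
        ]
        return total, empty


def fit(
    trials: list[Trial],
    behavior: BehaviorTable,
    init: DecisionParams,
    seed: int = 0,
    n_restarts: int = 5,
    max_evals: int = 2000,
    xtol: float = 1e-6,
    ftol: float = 1e-6,
    missing_penalty_ms: float = 2000.0,
    restart_spread: float = 0.5,
) -> FitResult:
    """Nelder-Mead fit of (TH_face, TH_house, alpha, RT_motor).

    The search runs in log space so all four parameters stay positive; u is
    held at its init value (0 in the reference computations) and one
    parameter set covers every noise level.  ``n_restarts`` seeded restarts
    perturb the init in log space and the best optimum is kept; results are
    deterministic for fixed seed and inputs.
    """
    if not trials:
        raise ValueError("no trials to fit")
    rng = np.random.default_rng(seed)
    cache = _TrialCache(trials, behavior, init.horizon, init.u, seed)
    x0 = np.log(
        [init.th_face, init.th_house, init.alpha, max(init.rt_motor, 1e-3)]
    )

    def unpack(x: np.ndarray) -> DecisionParams:
        thf, thh, alpha, rtm = np.exp(x)
        return DecisionParams(
            th_face=thf, th_house=thh, alpha=alpha, rt_motor=rtm,
            u=init.u, horizon=init.horizon,
        )

    def cost(x: np.ndarray) -> float:
        total, _ = cache.evaluate(unpack(x), missing_penalty_ms)
        return total

    def warm_start(log_th: np.ndarray) -> np.ndarray:
        """Given thresholds, choices and crossing times are fixed, so the RT
        map is linear in (alpha, rt_motor); seed them by least squares
        against the behavioral means."""
        probe = DecisionParams(
            th_face=float(np.exp(log_th[0])), th_house=float(np.exp(log_th[1])),
            alpha=1.0, rt_motor=1e-6, u=init.u, horizon=init.horizon,
        )
        units = simulate_level_means(trials, probe, np.random.default_rng(seed))
        merged = units.merge(
            behavior.means, on=["noise_level", "category"], suffixes=("_u", "_b")
        )
        if len(merged) < 2:
            return np.array([init.alpha, max(init.rt_motor, 1e-3)])
        u_vals = merged["mean_rt_ms_u"].to_numpy(float)
        b_vals = merged["mean_rt_ms_b"].to_numpy(float)
        A = np.column_stack([u_vals, np.ones_like(u_vals)])
        (alpha, rtm), *_ = np.linalg.lstsq(A, b_vals, rcond=None)
        if alpha <= 0:
            alpha = max(b_vals.mean() / max(u_vals.mean(), 1e-9), 1e-3)
        return np.array([alpha, max(rtm, 1e-3)])

    n_evals = 0

    # coarse scan over symmetric thresholds (alpha/rt_motor warm-started by
    # regression): the objective is near-degenerate along alpha x threshold,
    # so the global basin in the thresholds is narrow and must be located
    # before the simplex can refine it
    th_center = float(np.sqrt(init.th_face * init.th_house))
    scan: list[tuple[float, np.ndarray]] = []
    for g in np.geomspace(0.25, 4.0, 17):
        log_th = np.log([th_center * g, th_center * g])
        start = np.concatenate([log_th, np.log(warm_start(log_th))])
        scan.append((cost(start), start))
        n_evals += 1
    scan.sort(key=lambda t: t[0])

    starts = [x0] + [s for _, s in scan[:3]]
    while len(starts) < max(1, n_restarts):
        starts.append(x0 + rng.normal(0.0, restart_spread, size=4))

    best = None
    converged = False
    for start in starts[: max(1, n_restarts)]:
        res = minimize(
            cost,
            start,
            method="Nelder-Mead",
            options={"maxfev": max_evals, "xatol": xtol, "fatol": ftol},
        )
        n_evals += res.nfev
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # polish: rerun from the best point with a fresh simplex, which lets the
    # search escape a collapsed simplex near piecewise-flat threshold steps
    res = minimize(
        cost,
        best.x,
        method="Nelder-Mead",
        options={"maxfev": max_evals, "xatol": xtol, "fatol": ftol},
    )
    n_evals += res.nfev
    if res.fun < best.fun:
        best = res
    params = unpack(best.x)
    final, empty = cache.evaluate(params, missing_penalty_ms)
    return FitResult(
        params=params,
        objective=final,
        n_evals=n_evals,
        converged=converged,
        seed=seed,
        empty_levels=empty,
    )


class RaceModel(BaseEstimator):
    """sklearn-style wrapper around the race decision layer.

    ``fit(trials, behavior)`` optimizes the four free parameters against a
    behavioral RT table; ``predict(trials)`` returns the chosen category per
    trial (forced choice at the end of the trace when no bound is crossed).
    """

    def __init__(
        self,
        init_threshold: float = 10.0,
        init_alpha: float = 10.0,
        init_rt_motor: float = 300.0,
        u: float = 0.0,
        horizon: float | None = None,
        n_restarts: int = 5,
        max_evals: int = 2000,
        random_state: int = 0,
    ):
        self.init_threshold = init_threshold
        self.init_alpha = init_alpha
        self.init_rt_motor = init_rt_motor
        self.u = u
        self.horizon = horizon
        self.n_restarts = n_restarts
        self.max_evals = max_evals
        self.random_state = random_state

    def fit(self, X: list[Trial], y: BehaviorTable) -> "RaceModel":
        init = DecisionParams(
            th_face=self.init_threshold,
            th_house=self.init_threshold,
            alpha=self.init_alpha,
            rt_motor=self.init_rt_motor,
            u=self.u,
            horizon=self.horizon,
        )
        self.result_ = fit(
            X,
            y,
            init,
            seed=self.random_state,
            n_restarts=self.n_restarts,
            max_evals=self.max_evals,
        )
        self.params_ = self.result_.params
        return self

    def predict(self, X: list[Trial]) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        return np.array([classify(t.trace, self.params_, rng).choice for t in X])

    def predict_outcomes(self, X: list[Trial]) -> list[TrialOutcome]:
        rng = np.random.default_rng(self.random_state)
        return [classify(t.trace, self.params_, rng) for t in X]

    def score(self, X: list[Trial], y=None) -> float:
        """Fraction of trials whose predicted category matches the true label."""
        pred = self.predict(X)
        truth = np.array([t.label for t in X])
        return float(np.mean(pred == truth))
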