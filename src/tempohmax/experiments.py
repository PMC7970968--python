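"""Evaluation protocols: held-out accuracy/RT curves, deliberation and
bound-collapse sweeps, per-accumulator bound grids, and fast/slow RT splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .decision import DecisionParams, Trial, TrialOutcome, classify, decide, forced_choice
from .stimuli import GrayImage, make_phase_noise

__all__ = [
    "SweepResult",
    "InfeasibleBoundError",
    "evaluate_leave_n_out",
    "deliberation_sweep",
    "bound_collapse_sweep",
    "bound_grid",
    "fast_slow_split",
    "find_optimum_bound",
]


@dataclass
class SweepResult:
    """Sweep output: one row per (axis value, noise level) plus an overall
    per-axis-value summary."""

    axis: str
    table: pd.DataFrame
    overall: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")


class InfeasibleBoundError(RuntimeError):
    """No parameter grid point satisfies the reaction-time cap."""


def _evaluate_at(trials: list[Trial], params: DecisionParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial (choice, correct, rt_ms with NaN when undecided)."""
    choices, correct, rts = [], [], []
    for t in trials:
        out = decide(t.trace, params, rng)
        if out.decided:
            choices.append(out.choice)
            rts.append(out.rt_ms)
        else:
            choices.append(forced_choice(t.trace, params, float(t.trace.times[-1]), rng))
            rts.append(np.nan)
        correct.append(choices[-1] == t.label)
    return np.array(choices), np.array(correct, bool), np.array(rts, float)


def evaluate_leave_n_out(
    originals: list[GrayImage],
    n: int,
    seed: int,
    make_estimator,
    avg_mag,
    noise_levels: tuple[float, ...],
    n_runs: int = 10,
) -> pd.DataFrame:
    """Held-out accuracy and RT per noise level, averaged over repeated runs.

    Each run holds out ``n`` images per category (blocks sampled without
    replacement across runs for as long as the category lasts), trains a fresh
    end-to-end classifier on the remaining clean images, then evaluates the
    held-out images corrupted at every noise level.  ``n = 0`` evaluates on
    the training images themselves (resubstitution).  Returns one row per
    (run, noise_level) with accuracy and mean model RT; aggregate with
    ``groupby('noise_level').agg(['mean', 'sem'])``.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[GrayImage]] = {}
    for im in originals:
        by_cat.setdefault(im.label, []).append(im)
    for cat, ims in by_cat.items():
        if n >= len(ims):
            raise ValueError(f"n={n} leaves no training images for {cat!r}")
    # pre-shuffled hold-out order per category, reshuffled when exhausted
    orders = {c: list(rng.permutation(len(v))) for c, v in by_cat.items()}
    cursors = {c: 0 for c in by_cat}

    rows = []
    for run in range(n_runs):
        held, train = [], []
        for cat, ims in by_cat.items():
            if n == 0:
                chosen: set[int] = set()
            else:
                if cursors[cat] + n > len(ims):
                    orders[cat] = list(rng.permutation(len(ims)))
                    cursors[cat] = 0
                chosen = set(orders[cat][cursors[cat] : cursors[cat] + n])
                cursors[cat] += n
            for i, im in enumerate(ims):
                (held if i in chosen else train).append(im)
        if n == 0:
            held = list(train)
        est = make_estimator(run)
        est.fit(train, [im.label for im in train])
        for level in noise_levels:
            noisy = [make_phase_noise(im, avg_mag, float(level), rng) for im in held]
            trials = est.decision_trials(noisy, [im.label for im in held])
            _, correct, rts = _evaluate_at(trials, est.params_, rng)
            rows.append(
                (
                    run,
                    float(level),
                    float(correct.mean()),
                    float(np.nanmean(rts)) if np.isfinite(np.nanmean(rts)) else np.nan,
                    len(held),
                )
            )
    return pd.DataFrame(
        rows, columns=["run", "noise_level", "accuracy", "mean_rt_ms", "n"]
    )


def deliberation_sweep(
    trials: list[Trial],
    params: DecisionParams,
    deadlines: list[float],
    seed: int = 0,
) -> SweepResult:
    """Forced-choice accuracy at each deadline, per noise level and overall."""
    if list(deadlines) != sorted(deadlines):
        raise ValueError("deadlines must be sorted ascending")
    rng = np.random.default_rng(seed)
    rows = []
    for dl in deadlines:
        for t in trials:
            choice = forced_choice(t.trace, params, dl, rng)
            rows.append((dl, t.noise_level, choice == t.label))
    df = pd.DataFrame(rows, columns=["deadline", "noise_level", "correct"])
    table = (
        df.groupby(["deadline", "noise_level"])["correct"]
        .agg(accuracy="mean", n="count")
        .reset_index()
    )
    table["error_rate"] = 1.0 - table["accuracy"]
    overall = (
        df.groupby("deadline")["correct"].agg(accuracy="mean", n="count").reset_index()
    )
    overall["error_rate"] = 1.0 - overall["accuracy"]
    return SweepResult("deadline", table, overall, {"deadlines": list(deadlines)})


def bound_collapse_sweep(
    trials: list[Trial],
    params: DecisionParams,
    fractions: list[float],
    seed: int = 0,
) -> SweepResult:
    """Scale both bounds by each fraction of the operating point and re-decide.

    Fraction 1.0 reproduces the un-collapsed operating point; smaller
    fractions trade accuracy for speed.  Mean RT is over decided trials.
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        scaled = replace(params, th_face=frac * params.th_face,
                         th_house=frac * params.th_house)
        _, correct, rts = _evaluate_at(trials, scaled, rng)
        levels = np.array([t.noise_level for t in trials])
        for lvl in np.unique(levels):
            m = levels == lvl
            rows.append(
                (frac, lvl, correct[m].mean(), np.nanmean(rts[m]) if np.any(~np.isnan(rts[m])) else np.nan, int(m.sum()))
            )
    table = pd.DataFrame(
        rows, columns=["fraction", "noise_level", "accuracy", "mean_rt_ms", "n"]
    )
    table["error_rate"] = 1.0 - table["accuracy"]
    overall = (
        table.groupby("fraction")
        .apply(
            lambda g: pd.Series(
                {
                    "accuracy": np.average(g["accuracy"], weights=g["n"]),
                    "mean_rt_ms": np.nansum(g["mean_rt_ms"] * g["n"])
                    / g["n"].sum(),
                    "n": g["n"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    overall["error_rate"] = 1.0 - overall["accuracy"]
    return SweepResult("collapse-fraction", table, overall, {"fractions": list(fractions)})


def bound_grid(
    trials: list[Trial],
    th_face_values,
    th_house_values,
    params: DecisionParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Conditional accuracy of each choice type over a bound grid.

    For every (TH_face, TH_house) pair the race is re-run; ``face_accuracy``
    is the fraction of face choices whose stimulus really was of the first
    category (and symmetrically for ``house_accuracy``).  NaN where a choice
    type never occurs.
    """
    th_face_values = np.atleast_1d(th_face_values)
    th_house_values = np.atleast_1d(th_house_values)
    if len(th_face_values) == 0 or len(th_house_values) == 0:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    labels = np.array([t.label for t in trials])
    cat_a, cat_b = trials[0].trace.labels
    rows = []
    for thf in th_face_values:
        for thh in th_house_values:
            p = replace(params, th_face=float(thf), th_house=float(thh))
            choices, _, _ = _evaluate_at(trials, p, rng)
            def precision(cat):
                m = choices == cat
                return float((labels[m] == cat).mean()) if m.any() else np.nan
            rows.append((float(thf), float(thh), precision(cat_a), precision(cat_b)))
    return pd.DataFrame(
        rows, columns=["th_face", "th_house", "face_accuracy", "house_accuracy"]
    )


def fast_slow_split(rts_by_category: dict[str, list]) -> pd.DataFrame:
    """Split each category's correct RTs at the median into fast and slow halves.

    RTs are sorted ascending; the lower half is "fast", the upper half
    "slow" (odd counts put the middle trial in the slow half).  The two
    halves are compared with a two-sided Mann-Whitney rank-sum test.
    """
    rows = []
    for cat, values in rts_by_category.items():
        rts = np.sort(np.asarray(
            [v.rt_ms if isinstance(v, TrialOutcome) else float(v) for v in values]
        ))
        if len(rts) < 2:
            raise ValueError(f"need at least 2 correct trials for {cat!r}")
        half = len(rts) // 2
        fast, slow = rts[:half], rts[half:]
        if np.all(fast == fast[0]) and np.all(slow == slow[0]) and fast[0] == slow[0]:
            p = 1.0  # degenerate: identical samples
        else:
            p = float(mannwhitneyu(fast, slow, alternative="two-sided").pvalue)
        rows.append((cat, float(fast.mean()), float(slow.mean()), p, len(rts)))
    return pd.DataFrame(
        rows, columns=["category", "fast_mean_rt", "slow_mean_rt", "p_value", "n"]
    )


def find_optimum_bound(
    trials: list[Trial],
    th_face_values,
    th_house_values,
    params: DecisionParams,
    rt_cap_ms: float = 2000.0,
    seed: int = 0,
) -> DecisionParams:
    """Exhaustive grid search: maximize accuracy subject to mean RT <= cap.

    Ties break toward the lower mean RT.  Raises
    :class:`InfeasibleBoundError` when no grid point meets the cap.
    """
    th_face_values = np.atleast_1d(th_face_values)
    th_house_values = np.atleast_1d(th_house_values)
    if len(th_face_values) == 0 or len(th_house_values) == 0:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    best = None
    for thf in th_face_values:
        for thh in th_house_values:
            p = replace(params, th_face=float(thf), th_house=float(thh))
            _, correct, rts = _evaluate_at(trials, p, rng)
            decided = ~np.isnan(rts)
            mean_rt = float(np.mean(rts[decided])) if decided.any() else np.inf
            if mean_rt > rt_cap_ms:
                continue
            key = (float(correct.mean()), -mean_rt)
            if best is None or key > best[0]:
                best = (key, p)
    if best is None:
        raise InfeasibleBoundError(
            f"no (TH_face, TH_house) grid point attains mean RT <= {rt_cap_ms} ms"
        )
    return best[1]
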