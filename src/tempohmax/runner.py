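"""Staged end-to-end pipeline: fixtures -> encode -> train -> infer -> fit -> sweep.

Each stage persists its artifacts in the run directory and is skipped on
rerun when its outputs already exist, so a run is resumable from any
serialized intermediate.  All randomness derives from the root seed through
named per-stage substreams.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash, stage_seed
from .decision import BehaviorTable, DecisionParams, Trial, fit as fit_decision, trace_from_s2
from .experiments import bound_collapse_sweep, deliberation_sweep
from .frontend import SpikeEncoder, SpikeTrain
from .s2 import STDPLayer, infer_spikes, load_population, save_population
from .stimuli import GrayImage, load_image, save_png
from .synthetic import FixtureSpec, SyntheticBehaviorSpec, generate_behavior, generate_images

__all__ = ["run_pipeline"]

log = logging.getLogger("tempohmax")


def _stem(image_id: str, level: float | None) -> str:
    return f"{image_id}__clean" if level is None or np.isnan(level) else f"{image_id}__{level:.2f}"


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def _load_gray(path: Path, label: str, level, image_id: str) -> GrayImage:
    px = np.asarray(load_image(path), dtype=float) / 255.0
    return GrayImage(px, label=label,
                     noise_level=None if pd.isna(level) else float(level),
                     image_id=image_id)


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            log.info("stage %s: %.2fs", name, timings[name])

    return _Timer()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.model_dump(mode="json"), indent=2)
    )
    timings: dict[str, float] = {}
    images_dir, spikes_dir, s2_dir, sweeps_dir = (
        out / "images", out / "spikes", out / "s2", out / "sweeps",
    )
    manifest_path = out / "manifest.csv"
    behavior_path = out / "behavior.csv"
    model_path = out / "model.npz"
    fit_path = out / "fit.json"

    # -- fixtures ---------------------------------------------------------
    if not _done([manifest_path, behavior_path]):
        with _stage("fixtures", timings):
            spec = FixtureSpec(
                categories=config.fixtures.categories,
                image_size=tuple(config.fixtures.image_size),
                n_per_category=config.fixtures.n_per_category,
                noise_levels=tuple(config.fixtures.noise_levels),
                seed=stage_seed(config.seed, "fixtures"),
            )
            fixture = generate_images(spec)
            images_dir.mkdir(exist_ok=True)
            for im in fixture.originals + fixture.noisy:
                save_png(im, images_dir / f"{_stem(im.image_id, im.noise_level)}.png")
            fixture.manifest.to_csv(manifest_path, index=False)
            behavior = generate_behavior(
                SyntheticBehaviorSpec(
                    base_rt_ms=dict(config.behavior.base_rt_ms),
                    rt_slope_ms=config.behavior.rt_slope_ms,
                    rt_noise_sd=config.behavior.rt_noise_sd,
                    lapse_rate=config.behavior.lapse_rate,
                    n_trials=config.behavior.n_trials,
                    noise_levels=tuple(config.fixtures.noise_levels),
                    seed=stage_seed(config.seed, "behavior"),
                )
            )
            behavior.to_csv(behavior_path)

    manifest = pd.read_csv(manifest_path)
    manifest = manifest.drop_duplicates(["filename", "noise_level"])
    stems = [
        (_stem(r.filename, r.noise_level), r.filename, r.label, r.noise_level)
        for r in manifest.itertuples()
    ]

    # -- encode -----------------------------------------------------------
    spike_paths = {s: spikes_dir / f"{s}.csv" for s, *_ in stems}
    encoder = SpikeEncoder(
        wavelength=config.frontend.wavelength,
        width=config.frontend.width,
        kernel_size=config.frontend.kernel_size,
        orientations_deg=tuple(config.frontend.orientations_deg),
        scale_factors=tuple(config.frontend.scale_factors),
        epsilon=config.frontend.epsilon,
    ).fit()
    if not _done(list(spike_paths.values())):
        with _stage("encode", timings):
            spikes_dir.mkdir(exist_ok=True)
            for stem, image_id, label, level in stems:
                png = images_dir / f"{stem}.png"
                if not png.exists():
                    raise FileNotFoundError(f"encode: missing input image {png}")
                train = encoder.encode_one(_load_gray(png, label, level, image_id))
                train.to_csv(spike_paths[stem])

    # -- train ------------------------------------------------------------
    if not model_path.exists():
        with _stage("train", timings):
            clean = [(s, lbl) for s, _, lbl, lvl in stems if pd.isna(lvl)]
            if not clean:
                raise FileNotFoundError("train: no clean (noise-free) images in manifest")
            trains = [SpikeTrain.from_csv(spike_paths[s], image_id=s) for s, _ in clean]
            layer = STDPLayer(
                n_per_category=config.s2.n_per_category,
                a_plus=config.s2.a_plus,
                a_minus=config.s2.a_minus,
                epochs=config.s2.epochs,
                theta_fraction=config.s2.theta_fraction,
                threshold_factor=config.s2.threshold_factor,
                init_mean=config.s2.init_mean,
                init_sd=config.s2.init_sd,
                orientation_sensitive=config.s2.orientation_sensitive,
                c1_shapes=encoder.c1_shapes(tuple(config.fixtures.image_size)),
                random_state=stage_seed(config.seed, "s2"),
            )
            layer.fit(trains, [lbl for _, lbl in clean])
            save_population(layer.population_, model_path,
                            seed=stage_seed(config.seed, "s2"))

    # -- infer ------------------------------------------------------------
    noisy_stems = [t for t in stems if not pd.isna(t[3])]
    s2_paths = {s: s2_dir / f"{s}.csv" for s, *_ in noisy_stems}
    if not _done(list(s2_paths.values())):
        with _stage("infer", timings):
            s2_dir.mkdir(exist_ok=True)
            pop = load_population(model_path)
            for stem, image_id, label, level in noisy_stems:
                train = SpikeTrain.from_csv(spike_paths[stem], image_id=stem)
                infer_spikes(pop, train).to_csv(s2_paths[stem])

    # -- trials (in memory, from serialized S2 spikes) --------------------
    pop = load_population(model_path)
    cats = sorted(set(pop.categories))
    trials: list[Trial] = []
    for stem, image_id, label, level in noisy_stems:
        df = pd.read_csv(s2_paths[stem])
        times = {
            c: df.loc[df["category"] == c, "time"].to_numpy(float) for c in cats
        }

        class _Pooled:
            def __init__(self, times):
                self._times = times

            def category_times(self, category):
                return np.sort(self._times.get(category, np.array([])))

        trace = trace_from_s2(_Pooled(times), labels=tuple(cats),
                              n_bins=config.decision.n_bins, u=config.decision.u)
        trials.append(Trial(trace, float(level), str(label), image_id))

    # -- fit --------------------------------------------------------------
    if not fit_path.exists():
        with _stage("fit", timings):
            behavior = BehaviorTable.from_csv(behavior_path)
            init = DecisionParams(
                th_face=config.decision.init_threshold,
                th_house=config.decision.init_threshold,
                alpha=config.decision.init_alpha,
                rt_motor=config.decision.init_rt_motor,
                u=config.decision.u,
            )
            result = fit_decision(
                trials, behavior, init,
                seed=stage_seed(config.seed, "fit"),
                n_restarts=config.decision.n_restarts,
                max_evals=config.decision.max_evals,
            )
            result.to_json(fit_path, extra={"config_hash": config_hash(config)})

    fitted = json.loads(fit_path.read_text())
    params = DecisionParams(u=config.decision.u, **{
        k: fitted["params"][k] for k in ("th_face", "th_house", "alpha", "rt_motor")
    })

    # -- sweeps -----------------------------------------------------------
    collapse_path = sweeps_dir / "collapse.csv"
    deadline_path = sweeps_dir / "deadline.csv"
    if not _done([collapse_path, deadline_path]):
        with _stage("sweep", timings):
            sweeps_dir.mkdir(exist_ok=True)
            sweep_seed = stage_seed(config.seed, "sweep")
            collapse = bound_collapse_sweep(
                trials, params, config.sweep.collapse_fractions, seed=sweep_seed
            )
            collapse.to_csv(collapse_path)
            horizon = float(np.median([t.trace.times[-1] for t in trials]))
            deadlines = list(
                np.linspace(horizon / config.sweep.n_deadlines, horizon,
                            config.sweep.n_deadlines)
            )
            deadline = deliberation_sweep(trials, params, deadlines, seed=sweep_seed)
            deadline.to_csv(deadline_path)

    # -- report -----------------------------------------------------------
    collapse_df = pd.read_csv(collapse_path)
    at_optimum = collapse_df[collapse_df["fraction"] == collapse_df["fraction"].max()]
    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "timings_s": timings,
        "fit_objective_ms": fitted["objective"],
        "fitted_params": fitted["params"],
        "accuracy_by_level_at_operating_point": {
            str(r.noise_level): float(r.accuracy) for r in at_optimum.itertuples()
        },
        "n_trials": len(trials),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
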