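"""End-to-end classifier composing the front end, the STDP layer and the race.

`TemporalHMAX` is a sklearn-style classifier: ``fit`` encodes the training
images into latency spike trains, trains one STDP sub-population per class,
and calibrates a symmetric decision bound on the training trials (maximum
training accuracy, ties toward the lower mean RT).  ``predict`` runs the race
readout, with a forced choice by bound proximity when no accumulator crosses
within a trial's trace.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .decision import DecisionParams, Trial, classify, decide, trace_from_s2
from .frontend import SpikeEncoder, SpikeTrain
from .s2 import STDPLayer, S2SpikeTrain
from .stimuli import GrayImage

__all__ = ["TemporalHMAX", "make_trials"]


def make_trials(
    s2_trains: list[S2SpikeTrain],
    labels,
    noise_levels=None,
    class_order: tuple[str, str] | None = None,
    n_bins: int = 512,
    u: float = 0.0,
    image_ids=None,
) -> list[Trial]:
    """Bin S2 spike trains into accumulator traces tagged with trial metadata."""
    labels = list(labels)
    if class_order is None:
        class_order = tuple(sorted(set(labels)))
    if noise_levels is None:
        noise_levels = [0.0] * len(s2_trains)
    if image_ids is None:
        image_ids = [t.image_id for t in s2_trains]
    trials = []
    for s2t, lbl, lvl, iid in zip(s2_trains, labels, noise_levels, image_ids):
        trace = trace_from_s2(s2t, labels=class_order, n_bins=n_bins, u=u)
        trials.append(Trial(trace=trace, noise_level=float(lvl), label=str(lbl),
                            image_id=iid))
    return trials


class TemporalHMAX(ClassifierMixin, BaseEstimator):
    """Spiking hierarchical classifier with an accumulation-to-bound readout.

    Parameters
    ----------
    encoder, stdp:
        Optionally pre-configured :class:`SpikeEncoder` / :class:`STDPLayer`
        instances; defaults are built when omitted.
    threshold_fraction:
        The symmetric decision bound is this fraction of the mean final
        evidence of the winning accumulator on the training trials — the
        midpoint of the speed-accuracy trade-off by default.
    alpha, rt_motor:
        Time scale (ms per model unit) and non-decision time (ms) applied to
        crossing times; for pure classification they only scale reported RTs.
    n_bins:
        Bins per trial trace (the trace horizon is the trial's last spike).
    """

    def __init__(
        self,
        encoder: SpikeEncoder | None = None,
        stdp: STDPLayer | None = None,
        threshold_fraction: float = 0.5,
        alpha: float = 1.0,
        rt_motor: float = 0.0,
        u: float = 0.0,
        n_bins: int = 512,
        random_state: int = 0,
    ):
        self.encoder = encoder
        self.stdp = stdp
        self.threshold_fraction = threshold_fraction
        self.alpha = alpha
        self.rt_motor = rt_motor
        self.u = u
        self.n_bins = n_bins
        self.random_state = random_state

    def _encode(self, X) -> list[SpikeTrain]:
        return self.encoder_.transform(X)

    def fit(self, X: list[GrayImage], y) -> "TemporalHMAX":
        y = np.asarray([str(v) for v in y])
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("TemporalHMAX is a two-category classifier")
        self.encoder_ = (
            self.encoder if self.encoder is not None else SpikeEncoder()
        ).fit()
        self.stdp_ = (
            self.stdp
            if self.stdp is not None
            else STDPLayer(random_state=self.random_state)
        )
        trains = self._encode(X)
        self.stdp_.fit(trains, y)
        s2_trains = self.stdp_.transform(trains)
        trials = make_trials(
            s2_trains, y, class_order=tuple(self.classes_), n_bins=self.n_bins,
            u=self.u,
        )
        self.params_ = self._calibrate_threshold(trials)
        return self

    def _calibrate_threshold(self, trials: list[Trial]) -> DecisionParams:
        """Symmetric bound at ``threshold_fraction`` of the mean final
        evidence of the winning accumulator on the training trials.

        Half the available evidence by default: low enough that most trials
        cross the bound, high enough that single early spikes cannot decide.
        """
        finals = [
            max(float(t.trace.ac_face[-1]), float(t.trace.ac_house[-1]), 1.0)
            for t in trials
        ]
        th = max(1.0, self.threshold_fraction * float(np.mean(finals)))
        return DecisionParams(
            th_face=th, th_house=th, alpha=self.alpha,
            rt_motor=self.rt_motor, u=self.u,
        )

    def decision_trials(self, X, y=None, noise_levels=None) -> list[Trial]:
        """Encode images end to end into decision-ready trials."""
        trains = self._encode(X)
        s2_trains = self.stdp_.transform(trains)
        labels = y if y is not None else [""] * len(X)
        return make_trials(
            s2_trains, labels, noise_levels, class_order=tuple(self.classes_),
            n_bins=self.n_bins, u=self.u,
        )

    def predict(self, X) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        trials = self.decision_trials(X)
        return np.array(
            [classify(t.trace, self.params_, rng).choice for t in trials]
        )

    def predict_outcomes(self, X) -> list:
        rng = np.random.default_rng(self.random_state)
        return [
            classify(t.trace, self.params_, rng) for t in self.decision_trials(X)
        ]
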