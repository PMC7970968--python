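# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the synthetic data that stands in for laboratory
stimuli and psychophysics, and the numerical choices made where the design
was genuinely open.

## Front end

S1 kernels are 5×5 Gabors — a cosine carrier of wavelength 5 px running
perpendicular to the preferred bar axis inside an isotropic Gaussian
envelope of width (σ) 2 px — at orientations 22.5°, 67.5°, 112.5°, 157.5°
(offset from the cardinal axes so horizontal/vertical edges do not dominate).
Each kernel is mean-subtracted and L2-normalized, so a uniform image produces
zero response in the map interior; borders are zero-padded and therefore
respond weakly to uniform input, which is harmless downstream because border
responses pool like any others. Responses are rectified to magnitudes:
latency coding needs a non-negative "local contrast", and edge polarity is
not informative for this task.

The input is resized to scales (1.00, 0.71, 0.50, 0.35, 0.25) with
`round(factor × dimension)` pixel counts. C1 pools each oriented map over
7×7 windows slid with one-pixel overlap (stride 6); the output has
⌊n/6⌋ rows/columns per dimension, with edge-replication padding absorbing
the remainder so the window grid always covers the map (a 454×300 input
yields 75×50 at full scale). The implementation samples a
`maximum_filter(..., mode="nearest")` at window centers, which is
arithmetically identical to explicit padded window maxima and is verified
against a brute-force oracle in the tests. The cross-orientation stage takes
the pixelwise maximum over the four orientations; ties break toward the
lowest orientation index so results are order-independent.

Latency coding: every pooled activation v > ε (ε = 10⁻⁶, guarding against
unbounded reciprocals) emits one spike at time 1/v carrying its (scale, row,
column, winning orientation). Events are sorted by time, ties broken
lexicographically by (scale, row, column, orientation) for bit-for-bit
reproducibility. Model time is therefore in units of reciprocal activation;
it acquires milliseconds only through the fitted time scale α.

## S2: STDP training and multi-spike inference

Each cell has one weight per C1 afferent — per (scale, row, column,
orientation). Storing orientation-resolved weights uses the orientation tag
that the spike code explicitly carries; an orientation-blind variant
(weights shared across orientations at a site) is available via
`orientation_sensitive=False`.

Weights initialize i.i.d. Gaussian (mean 0.8, sd 0.05, clipped to [0, 1]).
The training threshold θ of a cell defaults to 2/3 of its mean total drive
over the training set — a calibration pass anchoring θ to what the cell can
actually reach. Training replays one image's events in latency order; among
the cells of the category being trained, the first to integrate past θ fires
once (one-winner-take-all per presentation; ties resolve to the larger
potential, then the lower cell index) and updates: causal afferents
(arriving at or before the postsynaptic spike) are potentiated
`w ← w + a₊ w(1−w)` and all other synapses depressed `w ← w − a₋ w(1−w)`,
with a₊ = 2⁻⁵ and a₋ = 0.75·2⁻⁵. The multiplicative soft bounds keep
weights in [0, 1] for any learning rate ≤ 1 and drive them toward a binary
template. Potentials reset at each image onset; updates happen once per
presentation.

Defaults run 400 epochs over the training images. With winner-take-all,
each presentation updates a single cell, so polarizing a cell's weights at
these learning rates takes on the order of a thousand presentations — the
training scale this family of models has always used. A known property of
global winner-take-all without homeostasis (homeostasis is out of scope) is
that a few cells per category capture most presentations and become
selective while the rest stay near initialization; the population-level
evidence streams still separate the categories, but population contrasts are
diluted relative to a fully engaged population.

At inference the threshold is f·θ with f = 0.5 by default (the magnitude of
the threshold reduction is a free design constant, exposed as
`threshold_factor`), the potential resets to zero after every spike
(overshoot discarded), all cells of both categories respond to every image,
and output spikes are stamped with the triggering afferent's time (no
synaptic delay). Setting f = 1 with a one-spike-per-cell cap reproduces the
unmodified single-spike pass exactly; this equivalence is asserted bitwise
in the tests.

## Decision layer

Spike trains pooled per category are binned (default: the trial's last
output spike divided into 512 bins) and accumulated per the race equations
with opposing-accumulator coefficient u = 0. "Reaching" a bound is the first
bin with AC ≥ TH, since discrete sums can jump past it. If both accumulators
first cross in the same bin, the larger fractional overshoot AC/TH wins;
exact ties fall to a seeded coin flip. Trials whose traces never cross within
the horizon are undecided; they are excluded from level means during
fitting (a fixed-penalty alternative is available), and classification
falls back to a forced choice by bound proximity AC/TH at the end of the
trace.

The fit objective is the literal sum over noise levels of the Euclidean
distance between model and observed (face, house) mean-RT pairs — a sum of
distances, not a mean of squares, so it is kept under the neutral name
`objective`. Model means are per (level, chosen category): a trial
contributes to the category it was categorized as. Optimization is
Nelder–Mead over log-transformed (TH_face, TH_house, α, RT_motor) — the log
keeps all four positive — with tolerances 10⁻⁶, at most 2000 evaluations per
start, and 5 restarts.

Two initialization devices make the simplex reliable. The objective is
nearly degenerate along α × ⌈TH⌉: for Poisson-like evidence the mean correct
RT depends on the product only, and thresholds are pinned down mainly by how
error trials contaminate the choice-conditioned means. The fit therefore
(1) scans 17 symmetric threshold values (¼× to 4× the initial geometric
mean), warm-starting (α, RT_motor) at each by least squares — once
thresholds are fixed, choices and crossing times are fixed, so RT is linear
in those two — and uses the best three scan points as additional simplex
starts; and (2) reruns the simplex once from the best optimum with a fresh
simplex before accepting it. On the parameter-recovery fixture this recovers
the generative α and RT_motor essentially exactly and the thresholds within
the integer-step resolution that the crossing rule allows (the crossing is
the ⌈TH⌉-th spike, so any TH in the same unit step is observationally
identical).

The classifier's default operating point (when no behavioral table is being
fitted) sets a symmetric bound at half the mean final evidence of the
winning accumulator on the training trials — the midpoint of the
speed–accuracy trade-off: low enough that nearly all trials cross, high
enough that no single early spike decides.

## Experiment protocols

*Leave-n-out*: each of (default) 10 runs holds out n images per category —
blocks drawn without replacement across runs until a category is exhausted,
then reshuffled — trains a fresh end-to-end classifier on the remaining
clean images, and evaluates the held-out images at every noise level;
decision parameters are recalibrated per run. *Bound collapse* scales both
thresholds by a common fraction and re-decides every trial. *Bound grids*
re-decide at every (TH_face, TH_house) pair and report the conditional
accuracy of each choice type (the precision of face choices rises with the
face bound). *Deliberation sweeps* force a proximity choice at fixed
deadlines. *Fast/slow splits* halve the correct trials at the median RT
(odd counts put the middle trial in the slow half) and compare halves with a
two-sided Mann–Whitney rank-sum test. *find_optimum_bound* searches a grid
exhaustively for the accuracy maximizer subject to a mean-RT cap (default
2000 ms), ties toward the lower mean RT.

One caveat the sweeps expose: forced-choice accuracy rises from chance to
its maximum across the decision period (deadlines up to roughly twice the
mean decided RT) and then *decays* for much longer deadlines, because after
the race would have finished only weak, late, noise-driven spikes keep
arriving and dilute the proximity readout. Accumulating more evidence is
beneficial exactly over the window in which informative evidence arrives.

## Synthetic data

The image generator draws two structured, edge-rich motif families —
"face": elliptical outline, two eye dots, nose and mouth strokes; "house":
rectangular walls, triangle roofline, cross-barred window, door — with
per-exemplar jitter in position (±5 %), scale (0.85–1.0) and stroke
intensity (0.75–1.0), Gaussian-smoothed (σ = 0.8 px). Noise variants follow
the phase-scrambling procedure exactly: the Fourier magnitude of every
stimulus is replaced by the set's average magnitude and the phase mixed as
(1−n)·φ_image + n·φ_random with φ_random i.i.d. uniform on (−π, π],
wrapped back to (−π, π]. The random field is built conjugate-antisymmetric
and self-conjugate frequencies (DC and Nyquist lines) keep the original
phase, so the inverse transform is real and mean luminance is preserved;
the real part is taken defensively and intensities clipped to [0, 1], with
8-bit quantization only at PNG export. Ten equally spaced noise levels
(0.0–0.9) are the default grid; the printed sources for this paradigm never
list the exact level values, so the grid is configurable.

The behavioral generator draws per-trial RTs as
`base[category] + slope·level + N(0, sd)`, truncated positive, with lapse
trials flipping the recorded choice. Defaults (base 550/580 ms, slope
400 ms per unit noise, sd 80 ms, lapse 0.05, 20 trials per level) give
human-plausible means rising from ~550 to ~950 ms across the grid.

What the fixtures do *not* emulate: photographic image statistics (the
motifs are line drawings with empty backgrounds), within-category natural
variability beyond geometric jitter, individual-subject RT distributions,
or sequential/attentional effects. Passing tests on the fixture demonstrate
the model's structural claims — selectivity from STDP, noise-dependent
evidence rates, speed–accuracy control by the bound — not performance on
natural images.

## Problem sizes and determinism

The test suite and the acceptance script run the end-to-end analyses on
64×96-pixel fixtures with 8 images per category at 5 noise levels, averaged
over 5 seeds, and fit decision parameters on 200 Poisson-evidence trials
(50 per level, 4 levels); these sizes give stable directions and exact
oracle agreement while keeping a full run in tens of seconds. Full-scale
(300×450, 100 images per category, 10 levels) runs use the same code paths
via `tempohmax run`. Every random draw flows from an explicit seed —
per-stage substreams are derived from the root seed by name — and repeated
runs are bit-identical, including simplex restarts and tie-breaking coin
flips.

## Known limitations

- Eq.-style threshold equality is tested as AC ≥ TH on binned counts, so
  reported crossing times are quantized to the bin width.
- Thresholds are identifiable from RT means only up to the unit step of the
  crossing count, and only when error rates are non-negligible; with
  near-perfectly separable evidence the fitted thresholds should be read as
  equivalence classes.
- The one-winner-take-all training regime leaves some cells untrained (see
  above); their unselective firing adds symmetric baseline drive to both
  accumulators and lowers the evidence contrast at high noise.
- The race has no leak, no collapsing bounds within a trial, and no mutual
  inhibition beyond the linear u term (u = 0 throughout); RT distributions
  beyond per-level means are not fitted.
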