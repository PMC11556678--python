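"""Closed-loop session driver and navigation scoring.

Per feedback step the driver estimates the current mental state (CMS) from
the incoming data, picks the most similar anchor as the display target,
computes target-related pattern strength, projects the CMS onto the semantic
map by landmark MDS and emits one :class:`~semnf.feedback.FeedbackFrame`
carrying both display variants.  It also records, per frame, the correlation
distance between the CMS and the *instructed* target — the quantity used to
score navigation performance within and between runs.

Two source modes are supported: ``trials`` (each row of the source is
already a CMS pattern, so the loop is testable without any volume
simulation) and ``volumes`` (rows are scanner volumes; the CMS is a
delay-shifted sliding-window average converted to percent signal change and
exponentially smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feedback import (FeedbackFrame, StyleConfig, circular_frame,
                       circular_layout, map_frame, pattern_strength,
                       similarities_to_anchors)
from .mapping import SemanticMap, project_pattern
from .rsa import AnchorSet, correlation_distance

__all__ = ["SessionConfig", "Trajectory", "NavigationSummary",
           "estimate_cms", "run_session", "navigation_metrics"]


@dataclass(frozen=True)
class SessionConfig:
    """Online-extraction and feedback parameters for one session.

    ``window_volumes`` (W) and ``hemodynamic_delay_volumes`` (D) define which
    volumes contribute to the CMS at step t: the W volumes ending D volumes
    before t's acquisition — a simple online-feasible estimator of the
    haemodynamically delayed response.  Defaults (W=4, D=2 at TR 2 s, i.e. a
    ~4 s shift) follow typical real-time fMRI practice.
    """

    tr_seconds: float = 2.0
    window_volumes: int = 4
    hemodynamic_delay_volumes: int = 2
    baseline_volumes: tuple[int, ...] = ()
    smoothing_alpha: float = 0.5
    metric: str = "correlation"
    metric_options: dict | None = None
    feedback_every: int = 1
    seed: int = 0
    style: StyleConfig = field(default_factory=StyleConfig)

    def __post_init__(self):
        if self.window_volumes < 1:
            raise ValueError("window_volumes must be >= 1")
        if not 0.0 <= self.smoothing_alpha <= 1.0:
            raise ValueError("smoothing_alpha must be in [0, 1]")
        if self.feedback_every < 1:
            raise ValueError("feedback_every must be >= 1")
        if self.hemodynamic_delay_volumes < 0:
            raise ValueError("hemodynamic_delay_volumes must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Ordered feedback frames plus navigation bookkeeping for one session."""

    frames: tuple[FeedbackFrame, ...]
    instructed_targets: tuple[str, ...]
    distance_to_target: np.ndarray
    run_boundaries: tuple[int, ...] = ()

    def __post_init__(self):
        d = np.asarray(self.distance_to_target, dtype=float)
        d.setflags(write=False)
        object.__setattr__(self, "distance_to_target", d)
        if len(self.frames) != d.size or len(self.instructed_targets) != d.size:
            raise ValueError("frames, instructed_targets and distances must align")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def runs(self) -> list[slice]:
        """Frame slices for each run, split at run_boundaries."""
        bounds = [0, *self.run_boundaries, self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


@dataclass(frozen=True)
class NavigationSummary:
    """Within- and between-run navigation performance.

    ``between_run_improvement`` is mean(run 1 distances) - mean(run 2
    distances): positive when the participant tracks the instructed target
    more closely in the second run.
    """

    block_means: tuple[tuple[str, float], ...]
    run_means: tuple[float, ...]
    run_slopes: tuple[float, ...]
    between_run_improvement: float | None


def estimate_cms(volume_window: np.ndarray, baseline_mean: np.ndarray,
                 config: SessionConfig, previous: np.ndarray | None = None) -> np.ndarray:
    """CMS estimate from one (already delay-shifted) window of volumes.

    Averages the window over time, converts to percent signal change against
    the baseline mean, then exponentially smooths against the previous
    estimate: ``alpha * psc + (1 - alpha) * previous``.  ``alpha = 1``
    disables smoothing.
    """
    W = np.asarray(volume_window, dtype=float)
    b = np.asarray(baseline_mean, dtype=float)
    if W.ndim != 2 or W.shape[0] != config.window_volumes:
        raise ValueError(
            f"window must be {config.window_volumes} x V volumes, got shape {W.shape}")
    if not np.all(np.isfinite(b)):
        raise ValueError("baseline mean contains non-finite values")
    if np.any(b == 0):
        raise ValueError("baseline mean contains zero voxels; PSC undefined")
    psc = 100.0 * (W.mean(axis=0) - b) / b
    if previous is None:
        return psc
    a = config.smoothing_alpha
    return a * psc + (1.0 - a) * np.asarray(previous, dtype=float)


def _block_boundaries(labels: tuple[str, ...]) -> list[tuple[int, int, str]]:
    """Contiguous (start, stop, label) blocks of an instruction sequence."""
    blocks = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            blocks.append((start, i, labels[start]))
            start = i
    return blocks


def run_session(source: np.ndarray, anchors: AnchorSet, smap: SemanticMap,
                config: SessionConfig, instructions: list[str],
                mode: str = "trials",
                run_boundaries: tuple[int, ...] = (),
                layout: dict[str, float] | None = None) -> Trajectory:
    """Drive a full closed-loop session over a recorded or simulated source.

    Parameters
    ----------
    source
        ``trials`` mode: n_steps x V matrix, each row one CMS pattern.
        ``volumes`` mode: T x V matrix of scanner volumes; feedback steps
        start once the delay-shifted window is full.
    instructions
        Per-feedback-step instructed target labels (``trials``) or
        per-volume labels (``volumes``; the label at the window's last
        contributing volume is used).
    run_boundaries
        Source-step indices (trial or volume numbers) at which a new run
        starts; converted internally to frame indices.

    The loop is fully deterministic given its inputs: replaying a recorded
    stream yields a bit-identical trajectory.
    """
    X = np.asarray(source, dtype=float)
    if X.ndim != 2 or X.shape[1] != anchors.voxel_count:
        raise ValueError(
            f"source must be steps x {anchors.voxel_count} voxels, got shape {X.shape}")
    if config.metric != smap.metric:
        raise ValueError(f"config metric {config.metric!r} != map metric {smap.metric!r}")
    if tuple(anchors.labels) != tuple(smap.labels):
        raise ValueError("anchors do not match the map")
    for lab in instructions:
        if lab not in anchors.labels:
            raise KeyError(f"instructed target {lab!r} not among anchors {anchors.labels}")
    if layout is None:
        layout = circular_layout(anchors, mode="generic")

    W, D = config.window_volumes, config.hemodynamic_delay_volumes
    if mode == "trials":
        if len(instructions) != X.shape[0]:
            raise ValueError("need one instruction per trial step")
        step_iter = [(t, X[t], instructions[t]) for t in range(0, X.shape[0], config.feedback_every)]
        frame_bounds = tuple(
            int(np.ceil(b / config.feedback_every)) for b in run_boundaries)
    elif mode == "volumes":
        if len(instructions) != X.shape[0]:
            raise ValueError("need one instruction per volume")
        if config.baseline_volumes:
            base_idx = np.asarray(config.baseline_volumes, dtype=int)
        else:
            base_idx = np.arange(min(W, X.shape[0]))
        baseline_mean = X[base_idx].mean(axis=0)
        # feedback begins once the delay-shifted window lies entirely after
        # the baseline period (a window equal to the baseline would give an
        # exactly-zero PSC pattern with undefined correlation)
        first = max(W + D - 1, int(base_idx.max()) + W + D)
        step_iter = []
        prev = None
        ts = list(range(first, X.shape[0], config.feedback_every))
        for t in ts:
            win = X[t - D - W + 1: t - D + 1]
            cms = estimate_cms(win, baseline_mean, config, previous=prev)
            prev = cms
            step_iter.append((t, cms, instructions[t - D]))
        frame_bounds = tuple(int(np.searchsorted(ts, b)) for b in run_boundaries)
    else:
        raise ValueError(f"unknown source mode {mode!r}")

    frames, dists, instructed = [], [], []
    for t, cms, target_label in step_iter:
        sims = similarities_to_anchors(cms, anchors)
        display_target = anchors.labels[int(np.argmax(sims))]
        intensity = pattern_strength(cms, anchors.pattern(display_target))
        coords = project_pattern(smap, anchors, cms,
                                 metric=config.metric,
                                 metric_options=config.metric_options)
        mframe = map_frame(smap, coords, intensity, style=config.style, t_index=t)
        cframe = circular_frame(
            {lab: sims[i] for i, lab in enumerate(anchors.labels)},
            intensity, layout, style=config.style, t_index=t,
            cms_coords=tuple(float(c) for c in coords))
        frames.append(FeedbackFrame(
            t_index=t, cms_coords=mframe.cms_coords,
            target_label=display_target, strength=intensity.strength,
            similarity=intensity.similarity, marker_size=mframe.marker_size,
            thermometer_fills=cframe.thermometer_fills,
            thermometer_labels=cframe.thermometer_labels,
            arrow_angle=cframe.arrow_angle, dist=cframe.dist))
        dists.append(correlation_distance(cms, anchors.pattern(target_label)))
        instructed.append(target_label)
    return Trajectory(frames=tuple(frames), instructed_targets=tuple(instructed),
                      distance_to_target=np.array(dists),
                      run_boundaries=frame_bounds)


def navigation_metrics(traj: Trajectory) -> NavigationSummary:
    """Score navigation performance from a trajectory.

    Returns per-block mean distance-to-target, per-run mean and least-squares
    slope of distance versus frame index (negative slope = within-run
    improvement), and the between-run improvement mean(run 1) - mean(run 2)
    when at least two runs exist.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    d = traj.distance_to_target
    block_means = []
    for a, b, lab in _block_boundaries(traj.instructed_targets):
        block_means.append((lab, float(d[a:b].mean())))
    run_means, run_slopes = [], []
    for sl in traj.runs():
        seg = d[sl]
        run_means.append(float(seg.mean()))
        if seg.size < 2:
            raise ValueError("run with < 2 frames: slope undefined")
        x = np.arange(seg.size, dtype=float)
        run_slopes.append(float(np.polyfit(x, seg, 1)[0]))
    improvement = (run_means[0] - run_means[1]) if len(run_means) >= 2 else None
    return NavigationSummary(
        block_means=tuple(block_means), run_means=tuple(run_means),
        run_slopes=tuple(run_slopes), between_run_improvement=improvement)
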