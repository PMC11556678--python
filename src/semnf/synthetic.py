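"""Synthetic closed-loop fMRI data: anchors, trials, volume runs, agent.

Everything downstream of a scanner is testable against this module: anchor
patterns with a prescribed pairwise correlation structure, noisy localizer
trials, HRF-convolved block-design volume time series, and a navigating
participant agent that emulates "engaging in an emotion" as convex mixture
movement in anchor space.  All generators are pure functions of their
parameters and seed: repeated calls are bit-identical.

The default four-state ground truth mirrors a typical emotion localizer
('happy', 'content', 'angry', 'sad'): states of the same valence correlate
at 0.5, states of opposite valence are uncorrelated.  Trial noise defaults
to SD 0.5 relative to the anchor SD — strong single-trial noise that still
lets 20-trial condition means recover the anchor structure, as a localizer
run must.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rsa import AnchorSet

__all__ = ["GroundTruth", "AgentConfig", "default_target_corr", "make_anchors",
           "make_trials", "double_gamma_hrf", "make_timeseries",
           "simulate_agent", "project_to_simplex"]

DEFAULT_LABELS = ("happy", "content", "angry", "sad")


def default_target_corr(n_cond: int = 4, within: float = 0.5,
                        between: float = 0.0) -> np.ndarray:
    """Valence-structured target correlation matrix: the first half of the
    states and the second half each form a correlated (same-valence) group."""
    C = np.full((n_cond, n_cond), between)
    half = n_cond // 2
    C[:half, :half] = within
    C[half:, half:] = within
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters for a synthetic localizer."""

    anchors: AnchorSet
    target_corr: np.ndarray
    noise_sigma: float = 0.5
    intensity_schedule: np.ndarray | None = None
    seed: int = 0


@dataclass(frozen=True)
class AgentConfig:
    """Navigating-participant parameters.

    The agent's hidden state is a mixture weight vector over the anchors
    (a point on the simplex); each step it moves a fraction
    ``learning_rate`` of the way toward the instructed target's vertex,
    is jittered by ``state_noise_sigma`` and re-projected to the simplex.
    The 'neutral' starting state is the uniform mixture by default.
    """

    start_state: np.ndarray | None = None
    learning_rate: float = 0.2
    state_noise_sigma: float = 0.02
    emission_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1]")
        if self.start_state is not None:
            w = np.asarray(self.start_state, dtype=float)
            if w.ndim != 1 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("start_state must be nonnegative and sum to 1")
            w = w / w.sum()
            w.setflags(write=False)
            object.__setattr__(self, "start_state", w)


def _check_corr(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("target correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("target correlation matrix must have unit diagonal")
    evals = np.linalg.eigvalsh((C + C.T) / 2)
    if evals.min() < -1e-10:
        raise ValueError(
            f"target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {evals.min():.3g})")
    return (C + C.T) / 2


def make_anchors(n_cond: int = 4, voxel_count: int = 500,
                 target_corr: np.ndarray | None = None,
                 labels: tuple[str, ...] | None = None,
                 seed: int = 0) -> tuple[AnchorSet, np.ndarray]:
    """Anchor patterns with a prescribed pairwise correlation structure.

    Draws ``n_cond`` i.i.d. standard-normal voxel vectors and mixes them by a
    matrix square root of the target correlation matrix, so the sample
    correlations converge entrywise to the target as the voxel count grows.
    Returns the anchor set and the *achieved* sample correlation matrix;
    tests should compare against the achieved values, not the target.
    """
    if target_corr is None:
        target_corr = default_target_corr(n_cond) if n_cond > 1 else np.ones((1, 1))
    C = _check_corr(target_corr)
    if C.shape[0] != n_cond:
        raise ValueError(f"target_corr is {C.shape[0]}x{C.shape[0]} but n_cond={n_cond}")
    if labels is None:
        labels = DEFAULT_LABELS[:n_cond] if n_cond <= 4 else tuple(
            f"state{i}" for i in range(n_cond))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_cond, voxel_count))
    evals, evecs = np.linalg.eigh(C)
    S = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    P = S @ Z
    achieved = np.corrcoef(P) if n_cond > 1 else np.ones((1, 1))
    if n_cond == 1:
        # AnchorSet requires >= 2 conditions; return the raw pattern matrix path
        return P, achieved
    return AnchorSet(labels=labels, patterns=P, source=f"synthetic(seed={seed})"), achieved


def make_trials(anchors: AnchorSet, condition_sequence,
                intensity_schedule=None, noise_sigma: float = 0.5,
                seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Noisy single-trial patterns: ``intensity * anchor + noise``.

    Noise SD is ``noise_sigma`` times the corresponding anchor's own SD, so
    ``noise_sigma`` is a relative (unitless) noise level.  Returns the
    trials x voxels matrix and the trial labels.
    """
    seq = list(condition_sequence)
    if intensity_schedule is None:
        intensity_schedule = np.ones(len(seq))
    intensity_schedule = np.asarray(intensity_schedule, dtype=float)
    if intensity_schedule.size != len(seq):
        raise ValueError("intensity_schedule length must match condition_sequence")
    rng = np.random.default_rng(seed)
    V = anchors.voxel_count
    out = np.empty((len(seq), V))
    sds = anchors.patterns.std(axis=1)
    for i, (lab, amp) in enumerate(zip(seq, intensity_schedule)):
        if lab not in anchors.labels:
            raise KeyError(f"unknown condition label {lab!r}")
        j = anchors.labels.index(lab)
        out[i] = amp * anchors.patterns[j] + noise_sigma * sds[j] * rng.standard_normal(V)
    return out, [str(s) for s in seq]


def double_gamma_hrf(t_seconds: np.ndarray, peak: float = 6.0,
                     undershoot: float = 16.0, peak_disp: float = 1.0,
                     under_disp: float = 1.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalized to 1.

    Defaults: response peak at 6 s, undershoot at 16 s, undershoot amplitude
    1/6 of the peak — the standard published shape.
    """
    from scipy.stats import gamma as gamma_dist
    t = np.asarray(t_seconds, dtype=float)
    h = (gamma_dist.pdf(t, peak / peak_disp, scale=peak_disp)
         - ratio * gamma_dist.pdf(t, undershoot / under_disp, scale=under_disp))
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


@dataclass(frozen=True)
class Block:
    """One task block of a run design."""

    condition: str
    onset_s: float
    duration_s: float


def make_timeseries(anchors: AnchorSet, block_design, n_volumes: int,
                    tr_seconds: float = 2.0, baseline: float = 100.0,
                    amplitude_psc: float = 2.0, noise_sigma: float = 0.2,
                    seed: int = 0) -> np.ndarray:
    """HRF-convolved block-design volume time series (T x V).

    Voxel signal is ``baseline * (1 + amplitude_psc/100 * anchor_v * conv(t)
    + noise_sigma/100 * eps)`` where ``conv`` is the boxcar of each block
    convolved with the canonical double-gamma HRF (peak-normalized), so
    ``amplitude_psc`` and ``noise_sigma`` are in percent-signal-change units.
    Blocks of different conditions must not overlap.
    """
    blocks = [b if isinstance(b, Block) else Block(*b) for b in block_design]
    for b in blocks:
        if b.condition not in anchors.labels:
            raise KeyError(f"unknown block condition {b.condition!r}")
    ivals = sorted((b.onset_s, b.onset_s + b.duration_s, b.condition) for b in blocks)
    for (a0, a1, ca), (b0, b1, cb) in zip(ivals[:-1], ivals[1:]):
        if b0 < a1 and ca != cb:
            raise ValueError(
                f"overlapping blocks of different conditions ({ca!r}, {cb!r})")
    t = np.arange(n_volumes) * tr_seconds
    hrf_t = np.arange(0, 32.0 + tr_seconds, tr_seconds)
    hrf = double_gamma_hrf(hrf_t)
    V = anchors.voxel_count
    signal = np.zeros((n_volumes, V))
    for lab in anchors.labels:
        box = np.zeros(n_volumes)
        for b in blocks:
            if b.condition == lab:
                box[(t >= b.onset_s) & (t < b.onset_s + b.duration_s)] = 1.0
        if box.any():
            conv = np.convolve(box, hrf)[:n_volumes]
            j = anchors.labels.index(lab)
            signal += np.outer(conv, anchors.patterns[j])
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_volumes, V))
    return baseline * (1.0 + amplitude_psc / 100.0 * signal
                       + noise_sigma / 100.0 * noise)


def project_to_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    w = np.asarray(w, dtype=float)
    u = np.sort(w)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, w.size + 1) > 0)[0][-1]
    theta = (1.0 - css[rho]) / (rho + 1)
    return np.clip(w + theta, 0.0, None)


def simulate_agent(anchors: AnchorSet, instruction_blocks,
                   agent: AgentConfig) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Navigating participant: emitted patterns plus ground-truth mixtures.

    ``instruction_blocks`` is a list of ``(target_label, n_steps)``.  Each
    step the mixture moves toward the instructed vertex by the learning rate
    (``w <- (1 - lr) w + lr e_target``), is jittered and re-projected to the
    simplex; the emitted pattern is the anchor mixture plus emission noise
    (SD ``emission_sigma`` times the mean anchor SD).  The mixture state
    persists across blocks, emulating a participant who carries their
    current mental state into the next instruction.

    Returns (patterns, per-step instructed labels, mixture trace).
    """
    n = anchors.n_cond
    w = (np.full(n, 1.0 / n) if agent.start_state is None
         else np.asarray(agent.start_state, dtype=float))
    if w.size != n:
        raise ValueError(f"start_state has {w.size} weights for {n} anchors")
    rng = np.random.default_rng(agent.seed)
    sd_scale = float(anchors.patterns.std(axis=1).mean())
    steps, labels, trace = [], [], []
    for target, n_steps in instruction_blocks:
        if target not in anchors.labels:
            raise KeyError(f"unknown instructed target {target!r}")
        e = np.zeros(n)
        e[anchors.labels.index(target)] = 1.0
        for _ in range(int(n_steps)):
            w = (1.0 - agent.learning_rate) * w + agent.learning_rate * e
            if agent.state_noise_sigma > 0:
                w = w + agent.state_noise_sigma * rng.standard_normal(n)
                w = project_to_simplex(w)
            pattern = w @ anchors.patterns
            if agent.emission_sigma > 0:
                pattern = pattern + agent.emission_sigma * sd_scale * rng.standard_normal(
                    anchors.voxel_count)
            steps.append(pattern)
            labels.append(target)
            trace.append(w.copy())
    return np.array(steps), labels, np.array(trace)
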