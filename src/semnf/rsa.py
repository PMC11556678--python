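"""Pattern containers, pairwise dissimilarity metrics and RDM construction.

Representational similarity analysis (RSA) characterizes a set of mental
states by the matrix of pairwise dissimilarities between the multi-voxel
activity patterns they evoke.  The workhorse metric for real-time use is the
correlation distance ``d = 1 - Pearson's r``, which ranges from 0 (patterns
identical up to a positive affine transform) through 1 (uncorrelated) to 2
(perfectly anticorrelated).  Euclidean and Mahalanobis distances are offered
as alternatives that retain amplitude information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

__all__ = [
    "VoxelPattern",
    "AnchorSet",
    "RDM",
    "ZeroVarianceError",
    "normalize_pattern",
    "correlation_distance",
    "euclidean_distance",
    "mahalanobis_distance",
    "estimate_noise_covariance",
    "build_rdm",
    "select_voxels",
    "METRICS",
]

log = logging.getLogger(__name__)

METRICS = ("correlation", "euclidean", "mahalanobis")


class ZeroVarianceError(ValueError):
    """A constant pattern was passed where Pearson correlation is undefined."""


def _values(pattern) -> np.ndarray:
    """Accept a VoxelPattern or any 1-D array-like; return a float vector."""
    if isinstance(pattern, VoxelPattern):
        return pattern.values
    v = np.asarray(pattern, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"pattern must be a 1-D vector of >= 2 voxels, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("pattern contains non-finite values")
    return v


@dataclass(frozen=True)
class VoxelPattern:
    """One multi-voxel activity vector (a current or anchor mental state).

    Parameters
    ----------
    values
        Voxel activations in arbitrary BOLD units or percent signal change.
    label
        Optional mental-state name (e.g. ``"happy"``).
    """

    values: np.ndarray
    label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {v.shape}")
        if v.size < 3:
            raise ValueError(f"voxel_count must be >= 3, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ValueError("pattern contains non-finite values")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def voxel_count(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AnchorSet:
    """Labelled base mental-state patterns measured in localizer runs.

    Rows of ``patterns`` are the anchor ("landmark") activity patterns, one
    per mental state, in the order given by ``labels``.
    """

    labels: tuple[str, ...]
    patterns: np.ndarray
    source: str = ""

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        P = np.asarray(self.patterns, dtype=float)
        if P.ndim != 2:
            raise ValueError(f"patterns must be 2-D (conditions x voxels), got shape {P.shape}")
        if len(labels) != P.shape[0]:
            raise ValueError(f"{len(labels)} labels for {P.shape[0]} pattern rows")
        if P.shape[0] < 2:
            raise ValueError("need at least 2 anchor conditions")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate anchor labels in {labels}")
        if not np.all(np.isfinite(P)):
            raise ValueError("anchor patterns contain non-finite values")
        if np.any(P.std(axis=1) == 0):
            bad = labels[int(np.argmin(P.std(axis=1)))]
            raise ZeroVarianceError(f"anchor {bad!r} has zero variance")
        P.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "patterns", P)

    @property
    def n_cond(self) -> int:
        return int(self.patterns.shape[0])

    @property
    def voxel_count(self) -> int:
        return int(self.patterns.shape[1])

    def pattern(self, label: str) -> VoxelPattern:
        """Return the anchor pattern for one mental-state label."""
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown anchor label {label!r}; have {self.labels}") from None
        return VoxelPattern(self.patterns[i], label=label)


@dataclass(frozen=True)
class RDM:
    """Symmetric representational dissimilarity matrix over anchor states."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    metric: str = "correlation"

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        M = np.asarray(self.matrix, dtype=float)
        n = len(labels)
        if M.shape != (n, n):
            raise ValueError(f"matrix shape {M.shape} does not match {n} labels")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if not np.allclose(M, M.T, atol=1e-10):
            i, j = np.unravel_index(np.argmax(np.abs(M - M.T)), M.shape)
            raise ValueError(
                f"RDM not symmetric: worst cell ({labels[i]!r}, {labels[j]!r}) "
                f"differs by {abs(M[i, j] - M[j, i]):.3g}"
            )
        M = (M + M.T) / 2.0
        if np.any(np.diag(M) != 0):
            raise ValueError("RDM diagonal must be exactly 0")
        if np.any(M < -1e-12):
            raise ValueError("RDM entries must be nonnegative")
        M = np.clip(M, 0.0, None)
        if self.metric == "correlation" and np.any(M > 2 + 1e-10):
            raise ValueError("correlation distances must lie in [0, 2]")
        M.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "matrix", M)

    @property
    def n_cond(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_pattern(p, method: str = "none", baseline=None) -> VoxelPattern:
    """Normalize a voxel pattern.

    ``zscore`` maps to mean 0 / SD 1; ``psc`` converts to percent signal
    change, ``100 * (p - baseline) / baseline`` elementwise; ``none`` is the
    identity.
    """
    v = _values(p)
    label = p.label if isinstance(p, VoxelPattern) else None
    if method == "none":
        out = v
    elif method == "zscore":
        sd = v.std()
        if sd == 0:
            raise ZeroVarianceError("cannot z-score a zero-variance pattern")
        out = (v - v.mean()) / sd
    elif method == "psc":
        if baseline is None:
            raise ValueError("psc normalization requires a baseline pattern")
        b = _values(baseline)
        if b.size != v.size:
            raise ValueError(f"baseline has {b.size} voxels, pattern has {v.size}")
        if np.any(b == 0):
            raise ValueError("psc undefined: baseline contains zero voxels")
        out = 100.0 * (v - b) / b
    else:
        raise ValueError(f"unknown normalization {method!r}; choose none, zscore or psc")
    return VoxelPattern(out, label=label)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def correlation_distance(a, b) -> float:
    """``1 - Pearson's r`` between two patterns, in [0, 2].

    0 means perfect correlation, 1 no correlation, 2 perfect anticorrelation.
    Raises :class:`ZeroVarianceError` for constant input rather than silently
    returning a value, because an undefined correlation would corrupt the map.
    """
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise ValueError(f"voxel counts differ: {va.size} vs {vb.size}")
    ca, cb = va - va.mean(), vb - vb.mean()
    na, nb = np.linalg.norm(ca), np.linalg.norm(cb)
    if na == 0 or nb == 0:
        raise ZeroVarianceError("correlation distance undefined for a constant pattern")
    r = float(np.dot(ca, cb) / (na * nb))
    return float(np.clip(1.0 - r, 0.0, 2.0))


def euclidean_distance(a, b, normalized: bool = False) -> float:
    """L2 distance between patterns; ``normalized`` divides by sqrt(voxel count)
    so values are comparable across ROI sizes."""
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise ValueError(f"voxel counts differ: {va.size} vs {vb.size}")
    d = float(np.linalg.norm(va - vb))
    return d / np.sqrt(va.size) if normalized else d


def mahalanobis_distance(a, b, noise_cov) -> float:
    """Mahalanobis distance ``sqrt((a-b)^T Sigma^-1 (a-b))``.

    ``noise_cov`` is either a per-voxel variance vector (diagonal covariance,
    the default estimator here since voxels usually outnumber trials) or a
    full covariance matrix; it must be positive definite.
    """
    va, vb = _values(a), _values(b)
    if va.size != vb.size:
        raise ValueError(f"voxel counts differ: {va.size} vs {vb.size}")
    diff = va - vb
    C = np.asarray(noise_cov, dtype=float)
    if C.ndim == 1:
        if C.size != va.size:
            raise ValueError(f"covariance dimension {C.size} != voxel count {va.size}")
        if np.any(C <= 0):
            raise ValueError("noise covariance is not positive definite (nonpositive variance)")
        return float(np.sqrt(np.sum(diff**2 / C)))
    if C.shape != (va.size, va.size):
        raise ValueError(f"covariance shape {C.shape} != ({va.size}, {va.size})")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ValueError("noise covariance is not positive definite") from None
    y = np.linalg.solve(L, diff)
    return float(np.linalg.norm(y))


def estimate_noise_covariance(residuals, shrinkage: float = 0.3) -> np.ndarray:
    """Diagonal noise covariance from residual patterns, shrunk toward the
    scaled identity.

    Returns the per-voxel variance vector ``(1 - shrinkage) * var_v +
    shrinkage * mean(var)``.  A diagonal target is used because the number of
    voxels typically far exceeds the number of residual samples, making the
    full sample covariance singular.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need a 2-D residual matrix with >= 2 samples")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    v = R.var(axis=0, ddof=1)
    out = (1.0 - shrinkage) * v + shrinkage * v.mean()
    if np.any(out <= 0):
        raise ValueError("shrunk covariance not positive definite (all-constant residuals?)")
    return out


def _pairwise(P: np.ndarray, metric: str, metric_options: dict | None) -> np.ndarray:
    opts = dict(metric_options or {})
    if metric == "correlation":
        D = squareform(pdist(P, metric="correlation"))
    elif metric == "euclidean":
        D = squareform(pdist(P, metric="euclidean"))
        if opts.get("normalized", False):
            D = D / np.sqrt(P.shape[1])
    elif metric == "mahalanobis":
        cov = opts.get("noise_cov")
        if cov is None:
            raise ValueError("mahalanobis metric requires metric_options['noise_cov']")
        cov = np.asarray(cov, dtype=float)
        VI = np.diag(1.0 / cov) if cov.ndim == 1 else np.linalg.inv(cov)
        if cov.ndim == 1 and np.any(cov <= 0):
            raise ValueError("noise covariance is not positive definite")
        D = squareform(pdist(P, metric="mahalanobis", VI=VI))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return D


def build_rdm(anchors: AnchorSet, metric: str = "correlation",
              metric_options: dict | None = None) -> RDM:
    """Pairwise dissimilarities between all anchor patterns, as an :class:`RDM`."""
    try:
        D = _pairwise(anchors.patterns, metric, metric_options)
    except ZeroVarianceError:
        raise
    except ValueError:
        raise
    if not np.all(np.isfinite(D)):
        i, j = np.argwhere(~np.isfinite(D))[0]
        raise ValueError(
            f"metric {metric!r} undefined for anchor pair "
            f"({anchors.labels[i]!r}, {anchors.labels[j]!r})"
        )
    np.fill_diagonal(D, 0.0)
    return RDM(labels=anchors.labels, matrix=D, metric=metric)


# ---------------------------------------------------------------------------
# voxel selection
# ---------------------------------------------------------------------------

def select_voxels(training_patterns, condition_labels, k: int) -> np.ndarray:
    """Rank voxels by between-condition discriminability and return the top k.

    The score is the per-voxel one-way F statistic across conditions — a
    simple deterministic stand-in for classifier weight maps used as a
    voxel-selection pre-processing step.  Ties are broken by ascending voxel
    index so the ordering is stable.
    """
    X = np.asarray(training_patterns, dtype=float)
    labels = np.asarray(condition_labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("training_patterns must be trials x voxels with one label per trial")
    conds = list(dict.fromkeys(labels.tolist()))
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions for voxel selection")
    groups = []
    for c in conds:
        g = X[labels == c]
        if g.shape[0] < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
        groups.append(g)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_oneway(*groups, axis=0)
    F = np.asarray(F, dtype=float)
    F[np.isnan(F)] = -np.inf  # undefined scores (zero variance everywhere) rank last
    order = np.lexsort((np.arange(X.shape[1]), -F))
    return order[:k]
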