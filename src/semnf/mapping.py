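"""Low-dimensional semantic maps: classical MDS and landmark projection.

The RDM over anchor mental states is embedded into a 2-D (or 3-D) map by
classical (Torgerson) multidimensional scaling: square the dissimilarities,
double-center, eigendecompose, and scale the leading eigenvectors by the
square roots of their eigenvalues.  Classical MDS is chosen over iterative
stress majorization because it is deterministic and closed-form, and because
it is exactly the basis required by the landmark-MDS out-of-sample projection
(de Silva & Tenenbaum): a new pattern is placed on the map from nothing but
its dissimilarities to the embedded anchors, without recomputing the map.

MDS output is defined only up to rotation/reflection, so a canonical
orientation (anchor 1 on the nonnegative first axis, anchor 2 with
nonnegative second coordinate, anchor 3 with nonnegative third) is applied to
make maps and replays bit-stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .rsa import RDM, AnchorSet, _pairwise, _values

__all__ = ["SemanticMap", "StressReport", "embed_rdm", "project_pattern",
           "stress", "canonical_orientation"]

log = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class StressReport:
    """Goodness of fit of a map to its RDM (Kruskal stress-1; 0 = perfect)."""

    stress: float
    formula: str = "kruskal_stress1"
    dims: int = 2


@dataclass(frozen=True)
class SemanticMap:
    """Anchor embedding plus everything needed to project new patterns.

    Attributes
    ----------
    labels, coords
        Anchor names and their ``n_cond x dims`` map coordinates (centered,
        canonically oriented, dimensionless map units).
    eigenvalues
        Retained (strictly positive, descending) MDS eigenvalues.
    eigenvectors
        The matching ``n_cond x dims`` eigenvectors of the double-centered
        matrix, in the *unrotated* frame — the landmark projection basis.
    sqdist_col_means
        Column means of the squared anchor-dissimilarity matrix, used to
        center a new pattern's squared-dissimilarity vector.
    rotation
        Orthogonal ``dims x dims`` matrix mapping the raw eigen-frame into
        the displayed (canonical) frame; applied to projected points too.
    metric, metric_options
        Dissimilarity metric the map was built with; projections must match.
    orientation
        Tag naming the canonicalization applied.
    """

    labels: tuple[str, ...]
    coords: np.ndarray
    dims: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    sqdist_col_means: np.ndarray
    rotation: np.ndarray
    metric: str = "correlation"
    metric_options: dict | None = None
    orientation: str = "raw"

    def __post_init__(self):
        for name in ("coords", "eigenvalues", "eigenvectors", "sqdist_col_means", "rotation"):
            a = np.asarray(getattr(self, name), dtype=float)
            a.setflags(write=False)
            object.__setattr__(self, name, a)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_cond(self) -> int:
        return len(self.labels)

    def anchor_coords(self, label: str) -> np.ndarray:
        i = self.labels.index(label)
        return self.coords[i]


def embed_rdm(rdm: RDM, dims: int = 2) -> SemanticMap:
    """Embed an RDM into ``dims`` map dimensions by classical MDS.

    Negative eigenvalues (correlation RDMs are generally non-Euclidean) are
    truncated; an error names the eigenvalue spectrum if fewer than ``dims``
    strictly positive eigenvalues exist.  The retained-variance fraction is
    logged.
    """
    if dims not in (1, 2, 3):
        raise ValueError(f"dims must be 1, 2 or 3, got {dims}")
    n = rdm.n_cond
    if n < dims + 1:
        warnings.warn(
            f"embedding {n} anchors in {dims} dimensions: configuration is "
            "not over-determined; map may be degenerate", stacklevel=2)
    D2 = rdm.matrix**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if evals.size else 0.0
    n_pos = int(np.sum(evals > tol))
    if n_pos < dims:
        raise ValueError(
            f"RDM supports only {n_pos} positive MDS eigenvalues, need {dims}; "
            f"spectrum = {np.array2string(evals, precision=4)}")
    lam = evals[:dims]
    V = evecs[:, :dims]
    # deterministic eigenvector sign: largest-magnitude component positive
    for j in range(dims):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    retained = float(lam.sum() / evals[evals > tol].sum())
    log.info("classical MDS: retained %.1f%% of positive-eigenvalue variance "
             "in %d dims", 100 * retained, dims)
    coords = V * np.sqrt(lam)
    smap = SemanticMap(
        labels=rdm.labels, coords=coords, dims=dims, eigenvalues=lam,
        eigenvectors=V, sqdist_col_means=D2.mean(axis=0),
        rotation=np.eye(dims), metric=rdm.metric, orientation="raw")
    return canonical_orientation(smap)


def project_pattern(smap: SemanticMap, anchors: AnchorSet, cms,
                    metric: str | None = None,
                    metric_options: dict | None = None) -> np.ndarray:
    """Place a new pattern on an existing map by landmark MDS.

    Computes the vector of squared dissimilarities from ``cms`` to every
    anchor, centers it against the stored column means of the squared
    anchor-dissimilarity matrix, and maps it through the stored eigen-basis:
    ``x_j = (mu - delta) . v_j / (2 sqrt(lambda_j))``, then rotates into the
    canonical frame.  Deterministic.
    """
    metric = smap.metric if metric is None else metric
    if metric != smap.metric:
        raise ValueError(f"metric {metric!r} does not match map metric {smap.metric!r}")
    if tuple(anchors.labels) != tuple(smap.labels):
        raise ValueError("anchor labels do not match map labels")
    v = _values(cms)
    if v.size != anchors.voxel_count:
        raise ValueError(f"pattern has {v.size} voxels, anchors have {anchors.voxel_count}")
    if metric == "correlation" and v.std() == 0:
        from .rsa import ZeroVarianceError
        raise ZeroVarianceError("cannot project a constant pattern under the correlation metric")
    opts = metric_options if metric_options is not None else smap.metric_options
    both = np.vstack([anchors.patterns, v])
    delta = _pairwise(both, metric, opts)[-1, :-1] ** 2
    x_raw = (smap.sqdist_col_means - delta) @ smap.eigenvectors / (2.0 * np.sqrt(smap.eigenvalues))
    return x_raw @ smap.rotation


def stress(smap: SemanticMap, rdm: RDM) -> StressReport:
    """Kruskal stress-1 between the RDM and the embedded distances.

    ``sqrt( sum_{i<j} (delta_ij - dhat_ij)^2 / sum_{i<j} delta_ij^2 )`` where
    ``delta`` are RDM entries and ``dhat`` embedded Euclidean distances.
    """
    if tuple(rdm.labels) != tuple(smap.labels):
        raise ValueError("RDM labels do not match map labels")
    iu = np.triu_indices(rdm.n_cond, k=1)
    delta = rdm.matrix[iu]
    diff = smap.coords[:, None, :] - smap.coords[None, :, :]
    dhat = np.sqrt((diff**2).sum(-1))[iu]
    denom = float((delta**2).sum())
    if denom == 0:
        raise ValueError("stress undefined for an all-zero RDM")
    s = float(np.sqrt(((delta - dhat) ** 2).sum() / denom))
    return StressReport(stress=s, dims=smap.dims)


def _orientation_matrix(coords: np.ndarray) -> tuple[np.ndarray | None, str]:
    """Orthogonal matrix Q (applied as ``coords @ Q``) realizing the anchor
    convention, or (None, tag) when the configuration is degenerate."""
    n, d = coords.shape
    a0 = coords[0]
    if np.linalg.norm(a0) < _DEGENERATE_TOL:
        return None, "degenerate:anchor1-at-origin"
    u1 = a0 / np.linalg.norm(a0)
    if d == 1:
        return np.array([[1.0 if u1[0] > 0 else -1.0]]), "canonical"
    if d == 2:
        u2 = np.array([-u1[1], u1[0]])
        if n > 1 and coords[1] @ u2 < 0:
            u2 = -u2
        return np.column_stack([u1, u2]), "canonical"
    # d == 3: Gram-Schmidt on anchors 1..3
    tag = "canonical"
    r1 = coords[1] - (coords[1] @ u1) * u1 if n > 1 else np.zeros(3)
    if np.linalg.norm(r1) < _DEGENERATE_TOL:
        # anchor 2 colinear with anchor 1: any perpendicular works; pick
        # deterministically from the standard basis
        k = int(np.argmin(np.abs(u1)))
        e = np.zeros(3)
        e[k] = 1.0
        r1 = e - (e @ u1) * u1
        tag = "canonical:anchor2-colinear"
    u2 = r1 / np.linalg.norm(r1)
    u3 = np.cross(u1, u2)
    if n > 2 and coords[2] @ u3 < 0:
        u3 = -u3
    return np.column_stack([u1, u2, u3]), tag


def canonical_orientation(smap: SemanticMap) -> SemanticMap:
    """Rotate/reflect a map into the canonical anchor frame.

    Rigid, distance-preserving and idempotent; coincident/degenerate anchor
    configurations pass through unchanged with a flagging orientation tag.
    """
    Q, tag = _orientation_matrix(smap.coords)
    if Q is None:
        return replace(smap, orientation=tag)
    return replace(
        smap,
        coords=smap.coords @ Q,
        rotation=smap.rotation @ Q,
        orientation=tag,
    )
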