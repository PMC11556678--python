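"""Feedback displays: target-related pattern strength and display geometry.

Two display variants are supported.  The map variant shows the current mental
state (CMS) as a point on the semantic map whose marker size encodes pattern
strength.  The circular variant arranges one thermometer per anchor state on
a circle; only the target's thermometer is filled (by pattern strength) and a
central arrow encodes similarity by pointing between the target and its most
similar layout neighbour.

Pattern strength dissociates intensity from similarity: on mean-centered
vectors it is the scalar projection coefficient of the CMS onto the target
mental state (TMS), ``(CMS . TMS) / (TMS . TMS)``, so scaling the CMS by
``k > 0`` leaves the Pearson similarity (the cosine of the angle theta)
unchanged while multiplying strength by exactly ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .rsa import RDM, AnchorSet, ZeroVarianceError, _values

__all__ = ["IntensityResult", "FeedbackFrame", "ArrowResult", "StyleConfig",
           "select_target", "pattern_strength", "map_frame",
           "circular_layout", "arrow_angle", "circular_frame"]


@dataclass(frozen=True)
class StyleConfig:
    """Display scaling knobs (display units are arbitrary screen units)."""

    s_min: float = 6.0        # marker size at zero strength
    s_max: float = 30.0       # marker size at/above strength_cap
    strength_cap: float = 1.5  # strength mapped to the largest marker
    fill_cap: float = 1.5      # strength mapped to a full thermometer


@dataclass(frozen=True)
class IntensityResult:
    """Similarity and target-related pattern strength of a CMS vs a TMS.

    ``similarity`` is the Pearson r (cosine of ``angle_theta`` on centered
    vectors); ``strength`` is the length of the CMS's projection onto the TMS
    relative to the TMS's own length, i.e. the normalized intensity.
    """

    target_label: str | None
    similarity: float
    angle_theta: float
    strength: float


@dataclass(frozen=True)
class ArrowResult:
    """Central-arrow geometry for the circular display."""

    arrow_angle: float
    dist: float
    target_label: str
    neighbour_label: str | None
    low_confidence: bool = False


@dataclass(frozen=True)
class FeedbackFrame:
    """One time-point of display state."""

    t_index: int
    cms_coords: tuple[float, ...]
    target_label: str | None
    strength: float
    similarity: float = float("nan")
    marker_size: float | None = None
    thermometer_fills: tuple[float, ...] | None = None
    thermometer_labels: tuple[str, ...] | None = None
    arrow_angle: float | None = None
    dist: float | None = None

    def to_dict(self) -> dict:
        return {
            "t_index": self.t_index,
            "cms_coords": list(self.cms_coords),
            "target_label": self.target_label,
            "strength": self.strength,
            "similarity": self.similarity,
            "marker_size": self.marker_size,
            "thermometer_fills": None if self.thermometer_fills is None
            else list(self.thermometer_fills),
            "thermometer_labels": None if self.thermometer_labels is None
            else list(self.thermometer_labels),
            "arrow_angle": self.arrow_angle,
            "dist": self.dist,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedbackFrame":
        return cls(
            t_index=int(d["t_index"]),
            cms_coords=tuple(d["cms_coords"]),
            target_label=d["target_label"],
            strength=float(d["strength"]),
            similarity=float(d["similarity"]),
            marker_size=d["marker_size"],
            thermometer_fills=None if d["thermometer_fills"] is None
            else tuple(d["thermometer_fills"]),
            thermometer_labels=None if d["thermometer_labels"] is None
            else tuple(d["thermometer_labels"]),
            arrow_angle=d["arrow_angle"],
            dist=d["dist"],
        )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ca, cb = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(ca), np.linalg.norm(cb)
    if na == 0 or nb == 0:
        raise ZeroVarianceError("Pearson correlation undefined for a constant pattern")
    return float(np.dot(ca, cb) / (na * nb))


def similarities_to_anchors(cms, anchors: AnchorSet) -> np.ndarray:
    """Pearson r between the CMS and every anchor pattern, in anchor order."""
    v = _values(cms)
    if v.size != anchors.voxel_count:
        raise ValueError(f"pattern has {v.size} voxels, anchors have {anchors.voxel_count}")
    return np.array([_pearson(v, p) for p in anchors.patterns])


def select_target(cms, anchors: AnchorSet) -> str:
    """Label of the anchor most similar (Pearson correlation) to the CMS.

    Ties are broken by anchor order, so the choice is stable.
    """
    r = similarities_to_anchors(cms, anchors)
    return anchors.labels[int(np.argmax(r))]


def pattern_strength(cms, tms, center: bool = True) -> IntensityResult:
    """Similarity and target-related pattern strength of CMS versus TMS.

    With ``center`` (default) both vectors are mean-centered first, so the
    similarity coincides with the Pearson r used everywhere else; ``strength``
    is the scalar projection coefficient ``(CMS . TMS) / (TMS . TMS)`` on
    those vectors.  Raw-vector mode (``center=False``) uses uncentered dot
    products and cosine similarity.
    """
    vc, vt = _values(cms), _values(tms)
    if vc.size != vt.size:
        raise ValueError(f"voxel counts differ: {vc.size} vs {vt.size}")
    if center:
        vc = vc - vc.mean()
        vt = vt - vt.mean()
    nt = np.linalg.norm(vt)
    if nt == 0:
        raise ZeroVarianceError("target pattern has zero centered norm")
    nc = np.linalg.norm(vc)
    if nc == 0:
        # a flat CMS carries no pattern: zero strength, undefined direction
        return IntensityResult(getattr(tms, "label", None), 0.0, np.pi / 2, 0.0)
    r = float(np.dot(vc, vt) / (nc * nt))
    r = float(np.clip(r, -1.0, 1.0))
    strength = float(np.dot(vc, vt) / np.dot(vt, vt))
    label = getattr(tms, "label", None)
    return IntensityResult(target_label=label, similarity=r,
                           angle_theta=float(np.arccos(r)), strength=strength)


def map_frame(smap, coords, intensity: IntensityResult,
              style: StyleConfig = StyleConfig(), t_index: int = 0) -> FeedbackFrame:
    """Map-display frame: CMS point at ``coords`` with strength-scaled marker.

    Marker size is an affine, clipped function of strength, monotone
    nondecreasing; negative strength (CMS anticorrelated with the target)
    renders at the minimum size rather than as an inverted marker.
    """
    coords = np.atleast_1d(np.asarray(coords, dtype=float))
    if coords.size != smap.dims:
        raise ValueError(f"coords have {coords.size} dims, map has {smap.dims}")
    frac = np.clip(intensity.strength, 0.0, style.strength_cap) / style.strength_cap
    size = style.s_min + (style.s_max - style.s_min) * frac
    return FeedbackFrame(
        t_index=t_index, cms_coords=tuple(float(c) for c in coords),
        target_label=intensity.target_label, strength=intensity.strength,
        similarity=intensity.similarity, marker_size=float(size))


# ---------------------------------------------------------------------------
# circular (thermometer) display
# ---------------------------------------------------------------------------

def _arc(a: float, b: float) -> float:
    """Shortest angular distance between two angles, in [0, pi]."""
    d = abs((a - b) % (2 * np.pi))
    return min(d, 2 * np.pi - d)


def _necklace_cost(order: tuple[int, ...], D: np.ndarray) -> float:
    """Mismatch between angular arc distances (gaps proportional to adjacent
    dissimilarities) and target separations pi * d_ij / d_max, over all pairs."""
    n = len(order)
    dmax = D.max()
    adj = np.array([D[order[i], order[(i + 1) % n]] for i in range(n)])
    total = adj.sum()
    if total == 0:
        gaps = np.full(n, 2 * np.pi / n)
    else:
        gaps = 2 * np.pi * adj / total
    ang = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    cost = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            cost += abs(_arc(ang[i], ang[j]) - np.pi * D[order[i], order[j]] / dmax)
    return cost


def circular_layout(anchors: AnchorSet | list[str], rdm: RDM | None = None,
                    mode: str = "generic") -> dict[str, float]:
    """Per-anchor thermometer angles (radians) on the circular display.

    ``generic`` spaces the anchors equally, ``2*pi/n`` apart starting at
    ``pi/2`` (top of the display) in declared label order — appropriate when
    the arrangement follows a fixed semantic scheme such as valence/arousal.
    ``dissimilarity`` searches all distinct circular orderings (necklaces,
    n <= 8) for the one whose angular arc distances best approximate the
    measured dissimilarities, then makes adjacent gaps proportional to
    adjacent dissimilarities.
    """
    labels = list(anchors.labels) if isinstance(anchors, AnchorSet) else list(anchors)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 anchors for a circular layout")
    if mode == "generic":
        return {lab: float((np.pi / 2 + 2 * np.pi * i / n) % (2 * np.pi))
                for i, lab in enumerate(labels)}
    if mode != "dissimilarity":
        raise ValueError(f"unknown layout mode {mode!r}")
    if rdm is None:
        raise ValueError("dissimilarity mode requires an RDM")
    if tuple(rdm.labels) != tuple(labels):
        raise ValueError("RDM labels do not match anchor labels")
    if n > 8:
        raise ValueError(
            f"dissimilarity layout searches (n-1)!/2 orderings and is limited "
            f"to n <= 8 anchors (got {n}); use generic mode")
    D = rdm.matrix
    if D.max() == 0:
        return circular_layout(labels, mode="generic")
    best_order, best_cost = None, np.inf
    # fix label 0 first; half of the remaining orderings are reversals
    for perm in permutations(range(1, n)):
        order = (0,) + perm
        if n > 2 and perm[0] > perm[-1]:
            continue  # reversal duplicate
        c = _necklace_cost(order, D)
        if c < best_cost - 1e-12:
            best_cost, best_order = c, order
    adj = np.array([D[best_order[i], best_order[(i + 1) % n]] for i in range(n)])
    total = adj.sum()
    gaps = np.full(n, 2 * np.pi / n) if total == 0 else 2 * np.pi * adj / total
    ang = (np.pi / 2 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])) % (2 * np.pi)
    return {labels[best_order[i]]: float(ang[i]) for i in range(n)}


def arrow_angle(similarities, layout: dict[str, float]) -> ArrowResult:
    """Central-arrow direction for the circular display.

    The target is the anchor with the highest similarity; the neighbour is
    whichever of the target's two layout-adjacent anchors has the larger
    clamped (nonnegative) similarity.  With ``t`` and ``nb`` the clamped
    target and neighbour similarities, ``dist = 1 - t / (t + nb)`` (0 when
    ``t + nb == 0``) and the arrow is displaced from the target's angle by
    ``dist`` times the signed angular gap toward the neighbour.  ``dist``
    never exceeds 0.5, so the arrow stays within the target-neighbour arc.
    Negative correlations are clamped to zero before the formula because it
    misbehaves for negative values; if no similarity is positive the arrow is
    pinned at the target with a low-confidence flag.
    """
    labels = list(layout.keys())
    if len(labels) < 2:
        raise ValueError("need >= 2 anchors")
    r = np.asarray([similarities[lab] if isinstance(similarities, dict)
                    else similarities[i] for i, lab in enumerate(labels)], dtype=float)
    ti = int(np.argmax(r))
    target = labels[ti]
    angles = np.array([layout[lab] for lab in labels])
    # circular adjacency from angular order
    order = np.argsort(angles, kind="stable")
    pos = int(np.where(order == ti)[0][0])
    left = int(order[(pos - 1) % len(labels)])
    right = int(order[(pos + 1) % len(labels)])
    t = max(r[ti], 0.0)
    cand = [left, right] if left != right else [left]
    nb_scores = [max(r[c], 0.0) for c in cand]
    best = int(np.argmax(nb_scores))  # tie -> first in (left, right) order
    ni, nb = cand[best], nb_scores[best]
    if t + nb > 0:
        dist = 1.0 - t / (t + nb)
        low_conf = False
    else:
        dist, low_conf = 0.0, True
    gap = (angles[ni] - angles[ti] + np.pi) % (2 * np.pi) - np.pi  # signed, (-pi, pi]
    arrow = float((angles[ti] + dist * gap) % (2 * np.pi))
    return ArrowResult(arrow_angle=arrow, dist=float(dist), target_label=target,
                       neighbour_label=labels[ni], low_confidence=low_conf)


def circular_frame(similarities, intensity: IntensityResult,
                   layout: dict[str, float], style: StyleConfig = StyleConfig(),
                   t_index: int = 0,
                   cms_coords: tuple[float, ...] = ()) -> FeedbackFrame:
    """Circular-display frame: one filled thermometer plus the central arrow.

    Only the target's thermometer is filled, by ``clip(strength, 0, cap)/cap``;
    to avoid information overload every other fill is exactly zero.
    """
    if intensity.target_label is not None and intensity.target_label not in layout:
        raise ValueError(f"target {intensity.target_label!r} not in layout")
    arrow = arrow_angle(similarities, layout)
    target = intensity.target_label if intensity.target_label is not None else arrow.target_label
    labels = tuple(layout.keys())
    fills = np.zeros(len(labels))
    fills[labels.index(target)] = np.clip(intensity.strength, 0.0, style.fill_cap) / style.fill_cap
    return FeedbackFrame(
        t_index=t_index, cms_coords=tuple(float(c) for c in cms_coords),
        target_label=target, strength=intensity.strength,
        similarity=intensity.similarity,
        thermometer_fills=tuple(float(f) for f in fills),
        thermometer_labels=labels,
        arrow_angle=arrow.arrow_angle, dist=arrow.dist)
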