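"""Target selection, pattern strength, and both display geometries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from semnf.feedback import (StyleConfig, arrow_angle, circular_frame,
                            circular_layout, map_frame, pattern_strength,
                            select_target, similarities_to_anchors)
from semnf.rsa import RDM, ZeroVarianceError
from semnf.mapping import embed_rdm

vectors = arrays(float, st.just(12),
                 elements=st.floats(-20, 20, allow_nan=False, width=32))


class TestSelectTarget:
    def test_noisy_anchor_selects_itself(self, anchors4, rng):
        cms = anchors4.patterns[1] + 0.01 * rng.standard_normal(anchors4.voxel_count)
        assert select_target(cms, anchors4) == anchors4.labels[1]

    def test_negated_anchor_is_not_selected(self, anchors4):
        cms = -anchors4.patterns[0]
        assert select_target(cms, anchors4) != anchors4.labels[0]

    def test_matches_correlation_loop(self, anchors4, rng):
        for _ in range(10):
            cms = rng.standard_normal(anchors4.voxel_count)
            rs = [np.corrcoef(cms, p)[0, 1] for p in anchors4.patterns]
            assert select_target(cms, anchors4) == anchors4.labels[int(np.argmax(rs))]

    def test_zero_variance_rejected(self, anchors4):
        with pytest.raises(ZeroVarianceError):
            select_target(np.ones(anchors4.voxel_count), anchors4)


class TestPatternStrength:
    def test_self_projection(self, rng):
        v = rng.standard_normal(30)
        res = pattern_strength(v, v)
        assert res.strength == pytest.approx(1.0)
        assert res.similarity == pytest.approx(1.0)
        assert res.angle_theta == pytest.approx(0.0, abs=1e-6)

    def test_scaled_cms_same_angle_double_strength(self, rng):
        """Same similarity (angle), stronger intensity: scaling the CMS by 2
        doubles the strength while leaving the correlation untouched."""
        tms = rng.standard_normal(25)
        res = pattern_strength(2.0 * tms, tms)
        assert res.strength == pytest.approx(2.0)
        assert res.similarity == pytest.approx(1.0)

    def test_centered_orthogonal(self):
        tms = np.array([1.0, -1.0, 1.0, -1.0])
        cms = np.array([1.0, 1.0, -1.0, -1.0])
        res = pattern_strength(cms, tms)
        assert res.strength == pytest.approx(0.0, abs=1e-12)
        assert res.similarity == pytest.approx(0.0, abs=1e-12)
        assert res.angle_theta == pytest.approx(np.pi / 2)

    def test_dot_product_oracle(self, rng):
        cms, tms = rng.standard_normal(40), rng.standard_normal(40)
        c, t = cms - cms.mean(), tms - tms.mean()
        res = pattern_strength(cms, tms)
        assert res.strength == pytest.approx(np.dot(c, t) / np.dot(t, t), abs=1e-12)

    def test_consistency_identity(self, rng):
        """strength = similarity * ||centered CMS|| / ||centered TMS||."""
        cms, tms = rng.standard_normal(33), rng.standard_normal(33)
        res = pattern_strength(cms, tms)
        c, t = cms - cms.mean(), tms - tms.mean()
        expect = res.similarity * np.linalg.norm(c) / np.linalg.norm(t)
        assert res.strength == pytest.approx(expect, abs=1e-10)
        assert 0 <= res.angle_theta <= np.pi

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(cms=vectors, tms=vectors, k=st.floats(0.01, 100))
    def test_scale_law(self, cms, tms, k):
        """For k > 0: similarity invariant, strength exactly k-scaled."""
        if np.std(tms) < 1e-3 or np.std(cms) < 1e-3:
            return
        base = pattern_strength(cms, tms)
        scaled = pattern_strength(k * cms, tms)
        assert scaled.similarity == pytest.approx(base.similarity, abs=1e-10)
        assert scaled.strength == pytest.approx(k * base.strength, rel=1e-10, abs=1e-12)

    def test_raw_mode_and_errors(self, rng):
        v = np.array([1.0, 2.0, 3.0])
        res = pattern_strength(2 * v, v, center=False)
        assert res.strength == pytest.approx(2.0)
        with pytest.raises(ZeroVarianceError):
            pattern_strength(v, np.ones(3))


class TestMapFrame:
    def make_map(self):
        rdm = RDM(("a", "b", "c"), 1.0 - np.eye(3))
        return embed_rdm(rdm, dims=2)

    def test_marker_size_affine_and_clipped(self):
        smap = self.make_map()
        style = StyleConfig(s_min=5, s_max=25, strength_cap=1.5)
        mk = lambda s: map_frame(
            smap, (0.1, 0.2),
            pattern_strength_result(strength=s), style).marker_size
        assert mk(0.0) == pytest.approx(5.0)
        assert mk(-2.0) == pytest.approx(5.0)  # negative strength floors
        assert mk(1.5) == pytest.approx(25.0)
        assert mk(99.0) == pytest.approx(25.0)
        assert mk(1.0) > mk(0.5) > mk(0.25)  # strictly monotone in range

    def test_dims_checked(self):
        smap = self.make_map()
        with pytest.raises(ValueError, match="dims"):
            map_frame(smap, (0.0, 0.0, 0.0), pattern_strength_result(1.0))


def pattern_strength_result(strength, similarity=0.5, label="a"):
    from semnf.feedback import IntensityResult
    return IntensityResult(target_label=label, similarity=similarity,
                           angle_theta=float(np.arccos(similarity)),
                           strength=strength)


class TestCircularLayout:
    def test_generic_equal_spacing(self):
        lay = circular_layout(["a", "b", "c", "d"], mode="generic")
        angles = np.array(list(lay.values()))
        assert angles[0] == pytest.approx(np.pi / 2)
        gaps = np.diff(np.r_[angles, angles[0] + 2 * np.pi]) % (2 * np.pi)
        assert gaps == pytest.approx(np.full(4, np.pi / 2))

    def test_all_equal_rdm_gives_equal_spacing(self):
        rdm = RDM(("a", "b", "c"), 1.0 - np.eye(3))
        lay = circular_layout(["a", "b", "c"], rdm=rdm, mode="dissimilarity")
        angles = np.sort(list(lay.values()))
        gaps = np.diff(np.r_[angles, angles[0] + 2 * np.pi])
        assert gaps == pytest.approx(np.full(3, 2 * np.pi / 3))

    def test_dominant_pair_gets_largest_gap(self):
        """The most dissimilar pair ends up adjacent with the widest gap."""
        M = np.full((4, 4), 0.6)
        np.fill_diagonal(M, 0.0)
        M[0, 2] = M[2, 0] = 1.8
        rdm = RDM(("a", "b", "c", "d"), M)
        lay = circular_layout(["a", "b", "c", "d"], rdm=rdm, mode="dissimilarity")
        # adjacency in angular order
        labs = sorted(lay, key=lay.get)
        pairs = [frozenset((labs[i], labs[(i + 1) % 4])) for i in range(4)]
        assert frozenset(("a", "c")) in pairs
        gaps = {}
        for i in range(4):
            a, b = labs[i], labs[(i + 1) % 4]
            gaps[frozenset((a, b))] = (lay[b] - lay[a]) % (2 * np.pi)
        assert max(gaps, key=gaps.get) == frozenset(("a", "c"))

    def test_limits_and_errors(self):
        with pytest.raises(ValueError, match="n <= 8"):
            labels = [f"s{i}" for i in range(9)]
            M = 1.0 - np.eye(9)
            circular_layout(labels, rdm=RDM(tuple(labels), M), mode="dissimilarity")
        with pytest.raises(ValueError, match="requires an RDM"):
            circular_layout(["a", "b"], mode="dissimilarity")


class TestArrowAngle:
    layout4 = {lab: np.pi / 2 + i * np.pi / 2 for i, lab in enumerate("abcd")}

    def test_zero_neighbour_pins_arrow_at_target(self):
        res = arrow_angle({"a": 0.7, "b": 0.0, "c": -0.2, "d": 0.0}, self.layout4)
        assert res.dist == pytest.approx(0.0)
        assert res.arrow_angle == pytest.approx(self.layout4["a"])
        assert not res.low_confidence

    def test_equal_similarities_give_half(self):
        res = arrow_angle({"a": 0.5, "b": 0.5, "c": 0.0, "d": 0.1}, self.layout4)
        assert res.dist == pytest.approx(0.5)
        mid = (self.layout4["a"] + self.layout4["b"]) / 2
        assert res.arrow_angle == pytest.approx(mid)

    def test_hand_evaluated_formula(self):
        """t = 0.6, nb = 0.3 on an equally spaced 4-anchor circle."""
        res = arrow_angle({"a": 0.6, "b": 0.3, "c": 0.0, "d": 0.1}, self.layout4)
        dist = 1 - 0.6 / (0.6 + 0.3)
        assert res.dist == pytest.approx(dist)
        assert res.arrow_angle == pytest.approx(np.pi / 2 + dist * np.pi / 2)
        assert res.target_label == "a" and res.neighbour_label == "b"

    def test_all_nonpositive_flags_low_confidence(self):
        res = arrow_angle({"a": -0.1, "b": -0.5, "c": -0.9, "d": -0.4}, self.layout4)
        assert res.dist == 0.0 and res.low_confidence
        assert res.arrow_angle == pytest.approx(self.layout4["a"])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r=arrays(float, st.just(5),
                    elements=st.floats(-1, 1, allow_nan=False)))
    def test_dist_bounds_and_arrow_interval(self, r):
        layout = {f"s{i}": np.pi / 2 + i * 2 * np.pi / 5 for i in range(5)}
        res = arrow_angle({f"s{i}": r[i] for i in range(5)}, layout)
        assert 0.0 <= res.dist <= 0.5
        # arrow lies within the closed target-neighbour arc
        ta = layout[res.target_label]
        na = layout[res.neighbour_label]
        gap = (na - ta + np.pi) % (2 * np.pi) - np.pi
        off = (res.arrow_angle - ta + np.pi) % (2 * np.pi) - np.pi
        lo, hi = sorted((0.0, gap))
        assert lo - 1e-12 <= off <= hi + 1e-12

    def test_two_anchor_neighbour(self):
        layout = {"a": np.pi / 2, "b": 3 * np.pi / 2}
        res = arrow_angle({"a": 0.4, "b": 0.4}, layout)
        assert res.dist == pytest.approx(0.5)
        assert res.neighbour_label == "b"


class TestCircularFrame:
    layout = {lab: np.pi / 2 + i * np.pi / 2 for i, lab in enumerate("abcd")}

    def frame(self, strength, target="a"):
        sims = {"a": 0.8 if target == "a" else 0.1,
                "b": 0.8 if target == "b" else 0.1, "c": 0.0, "d": 0.0}
        return circular_frame(sims, pattern_strength_result(strength, label=target),
                              self.layout)

    def test_zero_strength_all_empty(self):
        fr = self.frame(0.0)
        assert all(f == 0.0 for f in fr.thermometer_fills)

    def test_cap_fills_target_only(self):
        fr = self.frame(1.5)
        fills = dict(zip(fr.thermometer_labels, fr.thermometer_fills))
        assert fills["a"] == pytest.approx(1.0)
        assert all(v == 0.0 for k, v in fills.items() if k != "a")

    def test_at_most_one_nonzero_fill(self, rng):
        for _ in range(20):
            fr = self.frame(float(rng.uniform(-1, 2)))
            assert sum(f > 0 for f in fr.thermometer_fills) <= 1

    def test_target_switch_moves_the_fill(self):
        f1 = self.frame(1.0, target="a")
        f2 = self.frame(1.0, target="b")
        fills1 = dict(zip(f1.thermometer_labels, f1.thermometer_fills))
        fills2 = dict(zip(f2.thermometer_labels, f2.thermometer_fills))
        assert fills1["a"] > 0 and fills1["b"] == 0
        assert fills2["b"] > 0 and fills2["a"] == 0


def test_similarities_vector_matches_numpy(anchors4, rng):
    cms = rng.standard_normal(anchors4.voxel_count)
    got = similarities_to_anchors(cms, anchors4)
    expect = [np.corrcoef(cms, p)[0, 1] for p in anchors4.patterns]
    assert got == pytest.approx(expect, abs=1e-12)
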