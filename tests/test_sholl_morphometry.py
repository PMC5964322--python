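"""SWC parsing, Sholl geometry and group comparison."""

import math

import numpy as np
import pytest

from iclipkit import (
    NeuronTrace, SwcNode, read_swc, write_swc, sholl_profile,
    compare_sholl_groups,
)
from conftest import dense_sholl_oracle, random_neuron, tree_from_ring_counts


def line_trace(points, root=(0.0, 0.0, 0.0)):
    """Unbranched trace through ``points`` starting at the soma."""
    nodes = {1: SwcNode(1, 1, *root, 1.0, -1)}
    for i, (x, y, z) in enumerate(points, start=2):
        nodes[i] = SwcNode(i, 3, x, y, z, 0.5, i - 1)
    return NeuronTrace(nodes, 1)


class TestSwcIO:
    def test_parse_and_roundtrip(self, tmp_path):
        path = tmp_path / "n.swc"
        path.write_text(
            "# a comment\n"
            "1 1 0 0 0 2.0 -1\n"
            "2 3 10.5 0 0 0.5 1\n"
            "3 3 20.25 1.5 -3.0 0.5 2\n")
        trace = read_swc(path)
        assert len(trace.nodes) == 3 and trace.root_id == 1
        out = tmp_path / "copy.swc"
        write_swc(trace, out)
        again = read_swc(out)
        for nid, node in trace.nodes.items():
            other = again.nodes[nid]
            assert (node.x, node.y, node.z) == (other.x, other.y, other.z)
            assert node.parent_id == other.parent_id

    def test_dangling_parent_raises(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 3 5 0 0 1 9\n")
        with pytest.raises(ValueError, match="9"):
            read_swc(path)

    def test_multiple_roots_raise(self, tmp_path):
        path = tmp_path / "two.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 1 5 0 0 1 -1\n")
        with pytest.raises(ValueError, match="root"):
            read_swc(path)

    def test_cycle_raises(self, tmp_path):
        path = tmp_path / "cycle.swc"
        path.write_text("1 1 0 0 0 1 -1\n2 3 5 0 0 1 3\n3 3 6 0 0 1 2\n")
        with pytest.raises(ValueError, match="cycle"):
            read_swc(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.swc"
        path.write_text("# nothing\n")
        with pytest.raises(ValueError, match="empty"):
            read_swc(path)


class TestShollGeometry:
    def test_straight_radial_dendrite(self):
        """95 µm radial dendrite: one crossing at r = 10..90, none past it."""
        trace = line_trace([(95.0, 0.0, 0.0)])
        prof = sholl_profile(trace)
        assert len(prof.radii) == 35
        expected = [1 if r <= 90 else 0 for r in prof.radii]
        assert list(prof.intersections) == expected

    def test_bifurcation_at_45um(self):
        """Trunk to 45 µm, two branches to planar radius 100 µm: one crossing
        up to 40 µm, two from 50 to 100 µm, none beyond."""
        nodes = {
            1: SwcNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            2: SwcNode(2, 3, 45.0, 0.0, 0.0, 0.5, 1),
            3: SwcNode(3, 3, 60.0, 80.0, 0.0, 0.5, 2),   # |.| = 100
            4: SwcNode(4, 3, 60.0, -80.0, 0.0, 0.5, 2),  # |.| = 100
        }
        prof = sholl_profile(NeuronTrace(nodes, 1))
        for r, k in zip(prof.radii, prof.intersections):
            if r <= 40:
                assert k == 1
            elif r <= 100:
                assert k == 2
            else:
                assert k == 0

    def test_z_is_projected_out(self):
        flat = line_trace([(95.0, 0.0, 0.0)])
        tilted = line_trace([(95.0, 0.0, 200.0)])
        assert list(sholl_profile(flat).intersections) == \
            list(sholl_profile(tilted).intersections)
        # in 3D the tilted dendrite reaches much farther
        prof3d = sholl_profile(tilted, projection="3d")
        assert prof3d.intersections.sum() > sholl_profile(tilted).intersections.sum()

    def test_segment_dipping_through_circle_counts_twice(self):
        """A chord passing inside a radius and back out crosses it twice."""
        trace = line_trace([(50.0, 40.0, 0.0), (50.0, -40.0, 0.0)])
        prof = sholl_profile(trace)
        # chord from (50,40) to (50,-40): closest approach 50, endpoints at 64
        r60 = int(prof.intersections[list(prof.radii).index(60.0)])
        assert r60 == 3  # radial outbound once + chord dips twice

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(2)
        trace = random_neuron(rng, n_segments=25)
        base = sholl_profile(trace).intersections
        theta = 0.7
        c, s = math.cos(theta), math.sin(theta)
        moved = {}
        for nid, n in trace.nodes.items():
            x, y = n.x * c - n.y * s + 42.0, n.x * s + n.y * c - 13.0
            moved[nid] = SwcNode(nid, n.type_code, x, y, n.z, n.radius, n.parent_id)
        assert list(sholl_profile(NeuronTrace(moved, 1)).intersections) == list(base)

    def test_primary_neurite_lower_bound(self):
        """With every neurite longer than r0, the max intersection count is
        at least the number of primary neurites."""
        nodes = {1: SwcNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)}
        for i, angle in enumerate([0.0, 2.0, 4.0], start=2):
            nodes[i] = SwcNode(i, 3, 80 * math.cos(angle), 80 * math.sin(angle),
                               0.0, 0.5, 1)
        prof = sholl_profile(NeuronTrace(nodes, 1))
        assert prof.intersections.max() >= 3

    def test_matches_dense_resampling_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            trace = random_neuron(rng, n_segments=15, max_step=20.0)
            prof = sholl_profile(trace)
            oracle = dense_sholl_oracle(trace, prof.radii)
            assert list(prof.intersections) == list(oracle)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            NeuronTrace({}, 1)


class TestCompareShollGroups:
    @staticmethod
    def _profiles(counts_list, rng):
        profs = []
        for counts in counts_list:
            tree = tree_from_ring_counts(counts, rng)
            profs.append(sholl_profile(tree))
        return profs

    def test_identical_groups_null(self):
        rng = np.random.default_rng(4)
        base = [3, 5, 7, 8, 8, 6, 4, 2, 1] + [0] * 26
        counts = [list(np.maximum(0, np.array(base) + rng.integers(-1, 2, 35)))
                  for _ in range(4)]
        a = self._profiles(counts, rng)
        b = self._profiles(counts, rng)
        res = compare_sholl_groups(a, b)
        assert np.allclose(res.per_radius["p_bonferroni"], 1.0)
        assert res.group_f == pytest.approx(0.0, abs=0.1)
        assert res.group_p > 0.5

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(6)
        base = np.array([4, 6, 8, 8, 6, 4, 3, 2, 1] + [0] * 26)
        a = self._profiles([np.maximum(0, base + rng.integers(-1, 2, 35))
                            for _ in range(5)], rng)
        b = self._profiles([np.maximum(0, base + rng.integers(-2, 3, 35))
                            for _ in range(5)], rng)
        res = compare_sholl_groups(a, b)
        for _, row in res.per_radius.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 35 * row["p_raw"]))

    def test_reduction_band_detected(self):
        """Branching reduced only between 30 and 120 µm: significant radii
        concentrate in the altered band."""
        rng = np.random.default_rng(10)
        base = np.array([6, 8, 10, 12, 12, 12, 12, 12, 12, 12, 10, 8, 6, 4]
                        + [0] * 21)
        reduced = base.copy()
        reduced[2:12] = (reduced[2:12] * 0.35).astype(int)  # radii 30..120 µm
        a = self._profiles([np.maximum(0, base + rng.integers(-1, 2, 35))
                            for _ in range(6)], rng)
        b = self._profiles([np.maximum(0, reduced + rng.integers(-1, 2, 35))
                            for _ in range(6)], rng)
        res = compare_sholl_groups(a, b, labels=("control", "knockdown"))
        sig = set(res.significant_radii())
        assert sig  # the reduction is detected
        assert sig <= set(np.arange(30.0, 130.0, 10.0))
        assert res.group_p < 0.01

    def test_small_group_raises(self):
        rng = np.random.default_rng(3)
        a = self._profiles([[3, 3, 2] + [0] * 32] * 2, rng)
        with pytest.raises(ValueError, match="2 neurons"):
            compare_sholl_groups(a[:1], a)

    def test_mismatched_grid_raises(self):
        rng = np.random.default_rng(3)
        a = self._profiles([[3, 3, 2] + [0] * 32] * 2, rng)
        tree = tree_from_ring_counts([2, 2] + [0] * 10, rng)
        odd = sholl_profile(tree, r0=5.0)
        with pytest.raises(ValueError, match="grid"):
            compare_sholl_groups(a, [a[0], odd])
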