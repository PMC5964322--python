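"""Sholl analysis of reconstructed neurons and group comparison.

Reads SWC neuron reconstructions, projects them onto the XY plane (matching
analysis on z-stack maximum-intensity projections), and counts intersections
of the dendritic tree with concentric circles around the soma — by default
radii 10, 20, ..., 350 µm.

Crossings are counted per parent->child segment.  The planar distance to the
soma along a straight segment is convex in the segment parameter, so a
segment is split at its closest-approach point into at most two monotone
pieces and each piece contributes a crossing at radius r when
``d_lo < r <= d_hi`` (half-open, so a circle tangent at a node is credited to
exactly one piece).  For segments whose distance is monotone this reduces to
the classic straddle test on the two endpoints; for segments that dip inside
a circle and exit again both crossings are counted.

Groups of profiles are compared with an ordinary two-way ANOVA
(group x radius) plus Bonferroni-corrected per-radius two-sample t-tests,
reporting mean ± s.e.m. per radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_R0 = 10.0
DEFAULT_STEP = 10.0
DEFAULT_RMAX = 350.0


@dataclass(frozen=True)
class SwcNode:
    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root


@dataclass
class NeuronTrace:
    """A neuron reconstruction: a tree of SWC nodes rooted at the soma."""

    nodes: dict[int, SwcNode]
    root_id: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if roots[0].node_id != self.root_id:
            raise ValueError("root_id does not match the parentless node")
        for n in self.nodes.values():
            if not all(math.isfinite(v) for v in (n.x, n.y, n.z)):
                raise ValueError(f"node {n.node_id}: non-finite coordinates")
            if n.parent_id != -1 and n.parent_id not in self.nodes:
                raise ValueError(f"node {n.node_id}: dangling parent {n.parent_id}")
        # acyclicity + connectivity: every node must reach the root
        for n in self.nodes.values():
            seen = set()
            cur = n
            while cur.parent_id != -1:
                if cur.node_id in seen:
                    raise ValueError(f"cycle through node {cur.node_id}")
                seen.add(cur.node_id)
                cur = self.nodes[cur.parent_id]

    @property
    def soma(self) -> SwcNode:
        return self.nodes[self.root_id]

    def segments(self) -> list[tuple[SwcNode, SwcNode]]:
        """All parent->child segments."""
        return [(self.nodes[n.parent_id], n) for n in self.nodes.values()
                if n.parent_id != -1]


def read_swc(path) -> NeuronTrace:
    """Parse an SWC file ('#' comment lines skipped)."""
    nodes: dict[int, SwcNode] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: malformed SWC line {line!r}")
            nid, tcode, x, y, z, r, parent = parts
            node = SwcNode(int(nid), int(tcode), float(x), float(y), float(z),
                           float(r), int(parent))
            if node.node_id in nodes:
                raise ValueError(f"{path}: duplicate node id {node.node_id}")
            nodes[node.node_id] = node
    if not nodes:
        raise ValueError(f"{path}: empty SWC file")
    roots = [n.node_id for n in nodes.values() if n.parent_id == -1]
    if len(roots) != 1:
        raise ValueError(f"{path}: expected one root, found {len(roots)}")
    return NeuronTrace(nodes, roots[0])


def write_swc(trace: NeuronTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(trace.nodes):
            n = trace.nodes[nid]
            fh.write(f"{n.node_id} {n.type_code} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
                     f"{n.radius:.6f} {n.parent_id}\n")


@dataclass
class ShollProfile:
    """Intersections of the projected tree with concentric circles."""

    radii: np.ndarray  # µm, strictly increasing
    intersections: np.ndarray  # non-negative integers, same length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii,
                             "intersections": self.intersections})


def _segment_crossings(d0: float, d1: float, dmin: float,
                       radii: np.ndarray) -> np.ndarray:
    """Crossings of each radius by one segment split into monotone pieces.

    ``d0``/``d1`` are the endpoint distances, ``dmin`` the closest-approach
    distance along the segment (equal to min(d0, d1) for monotone segments).
    Each monotone piece crosses radius r once when dmin < r <= d_end.
    """
    return ((radii > dmin) & (radii <= d0)).astype(int) + \
        ((radii > dmin) & (radii <= d1)).astype(int)


def sholl_profile(trace: NeuronTrace, r0: float = DEFAULT_R0,
                  step: float = DEFAULT_STEP, rmax: float = DEFAULT_RMAX,
                  projection: str = "xy") -> ShollProfile:
    """Sholl intersection profile of a reconstruction.

    The default drops the z coordinate (XY projection, as when tracing
    maximum-intensity projections); ``projection="3d"`` uses full 3D
    distances.  Radii run from ``r0`` to ``rmax`` inclusive in steps of
    ``step`` (defaults: 10..350 µm, 35 circles).
    """
    if not trace.nodes:
        raise ValueError("empty trace")
    if projection not in ("xy", "3d"):
        raise ValueError(f"unknown projection {projection!r}")
    n_radii = int(math.floor((rmax - r0) / step + 1e-9)) + 1
    radii = r0 + step * np.arange(n_radii)

    soma = trace.soma
    if projection == "xy":
        center = np.array([soma.x, soma.y])
        coord = lambda n: np.array([n.x, n.y])
    else:
        center = np.array([soma.x, soma.y, soma.z])
        coord = lambda n: np.array([n.x, n.y, n.z])

    total = np.zeros(n_radii, dtype=int)
    for parent, child in trace.segments():
        p0 = coord(parent) - center
        p1 = coord(child) - center
        d0 = float(np.linalg.norm(p0))
        d1 = float(np.linalg.norm(p1))
        v = p1 - p0
        vv = float(v @ v)
        if vv == 0.0:
            continue  # zero-length segment cannot cross a circle
        t_star = float(-(p0 @ v) / vv)
        if 0.0 < t_star < 1.0:
            dmin = float(np.linalg.norm(p0 + t_star * v))
        else:
            dmin = min(d0, d1)
        total += _segment_crossings(d0, d1, dmin, radii)
    return ShollProfile(radii, total)


@dataclass
class ShollGroupComparison:
    """Two-way ANOVA (group x radius) plus Bonferroni per-radius post-tests."""

    anova: pd.DataFrame  # effects: group, radius, interaction (F, p, df)
    per_radius: pd.DataFrame  # radius, means/sems, t, p_raw, p_bonferroni
    n_radii: int
    alpha: float

    @property
    def group_f(self) -> float:
        return float(self.anova.loc["group", "F"])

    @property
    def group_p(self) -> float:
        return float(self.anova.loc["group", "p"])

    def significant_radii(self) -> np.ndarray:
        sig = self.per_radius["p_bonferroni"] <= self.alpha
        return self.per_radius.loc[sig, "radius_um"].to_numpy()


def _two_way_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Ordinary two-way ANOVA with interaction on a balanced-ish layout.

    Implemented through statsmodels OLS + anova_lm (type II sums of squares).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    model = smf.ols("intersections ~ C(group) * C(radius)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame({
        "F": [table.loc["C(group)", "F"], table.loc["C(radius)", "F"],
              table.loc["C(group):C(radius)", "F"]],
        "p": [table.loc["C(group)", "PR(>F)"], table.loc["C(radius)", "PR(>F)"],
              table.loc["C(group):C(radius)", "PR(>F)"]],
        "df": [table.loc["C(group)", "df"], table.loc["C(radius)", "df"],
               table.loc["C(group):C(radius)", "df"]],
    }, index=["group", "radius", "interaction"])
    return out


def compare_sholl_groups(profiles_a: list[ShollProfile],
                         profiles_b: list[ShollProfile],
                         alpha: float = 0.05,
                         labels: tuple[str, str] = ("A", "B")) -> ShollGroupComparison:
    """Compare two groups of Sholl profiles.

    Omnibus: ordinary two-way ANOVA with factors group and radius (each neuron
    contributes one observation per radius).  Post-test: per-radius two-sample
    t-tests with Bonferroni correction across all radii; per-radius
    mean ± s.e.m. reported per group.  Requires >= 2 neurons per group on a
    shared radii grid.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 neurons per group")
    radii = profiles_a[0].radii
    for p in profiles_a + profiles_b:
        if not np.array_equal(p.radii, radii):
            raise ValueError("profiles are not on a shared radii grid")

    mat_a = np.array([p.intersections for p in profiles_a], dtype=float)
    mat_b = np.array([p.intersections for p in profiles_b], dtype=float)

    long = pd.DataFrame({
        "group": np.repeat([labels[0], labels[1]], [mat_a.size, mat_b.size]),
        "radius": np.concatenate([np.tile(radii, len(mat_a)),
                                  np.tile(radii, len(mat_b))]),
        "intersections": np.concatenate([mat_a.ravel(), mat_b.ravel()]),
    })
    anova = _two_way_anova(long)

    n_radii = len(radii)
    rows = []
    for j, r in enumerate(radii):
        a, b = mat_a[:, j], mat_b[:, j]
        t, p = stats.ttest_ind(a, b)
        if np.isnan(p):  # zero variance in both groups
            t, p = 0.0, 1.0
        rows.append((r, a.mean(), a.std(ddof=1) / np.sqrt(len(a)),
                     b.mean(), b.std(ddof=1) / np.sqrt(len(b)),
                     float(t), float(p), float(min(1.0, n_radii * p))))
    per_radius = pd.DataFrame(rows, columns=[
        "radius_um", f"mean_{labels[0]}", f"sem_{labels[0]}",
        f"mean_{labels[1]}", f"sem_{labels[1]}", "t", "p_raw", "p_bonferroni"])
    return ShollGroupComparison(anova, per_radius, n_radii, alpha)
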