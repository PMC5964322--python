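"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from iclipkit import Region, TranscriptModel, SimConfig
from iclipkit.sholl_morphometry import NeuronTrace, SwcNode


@pytest.fixture
def small_sim_config():
    """A fast, fully-featured simulation config for unit tests."""
    return SimConfig(rng_seed=42, n_transcripts=60, n_reads=8000)


def make_transcript(tid="TX1", utr5=100, cds=500, utr3=1000, introns=(),
                    biotype="protein_coding"):
    """Build a protein-coding transcript model with optional introns in the CDS."""
    regions = [Region(0, utr5, "five_prime_utr")] if utr5 else []
    pos = utr5
    chunks = len(introns) + 1
    per = cds // chunks
    for i in range(chunks):
        size = cds - per * (chunks - 1) if i == chunks - 1 else per
        regions.append(Region(pos, pos + size, "cds"))
        pos += size
        if i < len(introns):
            regions.append(Region(pos, pos + introns[i], "intron"))
            pos += introns[i]
    if utr3:
        regions.append(Region(pos, pos + utr3, "three_prime_utr"))
        pos += utr3
    return TranscriptModel(tid, f"G_{tid}", biotype, pos, regions)


def make_ce(rows):
    """CE table from (transcript_id, position, unique_count) triples."""
    return pd.DataFrame(
        [(t, p, "+", "S1", c) for t, p, c in rows],
        columns=["transcript_id", "position", "strand", "sample", "unique_count"],
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_kmer_count(seq: str, kmer: str) -> int:
    """Sliding-window occurrence count, the k-mer counting oracle."""
    seq = seq.upper().replace("T", "U")
    kmer = kmer.upper().replace("T", "U")
    return sum(1 for i in range(len(seq) - len(kmer) + 1)
               if seq[i:i + len(kmer)] == kmer)


def exact_hypergeom_upper_tail(N: int, a: int, b: int, k: int) -> Fraction:
    """P[X >= k] for the overlap of fixed |A|=a with a uniform draw of b from
    N, by exact rational enumeration over the overlap support."""
    total = Fraction(0)
    denom = math.comb(N, b)
    for j in range(k, min(a, b) + 1):
        total += Fraction(math.comb(a, j) * math.comb(N - a, b - j), denom)
    return total


def dense_sholl_oracle(trace: NeuronTrace, radii: np.ndarray,
                       resolution: float = 0.01) -> np.ndarray:
    """Crossing-count oracle: each segment subdivided at ``resolution`` µm in
    the XY projection, crossings counted with the half-open rule on every
    consecutive sample pair."""
    soma = trace.soma
    center = np.array([soma.x, soma.y])
    total = np.zeros(len(radii), dtype=int)
    for parent, child in trace.segments():
        p0 = np.array([parent.x, parent.y]) - center
        p1 = np.array([child.x, child.y]) - center
        seg_len = float(np.linalg.norm(p1 - p0))
        n = max(2, int(math.ceil(seg_len / resolution)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        d = np.linalg.norm(pts, axis=1)
        lo = np.minimum(d[:-1], d[1:])
        hi = np.maximum(d[:-1], d[1:])
        for i, r in enumerate(radii):
            total[i] += int(np.sum((lo < r) & (r <= hi)))
    return total


def random_neuron(rng: np.random.Generator, n_segments: int = 20,
                  max_step: float = 25.0, extent: float = 150.0) -> NeuronTrace:
    """Random neuron tree: segments sprout from random existing nodes."""
    nodes = {1: SwcNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)}
    for i in range(2, n_segments + 2):
        parent = int(rng.choice(list(nodes)))
        px, py = nodes[parent].x, nodes[parent].y
        angle = rng.uniform(0, 2 * math.pi)
        step = rng.uniform(1.0, max_step)
        x = float(np.clip(px + step * math.cos(angle), -extent, extent))
        y = float(np.clip(py + step * math.sin(angle), -extent, extent))
        nodes[i] = SwcNode(i, 3, x, y, float(rng.normal(0, 5)), 0.5, parent)
    return NeuronTrace(nodes, 1)


def tree_from_ring_counts(counts, rng: np.random.Generator,
                          step: float = 10.0) -> NeuronTrace:
    """Tree whose Sholl profile on radii step, 2*step, ... equals ``counts``.

    ``counts[i]`` segments span ring i -> ring i+1 (radius (i+1)*step); tips
    are duplicated or dropped between rings to follow the prescribed counts.
    """
    nodes = {1: SwcNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)}
    angles = {1: float(rng.uniform(0, 2 * math.pi))}
    next_id = 2
    tips = [1]
    for i, c in enumerate(counts):
        c = int(c)
        radius = (i + 1) * step
        # choose c parents among current tips (with replacement = branching);
        # child angles stay near the parent's so segment distances to the
        # soma are monotone and each segment crosses exactly one grid circle
        parents = [tips[int(rng.integers(len(tips)))] for _ in range(c)] if c else []
        new_tips = []
        for parent in parents:
            angle = angles[parent] + float(rng.normal(0, 0.15))
            nodes[next_id] = SwcNode(next_id, 3, radius * math.cos(angle),
                                     radius * math.sin(angle), 0.0, 0.5, parent)
            angles[next_id] = angle
            new_tips.append(next_id)
            next_id += 1
        if not new_tips:
            break
        tips = new_tips
    return NeuronTrace(nodes, 1)
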