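"""Sequence determinants of RNA-protein binding: motif and seed statistics.

Implements the statistics used to characterize an RBP interactome against
miRNA targeting:

* TargetScan-style 7mer-A1 seed-match sites of mature miRNAs;
* overlapping k-mer counts per 3'UTR and per-kilobase densities
  (poly-U heptamer ``UUUUUUU`` as the binding-motif proxy);
* Welch's unequal-variance two-sample t-test for bound-vs-unbound
  comparisons on the count and the density scale;
* exact hypergeometric upper-tail enrichment for the overlap of two
  target-transcript sets within a finite universe;
* a positional nucleotide-frequency profile around crosslink sites;
* a permutation test for crosslink proximity to seed sites within 3'UTRs.

All sequence handling is U/T agnostic (normalized internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import TranscriptModel

logger = logging.getLogger(__name__)

POLY_U_7MER = "UUUUUUU"

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# miRNA seed sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', RNA alphabet."""

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = _to_rna(self.mature_seq)
        object.__setattr__(self, "mature_seq", seq)
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"{self.name}: non-ACGU characters in {seq!r}")
        if len(seq) < 8:
            raise ValueError(f"{self.name}: mature sequence must be >= 8 nt "
                             f"(positions 1-8 must exist), got {len(seq)}")


def seed_site_7merA1(mirna: MiRNA) -> str:
    """7mer-A1 target site of a miRNA (5'->3' on the target strand).

    The site is the reverse complement of miRNA positions 2-7 followed by an
    adenosine opposite position 1 (TargetScan convention).
    """
    seed = mirna.mature_seq[1:7]  # positions 2-7, 1-based
    return seed.translate(_RNA_COMPLEMENT)[::-1] + "A"


def load_mirna_panel(path=None) -> list[MiRNA]:
    """Load a miRNA panel TSV (columns: name, mature_seq; '#' comments).

    Without a path, loads the packaged panel of ten conserved miRNAs
    (ubiquitous, stem-cell, muscle, blood and brain-enriched) used for
    seed-match profiling.
    """
    if path is None:
        ref = resources.files("iclipkit").joinpath("data/mirna_panel.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [MiRNA(str(r["name"]), str(r["mature_seq"])) for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# k-mer counting and UTR profiles
# ---------------------------------------------------------------------------

def count_kmer(seq: str, kmer: str, overlapping: bool = True) -> int:
    """Occurrences of ``kmer`` in ``seq`` (overlapping by default).

    U/T are normalized on both sides.  A k-mer longer than the sequence
    yields 0.
    """
    if len(kmer) < 1:
        raise ValueError("kmer must be non-empty")
    seq = _to_rna(seq)
    kmer = _to_rna(kmer)
    n = 0
    i = seq.find(kmer)
    step = 1 if overlapping else len(kmer)
    while i != -1:
        n += 1
        i = seq.find(kmer, i + step)
    return n


def profile_utrs(
    annotation: dict[str, TranscriptModel],
    sequences: dict[str, str],
    kmer_panel: dict[str, str],
    overlapping: bool = True,
) -> pd.DataFrame:
    """Per-transcript 3'UTR k-mer counts and per-kb densities.

    ``kmer_panel`` maps a k-mer name (e.g. ``"polyU"`` or a miRNA site name)
    to its sequence.  The 3'UTR sequence is the concatenation of the
    transcript's 3'UTR intervals in transcript order.  Density is
    count / (UTR length / 1000); zero-length UTRs get count 0 and density 0.
    """
    rows = []
    for tid in sorted(annotation):
        if tid not in sequences:
            raise KeyError(f"transcript {tid} missing from sequence FASTA")
        model = annotation[tid]
        utr = model.utr3_sequence(sequences[tid])
        L = len(utr)
        for name, kmer in kmer_panel.items():
            c = count_kmer(utr, kmer, overlapping=overlapping) if L else 0
            density = c / (L / 1000.0) if L else 0.0
            rows.append((tid, L, name, c, density))
    return pd.DataFrame(rows, columns=["transcript_id", "utr3_length", "kmer",
                                       "count", "density"])


# ---------------------------------------------------------------------------
# Welch's t-test and bound/unbound comparison
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t_test(x, y) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (x̄ − ȳ) / sqrt(s²ₓ/nₓ + s²ᵧ/nᵧ) with Welch–Satterthwaite degrees of
    freedom; p from the Student-t survival function.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both groups have zero variance (df undefined)")
    se2x, se2y = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (se2x ** 2 / (nx - 1) + se2y ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


@dataclass
class BoundUnboundComparison:
    """Bound-vs-unbound k-mer comparison on the count and the density scale."""

    kmer: str
    mean_count_bound: float
    mean_count_unbound: float
    count_test: WelchResult
    mean_density_bound: float
    mean_density_unbound: float
    density_test: WelchResult
    n_bound: int
    n_unbound: int


def compare_bound_unbound(profiles: pd.DataFrame, targets: pd.DataFrame,
                          kmer_name: str) -> BoundUnboundComparison:
    """Compare per-UTR k-mer occurrence between bound and unbound transcripts.

    Reports the raw per-UTR count comparison and the per-kb density
    comparison separately (absolute occurrence conflates motif content with
    UTR length; the density scale removes the length component).
    """
    prof = profiles[profiles["kmer"] == kmer_name]
    if prof.empty:
        raise ValueError(f"no profile rows for k-mer {kmer_name!r}")
    merged = prof.merge(targets[["transcript_id", "bound"]], on="transcript_id",
                        validate="one_to_one")
    if len(merged) != len(prof):
        raise ValueError("targets table does not cover the profile universe")
    b = merged[merged["bound"]]
    u = merged[~merged["bound"]]
    if len(b) < 2 or len(u) < 2:
        raise ValueError("each group needs at least 2 transcripts")
    return BoundUnboundComparison(
        kmer=kmer_name,
        mean_count_bound=float(b["count"].mean()),
        mean_count_unbound=float(u["count"].mean()),
        count_test=welch_t_test(b["count"], u["count"]),
        mean_density_bound=float(b["density"].mean()),
        mean_density_unbound=float(u["density"].mean()),
        density_test=welch_t_test(b["density"], u["density"]),
        n_bound=len(b),
        n_unbound=len(u),
    )


# ---------------------------------------------------------------------------
# set-overlap enrichment
# ---------------------------------------------------------------------------

@dataclass
class OverlapEnrichment:
    overlap: int
    expected: float
    fold: float
    p_value: float
    n_a: int
    n_b: int
    universe: int


def overlap_enrichment(set_a, set_b, universe_size: int) -> OverlapEnrichment:
    """Exact hypergeometric enrichment of the overlap of two transcript sets.

    With |A| and |B| drawn from a universe of N transcripts, the chance
    expectation of the overlap is |A|·|B|/N; the p-value is the exact
    upper-tail probability P[X >= k] of the hypergeometric distribution.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError(f"universe ({universe_size}) smaller than |A ∪ B| ({len(a | b)})")
    k = len(a & b)
    expected = len(a) * len(b) / universe_size if universe_size else 0.0
    fold = k / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapEnrichment(k, expected, fold, min(p, 1.0), len(a), len(b),
                             universe_size)


# ---------------------------------------------------------------------------
# positional nucleotide profile
# ---------------------------------------------------------------------------

@dataclass
class PositionalProfile:
    """Nucleotide frequencies at offsets -flank..+flank around crosslinks.

    ``matrix`` is 4 x (2·flank+1) over rows A, C, G, U; each column sums to 1.
    """

    flank: int
    matrix: np.ndarray
    n_events: int
    n_skipped: int

    BASES = ("A", "C", "G", "U")

    def frequency(self, base: str, offset: int) -> float:
        return float(self.matrix[self.BASES.index(base), offset + self.flank])

    def central_u_frequency(self, width: int = 1) -> float:
        """Mean U frequency over the ``2·width+1`` central columns."""
        cols = slice(self.flank - width, self.flank + width + 1)
        return float(self.matrix[3, cols].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.BASES),
                            columns=range(-self.flank, self.flank + 1))


def positional_profile(ce: pd.DataFrame, sequences: dict[str, str],
                       flank: int = 10) -> PositionalProfile:
    """Nucleotide representation flanking crosslink sites.

    Events are weighted by their unique-event count.  Windows extending past
    a transcript end are skipped (and counted in ``n_skipped``).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    width = 2 * flank + 1
    counts = np.zeros((4, width))
    index = {b: i for i, b in enumerate("ACGU")}
    n_used = 0
    n_skipped = 0
    for rec in ce.itertuples(index=False):
        seq = sequences[rec.transcript_id]
        pos = int(rec.position)
        if pos - flank < 0 or pos + flank + 1 > len(seq):
            n_skipped += 1
            continue
        window = _to_rna(seq[pos - flank: pos + flank + 1])
        w = float(rec.unique_count)
        for j, base in enumerate(window):
            i = index.get(base)
            if i is not None:
                counts[i, j] += w
        n_used += 1
    if n_used == 0:
        raise ValueError("no crosslink events with a full in-range window")
    col_sums = counts.sum(axis=0, keepdims=True)
    matrix = counts / np.where(col_sums == 0, 1.0, col_sums)
    return PositionalProfile(flank, matrix, n_used, n_skipped)


# ---------------------------------------------------------------------------
# seed-proximity permutation test
# ---------------------------------------------------------------------------

@dataclass
class SeedProximityResult:
    median_abs_distance: float
    p_value: float
    n_events: int
    n_transcripts: int
    n_perm: int


def _utr_positions(model: TranscriptModel) -> np.ndarray:
    return np.concatenate([np.arange(s, e) for s, e in model.utr3_intervals]) \
        if model.utr3_intervals else np.empty(0, dtype=int)


def seed_proximity_bias(
    ce: pd.DataFrame,
    seed_sites: dict[str, list[tuple[int, int]]],
    annotation: dict[str, TranscriptModel],
    n_perm: int = 1000,
    seed: int = 0,
) -> SeedProximityResult:
    """Test whether crosslink events sit closer to miRNA seed sites than chance.

    Restricted to 3'UTR crosslink events on transcripts that carry at least
    one seed site.  The statistic is the median absolute distance from each
    event to the nearest seed-site start in the same 3'UTR; the null
    re-places every event uniformly within its own 3'UTR.  The p-value is the
    add-one-smoothed fraction of permutations with a median at most the
    observed one (small p: binding is biased toward seed vicinity).
    """
    rng = np.random.default_rng(seed)
    per_tx: list[tuple[np.ndarray, np.ndarray, int]] = []
    n_events = 0
    obs_dists = []
    for tid, grp in ce.groupby("transcript_id", sort=True):
        sites = seed_sites.get(tid)
        if not sites:
            continue
        model = annotation[tid]
        utr = _utr_positions(model)
        if len(utr) == 0:
            continue
        utr_set = set(utr.tolist())
        positions = [int(p) for p in grp["position"] if int(p) in utr_set]
        if not positions:
            continue
        starts = np.array(sorted(s for s, _ in sites))
        for p in positions:
            obs_dists.append(np.abs(starts - p).min())
        per_tx.append((starts, utr, len(positions)))
        n_events += len(positions)
    if n_events == 0:
        raise ValueError("no 3'UTR crosslink events on seed-carrying transcripts")

    observed = float(np.median(obs_dists))
    hits = 0
    for _ in range(n_perm):
        dists = []
        for starts, utr, k in per_tx:
            pos = utr[rng.integers(0, len(utr), size=k)]
            dists.append(np.abs(starts[None, :] - pos[:, None]).min(axis=1))
        if float(np.median(np.concatenate(dists))) <= observed:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return SeedProximityResult(observed, p, n_events, len(per_tx), n_perm)
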