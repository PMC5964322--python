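"""Peak calling on crosslink-event tables, target derivation and feature stats.

The peak caller scores every position of a transcript by the number of unique
crosslink events (CEs) in a centred window of width ``w``, builds a
per-transcript null by uniformly re-scattering the transcript's unique events
and recording the maximum windowed score of each scatter, converts observed
scores to empirical p-values against that max-statistic null, and controls the
false discovery rate with Benjamini–Hochberg across all candidate windows of
the whole run.  Significant positions closer than ``w`` are merged into peaks.

Candidate windows are positions that carry a CE and reach a minimum windowed
height (default 3 unique events): with a permutation floor of
1/(n_perm + 1) the BH threshold can only be cleared when the candidate set is
not dominated by singleton background positions, so a minimum-depth filter —
standard practice in CLIP peak callers — is applied before testing.

A transcript is a *target* when it owns at least one significant peak; the
target table over the full annotated universe feeds all downstream
bound-versus-unbound statistics (3'UTR length, k-mer enrichment, set overlap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import TranscriptModel

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["transcript_id", "start", "end", "summit", "height",
                "empirical_p", "fdr_q"]
TARGET_COLUMNS = ["transcript_id", "bound", "n_peaks", "total_unique_CEs",
                  "utr3_length"]

FEATURE_CLASSES = ("three_prime_utr", "five_prime_utr", "cds", "intron", "lincRNA")


def _window_scores(counts: np.ndarray, w: int) -> np.ndarray:
    """Sum of counts within +/-(w-1)/2 of each position (same length as input)."""
    half = (w - 1) // 2
    padded = np.concatenate([np.zeros(half), counts, np.zeros(half)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    return csum[w:] - csum[:-w]


def _perm_max_scores(n_events: int, length: int, w: int,
                     n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Max windowed score of each of ``n_perm`` uniform scatters of the
    transcript's unique events (each unique molecule re-placed independently,
    preserving the total)."""
    pos = rng.integers(0, length, size=(n_perm, n_events))
    mat = np.zeros((n_perm, length))
    rows = np.repeat(np.arange(n_perm), n_events)
    np.add.at(mat, (rows, pos.ravel()), 1.0)
    half = (w - 1) // 2
    padded = np.zeros((n_perm, length + 2 * half))
    padded[:, half:half + length] = mat
    csum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(padded, axis=1)], axis=1)
    windowed = csum[:, w:] - csum[:, :-w]
    return windowed.max(axis=1)


def call_peaks(
    ce: pd.DataFrame,
    annotation: dict[str, TranscriptModel],
    window_w: int = 15,
    n_perm: int = 100,
    fdr_alpha: float = 0.05,
    seed: int = 0,
    min_height: int = 3,
) -> pd.DataFrame:
    """Call significant CE peaks per transcript by permutation FDR.

    ``ce`` is a crosslink-event table (multiple samples are pooled by summing
    unique counts per position).  Returns a table with one row per peak:
    interval [start, end), summit (leftmost argmax of the windowed score),
    height (unique CEs in the summit window), empirical p and BH q at the
    summit.
    """
    if window_w % 2 != 1:
        raise ValueError("window_w must be odd")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)

    # pool samples: unique events per (transcript, position)
    pooled = (ce.groupby(["transcript_id", "position"], sort=True)["unique_count"]
              .sum().reset_index())

    cand_rows = []  # (transcript_id, position, score, empirical_p)
    per_tx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid, grp in pooled.groupby("transcript_id", sort=True):
        model = annotation.get(tid)
        if model is None:
            raise KeyError(f"transcript {tid} missing from annotation")
        L = model.length
        if window_w > L:
            logger.warning("transcript %s shorter than window (%d < %d): skipped",
                           tid, L, window_w)
            continue
        positions = grp["position"].to_numpy(dtype=int)
        weights = grp["unique_count"].to_numpy(dtype=float)
        counts = np.zeros(L)
        counts[positions] = weights
        scores = _window_scores(counts, window_w)
        per_tx[tid] = (counts, scores)

        cand_mask = scores[positions] >= min_height
        if not cand_mask.any():
            continue
        n_molecules = int(round(weights.sum()))
        perm_max = _perm_max_scores(n_molecules, L, window_w, n_perm, rng)
        for p_i in positions[cand_mask]:
            s_i = scores[p_i]
            emp_p = (1.0 + np.sum(perm_max >= s_i)) / (1.0 + n_perm)
            cand_rows.append((tid, int(p_i), float(s_i), float(emp_p)))

    if not cand_rows:
        return pd.DataFrame(columns=PEAK_COLUMNS)

    cand = pd.DataFrame(cand_rows, columns=["transcript_id", "position", "score",
                                            "empirical_p"])
    # pipeline-wide Benjamini-Hochberg across every candidate window
    cand["fdr_q"] = stats.false_discovery_control(cand["empirical_p"], method="bh")

    peaks = []
    for tid, grp in cand[cand["fdr_q"] <= fdr_alpha].groupby("transcript_id", sort=True):
        _, scores = per_tx[tid]
        grp = grp.sort_values("position")
        run: list[pd.Series] = []
        prev = None
        for _, row in grp.iterrows():
            if prev is not None and row["position"] - prev > window_w:
                peaks.append(_merge_run(tid, run, scores))
                run = []
            run.append(row)
            prev = row["position"]
        if run:
            peaks.append(_merge_run(tid, run, scores))

    out = pd.DataFrame(peaks, columns=PEAK_COLUMNS)
    logger.info("called %d peaks on %d transcripts (%d candidate windows)",
                len(out), out["transcript_id"].nunique() if len(out) else 0, len(cand))
    return out


def _merge_run(tid: str, run: list, scores: np.ndarray) -> tuple:
    positions = [int(r["position"]) for r in run]
    start, end = min(positions), max(positions) + 1
    # summit: leftmost argmax of the windowed score among merged positions
    run_scores = np.array([scores[p] for p in positions])
    summit = positions[int(np.argmax(run_scores))]
    best = int(np.argmax(run_scores))
    return (tid, start, end, summit, int(run[best]["score"]),
            float(run[best]["empirical_p"]), float(run[best]["fdr_q"]))


def derive_targets(
    peaks: pd.DataFrame,
    annotation: dict[str, TranscriptModel],
    ce: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Target table over the whole annotated universe.

    ``bound`` is true iff the transcript has at least one peak.  Every
    annotated transcript appears exactly once, so bound/unbound partition the
    universe used by all downstream statistics.
    """
    n_peaks = peaks.groupby("transcript_id").size() if len(peaks) else pd.Series(dtype=int)
    totals = (ce.groupby("transcript_id")["unique_count"].sum()
              if ce is not None and len(ce) else pd.Series(dtype=int))
    rows = []
    for tid in sorted(annotation):
        k = int(n_peaks.get(tid, 0))
        rows.append((tid, k >= 1, k, int(totals.get(tid, 0)),
                     annotation[tid].utr3_length))
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def assign_feature(position: int, transcript_id: str,
                   annotation: dict[str, TranscriptModel]) -> str:
    """Feature class of a transcript position.

    Protein-coding positions report their region label; exonic positions of
    lincRNAs report ``"lincRNA"`` (intronic lincRNA positions stay
    ``"intron"``).
    """
    model = annotation[transcript_id]
    label = model.label_at(position)  # raises on out-of-range
    if model.biotype == "lincRNA" and label == "noncoding_exon":
        return "lincRNA"
    return label


def feature_distribution(ce: pd.DataFrame, annotation: dict[str, TranscriptModel],
                         weight: str = "events") -> dict[str, float]:
    """Fraction of crosslink signal per feature class.

    ``weight="events"`` weighs positions by their unique-event count (the
    per-CE distribution); ``weight="positions"`` counts each crosslinked
    position once.  Fractions sum to 1.
    """
    if ce.empty:
        raise ValueError("empty crosslink-event table")
    if weight not in ("events", "positions"):
        raise ValueError(f"unknown weight mode {weight!r}")
    totals: dict[str, float] = {}
    for rec in ce.itertuples(index=False):
        label = assign_feature(int(rec.position), rec.transcript_id, annotation)
        w = float(rec.unique_count) if weight == "events" else 1.0
        totals[label] = totals.get(label, 0.0) + w
    grand = sum(totals.values())
    return {k: v / grand for k, v in sorted(totals.items())}


@dataclass
class UtrLengthComparison:
    """Bound-vs-unbound 3'UTR length summary (medians in kb)."""

    median_bound_kb: float
    median_unbound_kb: float
    p_value: float
    test: str = "mann-whitney-u"
    n_bound: int = 0
    n_unbound: int = 0


def utr_length_stats(targets: pd.DataFrame) -> UtrLengthComparison:
    """Compare 3'UTR lengths of bound vs unbound transcripts.

    Returns medians in kb and a two-sided Mann–Whitney U p-value (the
    comparison is of distribution location; the choice of rank test is
    reported in the result).
    """
    bound = targets.loc[targets["bound"], "utr3_length"].to_numpy(dtype=float)
    unbound = targets.loc[~targets["bound"], "utr3_length"].to_numpy(dtype=float)
    if len(bound) == 0 or len(unbound) == 0:
        raise ValueError("need at least one bound and one unbound transcript")
    res = stats.mannwhitneyu(bound, unbound, alternative="two-sided")
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and equal: no evidence of difference
        p = 1.0
    return UtrLengthComparison(
        median_bound_kb=float(np.median(bound)) / 1000.0,
        median_unbound_kb=float(np.median(unbound)) / 1000.0,
        p_value=p,
        n_bound=len(bound),
        n_unbound=len(unbound),
    )


def peaks_to_bed(peaks: pd.DataFrame) -> pd.DataFrame:
    """Peaks as BED6+1 (score = height, extra column = q-value)."""
    return pd.DataFrame({
        "chrom": peaks["transcript_id"],
        "start": peaks["start"].astype(int),
        "end": peaks["end"].astype(int),
        "name": "peak_" + peaks["summit"].astype(str),
        "score": peaks["height"].astype(int),
        "strand": "+",
        "fdr_q": peaks["fdr_q"],
    })
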