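"""Raw multiplexed iCLIP reads -> deduplicated crosslink-event table.

The truncation model of iCLIP places the reverse-transcription stop — and
therefore the 5' end of the sequenced insert — one nucleotide 3' of the
protein–RNA crosslink.  This module demultiplexes reads by their embedded
sample code, strips the random barcode (UMI), places inserts on transcripts
by unique exact match, and collapses PCR duplicates by
(transcript, position, sample, UMI) identity to yield unique crosslink
events (CEs).

Coordinates are 0-based half-open throughout; the crosslink position of a
read whose insert starts at ``start`` is ``start - 1``.  Reads mapping at
transcript start (position -1 undefined) are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio import SeqIO

logger = logging.getLogger(__name__)

CE_COLUMNS = ["transcript_id", "position", "strand", "sample", "unique_count"]


@dataclass(frozen=True)
class BarcodeSpec:
    """Layout of the read 5' end: random prefix + sample code + random suffix.

    The UMI is the concatenation of the two random parts.
    """

    random_prefix_len: int = 3
    code_length: int = 4
    random_suffix_len: int = 2

    @property
    def total_length(self) -> int:
        return self.random_prefix_len + self.code_length + self.random_suffix_len

    @property
    def umi_length(self) -> int:
        return self.random_prefix_len + self.random_suffix_len


@dataclass
class DemuxResult:
    """Demultiplexed reads plus routing counters."""

    reads: pd.DataFrame  # read_id, sample, umi, insert
    counts: dict[str, int]  # per-sample assigned counts + "undetermined"


def _iter_fastq(reads) -> "list[tuple[str, str]]":
    """Accept a FASTQ path or an iterable of (id, seq[, qual]) records."""
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            return [(rid.split()[0], seq) for rid, seq, _ in FastqGeneralIterator(fh)]
    return [(r[0], r[1]) for r in reads]


def demultiplex(reads, barcode_spec: BarcodeSpec, samples) -> DemuxResult:
    """Split reads by exact sample-code match and extract UMIs.

    ``samples`` is a mapping sample_name -> code, or a list of codes (the code
    doubles as the name).  The sample code is matched exactly (0 mismatches);
    reads whose code matches no configured sample are counted under
    ``"undetermined"`` and excluded from the output.  Reads shorter than the
    barcode are undetermined as well.
    """
    if not isinstance(samples, dict):
        samples = {code: code for code in samples}
    codes: dict[str, str] = {}
    for name, code in samples.items():
        if len(code) != barcode_spec.code_length:
            raise ValueError(f"sample {name}: code {code!r} length != {barcode_spec.code_length}")
        if code in codes:
            raise ValueError(f"samples {codes[code]!r} and {name!r} share code {code!r}")
        codes[code] = name

    p, c = barcode_spec.random_prefix_len, barcode_spec.code_length
    s = barcode_spec.random_suffix_len
    rows = []
    counts = {name: 0 for name in samples}
    counts["undetermined"] = 0
    for rid, seq in _iter_fastq(reads):
        if len(seq) <= barcode_spec.total_length:
            counts["undetermined"] += 1
            continue
        code = seq[p:p + c]
        name = codes.get(code)
        if name is None:
            counts["undetermined"] += 1
            continue
        umi = seq[:p] + seq[p + c:p + c + s]
        insert = seq[p + c + s:]
        rows.append((rid, name, umi, insert))
        counts[name] += 1

    df = pd.DataFrame(rows, columns=["read_id", "sample", "umi", "insert"])
    logger.info("demultiplex: %s", counts)
    return DemuxResult(df, counts)


class _SeedIndex:
    """Exact-match seed index: sorted 2-bit codes of every k-mer of the text.

    A query of length >= k is located by binary search on its leading k-mer
    code; candidate offsets are verified by direct string comparison, so
    separator-spanning or hash-colliding candidates are filtered out.
    """

    def __init__(self, text: str, k: int = 32):
        self.text = text
        self.k = k
        lut = np.zeros(256, dtype=np.uint64)
        for i, base in enumerate("ACGT"):
            lut[ord(base)] = i
        self._lut = lut
        enc = lut[np.frombuffer(text.encode(), dtype=np.uint8)]
        n = len(enc) - k + 1
        if n <= 0:
            self._order = np.empty(0, dtype=np.int64)
            self._codes = np.empty(0, dtype=np.uint64)
            return
        codes = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            codes += enc[j:n + j] * (np.uint64(4) ** np.uint64(j))
        self._order = np.argsort(codes, kind="stable")
        self._codes = codes[self._order]

    def _code(self, query: str) -> int:
        enc = self._lut[np.frombuffer(query[:self.k].encode(), dtype=np.uint8)]
        return int((enc * (np.uint64(4) ** np.arange(self.k, dtype=np.uint64))).sum())

    def occurrences(self, query: str, limit: int = 2) -> list[int]:
        if len(query) < self.k:
            raise ValueError("query shorter than seed length")
        code = np.uint64(self._code(query))
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        found: list[int] = []
        for pos in self._order[lo:hi]:
            pos = int(pos)
            if self.text.startswith(query, pos):
                found.append(pos)
                if len(found) >= limit:
                    break
        return sorted(found)


@dataclass
class MappingResult:
    """Unique-exact-match placements plus mapping counters."""

    placements: pd.DataFrame  # read_id, sample, umi, transcript_id, start, end, strand
    counts: dict[str, int]  # mapped / multimapped / unmapped


def _load_sequences(sequences) -> dict[str, str]:
    if isinstance(sequences, (str, Path)):
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
    return dict(sequences)


def map_reads_exact(demux: pd.DataFrame, sequences) -> MappingResult:
    """Place inserts on transcripts by unique exact substring match.

    ``sequences`` is a FASTA path or a mapping transcript_id -> sequence
    (U or T alphabet; both sides are normalized to T before matching).
    Inserts matching more than one location across the whole transcript set
    are discarded as multi-mappers; inserts matching nowhere are unmapped.
    Both are excluded from the output and counted.
    """
    seqs = _load_sequences(sequences)
    if not seqs:
        raise ValueError("empty transcript database")
    tids = sorted(seqs)
    norm = [seqs[t].upper().replace("U", "T") for t in tids]
    # concatenate with a separator outside the alphabet so matches cannot span
    text = "#".join(norm)
    offsets = np.zeros(len(tids), dtype=np.int64)
    for i in range(1, len(tids)):
        offsets[i] = offsets[i - 1] + len(norm[i - 1]) + 1
    index = _SeedIndex(text)

    def matches(insert: str, limit: int = 2) -> list[int]:
        """Up to ``limit`` start offsets of exact occurrences in ``text``."""
        if len(insert) >= index.k:
            return index.occurrences(insert, limit)
        found, i = [], text.find(insert)
        while i != -1 and len(found) < limit:
            found.append(i)
            i = text.find(insert, i + 1)
        return found

    # identical inserts (PCR duplicates) share a placement: look up once
    cache: dict[str, tuple] = {}

    def place(insert: str) -> tuple:
        """-> ("mapped", tid, start, end) | ("multimapped",) | ("unmapped",)"""
        hit = cache.get(insert)
        if hit is not None:
            return hit
        occ = matches(insert)
        if not occ:
            hit = ("unmapped",)
        elif len(occ) > 1:
            hit = ("multimapped",)
            counts["multimapped_unique_inserts"] += 1
        else:
            k = int(np.searchsorted(offsets, occ[0], side="right")) - 1
            start = occ[0] - int(offsets[k])
            hit = ("mapped", tids[k], start, start + len(insert))
        cache[insert] = hit
        return hit

    counts = {"mapped": 0, "multimapped": 0, "unmapped": 0,
              "multimapped_unique_inserts": 0}
    rows = []
    for rec in demux.itertuples(index=False):
        insert = rec.insert.upper().replace("U", "T")
        hit = place(insert)
        counts[hit[0]] += 1
        if hit[0] != "mapped":
            continue
        _, tid, start, end = hit
        rows.append((rec.read_id, rec.sample, rec.umi, tid, start, end, "+"))

    placements = pd.DataFrame(
        rows, columns=["read_id", "sample", "umi", "transcript_id", "start", "end", "strand"])
    logger.info("mapping: %s", counts)
    return MappingResult(placements, counts)


def call_crosslink_events(placements: pd.DataFrame) -> pd.DataFrame:
    """Collapse placements to a unique crosslink-event table.

    The crosslink position is ``start - 1``.  Reads with identical
    (transcript, position, sample, UMI) are one unique cDNA molecule; the
    ``unique_count`` of a (transcript, position, sample) row is the number of
    distinct UMIs observed there.  Placements with start 0 (crosslink would be
    -1, off the transcript) are dropped with a warning.
    """
    if placements.empty:
        return pd.DataFrame(columns=CE_COLUMNS).astype(
            {"position": int, "unique_count": int})
    df = placements.copy()
    n_at_start = int((df["start"] == 0).sum())
    if n_at_start:
        logger.warning("dropping %d reads mapping at transcript start "
                       "(crosslink position -1 undefined)", n_at_start)
        df = df[df["start"] > 0]
    df["position"] = df["start"] - 1
    uniq = df.drop_duplicates(["transcript_id", "position", "sample", "umi"])
    ce = (uniq.groupby(["transcript_id", "position", "sample"], sort=True)
          .size().reset_index(name="unique_count"))
    ce["strand"] = "+"
    ce = ce[CE_COLUMNS]
    logger.info("called %d unique crosslink events (%d unique molecules, %d reads)",
                len(ce), len(uniq), len(placements))
    return ce


def ce_table_to_bed(ce: pd.DataFrame) -> pd.DataFrame:
    """CE table as BED6: chrom=transcript, name=sample, score=unique_count."""
    return pd.DataFrame({
        "chrom": ce["transcript_id"],
        "start": ce["position"].astype(int),
        "end": ce["position"].astype(int) + 1,
        "name": ce["sample"],
        "score": ce["unique_count"].astype(int),
        "strand": ce["strand"],
    })


def run_event_calling(fastq, fasta, barcode_spec: BarcodeSpec, samples) -> tuple[pd.DataFrame, dict]:
    """Convenience composition: demultiplex -> map -> call events.

    Returns the CE table and a counter dict merging all stage counters.
    """
    demux = demultiplex(fastq, barcode_spec, samples)
    mapping = map_reads_exact(demux.reads, fasta)
    ce = call_crosslink_events(mapping.placements)
    counters = {"demultiplex": demux.counts, "mapping": mapping.counts,
                "n_unique_events": int(len(ce)),
                "n_unique_molecules": int(ce["unique_count"].sum()) if len(ce) else 0}
    return ce, counters
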