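"""Ground-truth simulator for iCLIP experiments in transcript space.

Generates a synthetic transcriptome (transcript models + sequences) in which a
configurable subset of protein-coding transcripts carries uridine-rich binding
motifs in the 3'UTR (the RNA-binding-protein targets) and a partially
overlapping subset carries miRNA 7mer-A1 seed-match sites.  From that
transcriptome it simulates a multiplexed iCLIP sequencing library under the
cDNA-truncation model: each signal read starts exactly one nucleotide 3' of
its crosslink position, carries a random-barcode/sample-code/random-barcode
prefix, and is emitted with PCR duplicates.

Everything operates in unspliced transcript coordinates (one sequence per
transcript, introns included), so intronic crosslink events exist without a
genome model.  All randomness flows through a single mandatory seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RNA_BASES = np.array(["A", "C", "G", "U"])
REGION_LABELS = ("five_prime_utr", "cds", "three_prime_utr", "intron", "noncoding_exon")

#: quality character used for every base of every simulated read
FASTQ_QUALITY_CHAR = "I"

_MAX_PLANT_RETRIES = 100


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) with a transcript-feature label."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Unspliced-coordinate transcript with a region map and biotype.

    The region intervals tile ``[0, length)`` exactly (sorted, non-overlapping,
    gap-free).  Protein-coding transcripts carry at least one CDS interval;
    lincRNAs carry only ``noncoding_exon``/``intron`` labels.
    """

    transcript_id: str
    gene_id: str
    biotype: str  # "protein_coding" | "lincRNA"
    length: int
    regions: list[Region]
    strand: str = "+"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.biotype not in ("protein_coding", "lincRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        pos = 0
        for reg in self.regions:
            if reg.start != pos:
                raise ValueError(
                    f"{self.transcript_id}: regions do not tile [0, {self.length}) "
                    f"(gap/overlap at {reg.start}, expected {pos})"
                )
            pos = reg.end
        if pos != self.length:
            raise ValueError(f"{self.transcript_id}: regions end at {pos}, length {self.length}")
        labels = {r.label for r in self.regions}
        if self.biotype == "protein_coding" and "cds" not in labels:
            raise ValueError(f"{self.transcript_id}: protein_coding without cds")
        if self.biotype == "lincRNA" and not labels <= {"noncoding_exon", "intron"}:
            raise ValueError(f"{self.transcript_id}: lincRNA with coding labels {labels}")

    def intervals(self, label: str) -> list[tuple[int, int]]:
        return [(r.start, r.end) for r in self.regions if r.label == label]

    @property
    def utr3_intervals(self) -> list[tuple[int, int]]:
        return self.intervals("three_prime_utr")

    @property
    def utr3_length(self) -> int:
        return sum(e - s for s, e in self.utr3_intervals)

    def utr3_sequence(self, sequence: str) -> str:
        """3'UTR sequence: concatenation of 3'UTR intervals in transcript order."""
        return "".join(sequence[s:e] for s, e in self.utr3_intervals)

    def label_at(self, position: int) -> str:
        if not 0 <= position < self.length:
            raise ValueError(
                f"position {position} outside [0, {self.length}) of {self.transcript_id}"
            )
        for reg in self.regions:
            if reg.start <= position < reg.end:
                return reg.label
        raise AssertionError("tiling invariant violated")


@dataclass
class TranscriptTruth:
    """Ground-truth annotation of one simulated transcript."""

    is_rbp_target: bool
    planted_motif_sites: list[tuple[int, int]]
    is_mir_target: bool
    planted_seed_sites: list[tuple[int, int]]
    expression_weight: float

    def validate(self, model: TranscriptModel) -> None:
        if self.expression_weight <= 0:
            raise ValueError("expression_weight must be > 0")
        if self.is_rbp_target != bool(self.planted_motif_sites):
            raise ValueError("is_rbp_target must match presence of planted motif sites")
        utr = model.utr3_intervals
        for s, e in self.planted_motif_sites + self.planted_seed_sites:
            if not any(us <= s and e <= ue for us, ue in utr):
                raise ValueError(
                    f"planted site [{s},{e}) outside 3'UTR of {model.transcript_id}"
                )


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment.

    ``transcripts`` maps transcript_id -> :class:`TranscriptTruth`.
    ``molecules`` (filled by :func:`simulate_iclip_reads`) has one row per
    unique cDNA molecule: origin (signal/background), transcript, crosslink
    position, UMI, PCR copy count and a truncation flag.
    """

    transcripts: dict[str, TranscriptTruth]
    molecules: pd.DataFrame | None = None

    @property
    def rbp_targets(self) -> set[str]:
        return {t for t, tr in self.transcripts.items() if tr.is_rbp_target}

    @property
    def mir_targets(self) -> set[str]:
        return {t for t, tr in self.transcripts.items() if tr.is_mir_target}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the characterized iCLIP study: a few hundred expressed
    transcripts of which ~20% are true binding targets with uridine-rich
    3'UTR motifs, longer 3'UTRs among targets (lognormal medians 1.99 vs
    0.72 kb), miR-128 7mer-A1 sites co-planted in 60% of targets, and a mean
    PCR duplication below 4 copies per unique cDNA.
    """

    rng_seed: int
    n_transcripts: int = 500
    fraction_rbp_targets: float = 0.2
    fraction_mir_targets: float = 0.3
    target_overlap_fraction: float = 0.6
    fraction_lincrna: float = 0.05
    # transcript architecture (lengths in nt; ranges are inclusive uniform)
    utr5_len: tuple[int, int] = (100, 300)
    cds_len: tuple[int, int] = (300, 1500)
    n_introns: tuple[int, int] = (0, 2)
    intron_len: tuple[int, int] = (200, 1000)
    utr3_median_target: float = 1990.0
    utr3_median_other: float = 720.0
    utr3_log_sigma: float = 0.6
    utr3_min_len: int = 50
    # binding-motif model: U-runs of 15-30 nt at 90% U (>=80% enforced)
    motif_len: tuple[int, int] = (15, 30)
    motif_sites_per_utr: tuple[int, int] = (1, 3)
    motif_u_prob: float = 0.9
    min_site_u_fraction: float = 0.8
    seed_sites_per_utr: tuple[int, int] = (1, 2)
    mirna_name: str = "miR-128-3p"
    mirna_seq: str = "UCACAGUGAACCGGUCUCUUU"
    # library
    n_reads: int = 200_000
    signal_fraction: float = 0.7
    read_length: int = 50
    random_prefix_len: int = 3
    sample_code: str = "ACGT"
    random_suffix_len: int = 2
    pcr_duplication_mean: float = 3.5
    background_base_probs: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        for name in ("fraction_rbp_targets", "fraction_mir_targets",
                     "target_overlap_fraction", "fraction_lincrna", "signal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_transcripts", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.pcr_duplication_mean < 1.0:
            raise ValueError("pcr_duplication_mean must be >= 1 (copies per molecule)")
        self._check_overlap_feasible()

    @property
    def barcode_length(self) -> int:
        return self.random_prefix_len + len(self.sample_code) + self.random_suffix_len

    @property
    def insert_length(self) -> int:
        return self.read_length - self.barcode_length

    def _target_counts(self) -> tuple[int, int, int, int]:
        """(n_coding, n_rbp, n_mir, n_overlap) implied by the fractions."""
        n_linc = int(round(self.n_transcripts * self.fraction_lincrna))
        n_coding = self.n_transcripts - n_linc
        n_rbp = int(round(self.n_transcripts * self.fraction_rbp_targets))
        n_mir = int(round(self.n_transcripts * self.fraction_mir_targets))
        n_overlap = int(round(self.target_overlap_fraction * n_rbp))
        return n_coding, n_rbp, n_mir, n_overlap

    def _check_overlap_feasible(self) -> None:
        n_coding, n_rbp, n_mir, n_overlap = self._target_counts()
        if n_rbp > n_coding:
            raise ValueError(
                f"fraction_rbp_targets requires {n_rbp} coding targets, "
                f"only {n_coding} protein_coding transcripts available"
            )
        if n_overlap > n_mir:
            raise ValueError(
                f"target_overlap_fraction implies {n_overlap} shared targets "
                f"but only {n_mir} miRNA targets requested"
            )
        if n_mir - n_overlap > n_coding - n_rbp:
            raise ValueError(
                f"{n_mir - n_overlap} miRNA-only targets requested but only "
                f"{n_coding - n_rbp} non-RBP-target coding transcripts available"
            )


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int,
                probs: tuple[float, float, float, float] | None) -> str:
    if length == 0:
        return ""
    idx = rng.choice(4, size=length, p=probs)
    return "".join(RNA_BASES[idx])


def _lognormal_length(rng: np.random.Generator, median: float, sigma: float,
                      min_len: int) -> int:
    return max(min_len, int(round(rng.lognormal(math.log(median), sigma))))


def _motif_sequence(rng: np.random.Generator, length: int, u_prob: float,
                    min_u_fraction: float) -> str:
    """U-rich run: each base U with prob ``u_prob``; redrawn until the
    realized U content reaches ``min_u_fraction``."""
    for _ in range(_MAX_PLANT_RETRIES):
        u_mask = rng.random(length) < u_prob
        others = rng.choice(3, size=length)  # A/C/G for the non-U positions
        if u_mask.mean() >= min_u_fraction:
            bases = np.where(u_mask, "U", np.array(["A", "C", "G"])[others])
            return "".join(bases)
    raise RuntimeError("could not draw a sufficiently U-rich motif site")


def _place_sites(rng: np.random.Generator, utr_start: int, utr_end: int,
                 site_lengths: list[int],
                 occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Place sites of given lengths uniformly in [utr_start, utr_end) without
    overlapping each other or ``occupied``; bounded rejection sampling."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for length in site_lengths:
        if utr_end - utr_start < length:
            raise ValueError(
                f"3'UTR of length {utr_end - utr_start} too short for a {length} nt site"
            )
        for _ in range(_MAX_PLANT_RETRIES):
            s = int(rng.integers(utr_start, utr_end - length + 1))
            e = s + length
            if all(e <= ts or s >= te for ts, te in taken):
                placed.append((s, e))
                taken.append((s, e))
                break
        else:
            raise RuntimeError("could not place a site without overlap (UTR too crowded)")
    return placed


def seed_match_site(mirna_seq: str) -> str:
    """7mer-A1 site of a mature miRNA (local copy to avoid import cycles;
    canonical definition lives in :mod:`iclipkit.enrichment_stats`)."""
    from .enrichment_stats import seed_site_7merA1, MiRNA
    return seed_site_7merA1(MiRNA("mirna", mirna_seq))


# ---------------------------------------------------------------------------
# transcriptome simulation
# ---------------------------------------------------------------------------

def simulate_transcriptome(
    config: SimConfig,
) -> tuple[dict[str, TranscriptModel], dict[str, str], SimTruth]:
    """Simulate transcript models, sequences and ground truth.

    Returns ``(annotation, sequences, truth)`` where ``annotation`` maps
    transcript_id -> :class:`TranscriptModel` and ``sequences`` maps
    transcript_id -> RNA string (A/C/G/U).  Deterministic given
    ``config.rng_seed``.
    """
    rng = np.random.default_rng([config.rng_seed, 0x5EED])
    n_coding, n_rbp, n_mir, n_overlap = config._target_counts()
    n_linc = config.n_transcripts - n_coding

    # assign roles: first n_coding ids are protein_coding; RBP targets are a
    # random subset of those, miRNA targets overlap them per the config
    coding_ids = [f"TX{i:05d}" for i in range(n_coding)]
    linc_ids = [f"TX{i:05d}" for i in range(n_coding, config.n_transcripts)]
    perm = rng.permutation(n_coding)
    rbp_set = {coding_ids[i] for i in perm[:n_rbp]}
    mir_from_rbp = {coding_ids[i] for i in perm[:n_overlap]}
    mir_only = {coding_ids[i] for i in perm[n_rbp:n_rbp + (n_mir - n_overlap)]}
    mir_set = mir_from_rbp | mir_only

    seed_site = seed_match_site(config.mirna_seq)

    annotation: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    truths: dict[str, TranscriptTruth] = {}

    for tid in coding_ids:
        is_rbp = tid in rbp_set
        is_mir = tid in mir_set

        utr5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds_total = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1))
        n_int = int(rng.integers(config.n_introns[0], config.n_introns[1] + 1))
        intron_lens = [int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                       for _ in range(n_int)]
        median = config.utr3_median_target if is_rbp else config.utr3_median_other
        utr3 = _lognormal_length(rng, median, config.utr3_log_sigma, config.utr3_min_len)
        # a designated target must be able to hold its planted sites
        if is_rbp or is_mir:
            need = config.motif_len[1] * config.motif_sites_per_utr[1] + \
                config.seed_sites_per_utr[1] * len(seed_site) + 20
            for _ in range(_MAX_PLANT_RETRIES):
                if utr3 >= need:
                    break
                utr3 = _lognormal_length(rng, median, config.utr3_log_sigma,
                                         config.utr3_min_len)
            else:
                raise RuntimeError(f"{tid}: could not draw a 3'UTR long enough for planting")

        regions = [Region(0, utr5, "five_prime_utr")]
        pos = utr5
        # split CDS into n_int+1 chunks separated by introns
        cuts = sorted(rng.choice(np.arange(1, cds_total), size=n_int, replace=False).tolist()) \
            if n_int else []
        chunks = [b - a for a, b in zip([0] + cuts, cuts + [cds_total])]
        for i, chunk in enumerate(chunks):
            regions.append(Region(pos, pos + chunk, "cds"))
            pos += chunk
            if i < len(intron_lens):
                regions.append(Region(pos, pos + intron_lens[i], "intron"))
                pos += intron_lens[i]
        regions.append(Region(pos, pos + utr3, "three_prime_utr"))
        length = pos + utr3

        model = TranscriptModel(tid, f"G{tid[2:]}", "protein_coding", length, regions)
        seq = _random_rna(rng, length, config.background_base_probs)

        utr_start, utr_end = model.utr3_intervals[0]
        motif_sites: list[tuple[int, int]] = []
        seed_sites: list[tuple[int, int]] = []
        if is_rbp:
            n_sites = int(rng.integers(config.motif_sites_per_utr[0],
                                       config.motif_sites_per_utr[1] + 1))
            lens = [int(rng.integers(config.motif_len[0], config.motif_len[1] + 1))
                    for _ in range(n_sites)]
            motif_sites = _place_sites(rng, utr_start, utr_end, lens, [])
        if is_mir:
            n_seeds = int(rng.integers(config.seed_sites_per_utr[0],
                                       config.seed_sites_per_utr[1] + 1))
            seed_sites = _place_sites(rng, utr_start, utr_end,
                                      [len(seed_site)] * n_seeds, motif_sites)

        seq_arr = np.array(list(seq))
        for s, e in motif_sites:
            seq_arr[s:e] = list(_motif_sequence(rng, e - s, config.motif_u_prob,
                                                config.min_site_u_fraction))
        for s, e in seed_sites:
            seq_arr[s:e] = list(seed_site)
        seq = "".join(seq_arr)

        annotation[tid] = model
        sequences[tid] = seq
        truths[tid] = TranscriptTruth(
            is_rbp_target=is_rbp,
            planted_motif_sites=sorted(motif_sites),
            is_mir_target=is_mir,
            planted_seed_sites=sorted(seed_sites),
            expression_weight=float(rng.lognormal(0.0, 1.0)),
        )
        truths[tid].validate(model)

    for tid in linc_ids:
        n_ex = int(rng.integers(1, 4))
        regions = []
        pos = 0
        for i in range(n_ex):
            ex = int(rng.integers(200, 1000))
            regions.append(Region(pos, pos + ex, "noncoding_exon"))
            pos += ex
            if i < n_ex - 1:
                intr = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                regions.append(Region(pos, pos + intr, "intron"))
                pos += intr
        model = TranscriptModel(tid, f"G{tid[2:]}", "lincRNA", pos, regions)
        annotation[tid] = model
        sequences[tid] = _random_rna(rng, pos, config.background_base_probs)
        truths[tid] = TranscriptTruth(False, [], False, [],
                                      float(rng.lognormal(0.0, 1.0)))

    logger.info("simulated %d transcripts (%d coding, %d lincRNA; %d RBP targets, "
                "%d miRNA targets, %d shared)",
                config.n_transcripts, n_coding, n_linc, n_rbp, n_mir, n_overlap)
    return annotation, sequences, SimTruth(truths)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Output of :func:`simulate_iclip_reads`.

    ``reads``: list of (read_id, sequence, quality) FASTQ records (DNA letters).
    ``true_ce``: BED-like table of unique (transcript, position) crosslink
    events with unique-molecule counts.
    ``molecules``: one row per unique cDNA molecule (the deduplication truth).
    """

    reads: list[tuple[str, str, str]]
    true_ce: pd.DataFrame
    molecules: pd.DataFrame


def _empty_molecules() -> pd.DataFrame:
    return pd.DataFrame({
        "molecule_id": pd.Series(dtype=str),
        "origin": pd.Series(dtype=str),
        "transcript_id": pd.Series(dtype=str),
        "position": pd.Series(dtype=int),
        "umi": pd.Series(dtype=str),
        "n_copies": pd.Series(dtype=int),
        "truncated": pd.Series(dtype=bool),
    })


def _empty_true_ce() -> pd.DataFrame:
    return pd.DataFrame({
        "transcript_id": pd.Series(dtype=str),
        "start": pd.Series(dtype=int),
        "end": pd.Series(dtype=int),
        "name": pd.Series(dtype=str),
        "score": pd.Series(dtype=int),
        "strand": pd.Series(dtype=str),
    })


def simulate_iclip_reads(
    annotation: dict[str, TranscriptModel],
    sequences: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
) -> SimulatedReads:
    """Simulate a multiplexed iCLIP library under the truncation model.

    Each unique cDNA molecule gets a crosslink position (uniform within a
    planted motif site for signal molecules; expression-weighted uniform over
    transcripts for background), a random UMI, and ``1 + Poisson(mean - 1)``
    PCR copies; copies are emitted until exactly ``config.n_reads`` reads
    exist.  The read is ``random_prefix + sample_code + random_suffix +
    insert`` where the insert starts one nt 3' of the crosslink.  Also fills
    ``truth.molecules``.
    """
    if config.insert_length <= 0:
        raise ValueError(
            f"read_length {config.read_length} <= barcode length {config.barcode_length}"
        )
    rng = np.random.default_rng([config.rng_seed, 0x4EAD])

    if config.n_reads == 0:
        truth.molecules = _empty_molecules()
        return SimulatedReads([], _empty_true_ce(), truth.molecules)

    tids = sorted(annotation)
    weights = np.array([truth.transcripts[t].expression_weight for t in tids])
    cum_bg = np.cumsum(weights) / weights.sum()
    target_ids = sorted(truth.rbp_targets)
    if config.signal_fraction > 0 and not target_ids:
        raise ValueError("signal_fraction > 0 but no RBP targets in truth")
    if target_ids:
        target_w = np.array([truth.transcripts[t].expression_weight for t in target_ids])
        cum_sig = np.cumsum(target_w) / target_w.sum()

    umi_len = config.random_prefix_len + config.random_suffix_len
    mean_extra = config.pcr_duplication_mean - 1.0

    mol_rows: list[tuple] = []
    reads: list[tuple[str, str, str]] = []
    emitted = 0
    mol_idx = 0
    while emitted < config.n_reads:
        is_signal = bool(rng.random() < config.signal_fraction) and bool(target_ids)
        if is_signal:
            tid = target_ids[int(np.searchsorted(cum_sig, rng.random(), side="right"))]
            sites = truth.transcripts[tid].planted_motif_sites
            s, e = sites[int(rng.integers(len(sites)))]
            xpos = int(rng.integers(s, e))
            # the insert must be non-empty: redraw if the crosslink sits on
            # the transcript's last nucleotide
            L = annotation[tid].length
            for _ in range(_MAX_PLANT_RETRIES):
                if xpos < L - 1:
                    break
                xpos = int(rng.integers(s, e))
            else:
                raise RuntimeError(f"{tid}: motif site at transcript end, no valid insert")
        else:
            tid = tids[int(np.searchsorted(cum_bg, rng.random(), side="right"))]
            L = annotation[tid].length
            xpos = int(rng.integers(0, L - 1))

        umi = "".join(RNA_BASES[rng.integers(0, 4, size=umi_len)])
        n_copies = 1 + int(rng.poisson(mean_extra))
        n_copies = min(n_copies, config.n_reads - emitted)

        L = annotation[tid].length
        insert_rna = sequences[tid][xpos + 1: xpos + 1 + config.insert_length]
        truncated = len(insert_rna) < config.insert_length
        prefix = umi[:config.random_prefix_len]
        suffix = umi[config.random_prefix_len:]
        read_seq = (prefix + config.sample_code + suffix + insert_rna).replace("U", "T")
        qual = FASTQ_QUALITY_CHAR * len(read_seq)

        mol_id = f"mol{mol_idx:07d}"
        for copy in range(n_copies):
            reads.append((f"{mol_id}:{copy}", read_seq, qual))
        mol_rows.append((mol_id, "signal" if is_signal else "background",
                         tid, xpos, umi, n_copies, truncated))
        emitted += n_copies
        mol_idx += 1

    molecules = pd.DataFrame(
        mol_rows,
        columns=["molecule_id", "origin", "transcript_id", "position", "umi",
                 "n_copies", "truncated"],
    )
    truth.molecules = molecules

    ce = (molecules.groupby(["transcript_id", "position"], sort=True)
          .size().reset_index(name="score"))
    true_ce = pd.DataFrame({
        "transcript_id": ce["transcript_id"],
        "start": ce["position"].astype(int),
        "end": ce["position"].astype(int) + 1,
        "name": config.sample_code,
        "score": ce["score"].astype(int),
        "strand": "+",
    })

    logger.info("simulated %d reads from %d unique molecules (duplication %.2f)",
                len(reads), len(molecules), len(reads) / len(molecules))
    return SimulatedReads(reads, true_ce, molecules)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    """Write transcript sequences as FASTA, U written as T."""
    with open(path, "w") as fh:
        for tid in sorted(sequences):
            fh.write(f">{tid}\n")
            seq = sequences[tid].replace("U", "T")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_annotation_table(annotation: dict[str, TranscriptModel], path) -> None:
    """Region map as a TSV (transcript_id, gene_id, biotype, start, end, label, strand)."""
    rows = []
    for tid in sorted(annotation):
        m = annotation[tid]
        for reg in m.regions:
            rows.append((tid, m.gene_id, m.biotype, reg.start, reg.end, reg.label, m.strand))
    pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", "start",
                                "end", "label", "strand"]).to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    annotation = {}
    for tid, grp in df.groupby("transcript_id", sort=True):
        grp = grp.sort_values("start")
        regions = [Region(int(r.start), int(r.end), r.label) for r in grp.itertuples()]
        annotation[str(tid)] = TranscriptModel(
            str(tid), str(grp.iloc[0]["gene_id"]), str(grp.iloc[0]["biotype"]),
            int(grp["end"].max()), regions, str(grp.iloc[0]["strand"]))
    return annotation


def write_truth_tables(truth: SimTruth, prefix) -> None:
    """Truth as TSVs: ``<prefix>.transcripts.tsv`` and ``<prefix>.molecules.tsv``."""
    rows = []
    for tid in sorted(truth.transcripts):
        tr = truth.transcripts[tid]
        rows.append((
            tid, tr.is_rbp_target,
            ";".join(f"{s}-{e}" for s, e in tr.planted_motif_sites),
            tr.is_mir_target,
            ";".join(f"{s}-{e}" for s, e in tr.planted_seed_sites),
            tr.expression_weight,
        ))
    pd.DataFrame(rows, columns=["transcript_id", "is_rbp_target", "motif_sites",
                                "is_mir_target", "seed_sites", "expression_weight"]
                 ).to_csv(f"{prefix}.transcripts.tsv", sep="\t", index=False)
    if truth.molecules is not None:
        truth.molecules.to_csv(f"{prefix}.molecules.tsv", sep="\t", index=False)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6-style table (chrom=transcript, 0-based half-open)."""
    df.to_csv(path, sep="\t", index=False, header=False)
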