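"""End-to-end reproducible run: simulate -> events -> peaks -> enrichment.

Composes the simulator, the crosslink-event caller, the peak caller and the
enrichment statistics into one deterministic pipeline with a machine-readable
report.  A single top-level seed is fanned out to every stochastic stage
through ``numpy.random.SeedSequence`` spawning, so stages are independent but
the whole run is reproducible bit-for-bit.

Against the simulator's ground truth the report also carries recovery
metrics: target recall/precision and crosslink-position accuracy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic_data import (
    SimConfig, SimTruth, TranscriptModel, simulate_transcriptome,
    simulate_iclip_reads, write_fasta, write_fastq, write_annotation_table,
    write_truth_tables, write_bed,
)
from .iclip_events import (
    BarcodeSpec, demultiplex, map_reads_exact, call_crosslink_events,
    ce_table_to_bed,
)
from .peak_annotation import (
    call_peaks, derive_targets, feature_distribution, utr_length_stats,
    peaks_to_bed, assign_feature,
)
from .enrichment_stats import (
    MiRNA, seed_site_7merA1, profile_utrs, compare_bound_unbound,
    overlap_enrichment, positional_profile, seed_proximity_bias, POLY_U_7MER,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``rng_seed`` is the only seed a user supplies; per-stage seeds are derived
    from it deterministically.  Round-trips losslessly through YAML.
    """

    rng_seed: int = 1
    sim: SimConfig | None = None  # derived from rng_seed when omitted
    window_w: int = 15
    n_perm: int = 100
    fdr_alpha: float = 0.05
    min_height: int = 3
    flank: int = 10
    n_perm_proximity: int = 200

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(rng_seed=_stage_seeds(self.rng_seed)["sim"])

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        sim = d.pop("sim", None)
        cfg = cls(**{k: v for k, v in d.items()}, sim=None)
        if sim is not None:
            for k in ("utr5_len", "cds_len", "n_introns", "intron_len", "motif_len",
                      "motif_sites_per_utr", "seed_sites_per_utr",
                      "background_base_probs"):
                if sim.get(k) is not None:
                    sim[k] = tuple(sim[k])
            cfg.sim = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage_seeds(rng_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (all < 2**31) from one top-level seed."""
    names = ["sim", "peaks", "proximity"]
    state = np.random.SeedSequence(rng_seed).generate_state(len(names))
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full synthetic-data pipeline and return the run report.

    When ``outdir`` is given, every intermediate artifact (FASTA, FASTQ,
    truth tables, CE table, peaks, targets, profiles, report JSON) is written
    there.
    """
    seeds = _stage_seeds(config.rng_seed)
    sim_cfg = config.sim
    report: dict = {
        "config_hash": config.config_hash(),
        "versions": {"iclipkit": __version__},
        "parameters": {
            "rng_seed": config.rng_seed, "window_w": config.window_w,
            "n_perm": config.n_perm, "fdr_alpha": config.fdr_alpha,
            "min_height": config.min_height, "flank": config.flank,
            "n_perm_proximity": config.n_perm_proximity,
        },
    }
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        annotation, sequences, truth = simulate_transcriptome(sim_cfg)
        sim = simulate_iclip_reads(annotation, sequences, truth, sim_cfg)
        n_mol = len(sim.molecules)
        report["simulate"] = {
            "n_transcripts": len(annotation),
            "n_true_targets": len(truth.rbp_targets),
            "n_true_mir_targets": len(truth.mir_targets),
            "n_reads": len(sim.reads),
            "n_unique_molecules": n_mol,
            "duplication_ratio": len(sim.reads) / n_mol if n_mol else float("nan"),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    try:
        stage("events")
        bc = BarcodeSpec(sim_cfg.random_prefix_len, len(sim_cfg.sample_code),
                         sim_cfg.random_suffix_len)
        demux = demultiplex(sim.reads, bc, [sim_cfg.sample_code])
        mapping = map_reads_exact(demux.reads, sequences)
        ce = call_crosslink_events(mapping.placements)
        report["events"] = {
            "demultiplex": demux.counts,
            "mapping": mapping.counts,
            "n_unique_events": int(len(ce)),
            "n_unique_molecules_called": int(ce["unique_count"].sum()) if len(ce) else 0,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'events' failed: {exc}") from exc

    try:
        stage("peaks")
        peaks = call_peaks(ce, annotation, config.window_w, config.n_perm,
                           config.fdr_alpha, seeds["peaks"], config.min_height)
        targets = derive_targets(peaks, annotation, ce)
        n_bound = int(targets["bound"].sum())
        report["peaks"] = {
            "n_peaks": int(len(peaks)),
            "n_bound": n_bound,
            "n_unbound": int(len(targets)) - n_bound,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'peaks' failed: {exc}") from exc

    try:
        stage("features")
        fractions = feature_distribution(ce, annotation, weight="events") if len(ce) else {}
        utr = utr_length_stats(targets) if 0 < n_bound < len(targets) else None
        report["features"] = {
            "ce_fractions": fractions,
            "utr_length": None if utr is None else {
                "median_bound_kb": utr.median_bound_kb,
                "median_unbound_kb": utr.median_unbound_kb,
                "p_value": utr.p_value, "test": utr.test,
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc

    try:
        stage("enrichment")
        mirna = MiRNA(sim_cfg.mirna_name, sim_cfg.mirna_seq)
        seed_site = seed_site_7merA1(mirna)
        panel = {"polyU": POLY_U_7MER, mirna.name: seed_site}
        profiles = profile_utrs(annotation, sequences, panel)
        enrich = {}
        if 2 <= n_bound <= len(targets) - 2:
            for name in panel:
                cmp_res = compare_bound_unbound(profiles, targets, name)
                enrich[name] = {
                    "mean_count_bound": cmp_res.mean_count_bound,
                    "mean_count_unbound": cmp_res.mean_count_unbound,
                    "count_p": cmp_res.count_test.p_value,
                    "mean_density_bound": cmp_res.mean_density_bound,
                    "mean_density_unbound": cmp_res.mean_density_unbound,
                    "density_p": cmp_res.density_test.p_value,
                }
        bound_set = set(targets.loc[targets["bound"], "transcript_id"])
        mir_set = truth.mir_targets
        overlap = overlap_enrichment(bound_set, mir_set, len(annotation))
        # motif profile on crosslinks supported by significant peaks: the
        # binding-site profile, not diluted by background events
        peak_ce = _ce_in_peaks(ce, peaks)
        profile_input = peak_ce if len(peak_ce) else ce
        profile = positional_profile(profile_input, sequences, config.flank) \
            if len(profile_input) else None
        seed_sites = {t: tr.planted_seed_sites
                      for t, tr in truth.transcripts.items() if tr.planted_seed_sites}
        proximity = None
        if len(ce) and seed_sites:
            proximity = seed_proximity_bias(ce, seed_sites, annotation,
                                            config.n_perm_proximity,
                                            seeds["proximity"])
        report["enrichment"] = {
            "kmer_tests": enrich,
            "overlap": {
                "overlap": overlap.overlap, "expected": overlap.expected,
                "fold": overlap.fold, "p_value": overlap.p_value,
                "n_bound": overlap.n_a, "n_mir": overlap.n_b,
                "universe": overlap.universe,
            },
            "positional_profile_central_u": None if profile is None
            else profile.central_u_frequency(width=2),
            "seed_proximity": None if proximity is None else {
                "median_abs_distance": proximity.median_abs_distance,
                "p_value": proximity.p_value, "n_events": proximity.n_events,
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'enrichment' failed: {exc}") from exc

    try:
        stage("recovery")
        rec = recovery_metrics(targets, ce, truth, sim.true_ce)
        if len(sim.true_ce):
            true_frac = true_feature_fractions(truth, sim.true_ce, annotation)
            rec["true_ce_fractions"] = true_frac
            called_utr3 = report["features"]["ce_fractions"].get("three_prime_utr", 0.0)
            rec["utr3_fraction_error"] = called_utr3 - true_frac.get("three_prime_utr", 0.0)
        report["recovery"] = rec
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'recovery' failed: {exc}") from exc

    if out is not None:
        write_fasta(sequences, out / "transcripts.fa")
        write_fastq(sim.reads, out / "reads.fastq")
        write_annotation_table(annotation, out / "annotation.tsv")
        write_truth_tables(truth, out / "truth")
        write_bed(sim.true_ce, out / "true_ce.bed")
        ce.to_csv(out / "crosslink_events.tsv", sep="\t", index=False)
        write_bed(ce_table_to_bed(ce), out / "crosslink_events.bed")
        peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
        write_bed(peaks_to_bed(peaks), out / "peaks.bed")
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)
        profiles.to_csv(out / "utr_kmer_profiles.tsv", sep="\t", index=False)
        if report["enrichment"]["positional_profile_central_u"] is not None:
            profile.to_frame().to_csv(out / "positional_profile.tsv", sep="\t")
        (out / "config.yaml").write_text(config.to_yaml())
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _ce_in_peaks(ce: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Crosslink events whose position falls inside a called peak interval
    (peak intervals widened by half a window on each side)."""
    if ce.empty or peaks.empty:
        return ce.iloc[0:0]
    keep = np.zeros(len(ce), dtype=bool)
    by_tx = {tid: grp[["start", "end"]].to_numpy()
             for tid, grp in peaks.groupby("transcript_id")}
    for i, rec in enumerate(ce.itertuples(index=False)):
        ivals = by_tx.get(rec.transcript_id)
        if ivals is None:
            continue
        pos = int(rec.position)
        if ((ivals[:, 0] <= pos) & (pos < ivals[:, 1])).any():
            keep[i] = True
    return ce[keep]


def recovery_metrics(targets: pd.DataFrame, ce: pd.DataFrame, truth: SimTruth,
                     true_ce: pd.DataFrame) -> dict:
    """Parameter-recovery metrics against the simulator's ground truth."""
    called = set(targets.loc[targets["bound"], "transcript_id"])
    true_set = truth.rbp_targets
    tp = len(called & true_set)
    recall = tp / len(true_set) if true_set else float("nan")
    precision = tp / len(called) if called else float("nan")

    called_pos = set(zip(ce["transcript_id"], ce["position"])) if len(ce) else set()
    true_pos = set(zip(true_ce["transcript_id"], true_ce["start"])) if len(true_ce) else set()
    pos_accuracy = (len(called_pos & true_pos) / len(called_pos)
                    if called_pos else float("nan"))
    return {
        "target_recall": recall,
        "target_precision": precision,
        "n_called_targets": len(called),
        "n_true_targets": len(true_set),
        "ce_position_accuracy": pos_accuracy,
    }


def true_feature_fractions(truth: SimTruth, true_ce: pd.DataFrame,
                           annotation: dict[str, TranscriptModel]) -> dict[str, float]:
    """Ground-truth CE feature distribution (weighting by unique molecules)."""
    totals: dict[str, float] = {}
    for rec in true_ce.itertuples(index=False):
        label = assign_feature(int(rec.start), rec.transcript_id, annotation)
        totals[label] = totals.get(label, 0.0) + float(rec.score)
    grand = sum(totals.values())
    return {k: v / grand for k, v in sorted(totals.items())}
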