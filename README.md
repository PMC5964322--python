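# iclipkit

Characterizing the mRNA interactome of an RNA-binding protein (RBP) from
iCLIP data, and relating it to miRNA targeting. iCLIP (individual-nucleotide
resolution crosslinking and immunoprecipitation) exploits reverse-transcription
truncation: the 5′ end of each sequenced cDNA insert sits one nucleotide 3′ of
the protein–RNA crosslink, so binding can be mapped at single-nucleotide
resolution once PCR duplicates are collapsed by their random barcodes (UMIs).

`iclipkit` implements the complete desk-scale analysis chain:

* **Crosslink-event (CE) calling** — demultiplexing by embedded sample codes,
  UMI extraction, unique-exact-match placement of inserts on transcripts, and
  collapse of reads to unique crosslink events at position `start − 1`.
* **Peak calling and target derivation** — windowed CE scores tested against a
  per-transcript permutation null (uniform re-scatter of the transcript's
  unique molecules, max-window statistic), with Benjamini–Hochberg FDR control
  across all candidate windows; a transcript with ≥ 1 significant peak is a
  *target*.
* **Feature and 3′UTR statistics** — CE distribution across 5′UTR / CDS /
  intron / 3′UTR / lincRNA classes; bound-vs-unbound 3′UTR length comparison
  (Mann–Whitney U, medians in kb).
* **Motif and seed-match statistics** — positional nucleotide frequencies
  around crosslink sites; overlapping k-mer counts per 3′UTR and per-kb
  densities for the poly-U heptamer `UUUUUUU` and TargetScan-style 7mer-A1
  miRNA seed sites (reverse complement of miRNA positions 2–7 plus `A`);
  Welch's unequal-variance t-test on the count and density scales; exact
  hypergeometric enrichment of the overlap between the RBP target set and a
  miRNA target set; a permutation test for crosslink proximity to seed sites.
* **Sholl morphometry** — SWC neuron reconstructions, XY-projected
  intersection profiles on concentric circles (default radii 10–350 µm in
  10 µm steps), and group comparison by two-way ANOVA with
  Bonferroni-corrected per-radius t-tests.
* **A ground-truth simulator** — synthetic transcriptomes with planted U-rich
  3′UTR motifs and co-planted miR-128 7mer-A1 sites, and multiplexed iCLIP
  reads generated under the truncation model with PCR duplication, so every
  stage can be validated against known truth.

## Worked example

```python
from iclipkit import RunConfig, run_pipeline

report = run_pipeline(RunConfig(rng_seed=1), outdir="run1")
print(report["peaks"])                       # {'n_peaks': 195, 'n_bound': 101, 'n_unbound': 399}
print(report["features"]["utr_length"])      # {'median_bound_kb': 2.084, 'median_unbound_kb': 0.661,
                                             #  'p_value': 9.0e-39, 'test': 'mann-whitney-u'}
print(report["recovery"]["target_recall"],
      report["recovery"]["target_precision"])  # 1.0 0.990
```

The default run simulates 500 transcripts (100 true RBP targets) and 200,000
reads, then recovers the planted structure: 101 transcripts are called bound
(recall 1.0, precision 0.99); 80.5% of unique crosslink events fall in 3′UTRs;
bound 3′UTRs have a median length of 2.08 kb versus 0.66 kb for unbound ones;
the crosslink-site profile is U-dominated (central U frequency 0.87); poly-U
density per kb of 3′UTR is strongly enriched among targets (8.9 vs 0.06,
Welch p ≈ 7×10⁻¹⁹); and the called target set overlaps the miRNA target set
twice as often as chance expects (60 observed vs 30.3 expected, exact
hypergeometric p ≈ 4×10⁻¹²) while crosslinks show no significant proximity
bias toward seed sites (permutation p ≈ 0.54). Every intermediate artifact
(FASTA/FASTQ, CE tables as TSV/BED6, peaks, targets, k-mer profiles, the JSON
report) is written to `run1/`.

The same stages are available from a shell:

```bash
iclipkit simulate --seed 1 --outdir sim/
iclipkit events --fastq sim/reads.fastq --fasta sim/transcripts.fa \
    --barcodes barcodes.tsv --out ce.tsv
iclipkit peaks --ce ce.tsv --annotation sim/annotation.tsv --out peaks.tsv
iclipkit sholl --swc-dir control/ --swc-dir knockdown/ --out sholl.tsv
iclipkit run --seed 1 --outdir run1/
```

## Documentation

`docs/methods.md` describes the simulation model, the peak-calling null and
its FDR control, the statistical conventions, and known limitations.
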