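# Methods

## Scope and coordinate conventions

All sequence analysis operates in *unspliced transcript space*: one sequence
per transcript containing its introns, with a region map that tiles
`[0, length)` with 5′UTR / CDS / intron / 3′UTR (or noncoding-exon) intervals.
This gives a single coordinate system in which intronic crosslink events
exist without a genome model, at the cost of ignoring genome-level effects
(overlapping genes, multi-isoform loci; see Limitations). Coordinates are
0-based half-open everywhere; sequences are RNA (`ACGU`) in memory and DNA
(`ACGT`) on disk.

## The synthetic experiment

The simulator generates the conditions the analysis is meant to recover.

**Transcriptome.** Default 500 transcripts, 5% lincRNA. Protein-coding
architecture: 5′UTR 100–300 nt, CDS 300–1500 nt split by 0–2 introns of
200–1000 nt, then the 3′UTR. 3′UTR lengths are lognormal with σ = 0.6 and
median 1990 nt for designated RBP targets versus 720 nt for all other coding
transcripts, reproducing the situation where bound mRNAs carry markedly
longer 3′UTRs. Background sequence is i.i.d. uniform over `ACGU`
(configurable to a first-order composition for stress tests). Expression
weights are lognormal(0, 1).

**Planted structure.** 20% of transcripts are RBP targets; each receives 1–3
uridine-rich runs of 15–30 nt in its 3′UTR, drawn at 90% U per position and
redrawn until the realized U content is ≥ 80%. 30% of transcripts carry
miRNA seed sites (1–2 copies of the 7mer-A1 site of miR-128-3p, `ACUGUGA`),
with 60% of the RBP targets among them (`target_overlap_fraction`), placed
disjointly from the motifs. Infeasible fraction combinations raise at
configuration time.

**Library.** Each unique cDNA molecule picks signal origin with probability
`signal_fraction` (default 0.7). Signal crosslinks are uniform within a
planted motif site of an expression-weighted target; background crosslinks
are uniform within an expression-weighted transcript. The insert starts one
nucleotide 3′ of the crosslink (truncation model) and is clipped at the
transcript end (flagged). The read is
`3 nt random prefix + 4 nt sample code + 2 nt random suffix + insert`
(50 nt total by default; the two random parts concatenate to the 5 nt UMI).
Each molecule is emitted `1 + Poisson(mean − 1)` times with mean 3.5,
matching a mean PCR duplication below 4; copies are emitted until exactly
`n_reads` (default 200,000) reads exist. The 3+4+2 barcode layout is a
standard iCLIP arrangement; the exact layout of any given experiment is a
configuration, not an assumption.

**What the simulator does not emulate:** sequencing errors, splice-isoform
mixtures, crosslinking-induced deletions/mutations, non-uniform fragment-
length distributions, genome-coordinate mapping ambiguity beyond exact
repeats. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to real-data
noise sources outside it.

## Crosslink-event calling

Demultiplexing requires an exact (0-mismatch) sample-code match; anything
else is counted as undetermined. Placement requires a *unique* exact
substring match across the whole transcript set (a 32-mer seed index over
the concatenated sequences, candidates verified by direct string
comparison); multi-mappers are discarded and counted rather than
fractionally assigned — the conservative CLIP convention, and the choice
that keeps ground-truth bookkeeping exact. The crosslink position is
`start − 1`; reads mapping at transcript start are dropped with a warning
(position −1 is undefined). Reads are collapsed to unique molecules by
identical (transcript, position, sample, UMI); no edit-distance UMI
clustering is attempted, which is exact for error-free reads and a
documented approximation otherwise.

## Peak calling and FDR

Per transcript, position `i` is scored by `s(i)`, the number of unique
molecules within ±(w−1)/2 (default w = 15). The null re-scatters the
transcript's unique molecules uniformly over its length — each molecule
independently, preserving the total — and records the *maximum* windowed
score per scatter (n_perm = 100). The empirical p-value is
`(1 + #{scatter maxima ≥ s(i)}) / (1 + n_perm)`. Scattering molecules
rather than weighted event stacks is essential: a stack kept intact would
reproduce its own height in every permutation and could never be
significant.

Candidate windows are CE positions with `s(i) ≥ min_height` (default 3
unique molecules). This pre-filter defines the multiple-testing family:
with a permutation resolution floor of 1/(n_perm+1) ≈ 0.01, a family
dominated by tens of thousands of singleton background positions would push
the Benjamini–Hochberg threshold below the floor and no position could ever
be rejected; requiring a minimal depth — as CLIP peak callers conventionally
do — keeps the family informative. BH runs once across all candidate windows
of the run (q ≤ 0.05 by default), giving a single interpretable FDR for
target derivation. Significant positions closer than w merge into peaks;
the summit is the leftmost argmax of `s`.

A transcript is *bound* iff it has ≥ 1 peak. The target universe is every
annotated transcript (the simulator has no unexpressed transcripts); an
expression filter for real data would be applied before this step.

Under a pure-background library the empirically calibrated bound fraction
is far below the nominal α (the max-statistic null plus the depth filter
are both conservative); the acceptance suite checks ≤ 1.5 × α.

## Statistical conventions

* **3′UTR length comparison**: two-sided Mann–Whitney U on bound vs unbound
  3′UTR lengths, medians reported in kb. The test choice is recorded in the
  result object since rank and t-approaches can disagree on skewed lengths.
* **k-mer statistics**: overlapping occurrences (non-overlapping available
  by flag); the poly-U motif proxy is the exact heptamer `UUUUUUU`; density
  is count per kb of 3′UTR, 0 for zero-length UTRs. Counts conflate motif
  content with UTR length, so count- and density-scale comparisons are
  reported separately, each with Welch's unequal-variance t-test
  (hand-implemented from the definition with Welch–Satterthwaite degrees of
  freedom; cross-checked against scipy in the test suite). Both-groups-
  constant input is rejected (df undefined).
* **7mer-A1 sites**: reverse complement of miRNA positions 2–7 followed by
  `A` (TargetScan convention); 7mer-m8 and 8mer site types are not counted.
  The packaged panel of ten conserved miRNAs carries miRBase release-22
  mature sequences.
* **Set overlap**: exact hypergeometric upper tail P[X ≥ k] with
  expectation |A||B|/N; the universe is all annotated transcripts and is
  recorded in the result.
* **Positional profile**: nucleotide frequencies at offsets −flank..+flank,
  events weighted by unique-molecule count, windows crossing a transcript
  end skipped and counted. In the pipeline the profile is computed on
  crosslinks inside significant peaks — the binding-site profile — since
  pooling all events dilutes the motif with background.
* **Seed proximity**: median absolute distance from 3′UTR crosslinks to the
  nearest seed-site start on the same transcript, against a null that
  re-places each event uniformly within its own 3′UTR; add-one-smoothed
  permutation p (floor 1/(n_perm+1)).

## Sholl analysis

SWC reconstructions are validated as single-rooted trees. Profiles are
computed on the XY projection (as when tracing maximum-intensity
projections); full 3D distances are available behind a flag. For each
parent→child segment the planar distance to the soma is convex in the
segment parameter, so the segment splits at its closest approach into at
most two monotone pieces; each piece crosses radius r when
`d_lo < r ≤ d_hi`. For monotone segments this is exactly the classic
two-endpoint straddle test; for segments that dip inside a circle and exit
again, both crossings count — which is what a dense resampling of the
polyline measures, and the test suite verifies exact agreement with a
0.01 µm resampling oracle. Radii default to 10, 20, …, 350 µm (35 circles).

Group comparison: ordinary two-way ANOVA (group × radius, each neuron one
observation per radius) as the omnibus, then per-radius two-sample t-tests
Bonferroni-corrected across the radii, with mean ± s.e.m. per group — the
standard "ANOVA with Bonferroni post-test" layout. Radii where both groups
are constant and equal report p = 1.

## Determinism and seeds

Every stochastic stage takes an explicit seed. The pipeline fans a single
top-level seed into per-stage seeds via `numpy.random.SeedSequence`, so runs
are bit-reproducible and stages remain independently re-runnable; the
config (including all thresholds) is hashed into the report. Simulation
seeds are mandatory by construction.

## Problem sizes

Defaults were chosen as the smallest scale at which every statistic is
comfortably in its asymptotic regime: 500 transcripts / 200,000 reads for
the pipeline; 200 transcripts / 80,000 reads for null calibration of the
peak caller; 200 repeats of 60 transcripts for p-value uniformity checks;
100 random trees for geometry oracles. A full default run completes in
seconds on one CPU.

## Known limitations

* Exact-match mapping is a deliberate stand-in for production alignment;
  it is only meaningful for error-free reads.
* The permutation null assumes within-transcript positional uniformity of
  background; real CLIP backgrounds are non-uniform (expression, structure,
  sequence bias).
* The empirical-p resolution is bounded by n_perm; q-values saturate at
  the floor and peaks cannot be ranked below it.
* lincRNA exonic positions are reported as a single "lincRNA" class, so
  the feature distribution is not a strict region-label histogram.
* The seed-proximity test conditions on the observed per-transcript event
  counts and 3′UTR boundaries; it does not model co-dependency between
  UTR length and miRNA targeting.
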