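# Methods

## Consensus summit detection

The central operation pools the peak summits of all samples on a
chromosome and estimates their density with a triangular (Bartlett)
kernel of half-width `bandwidth` (default 20 bp):

    d(x) = Σ_i max(0, 1 − |x − s_i| / bandwidth)

Rather than a normalized kernel density estimator, the sum is evaluated
*exactly* on the 1-bp integer grid, in integer arithmetic (the quantity
actually manipulated is `bandwidth · d(x) = Σ_i max(0, bandwidth − |x −
s_i|)`, an int64). This makes maxima, plateaus and ties exactly
reproducible, with no floating-point noise. Estimator-based
implementations need a tiny floor (default 1.0e−15) to zero numerical
noise before maximum detection; with exact sums every nonzero density is
at least `1/bandwidth`, so the floor is retained as a configurable no-op
for parameter compatibility.

A position is a candidate consensus summit when its density is ≥ every
density within ± `span`/2 (default span 100 bp). Runs of adjacent
equal-density candidates (plateaus, which arise whenever two summits are
an even number of base pairs apart) collapse to their integer midpoint,
rounding down. Candidates are then accepted greedily in order of density
descending, position ascending; a candidate closer than `span` to an
already accepted summit is discarded. Equal-density ties therefore
resolve leftmost-first, deterministically. Chromosomes are processed
independently; within a chromosome, summit clusters separated by more
than `2·bandwidth + span` cannot interact and are processed as
independent components.

Given the bandwidth, consensus summits locate true sites to about ±10 bp
when per-sample summit jitter is within ±5 bp; the test suite and the
acceptance script verify this bound on seeded fixtures.

## Consensus peaks

Each consensus summit is elongated `elongation` (100 bp) to both sides,
`[summit − e, summit + e)`. Overlapping adjacent intervals are both cut
at the midpoint of their overlap region; an odd-width overlap cuts at the
floor of the midpoint, so the left peak keeps the boundary base. The
result is a genome-wide set of pairwise non-overlapping peaks of width
≤ 2·elongation = 200 bp, each containing its summit.

A sample is **present** at a consensus peak when at least one of its
original peak summits lies inside the consensus interval (the interval,
not the 50% rule, defines the area of the consensus peak). Its fold
enrichment and −log10 q are copied from the highest-FE such original
peak. Absent samples can fall back to per-sample score tracks (bedGraph
step functions, as produced by pileup comparison with pseudocount 1:
FE = (treat + 1)/(control + 1)) evaluated at the consensus summit, else
(0, 0). `n_cell_types` counts distinct cell types with ≥ 1 present
sample, so two replicates or states of one cell type count once.

The **distance sensitivity sweep** reruns the consensus stage with
`span = distance` and `elongation = distance // 2` for each distance
(60–500 bp in the reference analysis) and reports the count of consensus
peaks present in all cell types alongside the total count. Larger
distances merge more summits, so the total is non-increasing in the
distance.

## Overlap statistics

Two peaks are at the same location when their overlap exceeds
`overlap_fraction` (default 0.5) of the **narrower** peak's width — a
strict inequality, so exactly half does not qualify; equal widths treat
the first argument as narrower (the outcome is identical). Pairwise
overlap percentages are referenced to the set with fewer peaks (and
reported symmetrically from the larger set). The stimulated/unstimulated
partition matches qualifying stim/unstim pairs 1:1 greedily in genomic
order — each peak joins at most one common locus — and reports
unique-stim / unique-unstim / common counts; by construction
`unique + common` equals each input's size. Percentages round half-up to
two decimals; one-decimal figures re-round from that.

Presence at FDR < 1% is expressed on the narrowPeak q column as
−log10(q) > 2 and applied as a pre-filter before partitioning.

## DR3 motif scanning

The DR3 element is represented as a PWM over A/C/G/T built from the
IUPAC consensus RGGTCANNGRGTTCA: unambiguous letters take
`match_prob` (default 0.997) with the remainder split over the other
bases, two-fold degenerate letters split `match_prob` over their two
bases, N is uniform; all probabilities are floored at 0.001 and columns
renormalized. Scores are cumulative natural-log odds against a uniform
0.25 background; an N in the sequence scores `ln(0.001/0.25)`. Because
N columns contribute zero regardless of base, the maximal score is
attained exactly by the 64 expansions of the degenerate consensus (4
R-choices × 16 spacer fillings); any change at an informative position
scores strictly less. The representative motif's native threshold
9.184643 and the sweep floor of 4 reproduce the reference analysis'
operating points on its own score scale; exact parity with scanners
using GC-adjusted backgrounds is not claimed, and thresholds are
configurable throughout.

Scanning considers every placement of the motif fully inside
`[summit − flank, summit + flank)` (flank 100 bp) on both strands; the
minus strand scores the reverse complement via a reverse-complemented
matrix, so strand symmetry is exact. The best hit above threshold is
returned, ties broken by offset ascending, plus strand before minus.
Windows running off a chromosome are N-padded. Derived statistics:

- **threshold sweep** — percentage of peaks with any hit, per threshold
  (non-increasing by construction; a peak counts once);
- **density profile** — all hits (not only best) per offset bin of the
  motif *center* within ±500 bp of the summit, normalized to hits per
  peak per bp;
- **FE-window curve** — peaks ranked by fold enrichment descending (ties
  by genomic position), consecutive disjoint windows of 100 peaks, per
  window the mean FE and the DR3 percentage at the native threshold; a
  trailing partial window is dropped;
- **SNP distances** — signed distance from the motif's central
  nucleotide (start + 7 for the 15-mer, the middle spacer base) to the
  nearest SNP, negative when the SNP is upstream (smaller coordinate).
  When two SNPs are equidistant the upstream one is reported; a
  chromosome without SNPs yields a missing value.

## Synthetic studies

The generator emulates a K-cell-type (default 6) stimulated/unstimulated
ChIP-seq compendium; its defaults are the study conditions the tests
assume:

- **genome**: i.i.d. uniform ACGT, one 1 Mb chromosome by default;
- **true sites**: 200 positions spaced ≥ 400 bp (edge margin 200 bp);
- **sharing**: each site is active in k cell types with probabilities
  (0.7561, 0.2112, 0.0200, 0.0076, 0.0031, 0.0018) — the observed
  cell-type-specificity fractions of the six-cell-type VDR compendium —
  over a uniformly drawn k-subset;
- **state**: each active (site, cell type) is stimulated-only,
  unstimulated-only or both with probabilities (0.60, 0.27, 0.13),
  following the observed stimulated/unstimulated partition;
- **fold enrichment**: site-level lognormal(μ=1.5, σ=0.8) — median ≈ 4.5
  with a long tail to ≈ 30, a realistic MACS2 FE range that reproduces
  the observed dynamic range of DR3 percentage across FE-ranked windows
  — times a per-cell lognormal(0, 0.25) factor and a 1.5× stimulated
  multiplier;
- **motif planting**: probability logistic in the site FE,
  P = 1/(1 + exp(−(−4 + 0.5·FE))), i.e. ≈ 5% at FE 2, 50% at FE 8,
  saturating well below 100% over the realized FE range; planted motifs
  are consensus expansions written into the genome centered on the site,
  random strand, each base kept with fidelity 0.95 (else uniform);
- **rendering**: one sample per (cell type, state); summit = true
  position + integer jitter uniform on [−5, +5]; interval = summit ±
  150 bp; q column fixed at 5.0 (the pipeline only thresholds it; no
  q-value model is simulated).

All randomness flows from one integer seed through a single generator in
the order genome → truth → samples, so fixtures are byte-identical under
a seed. What the generator does **not** emulate: read-level noise,
mappability and GC structure, peak-width variation, correlated
replicates, background binding and false-positive peaks. Passing tests
therefore demonstrate the correctness and calibration of the
*computational* pipeline on data satisfying its stated assumptions, not
robustness to every artefact of real ChIP-seq.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; summits are absolute
  positions. Files are plain text or gzip by extension.
- FASTA bases are uppercased; any non-ACGT character becomes N before
  scanning.
- Exact integer kernel sums (no FFT, no normalization) make consensus
  output deterministic including all tie configurations.
- The problem sizes used by the test suite and acceptance script (200
  planted sites on 1 Mb; 2,000 peaks for motif statistics; 10,000 sites
  for sharing-histogram calibration) are chosen so every statistical
  check has comfortable power while the whole suite runs in seconds.
- Known limitations: no BAM/score-track generation (tracks are consumed,
  not produced); no liftover between genome builds; the score scale of
  the bundled DR3 PWM is internally consistent but not calibrated to any
  external scanner's background model.
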