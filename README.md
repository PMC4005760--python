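# vdrmeta

Meta-analysis of transcription-factor ChIP-seq peak sets across many
samples, built around the binding profile of the vitamin D receptor
(VDR). Given per-sample peak calls in narrowPeak format (e.g. from MACS2)
for several cell types in ligand-stimulated and unstimulated states, the
package:

- finds **consensus summit locations** across all samples by triangular-kernel
  summit density and builds non-overlapping consensus peaks of at most 200 bp;
- computes **pairwise overlap statistics** with the
  more-than-50%-of-the-narrower-peak rule, stimulated/unstimulated
  partitions, and cell-type-specificity category counts;
- screens the **DR3-type motif** (RGGTCANNGRGTTCA, the VDR-RXR direct
  repeat spaced by 3 bp) with log-odds PWM scanning ±100 bp around peak
  summits, including threshold sweeps, summit-centered motif density
  profiles, the DR3-percentage curve over fold-enrichment-ranked peak
  windows, and signed motif-to-SNP distances;
- generates **seeded synthetic studies** (genome, planted binding sites,
  jittered per-sample peaks, planted motifs) with the statistical
  structure the analysis assumes, so every stage can be validated against
  known ground truth.

It is aimed at computational biologists comparing point-source ChIP-seq
peak sets across conditions or cell types.

## Method sketch

All summits from all samples are pooled per chromosome and smoothed with
a triangular kernel of half-width *b* = 20 bp:

    d(x) = Σᵢ max(0, 1 − |x − sᵢ| / b)

Local maxima of *d* within a 100 bp span become consensus summits
(accurate to ±10 bp given the bandwidth); each is elongated 100 bp per
side and overlaps between adjacent consensus peaks are truncated at their
midpoint, giving non-overlapping peaks < 200 bp. A sample is *present* at
a consensus peak when one of its original summits falls inside it;
otherwise metrics can be read from fold-enrichment/q-value score tracks
(FE = (treat + 1)/(control + 1)). Motif scanning scores every placement
of the PWM on both strands with the cumulative natural-log odds
Σⱼ ln(pⱼ(baseⱼ)/0.25); the representative DR3 motif uses its native
threshold 9.184643.

## Worked example

```bash
python examples/consensus_summits.py
```

prints (abridged):

```
consensus peaks        : 200
max peak width         : 200 bp (bound: 200)
max summit deviation   : 5 bp from a planted site (method accuracy: 10)

Cell-type specificity of consensus peaks:
  present in 1 cell type(s): 142
  present in 2 cell type(s): 53
  ...
```

A 6-cell-type study with 200 planted sites is simulated (seed 42), the
consensus stage run over its 12 samples, and every planted site resolves
to exactly one ≤200 bp consensus peak whose summit sits within 5 bp of the
truth; the cell-type sharing histogram equals the planted one. The other
scripts in `examples/` walk through overlap statistics, DR3 threshold
sweeps and FE-ranked DR3 curves, and motif-to-SNP distances. A thin CLI
(`vdrmeta simulate|consensus|sweep|overlap|categories|scan|sweep-threshold|profile|fe-curve|snp-distance`)
wraps the same entry points for shell use.

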