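"""Generate a synthetic multi-cell-type ChIP-seq study and inspect it.

Plants 200 true binding sites on a 1 Mb random chromosome, activates each
in a random subset of 6 cell types, and renders 12 samples (6 cell types
x stimulated/unstimulated) of narrowPeak-style calls with jittered
summits. Everything derives from one seed.
"""

from vdrmeta import SimulationConfig, simulate_study

result = simulate_study(SimulationConfig(seed=42))

print(f"true sites planted : {len(result.truth.sites)}")
print(f"samples rendered   : {len(result.samples)}")
print(f"sites with a DR3 motif written into the genome: "
      f"{int(result.truth.sites['motif'].sum())}")
print("peaks per sample:")
for s in result.samples:
    print(f"  {s.sample_id:<14} {len(s.peaks):>4}")
print("\nSharing across cell types (sites active in k cell types):")
for k, n in result.truth.category_histogram(6).items():
    print(f"  k={k}: {n}")
print("\nMost sites are specific to one cell type, mirroring the strong "
      "cell-type specificity seen in real VDR ChIP-seq compendia.")
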