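"""DR3 motif screening: threshold sweep and FE-ranked DR3 percentage.

The DR3 element (RGGTCANNGRGTTCA, the VDR-RXR direct repeat spaced by 3)
is scanned +/-100 bp around each peak summit on both strands with a
log-odds PWM. The native threshold of the representative motif is
9.184643; sweeps go down to 4. Peaks are then ranked by fold enrichment
and the DR3 percentage computed per 100-peak window.
"""

from vdrmeta import dr3_pwm, dr3_threshold_sweep, fe_window_curve, simulate_motif_peak_set

pwm = dr3_pwm()
genome, peaks, truth = simulate_motif_peak_set(2000, seed=0)

print(f"peaks: {len(peaks)}; motifs planted: {int(truth['planted'].sum())} "
      "(probability logistic in FE)\n")

sweep = dr3_threshold_sweep(peaks, genome, pwm, [4.0, 6.0, 9.184643, 12.0, 16.0])
print("threshold sweep (% of peaks with a DR3 hit):")
print(sweep.to_string(index=False))

curve = fe_window_curve(peaks, genome, pwm)
print("\nDR3 percentage per 100-peak FE-ranked window (first/last rows):")
print(curve.head(3).to_string(index=False))
print("...")
print(curve.tail(3).to_string(index=False))
print("\nThe percentage falls as the threshold rises, and high-FE windows "
      "carry far more DR3 elements than low-FE windows - the sigmoidal "
      "FE/motif relationship the screen is designed to expose.")
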