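"""Distance-decay curve and interaction-decay-exponent (IDE) fit.

The IDE is the slope of log10(contact frequency) vs log10(genomic distance);
values around -0.85 to -0.91 are typical of plant genomes. Here a known
exponent is planted and recovered.
"""

from hicks import contact, core, decay, synth

cs = core.ChromSizes([("chr1", 20_000_000)])
spec = synth.SyntheticSpec(cs, 40_000, decay_exponent=-0.85, cis_depth=500_000, seed=1)
records, _ = synth.simulate_hic(spec)

matrix = contact.bin_pairs(records, spec.bins())
balanced = contact.ice_balance(contact.mask_low_coverage(matrix), max_iter=2000, tol=1e-10)

curve = decay.decay_curve(balanced)
fit = decay.fit_ide(curve, bin_size=40_000)
print(f"decay curve: {len(curve.distances)} separations, "
      f"{curve.distances[0] / 1000:.0f} kb to {curve.distances[-1] / 1e6:.1f} Mb")
print(f"fitted IDE = {fit.exponent:.4f} +/- {fit.stderr:.4f} "
      f"over {fit.n_points} points in [{fit.fit_range[0] / 1000:.0f} kb, "
      f"{fit.fit_range[1] / 1e6:.0f} Mb]")
print(f"planted exponent was -0.85; absolute error {abs(fit.exponent + 0.85):.4f}")
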