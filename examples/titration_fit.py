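"""Dose-response analysis of a ratiometric titration.

Simulates three replicate titrations of a cGMP sensor (26 %FRET span, EC50
277 nM, Hill slope 1.5, 1 %FRET noise) plus a low-affinity cAMP series
(EC50 121 uM), converts intensities to %FRET against each replicate's
zero-ligand baseline, fits the Boltzmann sigmoid per replicate, and reports
EC50, Hill slope, R^2 and the cGMP/cAMP selectivity fold.
"""

from fretforge.titration import fit_replicates, selectivity, simulate_titration

cgmp = simulate_titration(
    bottom=0.0, top=26.0, ec50_m=277e-9, hill_slope=1.5,
    noise_sd=1.0, n_replicates=3, seed=1, nucleotide="cGMP",
)
camp = simulate_titration(
    bottom=0.0, top=26.0, ec50_m=121e-6, hill_slope=1.5,
    noise_sd=1.0, n_replicates=3, seed=2, nucleotide="cAMP",
)

fits_g, agg_g = fit_replicates(cgmp)
fits_a, agg_a = fit_replicates(camp)

print("cGMP (3 replicates):")
print(f"  EC50  = {agg_g['ec50_mean'] * 1e9:.0f} nM (sd {agg_g['ec50_sd'] * 1e9:.0f})")
print(f"  Hill  = {agg_g['hill_slope_mean']:.2f} (sd {agg_g['hill_slope_sd']:.2f})")
print(f"  span  = {agg_g['span_mean']:.1f} %FRET   min R^2 = {agg_g['r_squared_min']:.3f}")

print("cAMP (3 replicates):")
print(f"  EC50  = {agg_a['ec50_mean'] * 1e6:.0f} uM (sd {agg_a['ec50_sd'] * 1e6:.1f})")

fold = agg_a["ec50_mean"] / agg_g["ec50_mean"]
print(f"\nselectivity for cGMP over cAMP: {fold:.0f}-fold (>400 marks a selective sensor)")
print(f"first-replicate fold from individual fits: {selectivity(fits_g[0], fits_a[0]):.0f}")
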