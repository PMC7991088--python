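"""Bound-vs-free delta-FRET on a synthetic two-state campaign.

Generates a small ensemble of bound and ligand-free replicas with the
tethered-fluorophore generator (bound basins 5.5-7.5 nm, free shifted +2 nm,
forbidden 3-4 nm band), runs the running-average / ensemble-mean analysis,
and compares the recovered delta-E with the generator's exact stationary-law
expectation.
"""

import numpy as np

from fretforge import (
    GeneratorConfig,
    conformer_breakdown,
    d_histogram,
    delta_fret,
    make_two_state_ensemble,
)

length_us = 0.5  # scaled-down replicas; defaults emulate 10 us production runs
ens = make_two_state_ensemble(
    GeneratorConfig(state="bound", length_us=length_us),
    GeneratorConfig(state="free", length_us=length_us),
    n_bound=8,
    n_free=8,
    base_seed=2024,
)

bound, free = list(ens.bound_records), list(ens.free_records)
burn_in_ms = 0.2 * 8 * length_us * 1e-3  # 20% of each state's cumulative time
delta, sd = delta_fret(bound, free, burn_in_ms=burn_in_ms, window_ns=20.0)

print(f"estimated delta-FRET = {100 * delta:.1f}%  (running-average sd {100 * sd:.1f}%)")
print(f"stationary-law truth = {100 * ens.expected_delta_e:.1f}%")
print("(bound minus free mean efficiency, in absolute efficiency points x100)")

h = d_histogram(bound)
print(f"\nprobability mass in forbidden 3-4 nm band: {h.band_mass:.1f} (zero by topology)")

print("\nper-conformer sampling breakdown (bound state):")
cols = ["conformer_id", "mean_e", "mean_d_nm", "d_range_nm", "kappa2_coverage", "trapped"]
print(conformer_breakdown(bound)[cols].to_string(index=False, float_format="%.3f"))
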