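# fretforge

Design and validation computations for genetically encoded two-fluorophore
FRET biosensors — the kind built by threading a fluorescent protein into a
poorly conserved loop of a ligand-binding domain (e.g. a cyclic-nucleotide-
binding domain) and fusing a second one to its C-terminus, so that ligand
binding changes the inter-fluorophore geometry and hence the FRET signal.

It is aimed at computational structural biologists who screen sensor designs
against conformational ensembles (from coarse-grained MD or any source that
can export multi-model PDB), and at experimentalists who validate the
resulting constructs by ratiometric titration.

## What it computes

**Per-frame FRET observables.** For each conformation: the distance `D`
between the geometric centers of the two fluorescent modules, the
orientation factor

```
kappa = cos(theta_T) - 3 cos(theta_D) cos(theta_A),   kappa^2 in [0, 4]
```

from transition dipoles approximated by the center → Ser147-C-alpha axis of
each module, and the Foerster efficiency

```
E = 1 / (1 + (2 / (3 kappa^2)) (D / R0)^6)
```

with `R0` the Foerster radius at the isotropic average `kappa^2 = 2/3`
(default 4.9 nm for CFP/YFP, configurable).

**Ensemble analysis.** Running averages with sliding windows (default
100 ns) over concatenated replicas, convergence burn-in, bound-minus-free
`delta_FRET = <E>_bound − <E>_free`, per-conformer sampling breakdowns
(trapped-replica flags, kappa² coverage), RMSD traces, and
forbidden-distance-band occupancy reports.

**Synthetic ensembles with exact ground truth.** A seeded generator of
tethered two-fluorophore trajectories — metastable distance basins with
~2 µs dwells, a structurally forbidden 3–4 nm band carrying exactly zero
mass, nanosecond orientational decorrelation sweeping kappa² over [0, 4] —
whose stationary law has a closed form, so every pipeline estimate can be
checked against an integral oracle.

**Titration analysis.** %FRET from 527/485 nm intensity ratios against the
zero-ligand baseline, per-replicate Boltzmann dose-response fits
(`y = bottom + (top−bottom)/(1+exp((logEC50 − x)/s))`, Hill slope
`1/(s ln 10)`), EC50/Hill/R² with standard errors, and fold selectivity
between nucleotides.

**Insertion-site scanning.** Alignment column gap fractions and entropies
(residue and CLUSTAL-class), with a ranked sliding-window score for regions
permissive to fluorophore insertion.

## Worked example

```python
from fretforge import (GeneratorConfig, delta_fret, make_two_state_ensemble)

ens = make_two_state_ensemble(
    GeneratorConfig(state="bound", length_us=0.5),
    GeneratorConfig(state="free", length_us=0.5),
    n_bound=8, n_free=8, base_seed=2024,
)
delta, sd = delta_fret(list(ens.bound_records), list(ens.free_records),
                       burn_in_ms=8e-4, window_ns=20.0)
print(f"estimated delta-FRET = {100*delta:.1f}%  (sd {100*sd:.1f}%)")
print(f"stationary-law truth = {100*ens.expected_delta_e:.1f}%")
```

prints (see `examples/delta_fret_pipeline.py` for the full script):

```
estimated delta-FRET = 12.5%  (running-average sd 8.5%)
stationary-law truth = 11.8%
```

i.e. the analysis recovers the generator's exact bound-minus-free efficiency
difference (11.8 efficiency points) within its own sampling uncertainty, on
a campaign of 8+8 half-microsecond replicas.

On the titration side (`examples/titration_fit.py`), simulated triplicates
with 1 %FRET noise refit to their generating dose-response:

```
cGMP (3 replicates):
  EC50  = 307 nM (sd 35)
  Hill  = 1.43 (sd 0.29)
  span  = 26.2 %FRET   min R^2 = 0.995
cAMP (3 replicates):
  EC50  = 130 uM (sd 9.4)

selectivity for cGMP over cAMP: 423-fold (>400 marks a selective sensor)
```

The other examples cover per-frame geometry (`fret_geometry.py`),
multi-model PDB round trips with selection specs (`pdb_ensemble_io.py`) and
alignment scanning (`insertion_site_scan.py`). A thin CLI exposes the same
pipelines: `fretforge analyze|synth|titrate|msa-scan --help`.

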