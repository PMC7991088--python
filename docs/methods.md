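# Methods

## The problem

Genetically encoded FRET biosensors report a ligand (here a cyclic
nucleotide binding to a cyclic-nucleotide-binding domain, CNBD) through a
conformational change that moves two fluorescent-protein modules relative to
each other. Designing such a sensor in silico requires (i) predicting the
ligand-induced change in FRET efficiency from conformational ensembles of
the bound and free sensor, and (ii) validating the construct in vitro by
ratiometric titration. `fretforge` implements the computations on both
sides, plus a synthetic ensemble generator that makes the whole pipeline
testable against exact expectations without running molecular dynamics.

## FRET observables per frame (`geometry`)

For each conformation the observables are the inter-chromophore distance
`D` (distance between the geometric centers of the two fluorescent
modules), the orientation factor

    kappa = cos(theta_T) - 3 cos(theta_D) cos(theta_A),   kappa^2 in [0, 4],

and the Foerster efficiency

    E = 1 / (1 + (2 / (3 kappa^2)) (D / R0)^6,

where `R0` is the Foerster radius quoted at the isotropic average
`<kappa^2> = 2/3`, so `E(R0, 2/3) = 1/2` by definition. Each module's
transition dipole is approximated by the axis from its geometric center to
the C-alpha of its Ser147, a direction consistent with quantum-chemical
dipole calculations across fluorescent-protein variants. The geometric
center is the unweighted mean of the selected backbone-bead coordinates —
appropriate to the coarse observable; mass weighting would change nothing
material.

Numerics: `E` is evaluated as `q/(q+2)` with `q = 3 kappa^2 (R0/D)^6`, which
is exact at `kappa^2 = 0` and avoids overflow at small `D`. Dipole and
separation directions must be unit vectors within 1e-6; zero-length dipoles
and coincident centers raise a dedicated degenerate-geometry error. All
internal lengths are nm (PDB Angstrom converted on read), times ns.

`R0` default is 4.9 nm, a literature consensus for the CFP/YFP pair. It is a
required, documented configuration value (`ForsterParams`), not a constant:
predicted efficiencies, unlike the geometric observables, depend on it
directly, and the appropriate value varies with the fluorophore variants.

**Dynamic averaging.** `E` is computed per frame from the instantaneous
`(D, kappa^2)` and then averaged. This matters: because orientational motion
is fast and `E` is nonlinear in `kappa^2`, the per-frame average
`<E(kappa^2)>` differs from `E(<kappa^2>)` — at `D = R0` the former is
~0.38 against the latter's exactly 0.5. The per-frame convention is the
physically meaningful one when orientational sampling is fast compared to
the fluorescence timescale but the full dynamic-averaging limit is intended;
the static alternative can always be obtained by applying `fret_efficiency`
to averaged inputs.

## Ensemble averaging and convergence (`ensemble`)

Bound and free states are each sampled by many independent replicas
("conformers") started from distinct conformations. The analysis
concatenates their efficiency series, computes a sliding running average
(window default 100 ns = 1000 frames at the 100 ps recording interval), and
declares the contrast

    delta_FRET = <E>_bound - <E>_free

in absolute efficiency points (x100 for percent). The final means are
frame-weighted means over all frames, hence independent of concatenation
order to machine precision — a property the tests assert at 1e-12.

The quoted dispersion is the standard deviation of the running-average trace
after a burn-in cumulative time (default 0.04 ms, the convergence point of a
0.24 ms campaign; configurable for scaled-down runs). Per-frame standard
deviations are reported separately and clearly labelled — they measure the
width of the instantaneous E distribution, not the uncertainty of the mean.

By default windows do not straddle junctions between concatenated replicas
(each conformer is windowed separately and the windowed traces
concatenated), because a cross-junction window mixes unrelated
conformations; the final means are unaffected. A `concatenated` mode windows
the raw concatenation for users who want the literal convention.

Per-conformer breakdowns report mean E, mean and range of D, and the
fraction of 20 equal kappa^2 bins of [0, 4] visited. A conformer is flagged
"trapped" when its D range is below 25% of the pooled D range — an
operational cutoff for replicas stuck in a narrow conformational region; the
threshold is configurable and intentionally coarse.

RMSD traces use Kabsch least-squares superposition (via
`scipy.spatial.transform.Rotation.align_vectors`) by default; raw
(unsuperposed) RMSD is exposed as well, since either convention appears in
trajectory analyses.

## I/O conventions (`trajio`)

The ensemble interchange format is multi-model PDB plus a JSON manifest
(file, conformer id, state, frame spacing, production length) — every MD
package can export the former, and the manifest carries campaign bookkeeping
(16 bound + 8 free replicas of 10 us = 0.24 ms cumulative in the standard
design). Selections name the two modules as chain + residue ranges and each
tip (Ser147 C-alpha equivalent) as a single-residue selector with an
accepted bead-name list ("CA", "GC", ...), because coarse-grained models
name backbone beads differently and residue numbering follows the file
as-is. Missing frame-spacing metadata defaults to 100 ps with a warning.
Observable tables round-trip through commented-header CSV.

## The synthetic generator (`synthetic`)

The generator emulates the statistical structure of coarse-grained
simulation campaigns of a two-fluorophore sensor:

| feature | model | default |
|---|---|---|
| D basins | CTMC among Gaussian basins | bound: 5.5/6.5/7.5 nm; free: +2 nm |
| basin width | Gaussian s.d. | 0.3 nm |
| dwell times | switch rate 0.5 per us | ~2 us metastable dwells |
| forbidden band | zero-mass truncation | 3-4 nm |
| within-basin motion | Gaussian-copula AR(1) | 10 ns decorrelation |
| orientations | normalized 3-D OU per dipole | 1 ns decorrelation |
| recording | uniform frames | 100 ps |
| replica length | production time | 10 us |

Design choices, and why:

* **Markov-switching Gaussians rather than Brownian dynamics of linked
  domains.** The analysis consumes only `(D, kappa^2, E)`; this model gives
  the slow-basin/fast-orientation timescale separation the pipeline must
  handle, with a closed-form stationary law.
* **Gaussian-copula truncation rather than reflecting the path off the
  forbidden band.** A stationary standard AR(1) process is pushed through
  the inverse CDF of the band-truncated basin Gaussian, so the stationary
  marginal of D is *exactly* the truncated Gaussian (reflection would
  distort it), while retaining the intended temporal correlation. The
  forbidden band therefore has exactly zero occupancy, not merely small.
* **Normalized 3-D Ornstein-Uhlenbeck orientations rather than a stepwise
  random walk on the sphere.** The stationary law is exactly isotropic
  (`<kappa^2> = 2/3` holds exactly, and kappa^2 sweeps [0, 4] on the ns
  scale), decorrelation is exponential with the configured time constant,
  and the whole path is generated by vectorized linear filtering — millions
  of frames in well under a second.
* **Explicit geometry per frame.** The generator places actual centers and
  dipole tips (tips 2 nm from centers) and runs them through the same
  geometric code path as parsed PDB ensembles, so the generator exercises
  the pipeline end to end rather than short-circuiting to observables.

`expected_observables` is the integral oracle: mean D from the closed-form
truncated-Gaussian mean, mean E by Gauss-Legendre quadrature over the
mixture (via the inverse CDF) crossed with an orientational quadrature in
`(cos theta_D, cos theta_A, relative azimuth)`. Tests verify the oracle
independently against brute-force rejection-sampling Monte-Carlo of the same
stationary law.

What the generator does *not* emulate: force-field physics, linker
chemistry, solvent/ions, correlations between D and orientation, and
non-Markovian kinetics. Passing the recovery tests therefore demonstrates
that the *analysis* is correct and well-calibrated on data with the reported
statistical structure — not that any particular MD campaign was reproduced.

## Titration analysis (`titration`)

%FRET is computed from raw intensities per replicate against that
replicate's own zero-ligand baseline (exactly one C0 row required; the C0
point maps to exactly 0; negative responses are allowed). The dose-response
model on the log10-concentration axis is the Boltzmann sigmoid

    y = bottom + (top - bottom) / (1 + exp((logEC50 - x) / s)),

identical to the four-parameter Hill equation with Hill slope
`n_H = 1 / (s ln 10)`; both parameterizations are reported, and a test
checks the fitted Hill slope against an independent direct Hill-equation
fit. C0 is excluded from the fit axis (log 0 undefined). Fits are unweighted
least squares (no weighting convention is assumed), initialized from the y
extrema and the interpolated mid-response crossing with slope factor 0.5,
with up to 10 jittered restarts; standard errors come from the fit
covariance, EC50 and Hill-slope errors by the delta method. A
`fix_bottom` option provides the baseline-anchored variant. Replicates are
fitted independently and summarized as mean ± s.d. across replicates, the
convention for independent titration experiments. Degenerate (zero-variance)
responses and under-determined designs (< 5 distinct concentrations for the
free fit) raise errors rather than returning garbage.

The titration simulator emits raw intensity pairs (485 nm held at a
reference value, 527 nm solved from the target %FRET) so that `percent_fret`
inverts it exactly in the noiseless case; noise is Gaussian on %FRET
(default s.d. 1), three replicates by default, concentrations at half-log
spacing over 1e-10..1e-2 M. Defaults encode a high-affinity cGMP response
(span 26 %FRET, EC50 277 nM, Hill 1.5); the low-affinity cAMP counterpart
(EC50 121 uM) reuses the same span and slope, which are not separately
published for that curve.

## Insertion-site scanning (`msa`)

Per-column statistics over a protein alignment: gap fraction, Shannon
entropy (bits) over non-gap residues, and class entropy over the CLUSTAL
physicochemical partition (hydrophobic AILMFWV, positive KR, negative DE,
polar NQST, cysteine C, glycine G, proline P, aromatic HY). Gaps are treated
as insertions (captured by the gap fraction), not as a 21st symbol, so an
all-gap column has entropy 0. Class entropy is a coarsening and can never
exceed residue entropy.

The permissiveness score over a sliding window is
`mean gap fraction + mean entropy / log2(20)`; windows whose mean gap
fraction and mean entropy both exceed thresholds (defaults 0.25 and 0.5
bits) are returned ranked, ties broken by the lower start index. This score
is a pragmatic operationalization of "poorly conserved, with frequent
insertions" — no canonical definition exists — and the defaults were chosen
so that a region inserted in half the family members with variable sequence
where present qualifies, while conserved gapless regions never do.

## Problem sizes in tests and the acceptance script

The test-suite property runs use scaled-down campaigns — typically 8 bound +
8 free replicas at 0.2-1.5 us — which keep the full slow/fast timescale
structure (dwell times are *not* rescaled) while completing in seconds to
tens of seconds. Statistical assertions are made against the integral oracle
at two combined sampling standard errors estimated from the between-replica
scatter, so they are honest about the Monte-Carlo error of the scaled runs.
Generator defaults always retain the full-campaign conditions. The
acceptance script's titration targets are desk-scale by nature (three
replicate fits each) and run in seconds.

## Known limitations

* Predicted efficiencies inherit the uncertainty of `R0`; only geometric
  observables are R0-free.
* No spectral-overlap, refractive-index or quantum-yield corrections, and no
  photon-level simulation: `E` is the idealized Foerster form.
* The ensemble dispersion is a running-average s.d., not a block-bootstrap
  confidence interval; replicas are assumed independent.
* The generator's D and orientation processes are independent by
  construction; real sensors may correlate them.
* The insertion-permissiveness score is heuristic and should be read as a
  ranking, not a probability.
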