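# Methods

## Model overview

`inhibmap` treats the postsynaptic pyramidal cell as a purely passive
branched cable. The working hypothesis it operationalises is that the
*electrical weight* of an inhibitory contact is proportional to its EM
junction area — both in the charge it transfers and in its release
probability — while its *functional reach* is set by where on the cell it
lands: soma, dendritic shaft, or spine head behind a high-resistance neck.

## Calibration from EM junction areas

For a connection whose maximal IPSC charge `Q_max` is known (all proximal
terminals releasing), the unit charge is `q_unit = Q_max / Σ A_i`, summed
over the terminals within the 33 µm proximal threshold — the path distance
inside which dendritic terminals contribute measurably to the somatically
recorded IPSC. Per-synapse quantities follow:

- charge `q_i = A_i · q_unit` (fC),
- peak conductance `g_i = g_max · A_i / A_ref` with `g_max = 1.92` nS (the
  unitary maximal IPSC conductance) and `A_ref` the summed somatic junction
  area (0.950 µm² for the reference pair),
- release probability `p_i = 3.271·0.68·A_i + 0.018`, clipped to [0, 1].
  The base slope comes from excitatory terminal-size data; the 0.68 factor
  rescales it so the line reproduces the overall release probability
  measured as mean/maximal charge (193.1/326.1 ≈ 0.59). Probabilities are
  rounded to the nearest 0.05 when quoting per-synapse values (the published
  convention); simulations can use the unrounded line via
  `rounded_probabilities=False`. Rounding is half-away-from-zero, so the
  0.534 value of the largest somatic junction reports as 0.55.

For the second reference pair the per-synapse junction areas printed in the
source table sum to 3.013 µm² while the printed subtotal (and the unit-IPSC
table) uses 3.011 µm²; the bundled fixtures carry the per-synapse values
verbatim, and the unit-charge check for that pair goes through the printed
totals. The difference (0.07%) is rounding in the source, not in this
package.

## Passive cable model

Parameters (pre-adjustment): leak 1×10⁻⁴ S/cm², capacitance 1 µF/cm²,
axial resistivity 100 Ω·cm (385 Ω·cm inside spines), leak reversal −65 mV.
The membrane time constant is 10 ms.

**Elliptical-to-circular equivalence.** EM cross sections are elliptical;
a cylinder-based simulator preserves the cross-sectional area (hence axial
resistance) with `d = 2√(A/π)` and recovers the lost membrane perimeter by
scaling the leak and capacitance densities by `L/(π·d) ≥ 1`, where `L` is
the measured circumference. Sections without direct EM measurements get
`A` and `L` from the distal-length regressions `S(R)` and `L(R)`; `R` is
interpreted per-section as the summed dendritic length distal to the
section's origin (the definition is configurable — the source does not pin
it down).

**Spines.** Explicit neck (0.5 µm × 0.07 µm cylinder at 385 Ω·cm, i.e.
500 MΩ axial resistance) plus a head cylinder with length = diameter chosen
to hold the stated 0.043 µm³ volume (the source gives volume only). Spine
synapses attach at the neck's insertion point for path-distance purposes.

**Discretisation.** Sections split into compartments no longer than
min(5 µm, λ/40); junctions use half-compartment axial resistances in
series. The soma is a single cylinder of equal surface area (its
compartment shape is not specified in the source).

**Integration.** θ-method with θ = 0.5 (Crank–Nicolson) by default and
backward Euler as an option, dt = 0.025 ms. Crank–Nicolson is the default
because the solver's own convergence requirement — peak voltages move by
less than 0.1% under dt-halving — needs second-order accuracy at this step
size; both schemes are unconditionally stable on the stiff spine-neck
geometry. Synaptic conductances enter the system matrix implicitly: the
constant part is LU-factorised once and the few time-varying diagonal
entries are folded in per step with a Woodbury rank-k update. Voltage clamp
is ideal by default (the clamped compartment is pinned and the amplifier
current reported as the total current leaving it); an optional series
resistance models a non-ideal electrode, since the recording configuration
behind the published somatic currents is not fully specified.

Internal units are mV, ms, nS, pA, pF, µm — a mutually consistent set
(pA/mV = nS, pF·mV/ms = pA, nS·ms·mV = fC), so no conversion constants
appear in the integrator. Exported IPSC traces follow the recording
convention (inward negative).

## Kinetic synapse

Two-state (closed/open) transmitter-pulse scheme: during the 2.3 ms pulse
the open fraction relaxes toward 1 with τ_rise = 0.45 ms (peak
1−e^(−2.3/0.45) ≈ 0.994); afterwards it decays with τ_decay = 14.17 ms.
Conductance scale 1.92 nS, GABA_A reversal −77.5 mV, giving the measured
12.5 mV driving force at a −65 mV hold. The driving force is computed from
the local instantaneous membrane potential (conductance synapse), which is
what produces sublinear summation of co-located contacts and the shunting
component of the spine veto.

Two waveform shapes are provided. The default `"pulse"` is the literal
hard-pulse scheme above. Integrating it at fixed 12.5 mV driving force
yields ≈383 fC — about 17% above the measured 326 fC maximal charge,
because recorded decays are double-exponential and a single 14.17 ms decay
from the pulse peak over-integrates the tail. The `"smooth"` shape
`(1−e^(−t/τ_rise))·e^(−t/τ_decay)` transfers ≈330 fC (within 1%) and is
used where charge consistency matters; the choice is a parameter
everywhere. The functional form behind the published "duration time" is not
printed, so the hard pulse is kept as the default convention.

For the excitation/inhibition experiments an AMPA-like synapse uses the
same scheme with reversal 0 mV, 0.2 nS, and conventional fast kinetics
(0.3 ms pulse, 0.2/2.0 ms rise/decay) — only the conductance is constrained
by the source data; the time constants are package defaults and
configurable.

## Trace analysis conventions

- Onset: parabola fitted to the 10–90% rising phase, extrapolated back to
  baseline (the rising window is a package choice; the source states the
  parabola method only).
- Amplitude: extremum of the running 1.5 ms window average minus the mean
  baseline over the 4 ms preceding the presynaptic spike. For the default
  kinetic waveform this reads ≈2% below the instantaneous peak; tests
  assert against the windowed value computed independently.
- Noise level: sd over the baseline window (the source's estimator is not
  stated); events smaller than twice the noise level are failures, with the
  boundary counting as success.
- Charge: baseline-subtracted integral from onset over 5·τ_decay
  (configurable). pA·ms = fC on the native grid.
- Run-down screening ("stable periods"): optional linear-trend test on
  amplitude vs trial index (p < 0.05 trims the significant tail); the
  source does not define its criterion.

## Stochastic release and comparison

Per trial, each site releases independently with probability `p_i`,
contributing `q_i`; the trial charge is a weighted Bernoulli sum with mean
`Σ p_i q_i` and variance `Σ p_i(1−p_i) q_i²`. With the four somatic
reference sites the noiseless distribution has 16 atoms, enumerated exactly
as a test oracle. Failures (no site releasing) stay in the distribution —
the reference connection's success rate is 1.0, so this choice is inert
there. Optional Gaussian charge noise emulates the recording-noise floor.
Simulated and recorded charge distributions are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p). The recorded per-trial
charge list behind the published comparison is not available, so the
package's test is distributional: a synthetic "recorded" ensemble (n = 60,
the recorded trial count) drawn from the same generative model is not
rejected (p > 0.05) in ≥90% of seed replicates.

## Morphometry conventions

Class comparisons use two-sided Mann–Whitney U (exact for small untied
samples, normal approximation otherwise); regressions are ordinary least
squares with Pearson r, offered pooled or per cell type (the pooling used
in the source is not fully specified). Somatic synapses carry no size
covariate and enter class comparisons only. Bouton proportions are
mean-of-per-pair percentages with the population (ddof = 0) spread — that
convention, not the sample sd, reproduces the published 28.4 ± 7.6%.
Sholl profiles count exact sphere crossings per cylinder axis segment by
quadratic root counting, with half-open parameter intervals so shared
vertices count once.

## Synthetic data

The generator emulates the study conditions: a soma (15 µm equal-length
cylinder) with 6 basal dendrites of uniform 100–250 µm total length, each a
trunk plus two daughters, diameters and density scales derived from
`S(R)`/`L(R)`; optional apical trunk and spines at a configurable density.
Synapse tables draw per-class junction areas uniformly within the ranges
spanned by the reference tables (soma 0.05–0.45, shaft 0.04–0.18, spine
0.04–0.10 µm²; uniform because the source gives no distributional form),
with somatic contacts at distance 0 and dendritic ones placed on the
generated tree. Trial ensembles come from the Bernoulli-sum model plus
Gaussian charge noise; the ~5 pA recording-noise floor maps to charge noise
through a 2 ms effective integration window (5 pA × 2 ms = 10 fC) — a crude
but explicit conversion. All generators are deterministic under their seed.

What the synthetic data does *not* emulate: dendritic tortuosity and
per-segment diameter noise, correlated or multi-vesicular release,
receptor saturation, series-resistance artefacts, and the full anatomy of
the reconstructed cell. Passing tests therefore establish the internal
consistency of the calibration→simulation chain and its qualitative
site-dependence (soma > shaft > spine somatic impact, local spine veto,
sublinear co-located summation), not the absolute voltages of the deposited
reconstruction: published per-site peak deflections (0.78/0.12/0.07 mV and
kin) depend on that specific morphology and an unstated clamp convention,
and are represented here by the ordering and attenuation properties plus
the desk-computable ratio 1.33 mV / 0.12 mV ≈ 11 equivalent excitatory
inputs.

## Numerical and statistical choices

- Fits (double-exponential decay, kinetic parameters) use bounded
  least squares with a small deterministic multi-start; event detection is
  robust (median first pass, pre-event baseline second pass) and decay
  alignment uses a lightly smoothed peak so noise on the peak sample does
  not bias the fast component. At 5% noise the double-exponential
  time constants are recovered without bias (ensemble mean within a few
  percent) while single-trace estimates scatter by ~10% — the tests assert
  both the ensemble recovery and a majority per-seed band.
- Probability rounding to the 0.05 grid is half-away-from-zero.
- Degenerate inputs raise: zero junction/reference areas, empty ensembles,
  non-uniform time grids, circumference below the equal-area circle,
  forward references or cycles in SWC files, divergent integration.
- Monte Carlo sizes: 10 000 trials for headline means (sampling SE
  ≈ 0.8 fC), 10⁵ for moment-convergence tests; propagation tests run on
  ~100–150-compartment synthetic cells at dt = 0.025 ms, chosen so the full
  suite completes in well under a minute of simulation time.

## Known limitations

- Passive membrane only: no voltage-gated conductances, no GABA_B, no NMDA
  veto component, no short-term plasticity, no temperature dependence.
- SWC cannot encode mid-section branch points, so spine attachment
  positions quantise to polyline vertices on write/read round trips
  (section geometry itself is preserved to the 10⁻⁶ µm print precision).
- The release-probability line is taken as given (slope·area + intercept
  interpretation, validated against all four published per-synapse values);
  the package does not refit it, as the underlying terminal-size dataset is
  external.
- The Kolmogorov–Smirnov p-value is asymptotic; with 16-atom discrete
  distributions it is conservative but adequate at the sample sizes used.
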