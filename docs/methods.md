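# Methods

`memprobe` packages three desk-scale analyses of small-molecule/lipid-bilayer
interactions — fluorescence membrane-probe reduction, ITC partition fitting,
and bilayer structural observables — together with seeded generators that
produce inputs with the statistical structure each analysis expects. This
note records the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic data can and cannot certify.

## Fluorometry

**Laurdan generalized polarization.** GP = (I440 − I490)/(I440 + I490) on
blank-subtracted emission intensities. GP is a bounded ratio in [−1, 1] for
non-negative intensities; it is high in the gel phase (emission peaked near
440 nm) and low in the fluid phase (red-shifted emission near 490 nm).
Replicate shots (instruments typically record ≥12 per temperature) are
averaged **at the intensity level** before the ratio is formed. The
alternative — averaging per-shot GP values — is exposed as
`method="per_shot"`; the ratio-of-means default matches how blanks are
handled (also at the intensity level) and is less biased when the
denominator is noisy. The reported uncertainty is the standard error of GP
propagated to first order from the replicate scatter of the mean
intensities.

**Melting-point estimation.** GP-vs-T melting curves are fitted with a
descending four-parameter logistic,
GP(T) = GP_fluid + (GP_gel − GP_fluid)/(1 + exp((T − Tm)/w)),
the standard sigmoid for probe-reported lipid main transitions. The
midpoint Tm, width w, and the two plateaus are reported together with the
RMS residual and a model-free fallback (temperature of the steepest
finite-difference descent), which also seeds the fit. A curve whose GP
range does not exceed a threshold (default 0.2) is rejected with a
`NoTransitionError` rather than extrapolated: a flat curve carries no
transition information and a silent fit would report noise. Fits are done
with `scipy.optimize.curve_fit` under box bounds (w > 0, plateaus in
[−1, 1], Tm within one grid-span of the data).

**DPH anisotropy.** r = (I_VV − G·I_VH)/(I_VV + 2·G·I_VH) with
G = I_HV/I_HH. The G-factor is computed per sample quadruplet — all four
polarizer orientations are measured on each sample — so no global
instrument constant is assumed. Negative blank-subtracted intensities pass
through `blank_subtract` (over-subtraction is real data and worth seeing)
but are rejected with a named error wherever they make a ratio undefined;
clipping would hide instrument problems.

Both GP and r are invariant under uniform intensity rescaling and GP is
antisymmetric under swapping the two channels; both facts are enforced as
property tests.

## ITC partition analysis

Lipid vesicles are titrated into a dilute solute solution. The cumulative
heat after *i* injections follows the partition isotherm

    Σ δh_k = ΔH · V_cell · C_A0(i) · K·C_L0(i) / (1 + K·C_L0(i)),

with K the partition constant (mM⁻¹), ΔH the molar water→bilayer transfer
enthalpy, and C_A0/C_L0 the total solute/lipid concentrations in the cell
after *i* injections. The fit target is the cumulative heat, as the
isotherm is written; per-injection residuals are diagnostics only.

**Concentration bookkeeping.** The reference schedule is a 2 µL priming
injection followed by 28 × 10 µL at 600 s spacing into a 1.4565 mL cell:
282 µL injected, ~19 % of the cell volume, too much to ignore. Three
models are provided: `naive` (no correction), `dilution` (volume-additive;
both species live in V_cell + ΣV — the default), and `overfill` (perfusion
cell: each injection expels mixed content, factor (1 − v/2V)/(1 + v/2V)
per injection). The choice is a visible parameter, never hidden. A warning
is logged when the injected volume exceeds 25 % of the cell.

**Priming-injection treatment.** The priming injection's heat is excluded
from fitting but its lipid counts toward the concentrations, so the model
for the observed cumulative heat is referenced to the post-priming state:
Q_model(i) − Q_model(first). Without this offset a high-affinity titration
(where the priming injection already transfers a few percent of the
plateau) would bias the fit.

**Fitting.** Least squares via `lmfit` with K parameterized as log K
(positivity without an active bound), unit weights by default (per-point
weights optional), and an optional constant per-injection offset absorbing
heats of dilution. Starting values come from the data: ΔH₀ from the last
cumulative heat read as the saturation plateau ΔH·V_cell·C_A0, and K₀ as
the reciprocal of the lipid concentration nearest half-plateau. Standard
errors come from the fit covariance (K_se = K · σ_logK). A fit with no
usable covariance, a failed solver, or an all-zero heat signal (ΔH → 0
leaves K unidentifiable) is returned with `converged=False` and the solver
message — flagged, never silent.

**Thermodynamics.** ΔG = −RT·ln(f·K[M⁻¹]) with f = 55.5 M (mole-fraction
standard state, the molarity of water), then TΔS = ΔH − ΔG. The 55.5 M
factor is a parameter; it is the convention under which the three
published (K, ΔG) pairs this package is tested against are mutually
consistent at 26 °C, and the acceptance tests verify exactly that.
Temperatures are °C at the interfaces and converted to K only here. Heats
are µcal internally (µJ selectable, 1 cal = 4.184 J); molar quantities are
kJ/mol.

**Peak integration.** Raw power traces are integrated per injection window
(window = injection interval), with a per-window baseline that is either a
line through the leading/trailing 10 % of the window or the window median,
then a trapezoidal integral of power − baseline. A window with fewer than
4 samples is a `MissingDataError`.

## Bilayer observables

All observables assume a planar bilayer in the xy plane with the normal
along z (the standard semi-isotropic setup); no director fitting is done.
Molecules are unwrapped across periodic boundaries (minimum image relative
to each molecule's first atom) before any center of mass is taken, making
every observable invariant under re-wrapping.

**z-profiles.** For each named group (lipid P, glycerol, solute polar
part, terminal methyl, whole solute) the mass-weighted group COM is formed
per leaflet and per frame; the observable is the time- and leaflet-averaged
|z_group − z_bilayerCOM| with SE over frames. Leaflets are assigned per
molecule by the sign of the group COM's z relative to the bilayer COM;
molecules exactly at the midplane are excluded from that frame with a
logged count. Absolute-value folding (rather than signed per-leaflet
values) is used throughout.

**Order parameters.** United-atom chains carry no hydrogens, so for each
internal carbon C_i the two C–H unit vectors are reconstructed from the
backbone: with a, b the unit vectors to C_{i−1} and C_{i+1},
c = −(a+b)/|a+b| and n = (a×b)/|a×b|, the C–H directions are
c/√3 ± n·√(2/3) (tetrahedral H–C–H wedge). Then
S_CD(i) = ⟨(3cos²θ − 1)/2⟩ over both hydrogens, molecules, leaflets and
retained frames, θ being the angle to z. The profile is reported as
−S_CD — positive ≈ 0.5 for all-trans chains along the normal, 0 for
isotropic chains — with |S_CD| selectable. Terminal carbons have no local
frame and are omitted; indices are 1-based from the carbonyl carbon. The
per-carbon two-hydrogen average satisfies |S_CD| ≤ 0.5 for any geometry,
and the all-trans-along-z case gives exactly 0.5; both are tested, the
latter against the analytic construction, the magic-angle and isotropic
zeros by Monte-Carlo over 10⁴ orientations (tolerance 0.01, fixed seeds).

**Thickness.** Twice the time-averaged |z_P − z_COM| (the inter-leaflet
P–P distance). A frame with P atoms on only one side of the COM is an
error, not a number.

**Equilibration.** `equilibration_split(traj, f)` keeps frames with
t ≥ t_first + f·(t_last − t_first). The default fraction used by the
pipeline is 0.6, matching the common practice of discarding the leading
150 ns of a 250 ns run.

## Synthetic data

Every generator is the exact inverse of its analysis stage in the
noiseless limit, and this is asserted in tests: GP curves reduce back to
the logistic truth, polarized quadruplets invert to (r_true, G_true) to
machine precision, thermograms fit back to (K, ΔH) to <0.1 %, and
geometric fixtures reproduce their construction. Noise models: Gaussian
on the GP scale per shot for melting curves, additive Gaussian on
intensities for polarized quads, multiplicative Gaussian on per-injection
heats for ITC (typical instrument behavior); all default to zero and are
configurable.

The bilayer generator is a **geometric stand-in, not a physical
simulator**. Lipids are bead chains (P bead, glycerol bead, rigid
all-trans acyl chain of n carbons; C–C 0.153 nm) placed on two mirrored
leaflets; chain axes are drawn uniformly in solid angle within a cone of
half-angle (1 − s)·90° about the normal, so the order level s interpolates
between perfectly ordered (s = 1, −S_CD = 0.5) and isotropic (s = 0,
−S_CD = 0), monotonically (mean tilt-P₂ over the cone is
cosθ_max(1 + cosθ_max)/2). Head-plane separation defaults to tracking the
mean chain extent, so more ordered bilayers are thicker; it can be pinned
explicitly. Solute chains hang from a polar bead placed at a set depth.
Positional noise is rigid-body per molecule. Reference composition: 140
lipids, 5:1 lipid:solute molar ratio (28 solute molecules), 28 monovalent
counterions when the solute carries unit charge.

What passing tests show — and do not. The generators exercise the
*definitions* of the observables (bounded ratios, isotherm shape,
tetrahedral reconstruction, leaflet folding), which is everything the
analysis stages can see. They do not emulate photophysics (lifetime,
wobbling-in-cone), scattering or inner-filter effects, heats of dilution
beyond a constant offset, gauche defects or area/volume fluctuations of
real bilayers. Agreement on synthetic data therefore certifies the
algebra and the estimators, not instrument- or force-field-specific
behavior. Figure-level quantities with no published numbers (absolute GP
and r values, thermogram amplitudes, per-carbon profiles from long
trajectories) are checked as qualitative properties: monotone peak decay
at high K, ordered bilayers thicker than disordered ones.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to keep estimator
variance far below the asserted tolerances: Monte-Carlo order-parameter
zeros at 10⁴ chain orientations (SE ≈ 0.003 against a 0.01 band), noisy
ITC recovery over 200 seeded replicates of the full 29-injection
schedule, melting curves on the 31–55 °C grid with 12 replicates per
temperature, and bilayers of 20–140 lipids over 1–100 frames depending on
what the test measures. Random draws all flow through
`numpy.random.default_rng` with explicit seeds; identical specs are
bit-reproducible.

Known limitations: single-site partition model only (no aggregation or
permeation terms); fixed z normal; GRO blocks are parsed one frame per
block with times recovered from the title line; no binary trajectory
formats; the Tm fit assumes a single transition — multi-transition curves
will fit the dominant one or fail the range check.
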