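# Methods

`foldbind` implements the quantitative analysis with which hierarchical
folding-upon-binding of a disordered protein region (the Rac1-binding
region of POSH) is resolved: N-site Bloch-McConnell modelling and
constrained global fitting of ^15N CEST profiles, single-exponential R1rho
fits, and the ITC-based thermodynamic dissection (one-set-of-sites fits,
heat-capacity change, iso-entropic temperature, Spolar-Record entropy
decomposition and folded-residue count), together with a synthetic-data
generator that makes every stage verifiable by parameter recovery.

## Exchange model

Binding follows a strictly linear chain

    F + partner  <-(kon[partner], koff)->  A  <-(kAB, kBA)->  B  <-(kBC, kCB)->  C

with F the free disordered state, A a CRIB-anchored intermediate, B the
intermediate with the first recognition element (MRE1) folded, and C the
fully folded complex.  The 3-site variant omits A.  Linear topology is an
assumption, not an inference: the hierarchy is established independently
(anchor-motif mutation abolishes all binding), so no branched or cyclic
topologies are represented.

Populations are never free parameters.  The total bound fraction follows
from mass balance of the two total concentrations and the calorimetric Kd
(smaller root of C^2 - C(P0+R0+Kd) + P0 R0 = 0); the step equilibrium
constants K_AB = kAB/kBA and K_BC = kBC/kCB partition it among A, B, C.
The association step is closed by detailed balance: the pseudo-first-order
rate is k_app = koff * pA/pF, and kon is reported post hoc as
k_app / [partner_free].  Consequently the overall dissociation constant
implied by the rates is Kd = (koff/kon) / (1 + K_AB (1 + K_BC)); with the
study's rates this reproduces the measured 24 uM — an internal-consistency
check the package asserts.

Concentrations are in uM throughout the kinetics layer; conversion to molar
happens in exactly two places (`apparent_kd`, `derive_kon`) to prevent
silent 1e6 errors.

## CEST forward model

Magnetization is propagated in a basis of three Cartesian components per
state (3N dimensions).  Per state: transverse relaxation R2 on x/y,
longitudinal R1 on z, precession at Omega_i = 2 pi ((shift_i - carrier) *
nu_N - offset) and nutation at w1 = 2 pi B1.  Exchange couples identical
components across states with first-order rates whose columns conserve
summed magnetization exactly.  Design choices:

* In-phase ^15N magnetization only; scalar coupling, proton CSA/NOE and
  detection-period effects are not modelled.  The fitted quantities
  (shift differences, populations, rates) are insensitive to them at this
  fidelity, and the experimental setup suppresses amide-exchange artefacts.
* R1 drives Mz to zero (no recovery term); the reference plane is a
  zero-length saturation period, making the far-off-resonance baseline of a
  non-exchanging spin exactly exp(-R1 Tsat) — an assertable closed form.
* One R1 per residue shared by all states: minor-state R1 is not
  identifiable at ~6 % populations.
* A single nominal B1 (no inhomogeneity distribution).  The on-resonance
  window, where inhomogeneity dominates, is excluded from fits anyway
  (points within +-B1 Hz of the major dip); this is a stated limitation.
* CW saturation is a matrix exponential over Tsat, evaluated by batched
  diagonalization across offsets with a scipy `expm` fallback for
  ill-conditioned members; agreement with an adaptive ODE oracle is held
  to 1e-8.
* DANTE (D-CEST) saturation is a train of ideal delta pulses of flip angle
  2 pi B1/window separated by free precession of 1/window, raised to
  round(Tsat * window) periods.  Ideal pulses are an approximation (pulse
  widths are not specified in the source data conventions); the model
  reproduces the defining D-CEST properties — equivalence to CW inside the
  principal band at these B1 values, and periodicity of the profile in the
  offset with period equal to the window.
* ppm→Hz conversion happens at a single point using the configured ^15N
  Larmor frequency (96.3 MHz at a 950 MHz ^1H field by default).

## Staged CEST inference

The analysis mirrors the experimental procedure:

1. **Noise.**  Per-profile sigma from the second-difference filter,
   sigma^2 = sum(y_{i-1} - 2 y_i + y_{i+1})^2 / (6 (N-2)), which removes
   the locally smooth signal and works without long baselines.  Where the
   dips themselves curve within a few grid steps this estimator is biased
   high; for *picking thresholds* (not for fit weights) a median-based
   robust variant is therefore used.
2. **Dip picking and de-aliasing.**  Local minima deeper than a threshold
   (default 4 sigma) below the baseline, outside the major-state window.
   D-CEST dips are defined only modulo the window, so each pick is
   expanded into its alias set and a candidate is retained when at least
   two profiles (different windows, or the unaliased CW profile) agree
   within 0.3 ppm.
3. **Residue-specific 3-site fits** across all B1 fields with the bound
   population fixed and R2B = R2C tied.  Because picking leaves discrete
   ambiguities (B/C assignment, overlapping dips, alias sign), each
   residue is fit from every candidate (dw_FB, dw_FC) configuration and
   the best chi-square wins.  The B/C assignment is then challenged by an
   explicit swap test (re-fit with exchanged assignments; accept the
   original if the swap raises chi-square or reverts).
4. **Global 3-site fit** (koff, kBC, kCB global; shifts and relaxation
   rates residue-specific), seeded from the medians of the informative
   residue fits.
5. **Global 4-site fit** (koff, kex_AB, kex_BC, K_AB, K_BC global), warm
   started from the 3-site solution; dw_FA is free for residues in the
   anchored (CRIB) set — initialised at dw_FB, with R2A = R2B — and fixed
   at 0 elsewhere (with R2A = R2F).  Fixing rather than merely
   initialising dw_FA outside the anchored set keeps the boundary search
   identifiable and reflects the generator truth.
6. **Refinement.**  A global fit of ~80 parameters can park single
   residues in locally optimal but wrong assignments without the global
   parameters being able to pull them out.  The pipeline therefore
   alternates three escape moves with warm-started global refits:
   (a) *collective hypotheses* — a residue with one dominant dip is
   explained equally well with the intermediate B unshifted (dw_FB ~ 0)
   or co-shifted with the complex (dw_FB = dw_FC), but the global rates
   differ between the interpretations, so all degenerate residues are
   moved across jointly and the jump is kept only if the global refit
   improves; (b) *per-residue re-assignment* under frozen global rates for
   residues whose per-point misfit stands out, seeded from the picking
   candidates and from a coarse 2-D chi-square scan over (dw_FB, dw_FC),
   which is immune to aliasing mistakes; (c) rate-jittered restarts
   (+-50 % multi-start on the log-scale rate parameters) when neither
   discrete move fires.  Intermediate fits run at a relaxed tolerance;
   the final fit is polished at relative chi-square change < 1e-8.
7. **Model comparison** by F-test on the nested least-squares fits at
   alpha = 0.05 (the canonical choice for nested chi-square models).
8. **Bootstrap.**  Within-profile resampling with replacement (profile
   sizes preserved, implemented as multinomial residual weights), each
   replicate refit from the point estimate at a relaxed tolerance (the
   interval widths are set by the parameter spread across replicates, not
   by the last digits of each replicate optimum); 68 % percentile
   intervals are reported for the global parameters; non-converging
   replicates are dropped and counted (not imputed).
9. **Anchored-set boundary search**: all (lower, upper) residue-limit
   pairs in a candidate range are enumerated, each defining the anchored
   set for a full global 4-site fit; the minimal-residual subset wins, and
   an F-test against an anchor-free fit guards against spurious
   improvement.
10. **Grid search** over (kex_AB, kex_BC) re-optimises all remaining
    parameters per node, yielding a profile-likelihood surface whose
    minimum must agree with the free fit.

The optimiser is scipy's bounded trust-region least-squares ("trf", an
LM-class method): plain Levenberg-Marquardt supports neither the finite
bounds every parameter carries (shift differences +-20 ppm; rates 1e-3 to
1e4 s^-1; equilibrium constants 1e-3 to 1e3) nor the Jacobian sparsity
that makes the global fit tractable — residue-specific parameters touch
only their own residue's rows, so grouped finite differences cost ~12
residual evaluations per Jacobian instead of ~80.  Rates and equilibrium
constants are optimised in log10 space for conditioning.

## R1rho decays

Single exponentials I(t) = I0 exp(-R t), fit on the linear intensity scale
with uniform weights (a log transform would distort the noise at late
delays).  Negative intensities are retained — flooring them biases R
upward at low signal-to-noise.  The duplicated 70 ms delay enters as two
independent observations.  Uncertainties come from Monte Carlo resampling
of the per-plane noise (default 500 draws; the exact number used in the
original workflow is not stated).

## ITC thermodynamics

The one-set-of-sites model updates cell concentrations per injection with
the standard perfusion correction (both species diluted by 1 - dV/V0,
titrant accumulating), solves the single-site quadratic, and predicts
heat_i = dH V0 ([PM]_i - [PM]_{i-1}(1 - dV/V0)) + q_offset.  Concatenated
syringe refills into the same cell share one continuously evolving cell
composition.  All injections are used by default; a first-injection
exclusion flag exists.  The standard state for dG = RT ln(Kd) is 1 M —
required for the printed Kd↔dG magnitudes to be mutually consistent.

Per-temperature fits give (Kd, dH); dS is computed per temperature as
(dH - dG)/T and then regressed — mirroring how all three quantities are
plotted — rather than via van't Hoff analysis of Kd alone.  dCp is the
slope of dH vs T; T_S the zero crossing of dS vs T; Kd at an unmeasured
temperature comes from linear extrapolation of dG.  Note that with a
large negative dCp the exact dG(T) is convex (d2G/dT2 = -dCp/T), so the
linear protocol carries a systematic bias of order dCp·var(T)/(2T)
whenever the measured temperatures sit mostly on one side of the target:
on synthetic data anchored at Kd(25 C) = 24 uM the extrapolation from
5/10/15/35 C titrations returns ~30 uM.  The protocol is reproduced as
specified; the bias is a property of the method, quantified by the tests.  The entropy dissection
uses

    dS(T)   = dS_conf + dS_desolv(T) + dS_rt,
    dS_conf = -1.66 dCp ln(T_S/386 K) + 110 J/mol/K,
    dS_desolv(T) = 1.66 dCp ln(T/386 K),   dS_rt = -110 J/mol/K,

so the total vanishes identically at T = T_S (asserted to 1e-9).  The
folded-residue count divides dS_conf by -24 J/mol/K per residue and
rounds.  Explicit units in every field plus a round-trip test guard the
kJ-vs-J factor of 1000.

## Synthetic data

The generator's defaults are the study conditions: the 4-site rates
(kon = 7.3e5 M^-1 s^-1, koff = 56, kAB = 72, kBA = 64, kBC = 89,
kCB = 94 s^-1), 500 uM disordered region with 100 uM partner at
Kd = 24 uM, Tsat = 0.4 s, B1 = 5.2/10.3/20.5 Hz D-CEST with 240/448/800 Hz
windows sampled at 8/16/32 Hz plus 68.6 Hz CW sampled at 100 Hz over
103–134 ppm, and homoscedastic Gaussian intensity noise of 0.004
(fraction of the reference intensity), matching the single-sigma noise
model of the analysis.  Residue classes follow the folding hierarchy:
anchored residues (|dw_FA| in 1–4 ppm, dw_FB = dw_FA, dw_FC nearby),
MRE1-helix residues (dw_FA = 0, |dw_FB| in 1–5 ppm, dw_FC nearby), MRE2
residues (dw_FA = 0, dw_FB = f dw_FC with f in 0.2–0.8, |dw_FC| in 1–6
ppm — the intermediate resonance lies between free and complexed), and
linker residues (no shift changes).  The default roster has 12 residues:
the five anchored residues 325/327/330/331/333 plus three MRE1, three
MRE2 and one linker residue.  Major-state shifts are drawn within +-3.5
ppm of the carrier; relaxation rates from ranges typical of a disordered
~60-residue construct at 25 C (R1 1–2 s^-1, R2F 3–8 s^-1, minor-state R2
15–40 s^-1).

ITC truth propagates dH(T) = dH_ref + dCp (T - T_ref) and
dS(T) = dS_ref + dCp ln(T/T_ref) from the anchor (Kd = 24 uM and dH = 0 at
25 C, dCp = -2.8 kJ/mol/K), and builds 3x13 injections of 3 uL of 1000 uM
titrant into 125 uM cell material in a 200 uL cell (a PEAQ-type volume;
the actual cell volume is not printed) at 5/10/15/35 C.  Decay truth uses
the printed 11-delay schedule.

What the generator does *not* emulate — spectral overlap, peak picking
from raw spectra, B1 inhomogeneity, solvent-exchange artefacts,
heteroscedastic noise, baseline drifts in ITC thermograms — bounds what
passing tests show: recovery results demonstrate correctness of the
estimators under the stated noise model, not robustness to every
experimental pathology.

## Problem sizes and calibration scale

Single-dataset recovery checks run at the full default scale (12 residues,
4 B1 fields, ~1300 masked-in points, sigma = 0.004).  Repeated-fit
calibrations — F-test power and type-I rate over seed sweeps, bootstrap
coverage — run on a reduced scenario (3 residues spanning the three
shifted classes, 2 B1 fields, coarser offset grids) chosen so the full
calibration remains a single-CPU computation; the discriminating signal
(a distinct dw_FA class and partially shifted intermediates) is preserved.
Bootstrap defaults to 300 replicates in the pipeline and 100 in the
coverage check.

## Degenerate inputs and numerical edges

Zero partner concentration gives bound fraction 0; zero saturation time
returns the initial magnetization exactly; empty offset lists, non-finite
intensities, non-monotone offsets, invalid concentrations and
non-positive relaxation rates raise `InvalidInputError`.  Non-converged
fits are flagged, never silently accepted; singular covariances mark
uncertainties unavailable.  Equality of tied parameters (R2B = R2C, R2A
per anchoring rule) is enforced structurally (the tied parameter is not a
free variable), so ties hold to machine precision at every iteration, as
does the population-sum constraint.

## Known limitations

* The DANTE element is an ideal delta pulse; finite pulse widths would
  slightly attenuate far sidebands.
* The noise filter's curvature bias is documented rather than corrected;
  fit weights inherit it (conservatively down-weighting sharply curved
  profiles).
* The residue-refinement scan resolves assignment ambiguities only within
  +-7.2 ppm of the major state.
* kon is derived, not fitted: the data constrain koff and the populations;
  kon follows from mass balance at the constrained Kd.
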