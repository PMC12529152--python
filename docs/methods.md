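# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Cultivation model

State: viable cell density VCD (10⁶ cells/mL), glucose and lactate
(mmol/L), product P (mmol/L). The cultivation has two phases with separate
parameter sets; product forms only in the collect phase.

Rate laws:

- µ = µ_max · Glc/(K_Glc+Glc) · K_I,Lac/(K_I,Lac+Lac). The functional form
  combines one substrate-limitation factor and one lactate-inhibition
  factor — exactly the two constants the parameter set provides. Both
  factors are multiplicative Monod terms; alternatives (additive
  inhibition) would need constants the calibration does not define.
- µ_d = k_D·Lac/(K_D,Lac+Lac) + k_lag,max·K_M,lag/(K_M,lag+t). The second
  term models the transient stress after the media exchange; its clock t
  is the time since the exchange and restarts there. K_M,lag is a time
  constant in hours (it is added to t; a rate unit would be dimensionally
  inconsistent, so the printed h⁻¹ in the source table is read as an
  erratum).
- dVCD/dt = (µ−µ_d)·VCD; no lysis return of nutrients.
- dGlc/dt = −((µ−µ_d)/Y_X,Glc + m_Glc + q_product/Y_P,Glc)·VCD. The
  product-coupled term exists only in the collect phase.
- dLac/dt = Y_Lac,Glc·(−dGlc/dt). The lactate yield is *apparent*: it lumps
  growth-coupled conversion with other substrates metabolised to lactate,
  which is why calibrated values above the stoichiometric limit of 2 are
  retained as-is.
- dP/dt = 10³·q_product·VCD. The factor 10³ converts the per-mL cell basis
  (q in mmol/10⁶ cells/h × VCD in 10⁶ cells/mL = mmol/mL/h) to the
  per-litre product concentration. The glucose-side terms use the VCD
  value directly without this factor — the apparent-yield convention under
  which the parameter set was calibrated; the two conventions are
  internally consistent because the yields absorb the volume basis.
- particles/mL = P[mmol/L]·6.02214×10²⁰/10³ (Avogadro bridge, exact
  inverse provided).

Events are applied atomically between integration segments: the feed
bolus adds glucose (optionally diluting all species); the media exchange
sets glucose to the fresh-medium value, zeroes lactate and product, keeps
VCD (cells are carrier-attached) and restarts the lag clock. Ammonia
death is omitted: the calibration carries no ammonia constants.

Integration: LSODA, rtol 1e-8, atol 1e-10; states are clipped at zero
(consumption stops at substrate exhaustion). Fitting: trust-region
reflective least squares with bounds; residuals are weighted per variable
by the reciprocal of its observed range, since VCD, metabolites and
product have incommensurate units. Default initial conditions (VCD₀ 0.02
×10⁶/mL, Glc₀ 25 mM, fresh-medium Glc 25 mM) are plausible seeding and
medium values for microcarrier hMSC culture; no claim is made that they
reproduce any specific experimental run, which is why the trajectory
tests assert structure (phase shapes, closed forms, event semantics)
rather than absolute numbers.

## UF/DF

Flux decline: dJ/dv = −K_n (J−J_R) J^(2−n) with the specific permeate
volume v (L/m²) as independent variable; J_R is the crossflow residual
flux (classical dead-end laws are the J_R = 0 special case). Per-volume
rather than per-time was chosen because the mechanism changepoint is
located on the v axis. Darcy's law J = TMP/(η·R) provides the
pressure-side bridge; η defaults to water at 20 °C (1.002 mPa·s) since no
buffer viscosity is specified.

Identification (integral method): integrating the law once gives
J(v) − J(0) = a·∫J^(3−n)dv′ + b·∫J^(2−n)dv′ with a = −K_n, b = K_n·J_R.
The cumulative integrals are formed from the data by the trapezoidal
rule, making the problem linear least squares per candidate n — no
numerical differentiation of noisy flux data. The candidate with the
highest R² wins; an exhaustive split-point scan (minimum segment 5
samples) detects at most one mechanism changepoint, accepted only if the
length-weighted R² beats the single-mechanism fit by more than 1e-4.
A centered moving median (window 5) precedes the regression; it is the
identity on monotone noiseless data and its edges are left untouched so
the anchor J(0) is never distorted. The initial decay scale is
1/(K_n·J₀^(2−n)·…) ≈ 0.06 L/m² for the identified constants — much
shorter than the run — so sampling grids must refine near v = 0; the
synthetic generator's default grid is geometric from 10⁻⁴ L/m².

UFDF train: stages are analytic. A concentration stage with factor VCF
retains the solute mass fraction VCF^(−S) (concentration × VCF^(1−S));
constant-volume diafiltration with DV volumes leaves e^(−S·DV); particles
are fully retained (S = 0), which the configuration enforces. Sieving
coefficients are stage-constant; concentration polarization is out of
scope. Process time comes from integrating dt = dv/J(v) along the
simulated flux curve.

## Chromatography

A lumped-rate column model with component-dependent transport. Per
component: ε_tot,i is the accessible (lumped mobile) liquid fraction —
it sets the migration velocity v_i = u_sup/ε_tot,i and hence the
size-exclusion elution order and the dead time ε_tot·V/F; ε_s,i is the
pore void fraction of the stationary side; film exchange
k_eff·(6/d_P)·(1−ε_s)/ε_s·(c−c_p) couples the phases, and binding follows
∂q/∂t = k_kin(q_eq−q) toward the competitive Langmuir equilibrium
q_eq,i = q_max,i K_i c_p,i / (1 + Σ_j K_j c_p,j) with
K_i(c_mod) = K_i0·c_mod^(−β_i) (power law; exponential form available).
The film driving force is the concentration difference c − c_p: a
spatial-derivative difference has no mass-transfer meaning, so the
gradient form is provided only as a comparison flag
(`film_driving_force="gradient"`), and the concentration form is the
default — it is the only one that closes the mass balance.

Discretization: finite volumes, first-order upwind convection, central
dispersion, Danckwerts-type closed ends (no dispersive flux through the
column faces), fixed-step RK4 at a stability-limited step covering
convection CFL, dispersion, film exchange and the local binding rate
including the isotherm (Henry) slope k_kin·(1 + (1−ε_s)/ε_s·q_max·K).
The limit is re-evaluated in ten sub-intervals per step so it relaxes as
a salt gradient collapses the Henry coefficient. Configurations whose
Henry coefficients would require >2×10⁶ steps are rejected with a
diagnostic rather than integrated inaccurately. The upwind scheme's
numerical dispersion u·dx/2 is subtracted from the applied D_ax by
default (deferred correction, clipped at zero) so the effective
dispersion matches the nominal coefficient; moment-based recovery of
D_ax to ~0.1% at 300 cells depends on this. Mass conservation holds to
machine precision for all components (the exchange terms are constructed
phase-volume-consistently).

Moments: ε_tot from the first moment (corrected by half the injection
duration) and D_ax by inverting the closed-closed dispersion relation
σ²/t₀² = 2/Pe − 2/Pe²(1−e^(−Pe)) — exact at any Peclet number, unlike
the small-dispersion approximation.

CIP steps force full desorption (q_eq = 0 with a release rate of at
least 5/duration); frit capture is a saturable first-come-first-served
pre-column compartment applied to designated components during the load,
with the captured amount reported (its re-elution during reverse-flow
cleaning is bookkeeping, not hydrodynamics). Units are assay-native
(particles/mL, µg/mL, ng/mL); isotherm capacities share the component's
concentration unit per mL resin.

Isotherm calibration fits fraction-table concentrations (transport
parameters fixed from tracer moments first), normalising residuals per
component by its maximum observed concentration. Identifiability caveat:
K_i0 and β_i are only jointly identifiable when the data span a modifier
range; single-salt experiments constrain only K_i at that salt.

## Ledger and optimization

Recovery chains multiply step recoveries (order-invariant). Cumulative
impurity removals are computed from stream masses (concentration ×
volume): multiplying per-step removal *fractions* is not invariant to
volume changes between steps, so both conventions are reported and
labelled. Threshold comparisons are strict (<10 ng DNA/dose at 10¹⁰
particles per dose; <100 µg/mL protein). Computed purities can differ
from tabulated ones when the table's inputs were rounded; the ledger
always reports the computed value.

Productivity is pooled product per mL packed bed per hour of total cycle
(load through re-equilibration); this is the common convention and the
response function is replaceable. Pooling during scans uses a fixed
window in CV relative to a named method step, so the window scales with
flow like fraction-based pooling. Scans are exhaustive grids — the
deliverable is the response surface itself, and grids are reproducible
and trivially parallel; `constrained_optimum` is exact enumeration with
ties broken toward lower feed volume, then lower flow.

## Synthetic data

Generators wrap the forward simulators and apply measurement noise:
multiplicative lognormal by default (concentration assays are strictly
positive), mean-preserving with σ² = ln(1+CV²). Default CVs — particles
0.10, protein 0.05, DNA 0.05, VCD 0.10, glucose/lactate 0.03, flux
0.02 — are stand-ins of the magnitude seen in triplicate NTA/BCA/
PicoGreen scatter and are configurable per assay; real assay error models
(concentration-dependent variance, detection limits, NTA's instability
for post-elution samples) are not emulated. Zero-CV generation is
bit-identical to the deterministic simulator; every generator takes an
explicit seed and carries its generating truth in a bundle for recovery
assertions.

What passing tests show: internal consistency (generate → identify/fit
round trips), correct arithmetic on the printed process tables, and the
directional behaviour of the response surfaces. What they do not show:
agreement with any particular experimental chromatogram or flux curve —
the isotherm values and raw fraction data behind those are unpublished,
so the column-model checks are property-based (conservation, moments,
elution order, grid convergence) rather than numeric reproductions.

## Problem sizes

Defaults were chosen so the full suite runs on a single CPU in a few
minutes: 100 axial cells for physics checks (300 for moment recovery,
25–30 for calibration loops and scans), 400-point flux grids, 120 h
trajectories at daily sampling, 20-seed noise studies. All are arguments,
not constants.

## Known limitations

- The cultivation model is macroscopic: no microcarrier attachment,
  shear, oxygen transfer or differentiation state.
- The blocking-law family assumes one dominant mechanism per regime and
  at most one changepoint.
- The column model lumps pore diffusion into a film coefficient (no
  radial pore profiles) and treats the modifier as non-retained.
- The explicit time integrator is deliberate (simple, conservative,
  deterministic) but restricts practical Henry coefficients to ~10³;
  stiffer isotherms need an implicit solver.
- The pipeline driver represents the chromatography stages by their
  step factors for speed; the full column models are exercised directly
  by the analysis scripts and tests.
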