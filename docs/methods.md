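# Methods

## The saturation problem

Antibody uptake in solid tumors is a race between delivery and consumption.
Drug extravasates across tumor capillaries at a rate set by the vascular
permeability-surface area per tumor volume (PS/V), diffuses through the
interstitium, binds its cell-surface target, and is destroyed when the
bound complex internalizes.  When consumption wins, high-affinity antibody
is trapped and degraded near vessels (the binding-site barrier) and distal
receptors never see drug; when delivery wins, every receptor in the tumor
is occupied and further dose escalation buys little.  Which side wins is
what separates ADC dosing (toxicity-capped, hovering near the balance
point) from checkpoint-inhibitor dosing (well tolerated, far into
supersaturation).

## Dimensionless groups

For a Krogh cylinder — an annulus of tissue R_cap <= r <= R_Krogh fed by a
central capillary — the vessel surface per tumor volume is

    S/V = 2 R_cap / R_Krogh^2.

Two dimensionless groups summarize the race:

    Bi    = 2 P R_cap / (D eps)                        (Biot number)
    phi^2 = k_e R_Krogh^2 ([Ag]/eps) (1 + 1/Bi) / (D [Ab])   (full form)
    phi^2 = k_e [Ag] / ((PS/V) [Ab])                   (simplified form)

with k_e the internalization rate constant (ln 2 / half-life), [Ag] the
antigen concentration per tumor volume (receptors/cell x cell density /
Avogadro), [Ab] the plasma antibody concentration, D the interstitial
diffusivity, eps the accessible void fraction, and P the capillary
permeability.  The full and simplified forms differ exactly by a factor
(1 + Bi); the placement of the (1 + 1/Bi) term in the numerator is the only
algebra under which the full form reduces to the simplified form in the
small-Bi (permeability-limited) limit, and that reduction is enforced by a
unit test.  For typical antibody parameters Bi ~ 0.014, so the two forms
agree to ~1.4% and phi^2 is reported from the simplified form by default.

phi^2 is the canonical reported quantity (not phi): every regime statement
is made on the squared modulus.  Regime thresholds are 0.1 (supersaturated,
a 10-fold vascularization safety margin) and 1.0 (penetration-limited);
both are package constants.

A documented low-affinity variant scales the consumption term by the
equilibrium bound fraction, phi^2_lowaff = phi^2 * [Ab]/([Ab] + K_d).  It
converges to the high-affinity form as K_d -> 0 and is validated only
against the PDE simulator, not against any published closed form.

## Parameter registry

The registry ships 13 agent configurations (7 ADC rows including both
Enhertu expression strata, 4 PD-1 and 2 PD-L1 antibodies) with
package-insert doses, measured C_max/C_trough, receptor expression and
internalization half-lives, and PS/V = 6e-6 /s throughout.  PD-1 rows share
a 36 h half-life and 5,600 receptors/cell; PD-L1 rows share 35 h and
134,000 receptors/cell.  Dostarlimab is grouped with the PD-1 antibodies on
pharmacological grounds; because published tabulations are ambiguous about
its row, it is excluded from the grouped headline quantities that the
acceptance script reports.  Trodelvy's trough concentration is effectively
zero and is reported as an "unbounded" trough modulus rather than a number.

Values not fixed by the clinical sources are package defaults, chosen once
from the antibody-penetration literature and exposed in configuration:

| parameter | default | units | rationale |
|---|---|---|---|
| cell density | 3e8 | cells/mL | standard packed solid-tumor estimate |
| R_cap | 8 | um | typical tumor capillary radius |
| R_Krogh | 75 | um | typical half intercapillary distance |
| eps | 0.24 | — | antibody-accessible void fraction |
| D | 1e-11 | m^2/s | IgG interstitial diffusivity (~10 um^2/s) |
| P | derived | m/s | back-computed from PS/V = 6e-6 /s and S/V |
| body weight | 70 | kg | flat-dose to per-kg conversion |
| plasma volume | 0.04 | L/kg | dose to C_max estimate |

With these defaults the dose-to-C_max estimator reproduces the tabulated
C_max values within a few percent (e.g. 3.6 mg/kg at MW 148 kDa gives
0.63 uM against the measured 0.639 uM), but measured concentrations are
always preferred when present.  `expressing_cell_fraction` defaults to 1,
i.e. tabulated receptors/cell are treated as tumor averages; the field
exists for targets expressed by a subset of cells.

## Krogh-cylinder simulator

The dimensionless groups are shortcuts derived from distributed-parameter
models, so the package carries the model itself as an internal oracle.
With C free interstitial antibody (per L interstitial fluid) and B bound
antibody (per L tissue):

    eps dC/dt = eps D (1/r) d/dr (r dC/dr) - k_on C (Ag - B) + k_off B
    dB/dt     = k_on C (Ag - B) - k_off B - k_e B

- Robin condition at the vessel wall, -eps D dC/dr = P([Ab]_p(t) - C) at
  r = R_cap; zero flux at r = R_Krogh; zero drug initially.
- Total antigen is held constant by default (synthesis instantly replaces
  internalized receptor), matching the constant-[Ag] assumption of the
  analytic modulus; a `depletable` switch disables replacement for
  exploration and is excluded from validation claims.
- Binding defaults: k_on = 1e5 /(M s), K_d = 1 nM (k_off = k_on K_d).  The
  analytic criterion contains no kinetic constants; the defaults only need
  to sit in the avidity-dominated high-affinity regime.
- Plasma forcing is either a constant concentration or a biexponential
  decay.

Numerics: conservative cell-centred finite volumes on a uniform radial
grid (64 cells by default, minimum 16), with the wall flux expressed
through the series conductance of P and the half-cell diffusive path;
method of lines with SciPy's BDF integrator (rtol 1e-6, atol 1e-9 on
states scaled by the forcing peak and the antigen pool).  Because the
scheme is conservative, the mass-balance invariant — cumulative
trans-capillary influx equals free + bound + cumulative internalized drug
within 1% — is a genuine accuracy check on the integration and is computed
on every run.  Steady state is declared when the state change per
characteristic diffusion time R_Krogh^2/D falls below 1e-5, probed over
geometrically growing integration chunks.

Occupancy metrics interpolate the radial profile linearly between cell
centres: `saturated_fraction` is the antigen-weighted (annular-area)
fraction with occupancy >= 0.9 and `saturation_radius` is the outermost
radius with occupancy >= 0.5.  Interpolation makes both metrics vary
smoothly under grid refinement (observed change ~0.3% on doubling 64 -> 128
for a mid-transition configuration).

The sign of the vessel-wall boundary condition is fixed by physics: influx
raises C at the wall, so the outward gradient is negative there.  The
mass-balance test fails under the opposite sign convention.

## Synthetic cohorts and concordance

The generator emulates the clinical spread of the registry: log-uniform
internalization half-lives over 1.23–108 h, expression over 1,867–3e6
receptors/cell, C_max over 0.095–8.91 uM (the registry envelopes 3.7–36 h,
5,600–1e6 /cell and 0.28–2.97 uM, extended threefold each way, since these
parameters span orders of magnitude), uniform trough/peak ratios in
0.02–0.7, and a 1.5x log-uniform jitter on PS/V and cell density.  An
optional low-affinity mode samples K_d log-uniformly over 0.1–1000 nM and
uses the low-affinity modulus as ground truth.  A single explicit
`numpy.random.Generator` seeded from the spec drives all sampling; cohorts
and reports are byte-identical across runs of the same spec.

Concordance analysis partitions agents by analytic phi^2 at C_max into
< 0.3 (should saturate: steady-state saturated fraction >= 0.9), > 3
(should not: < 0.9), and an excluded boundary band 0.3–3; the acceptance
suite requires >= 95% agreement in each outer band on a 200-agent cohort.
In practice the PDE transition is sharp near phi^2 = 1 (supply can cover
at most a 1/phi^2 fraction of maximal consumption, so mean occupancy is
bounded by 1/phi^2 above the threshold), and observed concordance is 100%.
A matched-parameter experiment confirms the groups are the right summary:
parameter sets sharing phi^2, Bi and K_d/[Ab] collapse onto the same
saturated fraction within 0.05 even mid-transition.

What the synthetic cohort does *not* emulate: time-varying plasma
concentration during the concordance runs (agents are held at constant
C_max, matching the modulus's evaluation-point semantics), vascular
heterogeneity, antigen shedding or modulation, payload release and
bystander spread, immune-cell versus tumor-cell expression compartments,
and healthy-tissue uptake.  Passing concordance therefore shows the
analytic criterion summarizes the Krogh reaction-diffusion model, not that
either captures every feature of clinical data.

## Problem sizes and runtime choices

The registry analysis is closed-form and instantaneous.  Validation runs
use 64 radial cells and 200-agent cohorts, enough to populate all three
phi^2 bands while keeping a full steady-state labelling pass under a
minute; grid-doubling and master-curve experiments use single
configurations at mid-transition where the metrics are most sensitive.

## Limitations

- The modulus treats [Ab] as an externally supplied evaluation point
  (C_max, C_trough); it contains no plasma pharmacokinetics, so "saturated
  at trough" statements inherit the tabulated trough values.
- Receptor counts per cell are treated as tumor averages; for targets on a
  minor cell subset the `expressing_cell_fraction` field must be set
  explicitly.
- The low-affinity variant is a package construction validated only
  against the internal PDE oracle.
- The Krogh geometry assumes a uniformly spaced, uniformly perfused
  vascular lattice; tumors with chaotic vasculature violate this, which is
  precisely why the supersaturation threshold keeps a 10-fold margin.
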