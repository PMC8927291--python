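# tumorsat

Receptor-saturation analysis for tumor-targeted biologics: does a clinical
dose saturate the target throughout the tumor, or does target-mediated
consumption outrun vascular delivery and trap the drug around blood vessels?

`tumorsat` answers this with the antibody **Thiele modulus**, a dimensionless
ratio of the tumor's consumption capacity to its delivery capacity:

```
phi^2 = k_e [Ag] / ((PS/V) [Ab])
```

- `k_e` — internalization rate constant of the bound target (ln 2 / half-life),
- `[Ag]` — available antigen concentration per tumor volume
  (receptors/cell x cells/L / N_A),
- `PS/V` — vascular permeability-surface area per tumor volume (1/s),
- `[Ab]` — plasma antibody concentration (evaluated at C_max and C_trough).

`phi^2 << 1` means the dose supersaturates every receptor in the tumor
(typical of PD-1/PD-L1 checkpoint inhibitors); `phi^2 > 1` means consumption
wins, receptors far from vessels stay unoccupied, and penetration is limited
(the "binding-site barrier", the regime several antibody-drug conjugates
flirt with).  A full high-affinity form keeps the interstitial diffusion
resistance explicit through the Biot number `Bi = 2 P R_cap / (D eps)` and
equals the simplified form times `(1 + Bi)`.

The package provides:

- **`tumorsat.parameters`** — validated domain types (target, exposure,
  Krogh-cylinder physiology) and a built-in registry of 13 agent
  configurations: seven solid-tumor ADC configurations (Trodelvy, Kadcyla,
  Enhertu at IHC 3+ and IHC 2+, Padcev, mirvetuximab soravtansine, Tivdak)
  and six checkpoint inhibitors (nivolumab, pembrolizumab, cemiplimab,
  dostarlimab, atezolizumab, avelumab) with package-insert doses, C_max,
  C_trough, receptor expression and internalization half-lives.
- **`tumorsat.thiele`** — S/V, Biot number, the simplified / full / low-affinity
  Thiele forms, and regime classification (supersaturated < 0.1,
  saturating 0.1–1, penetration-limited > 1).
- **`tumorsat.krogh`** — a distributed-parameter Krogh-cylinder
  reaction-diffusion simulator (extravasation, interstitial diffusion,
  reversible binding, internalization) used as a mechanistic oracle to
  validate the analytic classifier.
- **`tumorsat.cohort`** — a synthetic virtual-agent generator spanning the
  clinical parameter envelope, with analytic-vs-PDE concordance reporting.
- **`tumorsat compute | simulate | cohort`** — a thin CLI over the above.

## Worked example

```bash
tumorsat compute --agent Kadcyla
```

```
name,agent_class,phi2_cmax,phi2_ctrough,biot,regime,provenance
Kadcyla,adc,3.57,136,0.0141,penetration_limited,FDA package insert (ado-trastuzumab emtansine); ...
```

Kadcyla (3.6 mg/kg Q3W against ~10^6 HER2/cell internalizing with a 7 h
half-life) has `phi^2 = 3.57` at C_max: endocytic consumption exceeds
vascular delivery several-fold even at peak plasma concentration, so dosing
is penetration-limited — the highest value among the approved ADCs.  By
trough (`phi^2 = 136`) the tumor consumes antibody two orders of magnitude
faster than it is supplied.  The Biot number 0.014 confirms delivery is
permeability-limited, justifying the simplified formula.

The same calculation in Python:

```python
import tumorsat as ts

agent = ts.registry_by_name(ts.load_registry())["Avelumab"]
res = ts.evaluate_agent(agent)
print(res.phi2_cmax, res.phi2_ctrough, res.regime.value)
# 0.030911003466431957 0.2033350845478563 supersaturated
```

Avelumab supersaturates PD-L1 at peak (`phi^2 = 0.031`) but, as the fastest
clearing checkpoint inhibitor, crosses the 10-fold safety margin
(`phi^2 > 0.1`) at trough — the only approved checkpoint agent to do so.
Running `tumorsat compute --all` classifies every ADC row as saturating or
penetration-limited and every checkpoint row as supersaturated.

The mechanistic simulator cross-checks the analytic shortcut:

```bash
tumorsat simulate examples/krogh_supersaturated.yaml --out-dir sim/
```

```
saturated_fraction: 1.0
saturation_radius_m: 7.5e-05
mass_balance_ok: true
```

A `phi^2 = 0.01` configuration saturates the entire Krogh annulus at steady
state, exactly as the analytic criterion predicts; the penetration-limited
example (`phi^2 = 100`) leaves all but a perivascular rim unoccupied.

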