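# poroendure

Fatigue endurance-limit prediction for porous 3D-printed titanium implant
specimens, directly from their design geometry.

## The problem

Endosseous dental implants must survive bending-compression fatigue testing
(ISO 14801 style: 30° off-axis load, 11 mm lever arm, survival defined as
enduring 5·10⁶ cycles). Porous implants — attractive for osseointegration
and local drug delivery — are weaker than solid ones, and running a full
fatigue campaign for every candidate pore architecture is prohibitively
slow: a single test can last days and each design needs dozens of
specimens. `poroendure` implements a calibrated workflow that replaces most
of that testing with computation, for engineers and researchers developing
porous TPMS-lattice implants:

1. **Geometry.** Specimens are 4.5 mm cylinders whose porous band is built
   from a triply periodic implicit unit cell (skeletal Schwarz Primitive
   `SP`: `cos X + cos Y + cos Z`, or Schwarz W `SW`:
   `cos X cos Y + cos Y cos Z + cos Z cos X`). The level threshold `t`
   (solid ⇔ `f ≥ t`) is resolved by bisection until the voxel-counted void
   fraction of one cell hits the design porosity.
2. **Metrology.** Selective laser melting sinters extra material onto the
   struts, so printed porosity is systematically below design porosity, by
   a unit-cell-specific amount. Porosity is measured by voxel counting in a
   central 3 mm cubic ROI of the band; an affine correction
   `p_printed = s·p_design + i`, fitted per cell type, predicts the deficit
   and yields *adjusted* designs that target the printed porosity.
3. **Monotonic analysis.** Experimental ultimate loads are the maximum
   recorded force. Virtual (finite-element-style) test curves keep
   hardening past real failure, so their ultimate is read with the
   plastic-displacement offset criterion: the force where
   `u_pl = u − F/k` first reaches a threshold `u_ult_pl`, calibrated
   (0.07 mm) by maximizing the Pearson R² against paired experimental
   ultimates. Tensile stress–strain records yield `E` (0–400 MPa window
   slope), the 0.2 %-offset yield stress, UTS and elongation at break.
4. **Fatigue.** All designs collapse onto one normalized S–N power law
   `F_cyclic / F_ult = a · N_f^b`, fitted on failures only (runouts at
   5·10⁶ cycles are right-censored) by log-log least squares with life as
   the random variable. The endurance limit is the extrapolated normalized
   load at 5·10⁶ cycles, `a·(5·10⁶)^b`, with a stratified-bootstrap 95 % CI.
5. **Prediction.** A per-cell-type affine map `F_ult_exp = c·F_ult_FE + d`
   links virtual to experimental ultimates. Chained, the endurance load of
   a new design is predicted from a virtual test alone:
   `F_endurance = a · (c·F_ult_FE + d) · (5·10⁶)^b`.

A `synthetic_data` generator (the `poroendure.synthetic` module) stands in
for the laboratory and the FE solver: morphological-dilation printing
deviation, a bilinear virtual tester with power-law porosity scaling, and
lognormal fatigue scatter with censoring — so the entire workflow runs and
is tested end-to-end with no external data.

## Worked example

`examples/05_full_workflow.py` generates the six-design synthetic study
(50/60/70 % porosity × SP/SW), calibrates on the 60/70 % designs and
predicts the held-out 50 % designs:

```
offset criterion calibrated: u_ult_pl = 0.065 mm
S-N fit: a = 4.18, b = -0.222; endurance at 5e6 cycles = 13.6% of F_ult
  (95% CI [12.9%, 14.3%])
porosity correction SP: printed = 1.02 x design -0.058 (R2 = 1.000)
porosity correction SW: printed = 1.17 x design -0.235 (R2 = 1.000)

design_id strategy  F_ult_pred  F_ult_exp  rel_error  endurance_load_N  in_band
     50SP original         835        824     0.0125               114     True
     50SW original    1.16e+03   1.11e+03     0.0495               158     True
     50SP adjusted         827        824    0.00331               113     True
     50SW adjusted    1.15e+03   1.11e+03     0.0374               157     True
     50SP     scan         827        824    0.00282               113     True
     50SW     scan     1.1e+03   1.11e+03    0.00426               150     True
```

Reading the numbers: the offset threshold lands one grid step from the
generator's 0.07 mm truth; the fitted endurance limit (13.6 % of the
monotonic ultimate, CI [12.9 %, 14.3 %]) sits inside the 10–15 % survival
band; and the three geometry strategies order as expected — predictions
from the as-designed geometry carry the largest ultimate-load error
(it ignores the printing deviation entirely), porosity-adjusted designs do
better, and scan-based geometry tracks the experiments to a fraction of a
percent. Every predicted endurance load falls inside the experimental
survival band (`in_band`).

The other examples each exercise one capability: `01` porous-specimen
voxelization and STL export, `02` the printing deficit and its correction,
`03` the two ultimate-load criteria and tensile properties, `04` censored
S–N fitting and the bootstrap CI.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the workflow's headline quantities from scratch (about 15 s):
the S–N parameters recovered by the censored fit from synthetic campaigns
generated with the calibrated law (medians over 20 seeds); the closed-form
normalized endurance limit at 5·10⁶ cycles in percent; the tensile modulus
and 0.2 %-offset yield returned on the analytic stress–strain fixture; the
re-measured porosity of a bisected 70 % SP unit cell in the 3 mm ROI; and
the fatigue-observation count of the default synthetic study. Results are
written as JSON, one entry per target id.
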