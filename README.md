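# cardiopol

Rotating-polarizer Stokes polarimetry of ventricular myocardium: reduce
angular voltage sweeps to the degree of linear polarization (DOLP), and
discriminate fibrotic from healthy heart tissue by the slope of DOLP against
tissue thickness.

## The problem

Cardiac fibrosis replaces the well-ordered cardiomyocyte architecture of the
myocardium with disorganized collagen. The change in tissue anisotropy shows
up in how the tissue depolarizes transmitted light, which a simple
transmission polarimeter can measure: an unpolarized 850 nm source, a linear
polarizer rotated 0°–180° in 10° steps, the tissue, a fixed analyzer and a
photodiode. For such a train the detected voltage is band-limited to a single
harmonic,

    V(θ) = c0 + c1·cos 2θ + c2·sin 2θ,

so least squares on {1, cos 2θ, sin 2θ} recovers the linear Stokes
parameters (S1, S2, S3) = (2c0, 2c1, 2c2) and

    DOLP = √(S2² + S3²) / S1 = √(c1² + c2²) / c0 ∈ [0, 1].

Because depolarization also grows with optical path length, DOLP confounds
disease with specimen thickness. The package removes the confound with a
slope-based analysis: regress DOLP on thickness per clinical group (healthy
control, rheumatic heart disease RHD, myxomatous valve disease MV), then
classify individual samples against a cut-off line whose slope (mm⁻¹) lies
between the two group slopes. This is for biophotonics researchers and
instrument builders who need the full chain — forward Mueller-calculus
simulation of the instrument, sweep reduction, cohort statistics,
classification — as testable, scriptable pieces.

## Worked example

The per-subject DOLP values of the 17-subject study cohort (7 control, 7
RHD, 3 MV; one left- and one right-ventricle specimen each) are packaged:

```sh
$ cardiopol summarize
Group: control
subject      DOLP LV   DOLP RV
C1             0.135     0.075
C2             0.110     0.078
...
mean±SEM   0.088±0.011 0.060±0.008
```

The control group's mean DOLP is 0.088 ± 0.011 (LV) and 0.060 ± 0.008 (RV):
healthy myocardium depolarizes strongly, so little linear polarization
survives. The diseased groups retain more (e.g. MV RV: 0.121 ± 0.028) —
fibrotic collagen buildup scatters, and hence depolarizes, less.

Per-sample thicknesses were never published, so the classification stage is
demonstrated on a simulated cohort generated at the study's group slopes and
thickness statistics:

```sh
$ cardiopol simulate --out sim --seed 3
$ cardiopol report --samples sim/samples.csv --contrast control-vs-RHD
...
"fits": {
  "control": {"slope_per_mm": -0.0124, "n": 14, ...},
  "RHD":     {"slope_per_mm": -0.1073, "n": 14, ...}},
"cutoff": {"slope_per_mm": -0.0599, "strategy": "max-accuracy", ...},
"metrics": {"sensitivity": 0.714, "specificity": 0.857, "accuracy": 0.786, ...}
```

DOLP falls faster with thickness in the diseased group (−0.107 mm⁻¹ vs
−0.012 mm⁻¹ here); the selected cut-off slope between them labels each
sample by whether its slope relative to the anchor point is steeper than the
cut-off, giving 78.6% accuracy on this 28-sample draw. With the `fixed`
strategy (`--cutoff-strategy fixed --cutoff-slope -0.056`) a published
cut-off can be applied instead.

From Python the same pieces are scikit-learn estimators:

```python
import numpy as np
from cardiopol import SweepReducer, SlopeCutoffClassifier, simulate_cohort

samples = simulate_cohort(seed=3)                      # full measurement chain
X = np.array([[s.thickness_mm, s.dolp] for s in samples if s.group != "MV"])
y = np.array([s.group for s in samples if s.group != "MV"])
clf = SlopeCutoffClassifier(control_class="control").fit(X, y)
clf.cutoff_.slope, clf.score(X, y)                     # (-0.0599, 0.786)
```

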