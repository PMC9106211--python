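# Methods

## Optical model

The instrument is modelled in Mueller calculus as the chain

    source (I₀, 0, 0, 0) → LP(θ) → [retarder(δ, φ)] → depolarizer(d) → LP(0°) → detector,

with the first polarizer stepped over θ = 0°, 10°, …, 180°. Tissue is an
isotropic partial depolarizer diag(1, d, d, d): `d` is the fraction of
polarization the specimen retains, the single bulk parameter the instrument
can see. Optional linear retardance models the intrinsic birefringence of
ordered myocardial fibers; because a retarder only rotates the polarized
part of the Stokes vector (its 3×3 block is orthogonal), it lowers the
*linear* DOLP seen by the analyzer without destroying polarization.

Without birefringence the detected voltage has the closed form
V(θ) = (I₀·g/4)(1 + d·cos 2θ), with g the detector gain in mV per source
unit. This closed form is kept out of the implementation and used as the
independent oracle in the tests.

Stokes parameters follow the 1-based numbering convention common in
instrumentation work: S1 is the total intensity (often written S0
elsewhere). S4 is carried through the algebra but is structurally zero in
every reduction — a rotating *linear* polarizer cannot measure the circular
component.

## Sweep reduction

How the 19 voltage readings become Stokes parameters is a design choice of
this package: ordinary least squares on the basis {1, cos 2θ, sin 2θ}, the
standard rotating-element Fourier reduction. The signal of any linear train
is band-limited to the single 2θ harmonic, so the 19-point grid oversamples
it and the reduction is exact at machine precision on noiseless data
(property-tested). Detector gain cancels in the DOLP ratio, making the
reduction unit-invariant. Both 0° and 180° (the same polarizer state) are
retained with equal weight; the redundancy only tightens the fit.

An equivalent discrete-analyzer path (`stokes_from_analyzer_intensities`,
from the four flux measurements I_H, I_V, I_±45) is provided; the two agree
on noiseless data.

Degenerate inputs: a fitted mean level c0 ≤ 0 is rejected as non-physical;
a modulation amplitude exceeding c0 by more than 1 × 10⁻⁶ relative is
rejected as over-modulated, while smaller overshoots (noise) are clamped
onto the physical boundary DOLP = 1. Physicality of Stokes vectors
(S2²+S3²+S4² ≤ S1²) is enforced at 1 × 10⁻⁹ relative tolerance.

## Slope-based classification

Within each group, DOLP is regressed on thickness by OLS, left- and
right-ventricle samples pooled (the analysis treats ventricle as part of the
thickness variation, not a separate stratum; each group is summarized by one
line). The discriminating cut-off is a line whose slope lies strictly
between the two group slopes. Two open choices are exposed as parameters:

* **Cut-off slope.** `fixed` applies a user-supplied value (e.g. a published
  cut-off of −0.056 mm⁻¹ for the RHD contrast or −0.1 mm⁻¹ for MV);
  `max-accuracy` (default) grid-searches 201 candidates strictly between the
  group slopes and keeps the most accurate, ties broken toward the midpoint.
* **Anchor point.** The cut-off line must pass through somewhere. Default:
  the intersection of the two group fit lines — the unique point both fitted
  populations share, so the per-sample rule is invariant to which side of
  the anchor a sample sits. Alternative: thickness 0 at the mean of the two
  intercepts.

A sample is labelled diseased when the slope of the line joining it to the
anchor is strictly steeper (more negative) than the cut-off slope; a sample
exactly on the cut-off line is control (the boundary belongs to the
non-diseased side). A sample within 10⁻⁹ mm of the anchor thickness, where
the slope is undefined, is labelled by its DOLP side: strictly above the
anchor DOLP → diseased (the diseased groups carry the higher intercept).
Contrasts are pairwise (control vs RHD, control vs MV); there is no
three-class rule.

Group summaries report the standard error of the mean (sample SD with n−1
denominator over √n); a single observation has SEM 0 by convention. Reported
proportions are rounded half-up to 2 decimals in percent for display only;
JSON reports keep full precision.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the analysis assumes:
per group, thicknesses are drawn from a truncated normal (lower bound
0.1 mm) at the study's published per-group-and-ventricle means and SDs
(control 1.657/1.821 mm, RHD 1.396/1.493 mm, MV 0.867/0.857 mm for LV/RV);
the depolarization factor is the group line
d = clamp(intercept + slope·thickness, 0, 1) plus Gaussian scatter; the
voltage sweep is simulated through the full Mueller train with additive
detector noise and then *reduced* like real data, so synthetic cohorts
exercise the entire measurement chain.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| group slopes | −0.0422 / −0.0808 / −0.1699 mm⁻¹ | the published control/RHD/MV values |
| group intercepts | 0.1469 / 0.1997 / 0.2555 | not published; derived so each line passes through its group's pooled mean (thickness, DOLP) point |
| `dolp_noise_sd` | 0.02 | biological scatter about the group line; chosen to match the visual spread of the published scatter, a free parameter not a published value |
| `source_intensity`, `gain` | 1000, 1 mV/unit | noiseless voltages span ≈250(1±d) mV, a realistic photodiode-amplifier scale |
| `noise_sd_mv` | 1.0 | ≈0.4% of the mean level; the physical instrument's 10 kHz modulation/lock-in electronics are abstracted into this single additive term |
| subjects | 7 control / 7 RHD / 3 MV, ×2 ventricles | the study cohort shape |

What the generator does **not** emulate: spatial heterogeneity within a
specimen, wavelength dependence (single 850 nm operating point), explicit
collagen microstructure (disease enters only through the DOLP–thickness
line), within-subject sweep replicates (exposed as repeated calls, no
default count), and any correlation between a subject's LV and RV beyond
shared group parameters. Passing tests therefore show the *pipeline* is
correct and well-calibrated under the assumed statistical structure, not
that real fibrotic tissue follows a linear DOLP–thickness law.

## Monte-Carlo calibration results and a small-N limitation

At the defaults above, 500 simulated study cohorts recover the configured
group slopes to within ~2% on average (the OLS slope estimator is unbiased),
and the replicate-averaged slopes reproduce the configured ordering
|control| < |RHD| < |MV|. A single cohort of 7+7+3 subjects, however, does
not order the three slopes reliably: the slope sampling SDs
(≈0.037/0.047/0.086 mm⁻¹, driven by the narrow ~0.1 mm within-group
thickness spreads) exceed the inter-group gaps (0.039 and 0.089 mm⁻¹), and
the correct ordering appears in only ≈48% of replicates. This is a property
of the study conditions themselves, not of the estimator, and it is why the
tests assert ordering of the *mean* slopes while asserting only
better-than-chance ordering per replicate. It mirrors the caution that
conclusions from a 17-subject cohort need a larger follow-up.

Classifier sanity is checked on constructed cohorts whose groups are
separated by many multiples of the scatter: there the max-accuracy cut-off
reaches accuracy 1.0 and the confusion-metric identities hold exactly.

## Numerical conventions

Angles are degrees at every interface and converted to radians once,
internally; Mueller rotations use the 2θ convention. Voltages are mV
throughout (reductions are unit-invariant). Simulated voltages are clipped
at 0 mV — a photodiode cannot report negative flux; at the default noise
level the clip is a < 10⁻⁴ probability event per reading and its bias is
far below the DOLP scatter. Determinism: every stochastic entry point takes
a seed or `numpy.random.Generator`, identical seeds give bit-identical
cohorts and byte-identical JSON reports.
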