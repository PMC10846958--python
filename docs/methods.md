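# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data experiments do and do not demonstrate.

## Contact model and units

A four-sided pyramidal tip indenting an isotropic, linear-elastic,
adhesionless half-space produces F = (2/π)·E/(1−ν²)·tan(α)·δ². Working
units are kPa, µm and nN; since 1 kPa = 1 nN µm⁻², the prefactor
C = (2/π)·tan(α)/(1−ν²) is dimensionless and F[nN] = C·E[kPa]·δ[µm]².
Defaults: ν = 0.5 (incompressible hydrated tissue; configurable 0–0.5) and
α = 20°, the effective half-angle convention for sharp silicon-nitride
probes. Recovery experiments use the same α in generator and fit, so their
outcome does not depend on the probe datasheet value. Cantilever statics:
F = k·d with k in N m⁻¹ ≡ nN nm⁻¹, and δ = (z − z₀) − d.

## Curve processing

*Baseline.* A straight line fitted to the leading 30% of the approach is
subtracted from the whole force channel (offset and tilt are instrument
artefacts affecting the entire signal). After a first contact-point
estimate the line is refitted over the full pre-contact region; the longer
lever arm suppresses the extrapolation error that otherwise tilts the
post-contact force and was found to dominate the modulus error budget at
realistic noise (reducing the median relative error on 5%-noise curves from
~8% to ~4%).

*Contact point.* The instrument vendor's processing chain is proprietary,
so the package uses a parameter-light change-point method: for each
candidate sample the piecewise model "zero force before contact, Hertz
parabola in δ after contact" is fitted (the parabola amplitude has a closed
form), and the candidate minimising the residual sum of squares seeds a
bounded Brent refinement of z₀ (absolute tolerance 10⁻⁸ µm). Because the
parabola abscissa already uses δ = (z − z₀) − d, the objective vanishes
exactly at the true contact point of a clean curve: the full chain then
returns E to better than 10⁻⁶ relative error, which the test suite checks
over E ∈ {1, 5, 11, 50} kPa × α ∈ {15°, 20°, 25°}. Curves whose maximum
force never exceeds five robust SDs of the leading baseline are flagged
"no contact". A curve contacting at the very first sample is handled (the
scan includes index 0), but then no baseline can be estimated — such
curves are only meaningful pre-corrected.

*Fit and QC.* E is the closed-form least-squares solution of F against
C·δ²; goodness of fit is the RMS force residual in nN. QC rejects: depth
above 10% of the section thickness (default thickness 20 µm → 2 µm limit),
RMS above 10% of peak force, or E outside [0.01, 10⁴] kPa. All cut-offs are
function arguments with these defaults. The per-ROI representative value is
the median over accepted fits (even counts: mean of the central pair);
accepted + rejected always equals the curve total.

## Synthetic data: what it emulates

*Curves.* The generator solves the static force balance k·d = C·E·(s − d)²
per sample (cancellation-free quadratic root), so post-contact forces obey
the Hertz law exactly at the recorded ground-truth modulus; artefacts are
additive Gaussian force noise (absolute, or relative to the curve's peak
force — the study conditions use 5% relative), a linear baseline
(default 0.2 nN offset, 0.05 nN µm⁻¹ tilt) and Gaussian contact-point
jitter (0.05 µm). Ramps default to 1 µm depth, 1.5 µm pre-contact travel,
200 samples. Not modelled: adhesion, viscoelastic relaxation, retract
segments, thin-film substrate effects — passing recovery tests therefore
shows correctness of the processing chain under its own model assumptions,
not robustness to those physical effects.

*Group moduli.* Ground-truth per-ROI moduli are lognormal — the
distribution observed for arterial indentation data — calibrated in closed
form from the group median m and IQR: µ = ln m,
σ = asinh(IQR/(2m))/z₀.₇₅, which reproduces the requested quartiles
exactly. Sampling is stratified by default (one inverse-CDF draw per
equal-probability stratum, order permuted): the generator's purpose is to
hand downstream stages a cohort that *embodies* its nominal quantiles, so
recovery errors measure the pipeline rather than lognormal sampling
noise. Plain iid draws (`method="iid"`) are used wherever a test is about
sampling behaviour itself. All 25 curves of an ROI share the ROI's true
modulus; within-ROI heterogeneity enters only through measurement noise.

*Images.* Polarized-light tiles are a dark noisy background (levels 5–55,
all below the 75 threshold) on which anti-aliased straight fibre segments
(bright levels 150–255) are stamped until the at-or-above-threshold pixel
fraction reaches the target, then trimmed/filled at pixel granularity so
the stored truth coverage is exact to one pixel. Orientation statistics are
deliberately not controlled (out of scope); only area fraction is
meaningful. Section-thickness effects on the polarized signal are not
modelled — density is planar.

*Transforms.* Grid pairs carry the intersections of a 50 µm grid as
landmarks; frame-B coordinates are the true similarity image plus isotropic
Gaussian noise (default 0.5 µm), and image B is the warp of image A.

*Coupling.* Coupled cohorts draw density as the conditional Gaussian given
the modulus z-score (default SD 8 percentage points, population correlation
ρ configurable; study default 0.6, matching the strength of association the
pipeline is meant to exhibit), clipped to [0, 100] (rare at the defaults).

## Imaging conventions

Coordinates are µm, origin top-left, y down; pixel (r, c) has centre
((c+0.5)p, (r+0.5)p) at pitch p. ROI boxes are half-open [x, x+50) µm with
pixel-centre membership, so tiled ROIs never double-count. Binarization is
inclusive (pixel ≥ 75 → white); the threshold's strictness is a one-level
ambiguity absorbed by the ±2-point tolerances used throughout. RGB inputs
are converted with standard luminance weights. Threshold calibration scans
all 256 levels against a user-supplied reference density (the reference is
an external measurement, not a constant of this package) and breaks ties
toward the lower level.

## Co-registration

Default family is similarity — sections are rigid objects imaged at
possibly different magnification; affine is available for sectioning shear.
Estimation is least-squares landmark alignment (scikit-image backend)
with degeneracy checks (pair counts, collinearity). The error metric is
100 × mean held-out landmark displacement / 50 µm grid pitch; the report
also carries the per-landmark errors, since pooling convention (per-section
vs per-landmark) is a free choice. At the default 0.5 µm landmark noise the
two-leg chain scores ~1%; the metric is exactly 4% for a uniform 2 µm
displacement.

## Statistics

Quartiles use linear interpolation; log-modulus uses natural log (any base
yields the same Pearson ρ). The lognormality KS test estimates (mean, SD)
from the log data and computes p by parametric bootstrap (default
B = 1999, seed-controlled), since the naive KS p is anti-conservative with
estimated parameters; for a location–scale family the null distribution of
D is parameter-free, so the bootstrap is exact up to Monte Carlo error.
Binning sorts pairs by density and replaces consecutive chunks of six by
coordinate-wise medians; a final short chunk is kept as its own bin, so 67
pairs give 12 bins and 91 give 16 (a 91-pair pooled analysis can *not*
produce 17 non-overlapping six-point bins; the pipeline follows the
procedure literally). Pearson correlation on bin medians uses the t-based
two-sided p on n_bins − 2 df. Wilcoxon comparisons use the exact null for
tie-free samples up to n = 25 per group, otherwise the tie-corrected normal
approximation; the choice is recorded in the output. No multiple-testing
correction is applied, and the output metadata says so.

## Problem sizes and tolerances in the validation suite

Recovery experiments run at the study sample sizes (1379 healthy, 392
lipid-core, 1506 fibrous-cap curves; 67 density ROIs) with 5% force noise;
medians are recovered within ±10% (moduli) and ±2 percentage points
(densities). The KS type-I-error check uses 500 replicates of n = 1000
with B = 499 bootstrap draws per replicate (vectorised); the power check
uses 20 replicates of uniform data. The noise-robustness check uses 500
curves. These sizes are the package's own validation design and are chosen
so the whole suite completes in well under a minute of CPU per heavy test.

## Known limitations

Linear-elastic, isotropic, adhesionless contact only; no spring-constant
calibration; no intensity-based grid detection (landmarks are inputs); no
fibre-orientation metrics; the synthetic discard rate is near zero, unlike
real cohorts where probe contamination and heterogeneity discard a
substantial fraction of curves — discard *accounting* is implemented and
tested, but realistic discard *causes* are not simulated.
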