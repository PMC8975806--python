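# Methods

This note records the models implemented, the parameters that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Camera and localization model

Frames follow the sCMOS measurement model

    ADU = offset + gain · Poisson(PSF + background) + N(0, variance),

with per-pixel offset, gain and read-noise variance maps. The PSF is a
pixel-area-integrated 2D Gaussian; its width is not a measured quantity
here and defaults to 1.3 px sd (≈85 nm at 65 nm pixels), configurable.

Detection filters each frame with small (143 nm) and large (286 nm)
Gaussian kernels, both weighted by the inverse per-pixel variance
(`gauss(I·w)/gauss(w)`), and takes local maxima of the difference image.
The threshold is expressed in units of the robust (MAD-based) noise sd of
the filtered image, default 4; uniform rescaling of the variance map leaves
the candidate set invariant.

Crop fitting maximizes the variance-stabilized sCMOS likelihood: photon-
converted data are augmented by `variance/gain²` pseudo-counts so a Poisson
likelihood absorbs the Gaussian read noise. This is a published, testable
approximation of the exact Poisson⊗Gaussian convolution and is the single
likelihood used throughout (fitting, model selection and CRLB), so the
three are mutually consistent. The emitter count per 9×9 crop follows a
push-and-pull rule: emitters are added at the residual maximum while the
BIC improves and removed when removal improves it, capped at 3 per crop.
Per-emitter precision is the CRLB from the analytic Fisher information of
the same likelihood; empirical position-error sd agrees with it within 20%
at ≥2000 photons (verified by simulation), and the zero-background limit
reproduces sqrt(s² + a²/12)/sqrt(N).

The precision distribution is summarized by the mode (density peak) of a
maximum-likelihood skew-normal fit. The mode was chosen over the raw
location parameter because the location estimate of a skew-normal is
ill-determined on nearly symmetric samples, while the mode equals the mean
for symmetric data and sits below the arithmetic mean for right-skewed
data, which is the behavior wanted of an "average precision".

Blink merging chains localizations that appear in consecutive frames within
2.5× the average precision, greedily frame to frame; chains collapse to a
photon-weighted mean with summed photons. The greedy rule is not strictly
idempotent in pathological geometries (two chains whose averaged centroids
move within the gate), but is idempotent whenever events are separated by
more than the merge radius, which is the regime the merge is meant for.

## Channel registration

The second-order warp uses the tensor monomial basis
[1, y, y², x, xy, xy², x², x²y, x²y²]. Bead coordinates are mean-centered
and scaled by their sd before solving the least-squares system — raw nm
coordinates make the x²y² column ~10¹⁸ and the normal equations numerically
singular — and the coefficients are re-expanded exactly into the original
frame, so any true second-order warp is recovered to ≤1e-9 relative error
from ≥9 noiseless beads. The reported residual is the rms per coordinate,
so bead noise of sd s appears as residual ≈ s. Bead pairing across channels
is nearest-neighbor with a 500 nm gate.

## Pair correlation

g(r) and c(r) are pairwise-distance histograms normalized by the expected
pair count of a uniform pattern in the same rectangular ROI. The edge
correction is analytic: the expected CSR mass per radial bin integrates
2πr·γ(r) with γ the isotropized set covariance of the rectangle
(γ(r) = WH − 2(W+H)r/π + r²/π, valid to r ≤ min(W, H)); r_max must not
exceed the shorter ROI side. Defaults dr = 10 nm, r_max = 1000 nm. For
≤300 points the KD-tree histogram is verified bin-for-bin against a
quadratic-loop oracle.

Fits are weighted nonlinear least squares with per-bin weights √(pair
count) and multi-start grids over (σ, r_app) and (x_c, σ). One
identifiability point matters in practice: the first (short-range) term of
the two-Gaussian model comes from repeated localizations of the same
fluorophore, so on input that is already blink-merged to one localization
per molecule that term is absent and ⟨ρ⟩ cannot be inferred from the curve.
The fit therefore accepts `self_term=False` together with ⟨ρ⟩ fixed at the
empirical count density and σ fixed at the known localization precision —
both quantities the localization stage provides. All four parameters are
free by default, and a curve synthesized from the full model is recovered
to 1e-6.

The focus content ⟨N⟩ = 2π⟨ρ⟩A·r_app² is implemented exactly as printed and
checked against numerical quadrature of its displayed integrand to 1e-6.
Note the factor conventions of the correlation Gaussian (4(σ²+r_app²)) and
the content integrand (2r_app²) are not mutually consistent as a
probabilistic model; both displayed forms are implemented verbatim and the
discrepancy is deliberately left unresolved. Similarly, the symmetric
cross-correlation model is a radial parameterization, not the exact
radialization of a 2D displaced Gaussian; fitting it to such data biases
x_c downward by a few nm at x_c/σ ≈ 2.5, well within the ±10 nm recovery
target.

## Dwell-time kinetics

Movies are block-averaged every 4 frames (effective frame time = 4 × raw,
e.g. 0.12 s at 33 Hz) and background-subtracted with a grayscale
rolling-ball of radius 10 px. Linking is globally optimal nearest
assignment per frame pair (Hungarian) with a 500 nm gate and no gap
closing; tracks shorter than 2 effective frames are dropped. tau_on is
(last − first + 1) × effective frame time.

The tau_on distribution is analyzed as a survival curve S(t) = P(tau_on > t)
evaluated on the frame grid. With on-times quantized upward to whole
frames, P(tau_on > jΔ) for an exponential duration is exactly exp(−jΔ/τ),
so the survival form introduces no discretization bias in the fitted
lifetimes — the reason it is the default over a density histogram (also
available). The two-exponential fit orders components so tau_fast < tau_slow
and reports tau_fast as the dwell time and tau_slow as photobleaching,
matching the source analysis's assignment; components closer than a 1.5×
ratio are flagged as collapsed and refit with a single exponential.

The synthetic on-time generator uses two populations — transient molecules
that unbind (exponential, mean 0.51 s) and a persistent fraction (default
0.2) terminated only by photobleaching (exponential, mean 3.8 s) — because
a single binding population cannot produce two decays. This is one
admissible mechanism, not an established one; the fit itself is agnostic to
it. The generator ignores re-binding, blinking, detection misses and
multi-molecule loci, so recovery tests demonstrate estimator correctness
under the stated mixture, not robustness to those real-data effects.

## Ok-seq fork directionality

Replication fork directionality (RFD) is read as the Crick-strand fraction
of Okazaki fragments per 1 kb bin; %L→R = 100·crick/(crick+watson), with
zero-coverage bins treated as missing. Fragments are assigned to bins by
midpoint (5′-end assignment differs by at most one bin at ≤200 bp fragment
length). Minus-strand genes are mirrored and complemented (offset negated,
pct → 100 − pct) so transcription always reads left to right; mirroring
twice is the identity.

The programmed RFD model is piecewise: background 0.5; an origin of
efficiency e at the TSS lowers RFD by e/2 over a 15 kb upstream flank and
raises it e/2 through the gene body (net step e across the origin);
termination relaxes linearly back to background across a 20 kb zone
centered on the TTS. Overlapping gene contributions superpose as deviations
from background and are clipped to [0.05, 0.95]. Counts are multinomial
over bins with binomial strand splitting, so the generator's statistics are
exactly the sampling model a binomial oracle predicts.

Step statistics per gene are mean %L→R over +1..+10 kb minus mean over
−50..−30 kb at the TSS (±1–10 kb at the TTS). Because the upstream flank of
the model extends only 15 kb, the TSS statistic measures the step against
the far-field background (≈ 50·e percentage points), while the local step
across the origin is the full 100·e; tests and the acceptance suite use the
local ±10 kb step for the step-height check. Groups are compared with the
tie-corrected Kruskal–Wallis H (chi-squared p, or exact permutation
enumeration for n ≤ 10), with ε² = H/(n−1) as the omnibus effect size and
rank-biserial r = 1 − 2U/(n₁n₂) pairwise — the standard nonparametric
companions, since no specific effect-size metric is prescribed by the
source analysis. Per-gene statistics (each gene weighted equally) are the
unit of comparison.

## Fiber statistics

Lengths convert at 1 μm = 2.59 kb. Symmetry ratios are directional
(left/right CldU, first pair member = leftward fork) as printed, with a
min/max option; zero-length members are excluded and counted. The origin
fraction counts bidirectional pairs as single structures. The Mann–Whitney
test enumerates all C(n, n₁) group assignments with mid-ranks when
min(n) ≤ 8 (two-sided p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1) and
otherwise uses the tie-corrected normal approximation; the two agree within
0.01 at n = 8 vs 8. Population doublings follow
n = 3.32(log₁₀ UCY − log₁₀ l) + X.

## Problem sizes and reproducibility

Recovery suites use 8–20 replicate seeds per check, ROIs of 6×6 μm² at
~90 molecules/μm², 5,000 on-time events, and 60–200 genes at 100–500
fragments/kb — sizes at which the estimators' sampling error sits well
inside the stated tolerances while the full suite runs in well under a
minute. Every stochastic function takes an explicit seed (or a numpy
Generator) and owns no global state; identical seeds reproduce
byte-identical outputs, which the test suite asserts stage by stage.

## Known limitations

No drift correction, 3D/astigmatic fitting, or spectral unmixing; no
diffusion-state analysis or gap closing in tracking; origin calling as
discrete peaks is out of scope (continuous bias only); fiber structure
classes are caller-provided labels, as image measurement is manual in the
underlying assay. The exact Poisson⊗Gaussian sCMOS likelihood is
approximated (see above) rather than evaluated by convolution.
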