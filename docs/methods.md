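# Methods

## Scope and data model

The package quantifies the three carbamazepine crystal forms (CBZ I,
CBZ III, CBZ dihydrate) in excipient-laden tablets from Raman spectra by
interval PLS. No public instrument dataset accompanies this problem, so
the package ships a synthetic spectrum generator that emulates a
laboratory tablet-assay campaign of this kind; the calibration, selection
and reporting machinery is data-agnostic and accepts any long-format
spectra CSV with a matching mixture-design table.

## The mixture design

Fifteen 300 mg tablets: 250 mg of a fixed excipient blend and nominally
50 mg of CBZ split between the three forms following a ternary design —
three pure-form tablets, three binary midpoints, three corner-weighted
ternary points and one centroid for calibration (samples 1–10), plus five
ternary validation points (samples 11–15). The per-tablet polymorph masses
are fixed constants of the design (total CBZ 49.0–50.8 mg per tablet).
Responses are percentages of the tablet's total CBZ mass, which sum to
100% by construction. The CBZ fraction of the tablet is nominally
50/300 = 16.67%; the actual per-tablet values (16.4–16.9%) are used
wherever the fraction matters.

## The synthetic generator

Each component — the three polymorphs and one pooled excipient blend — is
a sum of Gaussian and Lorentzian bands on a 52–1708 cm⁻¹ axis (default
2 cm⁻¹ grid, 829 points; the shapes are pure rather than Voigt so every
band property is analytically testable). Each polymorph owns three anchor
bands, one in each of the regions 160–250, 700–800 and 1000–1100 cm⁻¹
where the real polymorphs are spectrally distinctive; anchors are spaced
so no other component has a band center within one FWHM, and randomly
placed extra bands (5–12 per polymorph) keep clear of all anchors so the
uniqueness invariant holds by construction. The excipient blend has six
broad (FWHM 80–200 cm⁻¹), low-amplitude bands: excipients are held at a
constant 250 mg in every tablet and the pooled component reflects that the
calibration cannot (and need not) distinguish them.

A tablet's noiseless spectrum is the tablet-mass-fraction-weighted sum of
the component spectra. Replicate r of a tablet is

    I_r(ν) = g_r · Σ_k (w_k + δ_rk) S_k(ν) + b_r(ν) + ε_r(ν)

with per-replicate weight jitter δ (relative Gaussian, clipped at zero and
renormalized to a composition — the laser spot samples a slightly
different local composition at each surface point), mean-one lognormal
gain g_r, a quadratic baseline b_r with small random coefficients, and
i.i.d. Gaussian noise ε_r. Ten replicates per tablet by default — the
standard way to average out subsampling on a tablet surface. All randomness derives from one master seed via
independent seed sequences keyed on the sample id, so the full dataset is
bit-reproducible and independent of generation order.

Instrument noise figures vary by spectrometer and acquisition settings,
so the preset magnitudes are the package's own choices: `low` (additive sd 5·10⁻⁴, gain 1%,
baseline 2·10⁻³, jitter 1%) approximates a well-averaged benchtop
acquisition; `paper_like` (2·10⁻³, 5%, 8·10⁻³, 4%) is a deliberately
rougher setting. Both are configuration, not constants. The generator does
not model instrument response, cosmic-ray spikes, or physically accurate
carbamazepine band positions — passing tests demonstrate that the
calibration machinery recovers compositions under the stated statistical
structure, not that it would achieve any particular error on real spectra.

## Preprocessing

Fixed order: average the replicates → normalize the average spectrum to
unit trapezoidal area (cancelling overall intensity variation; the area is
computed on the possibly non-uniform axis) → first derivative with respect
to wavenumber (separating overlapped bands and removing additive
baselines) → extract the selected intervals. The derivative is
Savitzky–Golay, window 7, polynomial order 2 by default — standard
chemometric practice, robust to noise — applied with polynomial edge
interpolation so the output length equals the input length; a plain
central difference is available and serves as the derivative oracle in
tests. Interval bounds are inclusive in cm⁻¹ and map to the grid points
inside them.

## PLS and latent-variable choice

Classical NIPALS PLS2: one model for the three responses jointly, X and Y
column-centered (recomputed inside every cross-validation fold; no
leakage), no variance scaling (derivative features share units, and
interval selection is deliberately scale-sensitive). Convergence tolerance
1e−12 on the weight vector, at most 500 iterations per component; if the
centered X runs out of rank the extraction stops early with a warning.
Predictions are not clipped to [0, 100] and not forced to sum to 100%;
post-hoc clipping is left to the caller so the calibration scatter stays
honest. Explained X-variance per component is the score–loading outer
product's share of the centered-X sum of squares.

The latent-variable count is chosen from the leave-one-out RMSECV curve
by a parsimony rule: the smallest k such that the (k+1)-th component
improves the response-averaged RMSECV by less than 5% (relative),
guarding against over-fitted models. An exact zero in the curve stops the
search. Because the three responses close to 100%, the response matrix has
rank 2, and the third spectral direction (the small tablet-to-tablet
variation in total CBZ mass) carries little usable signal — so the rule
legitimately settles on 2 components for noiseless synthetic data (see
"the nonlinearity floor" below) and on 2–3 under realistic noise.

## Interval selection (iPLS)

The axis is partitioned into contiguous equal-point-count intervals
(default 20; remainder points join the last interval). Each candidate
interval set is scored by the leave-one-out RMSECV averaged over the three
responses, with the LV count re-optimized per candidate set (minimum over
1–10 components, ties to fewer) since narrow intervals support fewer
components. A greedy forward search starts from the best singleton and
adds the interval with the largest error decrease until the relative
improvement drops below 2% or five intervals are selected; ties break
toward lower wavenumber. For partitions of up to ~10 intervals an
exhaustive subset search is available and doubles as the test oracle — on
the synthetic test family the greedy result is required to be within 10%
of the exhaustive optimum. Validation tablets never enter interval
selection or LV choice; the calibration stage drops their spectra before
any computation, which the test suite verifies by corrupting them on disk
and asserting a byte-identical model.

Because the responses are closed (two polymorph concentrations determine
the third) and components share many bands, the error-minimizing search
has no incentive to select a distinctive band of *every* polymorph; a
single well-chosen interval often suffices. The selected ranges therefore
need not coincide with the visually distinctive regions, and no such
coincidence should be read into a fitted model.

## Error reporting

RMSEC, RMSECV (from the held-out LOO predictions at the chosen LV count)
and RMSEV per polymorph, in % wt/wt on the CBZ-mass basis, with the
tablet-mass basis obtained by multiplying with the run's actual mean CBZ
tablet fraction (not a hard-coded 16.67%). R² is pooled over calibration
and validation tablets, with per-subset values reported alongside.
Reports store full precision and render at two decimals.

## The response-nonlinearity floor (known limitation)

For noiseless synthetic data one might expect machine-precision errors.
They are not attainable on the CBZ-mass basis, for a structural reason:
spectra mix in *tablet*-mass fractions mₖ/(M+250) while the responses are
*CBZ*-mass percentages 100·mₖ/M, and the designed tablets' total CBZ mass
M varies (49.0–50.8 mg). The response is therefore a ratio — not an affine
function — of the three free spectral coordinates, and no linear model on
the rank-3 feature space can interpolate it; area normalization with
unequal component areas adds a second ratio of the same kind. The best
attainable RMSE has a floor of roughly 0.2–2% depending on the component
areas. The identity *is* exact on the tablet-mass basis when all component
spectra have equal integrated area, and the test suite pins both facts:
machine-precision recovery in the equal-area/tablet-basis regime, and the
floor bound (< 2.5%) in the faithful regime. Practically the floor is far
below the noise-driven errors of any real acquisition.

## Problem sizes and numerical choices

Default runs use the full 829-point grid, 15 tablets × 10 replicates, a
20-interval partition and LV candidates 1–10; a complete
generate → calibrate → validate cycle takes a few seconds on one core, and
the test suite uses single-replicate noiseless variants where replicates
are redundant. Degenerate inputs are handled explicitly: constant
responses yield an intercept-only model; zero-area spectra, empty interval
selections, fold-rank collapse (components reduced and logged) and axis
mismatches raise informative errors.
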