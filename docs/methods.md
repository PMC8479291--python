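# Methods

## The measurement

A factor that translocates from cytoplasm to nucleus changes the *spatial*
distribution of its fluorescence, not necessarily its total. Imaging flow
cytometry captures a per-cell image pair — the reporter channel and a DNA
stain — so translocation can be read out as the pixel-wise correlation of
the two images inside the nuclear region. `nuctrans` quantifies this with
the per-cell similarity score

SS = ln((1 + r′)/(1 − r′)),  r′ = clamp(r, −r_max, +r_max),  r_max = 1 − 10⁻⁶,

where r is the sample Pearson correlation between the reporter and DNA-stain
pixel values over exactly the pixels of the nuclear mask. The transform is
2·atanh(r): odd, strictly increasing, zero at r = 0, and unbounded as
|r| → 1, which spreads the compressed top of the correlation scale into an
approximately location-scale family that population statistics handle well.
The clamp keeps SS finite on perfectly correlated inputs (e.g. a channel
correlated with itself); clamping affects only |r| > 1 − 10⁻⁶.

The shift between a treated and a control population is summarized by the
Fisher's discriminant ratio

Rd = (mean SS_test − mean SS_control) / (sd SS_test + sd SS_control)

with sample (n − 1) standard deviations. Rd is kept signed; a positive
value means the test group moved toward nuclear localization. When both
standard deviations vanish the ratio degenerates: equal means give Rd = 0,
unequal means are reported as ±∞ (infinite separation) rather than a
finite number. Rd values below ≈ 0.1 are conventionally read as background
level; the package annotates rather than hard-codes any cutoff.

Cells whose mask is smaller than `min_mask_px` or whose masked pixel values
are constant in either channel carry no correlation information; they are
flagged (`mask_too_small`, `zero_variance`), excluded from population
statistics, and counted in the run log.

## Nuclear masking

The nuclear region of interest is segmented from the DNA-stain image by a
deliberately parameter-light chain: Gaussian smoothing (σ = 1 px) → global
threshold (Otsu by default, or a fixed value) → binary closing (disk radius
2 px) → hole filling → retention of the largest 8-connected component.
Commercial instrument software uses a proprietary morphology mask; this
chain is a reproducible surrogate that is accurate to about one pixel on
disk-like nuclei (Jaccard ≥ 0.95 against geometric ground truth in the
tests), which is sufficient because the SS statistic needs only an
approximate nuclear region. Whether the instrument's mask is slightly
dilated or eroded relative to the visible nucleus is unknowable from the
outside, so mask tightness is left as configuration (smoothing, threshold,
closing radius) rather than fixed behavior. A constant image, which no
threshold can split, yields an invalid empty mask instead of an error.

## Gating and quadrants

Events pass the analysis gate iff brightfield area lies within
[area_min, area_max], aspect ratio ≥ aspect_ratio_min, viability-dye
intensity ≤ livedead_max, and DNA-stain total ≥ nuclear_stain_min; bounds
are inclusive, criteria are evaluated in the order singlet → live →
nucleated, and the first failure is logged per event. Numeric thresholds
are instrument-session-specific in practice; the defaults are calibrated
to the synthetic generator's default geometry (area within
[0.7, 1.4] × π r_cell², aspect ≥ 0.7, Live/Dead ≤ 150, DNA total ≥ 28 000
= whole-image background plus a quarter of the nominal nucleus signal) and
`gate_config_for(spec)` derives matching thresholds for any other spec.
Apoptosis quadrant classification is independent of gating: each event
falls in exactly one annexin-V × viability quadrant, with strict (>)
positivity on both axes so the partition is unambiguous at thresholds.

## The synthetic generator

Each synthetic event is a cell rendered as two concentric disks on a 64×64
grid (cell radius 20 px, nucleus radius 10 px by default — small enough for
desk-scale suites while leaving ≈ 314 nucleus pixels for a stable
correlation). Per event, a nuclear fraction f is drawn from
Normal(mean, sd) clipped to [0, 1]; the reporter deposits f of its total
intensity (default 50 000 a.u.) uniformly over the nucleus and 1 − f
uniformly over the cytoplasmic annulus, and the DNA channel is the nucleus
disk at intensity 100 over background 5. Additive Gaussian noise
(sd = 2, clipped at 0) is the default detector model, with a Poisson
option; an optional crosstalk coefficient (default 0) bleeds a fraction of
the DNA channel into the reporter to emulate drug autofluorescence.
Defaults put control populations (f ≈ 0.2) at low/negative SS and strongly
translocated ones (f ≈ 0.8–1.0) several SS units higher, the qualitative
operating regime of real reporter/DNA-stain data.

Channel intensities are rendered **coverage-weighted**: each pixel receives
intensity proportional to the fraction of its area covered by the disk
(4×4 supersampling), as a physical detector integrates photons over the
pixel. This matters for the statistic itself. With hard-edged disks the
interior of a perfect mask is spatially constant in both channels, and
since Pearson correlation is invariant to affine intensity changes, the
within-mask reporter would carry *no* information about f — discrimination
would hinge on whether the segmented mask happens to spill over the
nucleus boundary, making population medians unstable. The graded boundary
ring that coverage rendering places inside every mask carries the
nucleus-versus-cytoplasm contrast consistently, giving a smooth, strictly
monotone dose response. Ground-truth nucleus masks, by contrast, use plain
pixel-center membership (a pixel belongs iff its center lies in the disk),
which keeps truth binary and testable.

Scalar gating features are planted per category: singlets draw area in
[0.9, 1.1] × π r_cell² with aspect ratio 0.85–1.0 and Live/Dead 10–50;
doublets double the area (1.8–2.2×) at aspect 0.35–0.55; dead events draw
Live/Dead 500–1000; anucleate events are rendered without a nucleus (DNA
channel = background, reporter spread over the whole cell disk). With the
calibrated default gate these categories separate perfectly in the
noise-free setting and ≥ 99 % of noisy singlets still pass.

All generators are pure functions of spec + seed (one `numpy` Generator
drawn through in a fixed order), so identical specs regenerate
byte-identical events. Total deposited reporter intensity equals the
spec's value exactly before background/noise.

What the generator does *not* emulate: optics (no point-spread function,
no depth effects), spectral spillover/compensation (done upstream in the
instrument), chromatin texture or nucleoli, irregular cell shapes, and
touching-cell segmentation problems. Passing tests therefore demonstrate
the correctness of the statistics and the pipeline's behavior on
disk-like, well-separated cells — not segmentation robustness on real
morphologies.

## Companion assays

ΔΔCT: technical replicates are aggregated by the arithmetic mean of CT
values (the standard convention) before differencing; ΔCT = mean CT_target
− mean CT_reference; the default calibrator is the mean ΔCT across all
samples, so fold changes (2^−ΔΔCT) are relative to the cohort average, and
a named calibrator sample can be substituted. Both ΔΔCT and fold change
are emitted, since reports in the field use either unit. No
amplification-efficiency correction is applied.

Relative proliferation rescales a treated count linearly so the
pre-treatment count is 0 % and the untreated end point 100 %; values below
0 % indicate net cell loss, and the scale is undefined (an error) when the
untreated culture did not grow past baseline.

## Numerical and design choices

- Pearson r is computed by `numpy.corrcoef` on the masked values and
  cross-checked in the tests against an independent loop implementation to
  10⁻⁹; r is clipped to [−1, 1] against floating-point overshoot.
- Masks use 0-based, row-major pixel grids; masks and images share shapes
  exactly and mismatches are errors, not warnings.
- An optional per-image background-percentile subtraction (default off) is
  available before correlation, since whether instruments subtract
  background upstream varies.
- Group significance testing (t-tests/ANOVA) is ordinary statistics, out of
  scope here; Rd tables carry the group sizes needed to run them with
  standard packages.
- The end-to-end runner writes CSV tables with fixed float formatting and a
  run log without timestamps, so a rerun with the same input, config and
  seed is byte-identical — determinism is a tested contract, not an
  accident.
- Problem sizes in the test suite (populations of 200 events at 64×64,
  1000-sample normal draws for Rd recovery) were chosen so the full suite
  and the reproduction script each run in seconds on one CPU while keeping
  Monte-Carlo tolerances comfortable (e.g. |Rd − 1| ≤ 0.1 at n = 1000,
  where the standard error is ≈ 0.027).

## Known limitations

- The SS is a correlation, not a nuclear/cytoplasmic intensity ratio: a
  cell with reporter uniformly everywhere scores near zero, not 50 %.
  Alternative colocalization metrics (Manders, translocation indices) are
  deliberately out of scope.
- Rd assumes roughly unimodal SS distributions per group; strongly bimodal
  responses (a responding subpopulation) compress into one number.
- The aspect-ratio feature is planted as a scalar, not derived from the
  rendered image; rendered geometry is always circular. Doublet *images*
  are not rendered as two touching cells — only their gating features are
  emulated — so the mask module's behavior on true doublet images is
  untested by design (they are gated out upstream).
- Otsu thresholding assumes a bimodal intensity histogram; extremely dim
  nuclei (near the noise floor) can produce fragmented masks, which the
  `min_mask_px` validity floor then flags rather than silently scoring.
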