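# Methods

## Model and assumptions

Let `S(z, y, x)` be the signal-of-interest (SOI) stack and
`N(z, y, x)` the normalization-signal (NS) stack, both single-channel,
integer-valued at 8 or 16 bit, with section index `z = 0` at the
shallowest focal plane. The working model of depth loss is
multiplicative and section-wise: the detected signal at depth `z` is
the true signal times an unknown attenuation factor shared by both
channels. The correction needs three assumptions:

1. **Proportionality** — NS and SOI lose signal by the same per-section
   factor (similar photostability and detection efficiency).
2. **NS depth coverage** — the NS is distributed near-uniformly through
   the depth of the sample (a nuclear stain or housekeeping label), so
   its per-section mean tracks attenuation rather than biology.
3. **Separable background** — a fixed intensity window distinguishes
   signal from background/artifact across all sections, and background
   pixels are (near-)zero.

## Section-specific normalization

For each section the NS *section-specific mean* is

    m(z) = mean{ N(z, y, x) : N(z, y, x) != 0 }

Zero pixels are always excluded: they are background and would dilute
the mean with depth-independent mass. No user threshold is applied to
the NS — the depth-loss information is concentrated in its low pixel
values, which a threshold would discard. The user window `[lo, hi]`
gates the SOI only. The normalized stack is

    S'(z, y, x) = S(z, y, x) / m(z) * max_k m(k)    if lo <= S <= hi and S != 0
                  0                                 otherwise

`m(z)` must be defined at every section; an all-zero NS section is a
hard error (naming the section) rather than an imputed value, because a
silently guessed mean would corrupt every pixel at that depth.

The `max_k m(k)` factor is a deliberate interpretive choice: raw
ratios are well below 1 and would vanish when exported at the native
integer bit depth. Multiplying by the maximum NS mean leaves the
brightest-NS section approximately unchanged and brightens deeper
sections, keeping the output on an intensity-like scale. The raw-ratio
output remains available (`rescale_mode="none"`). Out-of-window pixels
are zeroed, not dropped, so image geometry and resolution are
preserved; export clips to `[0, 2^bit_depth - 1]` and rounds to the
source dtype.

## Projections and scaling

Mean projections are plain arithmetic means along one axis, including
zeros — the zero-exclusion rule belongs to the mean *statistics*
feeding normalization and depth profiles, not to image projection,
where dropping zeros would misrepresent empty space. The three views
are min/max scaled to 8-bit independently (each fills its own 0–255
range); joint scaling would let one dim view waste the dynamic range of
the others. A constant image maps to all zeros by convention. Rounding
throughout the integer-mapping paths (min/max scale, contrast rescale)
is half-away-from-zero, chosen over banker's rounding so that equal
ties always move toward brighter output and the mapping is monotone in
the strict sense users expect from a contrast control.

The contrast rescale maps `[user_min, user_max]` onto the full range
with `alpha = dtype_max / (user_max - user_min)` and
`beta = user_min * alpha`; `out = clip(round(alpha*p - beta), 0,
dtype_max)`. The subtractive sign of `beta` is the only convention
under which `user_min -> 0` and `user_max -> dtype_max` exactly;
out-of-window values saturate (standard brightness/contrast
semantics). An interactive reference-plane picker is replaced by a
printed per-section min/percentile/max table.

## Diagnostics

The depth profile reports each section's masked mean as a percent of
the maximum section mean; its maximum entry is exactly 100 and it is
invariant under global intensity rescaling. Raw means are exported
alongside the percentages since either reading can be wanted.
Histogram cubes bin the masked pixels of each section over uniform
bins spanning the dtype range (real-valued normalized stacks, having
no ceiling, are binned over `[0, observed max]`; defaults to 256 bins)
and render with a `log(1 + count)` color scale so empty bins stay
defined.

## The phantom generator

Synthetic validation pairs emulate the imaging regime the tool is
built for, with every estimated quantity known by construction:

- **Geometry** — a cylindrical "cluster": a disk of radius 0.42 x the
  frame side, constant across depth, on an exactly-zero background.
  Default 40 sections of 128x128 at 8 bit.
- **Attenuation** — `a(z) = exp(-lambda*z)` applied identically to both
  channels, `lambda` set so the deepest section retains 30% (the severe
  end of observed depth loss in thick-cluster imaging); linear and
  custom factor schedules exist for edge cases.
- **NS pattern** — uniform disk at level 180/255 by default; a
  "nuclei" variant adds brighter blob structures.
- **SOI patterns** — `uniform` (depth-independent, mitochondrial-marker
  style), `top_shell` (top slab plus peripheral annulus at one third
  background level inside, membrane-receptor style), and
  `peripheral_shell` (annulus only).
- **Noise and quantization** — optional additive Gaussian noise acts on
  signal-bearing pixels only, then `clip(round(.))` to the integer
  range. Background stays exactly zero: the zero-exclusion rule
  presumes genuinely empty background, and noisy nonzero background
  counts would pollute the NS mean with a depth-independent term that
  has nothing to do with the proportionality being tested. This is the
  main idealization: real detectors leave low nonzero background
  counts, out-of-focus haze, and spatially varying (not purely
  section-wise) attenuation, so passing these tests demonstrates
  correctness of the computation, not robustness to every acquisition
  artifact.
- **Matched levels** — NS and SOI default to the same base level, which
  makes integer quantization cancel exactly in the SOI/NS-mean ratio;
  noise-free flatness recovery is therefore testable to 1e-6 relative
  rather than being limited by rounding of order 0.5/level.

`expected_flat_profile` returns the analytically expected
post-normalization profile (all 100% for a uniform SOI, occupancy-
proportional for shells). For noisy runs the tolerance band per
section is

    tol(z) = 100 * ( rs(z) + sqrt(2 ln Z) * max_k rs(k) )

where `rs(z)` is the relative standard error of the section's
SOI/NS-mean ratio using per-pixel variance `sigma^2 + 1/12` (noise plus
quantization), propagated through both channels' foreground pixel
counts. The `sqrt(2 ln Z)` extreme-value term accounts for the
percent-of-max normalization dividing by the *noisiest maximum* over
all `Z` sections; measured profiles are expected to stay within a
small multiple (3x) of this band.

## Numerical and interface choices

- Filenames sort natural-numerically (`s2` before `s10`); section order
  is semantically critical and confocal exporters number frames.
- Multichannel frames reduce to grayscale with ITU-R 601 luma weights
  0.299/0.587/0.114, rounded to nearest, treating input channel order
  as RGB (documented; BGR sources would need swapping upstream).
- Coordinates are 0-based with half-open ROIs, `y` = row, `x` = column.
- All randomness flows through a single seed; identical seeds give
  bit-identical phantoms and pipeline outputs, and no command mutates
  its inputs.
- Thresholds gate normalization and the mean statistics only, not the
  projections; whether projections should also be thresholded is a
  genuinely open interface question and was resolved toward "no" to
  keep SNIP a faithful mean projection.

## Problem sizes

The validation suite runs phantoms of 40x128x128 (about 0.65 Mvoxel
per channel), 100 repetitions for the noisy-robustness fraction, 100
random matrices for the scaling contract and 50 random 3x4x4 stacks
for the oracle-equivalence checks — sizes chosen so the full suite and
the acceptance script each complete in seconds while keeping every
per-section statistic well away from small-sample noise floors.

## Known limitations

- A single NS mean per section models attenuation as constant within a
  focal plane; laterally varying attenuation (edge shadowing,
  monolayer interference) is out of scope and is handled operationally
  by ROI cropping.
- The fixed intensity window is applied to every section; true signal
  that falls below the window deep in the sample is excluded from the
  statistics (inherent to fixed-range histogram thresholding).
- No photobleaching kinetics, PSF, or scattering physics in the
  phantoms; no gamma or nonlinear contrast adjustment; no multipage
  hyperstack or vendor bioformat parsing (export TIFF sequences
  first).
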