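# Methods

## Signal model

Each synthetic subject is a 4D series on a shared grid. Brain voxel `v`
carries

    s_v(t) = a_v · L(t − τ_v) + c_v · cos(2π f_card t) + ε_v(t)

where

- `L` is the subject's systemic low-frequency oscillation (sLFO): white
  Gaussian noise whose Fourier components outside 0.01–0.15 Hz are removed,
  then standardized to zero mean and unit variance. Out-of-band power is
  numerically zero by construction.
- `τ_v` is a smooth lag field (Gaussian-filtered white noise, rescaled to
  ±4 s by default), snapped to whole multiples of the TR. Lags are realized
  as whole-TR *circular* shifts of `L`, so the planted lag is exactly
  representable on the analysis lag grid and recoverable without
  interpolation error. The SSS seed strip is forced to lag 0, making the
  extracted seed the phase reference of the lag field.
- `a_v` is the tissue mixing fraction: VA 0.9, GM 0.5, WM 0.15, CSF 0.0.
  These are free parameters — chosen once to respect the vascular-density
  ordering VA > GM > WM with CSF essentially blood-free — not measured
  quantities.
- `c_v` is a cardiac amplitude, nonzero (0.5) only in an inferior "arterial"
  zone where the mixing fraction is forced to 0. At TR 0.72 s the 1.1 Hz
  tone aliases to |1.1 − 1/0.72| ≈ 0.289 Hz, which lies outside the analysis
  band and is therefore largely removed by the band-pass — the zone
  contributes high-amplitude raw voxels that end up with low maxcc, the
  arterial signature the analysis should tolerate.
- `ε_v` is white Gaussian noise, sd 0.5, independent across voxels and
  subjects; voxels outside the brain mask are exactly zero (exercising the
  zero-variance code path). The sd was fixed at 0.5 so that a GM voxel
  (mixing 0.5) has broadband SNR 1 before filtering; after band-passing,
  in-band SNR is substantially higher (the 0.01–0.15 Hz band holds ~20% of
  the white-noise power at this TR).

Geometry is concentric synthetic shapes — WM core (normalized ellipsoidal
radius r < 0.55), GM shell (0.55–0.85), CSF rim (0.85–1.0), plus VA
filaments: two through-brain venous columns and a 20-voxel posterior–superior
SSS strip. The MRA-derived VA class takes precedence over the concentric
labels, so the four tissue classes are pairwise disjoint and stacked
distribution bars sum to 100%. The downstream statistics depend only on mask
membership, so anatomical realism is deliberately not attempted.

Cohorts share geometry; sLFOs, lag fields and noise are independent across
subjects via seeds derived deterministically from one cohort seed.

## Analysis parameters

| parameter | default | notes |
|---|---|---|
| band | 0.01–0.15 Hz | sLFO band; also the ALFF summation band |
| filter | order-3 Butterworth, zero-phase | forward–backward pass squares the magnitude response; reflective padding of 3×2×order samples |
| smoothing | 3 mm FWHM | FSL convention (FWHM, not σ); applied before the temporal filter — both are linear, so the order does not affect results and is recorded in the manifest |
| maxcc threshold | 0.3, strict `>` | compensates the correlation inflation from band-passing and the lag search; no further multiplicity correction |
| lag window | ±6 s, whole-TR grid | TR 0.72 s ⇒ shifts k ∈ [−8, +8] (±5.76 s); truncated-overlap Pearson per lag, re-standardized, no circular wraparound |
| lag tie-break | smallest \|lag\|, then negative | deterministic argmax |
| bins | 10, equal count | remainder voxels go to the lowest bins; ties in map values resolved by x-fastest voxel index (stable sort) |
| ALFF convention | one-sided 2\|X\|/n, band-inclusive | a unit cosine on a bin gives ALFF = 1; any fixed convention rescales the map only, and binning is rank-based |
| ALFF ranking set | all brain voxels | config switch `alff_valid_mode: maxcc_valid` reuses the maxcc validity mask, which makes maxcc and ALFF curves directly comparable |
| swap pooling | all n(n−1) maps as units | config switch for within-subject averaging first |

Degenerate inputs: zero-variance voxels (e.g. outside-brain padding) get
maxcc 0 and are invalid, never an exception; zero-variance slope samples in
the t-tests return a flagged degenerate result (t=0, p=1 for all-zero;
p=0 for identical nonzero values) rather than raising.

## What the phantom does and does not emulate

Emulated: a shared blood-borne oscillation with tissue-graded contribution
and voxelwise delay; venous seed extraction; arterial aliased pulsation;
thermal noise; cohort structure for the swapped-seed control.

Not emulated: neuronal/resting-state network fluctuations, voxel-specific
vascular LFO variability, motion, registration and segmentation error,
anatomical geometry. Consequences worth knowing:

- Real GM/WM slopes are an order of magnitude shallower (≈ ±0.03
  fraction/bin) than the phantom's (≈ +0.13 / −0.09), because real tissue
  classes overlap broadly in sLFO content while the phantom's mixing
  fractions are crisp. Passing slope-sign tests demonstrates the pipeline's
  ordering behavior, not effect-size realism.
- CSF shows no top-decile enrichment in the phantom (in real data it stems
  from segmentation/registration error at GM/VA boundaries, which is not
  modeled), so the bin-10-vs-9 CSF contrast is degenerate on phantoms while
  the VA contrast is strongly positive.
- **Swap-null bias.** Because every GM voxel shares the *same* sLFO
  realization, a swapped map's GM voxels share the single draw
  corr(sLFO_i, sLFO_j): their spurious maxcc values cluster in a narrow
  band, while noise-dominated voxels reach the upper tail independently.
  Per-voxel spurious-rate distributions are tissue-flat (verified by
  Monte-Carlo), but *within the ranked valid set* GM concentrates in low
  bins, giving the swapped GM slope a small systematic negative bias
  (≈ −0.02 fraction/bin pooled over maps). With 56 maps as test units this
  bias is detectable in a sizeable fraction of replicates, so the swap-null
  "flatness" holds only approximately on phantoms. Real data decorrelates
  voxels through voxel-specific in-band variability; adding such variability
  is out of scope here. The true-vs-swapped slope contrast is unaffected and
  decisive in every replicate.
- On clean phantoms many swapped maps have fewer valid voxels than bins at
  the 0.3 threshold (especially on small grids); these maps are reported as
  insufficient and excluded from the swap statistics rather than failing the
  run. A config option can lower the swap threshold instead; lowering it to
  0.2 makes all maps usable but also increases the power with which the
  clustering bias above is detected.

## Numerical choices

- The zero-phase filter's time-reversal symmetry is exact only beyond the
  boundary transient: the 0.01 Hz band edge rings for ~10² s, so edge
  samples differ between forward-then-backward and backward-then-forward
  passes regardless of padding length. Interior symmetry is at machine
  precision and is what the tests assert.
- The filter's magnitude response is validated against the closed-form
  order-3 Butterworth band-pass magnitude with bilinear prewarping,
  |H|² = 1/(1 + w⁶), w = (W² − W₁W₂)/((W₂−W₁)W), W = 2 fs tan(π f / fs);
  time-domain attenuation measurements use lock-in estimation with generous
  transient discard.
- maxcc vectorization iterates lags in tie-break priority order with a
  strict-greater update, which reproduces the per-voxel
  `lagged_pearson` + `max_correlation` semantics exactly; equality with a
  first-principles triple-loop oracle is asserted to 1e−10.
- Equal-count binning sorts stably on the map value with the x-fastest
  linear voxel index as tie-break, so any strictly monotone transform of the
  map yields identical bins.
- Problem sizes: unit tests run on 16×16×8×300 phantoms; the end-to-end
  checks use the default 32×32×16×500 cohort and a 20-replicate swap study
  at 16×16×8×500. These sizes give ≈ 6700 brain voxels (default grid) and
  ≈ 420 voxels per decile, ample for the rank statistics while keeping the
  full suite in a few minutes.

## Known limitations

- Whole-TR lag grid: no sub-TR lag interpolation (the planted truth is also
  whole-TR, so recovery checks are exact by design).
- The SSS ROI is an explicit mask input; no automatic vessel detection.
- No denoising/regression of the sLFO from the data; the pipeline
  characterizes the sLFO content, it does not remove it.
- The cohort t-tests treat swapped maps (default pooling) as independent
  units although maps sharing a data subject are weakly dependent.
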