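# Methods

This note records the models implemented in `rnpstoich`, the parameters that
matter, the design choices made where several defensible options existed, and
what the synthetic-data generator does and does not emulate.

## Coordinate and unit conventions

Positions and lengths are micrometres, times seconds, velocities µm s⁻¹.
Each microtubule's minus end sits at coordinate 0 and positions increase
toward the plus end, so dynein-driven transport decreases the coordinate and
processive velocities are negative. Frame indices are 0-based; segment time
intervals are half-open `[t_start, t_end)`. All tables are tab-separated
text.

## Synthetic trajectories (`simkit`)

The generator emulates particle tracks as they appear after kymograph
digitisation: per-frame point samples of position along the microtubule
axis, corrupted by Gaussian localisation noise. It does **not** model the
imaging chain itself — no point-spread-function fitting, photobleaching,
blinking, motion blur during exposure, or off-axis motion — so passing tests
demonstrate correctness of the downstream statistics, not robustness to
detection or tracking errors.

Defaults describe the reconstituted transport assay: 500 frames at
`frame_interval` 0.5 s (~2 frames s⁻¹), `pixel_size` 0.105 µm,
`localisation_sd` 0.05 µm (roughly half a pixel), microtubules of
15 ± 3 µm, class mixture (static, diffusive, processive) = (0.1, 0.1, 0.8).

Per track: a class is drawn from `class_probs`; attachment time and landing
position are uniform over the movie and the microtubule. Static tracks hold
their position; diffusive tracks are unbiased Gaussian random walks with
`diffusion_coeff` 0.05 µm² s⁻¹; both detach after an exponential attachment
duration (`attach_duration_mean` 10 s — the assay literature gives no
dwell-time distribution, so this is a package choice, set once to yield
mostly-accepted events at the 1.5-s binding threshold). Processive tracks
draw a total run length from an exponential with `run_length_mean` 5 µm and
consume it at piecewise-constant speeds: segment durations exponential with
rate `segment_switch_rate` 0.1 s⁻¹, speeds from a truncated (≥0) normal,
mean 1.0 and sd 0.3 µm s⁻¹ — the truncated normal is a convenience family
chosen for testability, not an empirical claim about motor mechanochemistry.
A particle reaching the minus end arrests there and dwells for
`minus_end_dwell` (default: the remainder of the movie, mirroring the
minus-end accumulation such assays show). Ground truth (class, run length,
segment velocities, arrest and truncation flags) is recorded per track, and
a single seeded `numpy.random.Generator` drives everything, so identical
configurations reproduce identical track sets.

Dye-assignment simulators mirror the two labelling chemistries (binomial
per-polypeptide, Poisson per-RNA) complex by complex, and are checked
against the closed forms below to four binomial standard errors at n = 10⁵.

## Track classification (`motility`)

The scoring thresholds are the assay's manual-analysis conventions, made
explicit and configurable (`ClassifyParams`):

* **Binding event**: ≥ `min_frames` = 3 frames and ≥ `min_duration` = 1.5 s,
  where event duration is `n_frames × frame_interval` (each frame represents
  one sampling interval, so three frames at 2 frames s⁻¹ count as 1.5 s).
* **Processive**: net displacement ≤ −`processive_min_net` (0.5 µm, five
  pixels) toward the minus end *and* directionality |net|/path ≥
  `directionality_min` (0.7). "Without significant diffusive behaviour" is
  not a quantitative rule anywhere, so the directionality ratio is this
  package's operationalisation; both thresholds are exposed.
* **Static**: maximum excursion from the mean position ≤
  `static_max_excursion` (0.15 µm ≈ 2√2 × a 50-nm localisation sigma).
* **Diffusive**: neither of the above.

Before measuring net displacement and path length, stationary leading and
trailing plateaus are trimmed: a plateau is the maximal stretch that never
escapes `static_max_excursion` of the track's first/last level, judged on a
3-point median filter so single noisy frames neither end nor extend it, and
one plateau sample is kept on each side. Without this, the localisation
noise accumulated during a long minus-end arrest dwell inflates the path
length and pushes genuinely processive, end-arrested runs into the diffusive
class — a kymograph scorer plainly counts those as processive. Trimming can
consume at most `static_max_excursion` of true motion at each end, which is
below the noise scale.

Classification is deterministic, invariant to uniform time shifts, and, for
noiseless tracks whose ground truth exceeds the thresholds, reproduces the
generating class exactly (tested). Runs shorter than the binding threshold,
or landing so close to the minus end that their observable displacement is
under 0.5 µm, are information-limited: no threshold-faithful classifier can
score them, and the classified processive fraction of a simulated population
therefore sits a few percentage points below the generating probability
(≈76% observed for an 80% generating mixture at the default conditions).

**Velocity segmentation.** Constant-velocity segments are found by optimal
partitioning: dynamic programming over all segment boundaries with the
within-segment OLS-line residual sum of squares as cost and a per-changepoint
penalty `changepoint_penalty · σ² · log n` (default multiplier 10), where σ
is estimated robustly from second differences (MAD/√6 scaling; second
differences of a piecewise-linear signal are pure noise away from
changepoints). A 10⁻¹² penalty floor makes noiseless tracks resolve to the
fewest segments achieving zero cost, so exact piecewise-linear inputs are
segmented exactly. Minimum segment length is 3 frames; adjacent segments
whose slopes differ by less than `velocity_merge_tol` (0.1 µm s⁻¹) are
merged. The implementation is cross-checked against an exhaustive
single-changepoint least-squares search, and recovers ≥90% (in practice
~100%) of changepoints within ±2 frames at 50-nm noise. Segments with
|v| < `pause_velocity` (0.05 µm s⁻¹) are flagged as pauses and excluded from
velocity summaries while remaining inside the run.

**Run lengths and censoring.** A run length is the magnitude of the total
displacement of the motile portion, pauses and velocity changes included.
Runs enter run-length statistics only if the entire run was observed
(appears after movie start, disappears before movie end, final position
> 0.2 µm from the minus end) or the run began > 5 µm from the minus end, so
that boundary truncation cannot dominate. On simulated exponential runs this
rule removes most of the truncation bias (tested) but not all of it — runs
starting > 5 µm can still be cut by the microtubule end, so a small downward
bias (≈5–9% at 5-µm runs on 20-µm microtubules) remains; this matches the
rule's intent of bias *reduction* with a simple criterion. The distribution
is summarised by least squares on the empirical survival curve,
`1 − CDF(x) = exp(−x/λ)`; the sample mean (the maximum-likelihood estimate)
is the test oracle, and group comparisons should use raw run lengths, not λ.
Fits require ≥10 runs; degenerate inputs (fewer than 3 distinct values)
return the sample mean flagged `poorly_conditioned`.

**Background correction.** Event counts from microtubule-free coverslip
regions (sampled at the median microtubule length) are averaged, scaled
linearly to each microtubule's length, subtracted, and floored at zero.
Linear scaling generalises equal-length sampling with the same expectation.

**Co-localisation.** Tracks from two channels on the same microtubule are
co-transported if, over common frames, positions agree within `max_gap`
(0.21 µm = 2 pixels) for ≥ `min_overlap_fraction` (0.5) of the shorter
track's frames; matching is greedy by agreement score with each track used
once. Both thresholds are configuration choices standing in for manual
scoring.

## Labelling models and copy-number inversion (`stoichiometry`)

Closed forms are exact (inclusion–exclusion over independent polypeptides;
Poisson detection for RNA) and are verified in tests against brute-force
enumeration of all 3^k outcome combinations. Observed fractions are
conditioned on detection (≥1 dye), matching what the assay can see; the
unconditional dual probability is also exposed because the 40%
obligate-dimer figure is conventionally quoted unconditionally (0.405, vs
0.409 detected-conditional). Copy-number support is {1, 2} — the
dimer/monomer framework of this assay; the k-copy forward model accepts any
k ≥ 1 but mixtures beyond two components are out of scope.

Inversions are closed-form and clipped to [0, 1]; an observed dual fraction
above the two-copy maximum returns 1 with an `out_of_model` flag rather than
an error. Forward∘inverse is the identity to 10⁻¹² across the admissible
range (tested). Confidence intervals propagate an interval on the observed
dual fraction through the monotone inversion: the default is a seeded
multinomial bootstrap over complexes (1000 resamples, percentile interval);
a Wilson score interval is available as a closed-form alternative. With 300
complexes at a true two-copy fraction of 0.9, the estimator's mean error is
< 0.03 and 95% intervals cover the truth in ≥ 90% of replicates (tested).

The dye split `q_dyeA` defaults to 0.5 but is a parameter, since real dye
batches are balanced empirically. Labelling efficiency and mean dyes per RNA
are inputs measured by spectrophotometry, not estimated here. Two same-colour
RNAs in one particle are scored single-colour (intensity is not used).

## Statistical comparisons (`pipeline`)

`compare_conditions` dispatches to Student's t, Welch's t, or Mann-Whitney
(two-sided), reporting the statistic, p-value and group means; Welch's
type-I error under the null is calibrated in the test suite. No
multiple-comparison machinery is included.

## Problem sizes and determinism

Simulation-based tests use 200–600 tracks per condition and Monte-Carlo
checks use 10⁴–10⁵ complexes with 4-SE bands — sizes at which the asserted
effects are resolvable with comfortable margins on a single CPU in seconds.
Every stochastic component takes an explicit seed; the pipeline derives all
stage seeds from one configured value, and reports carry a provenance block
(config hash excluding output paths, seed, package version) so identical
configurations produce byte-identical report bodies.

## Known limitations

* Tracks are point samples; exposure-time blur and detection dropouts are
  not modelled, so classifier robustness to tracking artefacts is untested.
* The attachment-duration, pause and minus-end-dwell distributions are
  package choices, not measured quantities.
* The run-length survival fit assumes a one-phase exponential; multi-phase
  decays will be summarised by a single effective scale.
* Background correction assumes spatially homogeneous off-microtubule
  binding.
* Crossing or overlapping trajectories are assumed already resolved by the
  upstream digitisation; no tracker is included.
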