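# rnpstoich

Analysis tools for reconstituted single-molecule mRNA-transport assays:
classification and kinetic quantification of particle tracks on microtubules,
and copy-number inference for the proteins and RNA of the transport machinery
from dual-colour labelling experiments.

## The problem

In a minimal reconstitution of dynein-based mRNA transport, fluorescent RNA,
the adaptor proteins that link it to the motor (an Egl-type RNA-binding
protein and a dimeric BicD-family coiled-coil adaptor), dynein and dynactin
are combined on surface-immobilised microtubules and imaged by TIRF
microscopy at ~2 frames s⁻¹ with 105-nm pixels. Two quantitative questions
follow:

1. **Motility.** Which microtubule-binding events are processive (directed,
   minus-end-ward), static, or diffusive? How fast are the
   constant-velocity stretches of a run, and how long are run lengths once
   boundary truncation is accounted for?
2. **Stoichiometry.** How many copies of each protein — and how many RNA
   molecules — does an active transport complex carry? The assay observable
   is the fraction of motile complexes showing *both* of two spectrally
   distinct dyes after mixed labelling.

`rnpstoich` implements both analyses plus a synthetic-data generator that
reproduces the statistical structure the analyses assume, so the full
pipeline runs and is testable at desk scale with no imaging data.

## Models at the core

**Binomial SNAP labelling.** Each of the *k* polypeptides of a complex
carries a dye with probability *p* (labelling efficiency); a labelled
polypeptide is dye A with probability *q*, else dye B. By
inclusion–exclusion,

    P(dual)  = 1 − (1−pq)^k − (1−p(1−q))^k + (1−p)^k

For a dimer at *p* = 0.9, *q* = 0.5 this gives 0.405 (~40% dual), against
0.50 at complete labelling. A mixture with two-copy weight φ shows a
detected-conditional dual fraction φ·dual₂ / (φ·det₂ + (1−φ)·det₁) with
det_k = 1 − (1−p)^k, which inverts in closed form to estimate φ from an
observed dual fraction.

**Poisson RNA body labelling.** Each RNA carries Poisson(μ) dyes of its
preparation's colour (μ ≈ 3), so it is detected with probability
L = 1 − e^(−μ). For particles holding one or two RNAs drawn from an
equimolar two-colour mix (colour-A probability *a*), the dual fraction among
detected particles is

    f₂·2a(1−a)L² / [(1−f₂)·L + f₂·(1−(1−L)²)]

At μ = 3 and *a* = 0.5, an observed dual fraction of 14% inverts to
f₂ ≈ 0.30: 30% of particles with two RNAs, 70% with one.

**Track classification.** A track is a binding event if it spans ≥3 frames
(≥1.5 s); it is processive if, after trimming stationary attachment/arrest
plateaus, it moves ≥0.5 µm net toward the minus end with a net/path
directionality ratio ≥0.7; static if it never strays >0.15 µm from its mean
position; diffusive otherwise. Velocities come from penalised
piecewise-linear changepoint segmentation; run lengths are total
displacements, pauses included, restricted to runs that were fully observed
or started >5 µm from the minus end; the run-length distribution is
summarised by a least-squares fit of exp(−x/λ) to the empirical 1 − CDF.

## Worked example

```python
import rnpstoich as rs

# 500 synthetic tracks, 80% generated processive, 50-nm localisation noise
cfg = rs.SimConfig(n_tracks=500, class_probs=(0.1, 0.1, 0.8), seed=1)
ts = rs.simulate_trackset(cfg)
events = rs.classify_trackset(ts)

frac = rs.motility_fractions(events)
print(frac[frac.mt_id == "pooled"].to_string(index=False))
runs = rs.extract_run_lengths(events)
print(f"eligible runs: {len(runs)}, run-length scale: {rs.fit_decay(runs).scale:.2f} um")

counts = rs.DualColourCounts(n_dual=39, n_A_only=31, n_B_only=30)
est = rs.infer_two_copy_fraction(counts, p_label=0.9, random_state=1)
print(f"two-copy fraction: {est.two_copy_fraction:.3f} "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
```

prints

```
 mt_id  n_events  fraction_processive  fraction_static  fraction_diffusive
pooled       393              0.75827         0.132316            0.109415
eligible runs: 224, run-length scale: 4.94 um
two-copy fraction: 0.949 (95% CI 0.689-1.000)
```

Of the 500 simulated tracks, 393 qualify as binding events; 75.8% of those
are classified processive (slightly below the generating 80% because
sub-threshold runs — shorter than 3 frames, or starting too close to the
minus end to achieve 0.5 µm of observable displacement — cannot be scored).
The censored run-length fit recovers the generating 5-µm mean. The
dual-colour counts (39% dual at 90% labelling efficiency) invert to a
two-copy fraction of ~0.95: essentially every complex carries a protein
dimer.

The same analyses are available from a shell:

```sh
rnpstoich simulate --out out --seed 1
rnpstoich kinetics --tracks out/tracks.tsv --out out
rnpstoich stoich --counts counts.tsv --model snap --p-label 0.9 --out out
```

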