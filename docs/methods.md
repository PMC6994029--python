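# Methods

This note documents the models, conventions and numerical choices behind
`picover`, and what the synthetic validation does and does not demonstrate.

## Measurement model

A measurement is a deterministic pipeline over an 8-bit RGB image:

1. **Crop** to a rectangular ROI; a physical crop (e.g. 1 mm²) is resolved
   through the image's µm/pixel scale, rounded to the nearest whole pixel.
2. **(Optional) contrast stretch** of each channel: clip values are chosen
   from the histogram so that at most half of `saturated_fraction` of the
   pixels falls below/above them (the conventional recommendation is 1%
   total, split equally between tails), then [low, high] is mapped linearly
   to [0, 255]. The map is monotone, so it changes thresholds but never the
   relative order of pixels.
3. **HSB conversion** (hexcone model): brightness = max(R,G,B), saturation
   = (max−min)/max, hue = sector angle, each scaled to bytes. Hue of
   achromatic pixels is defined as 0; saturation bands exclude achromatic
   pixels whenever that convention could matter. For linearized workflows,
   sRGB→CIELAB (IEC 61966-2-1 gamma decode, D65/2°) is provided instead;
   L* is byte-scaled from [0,100] and a*/b* are offset by +128 (the byte
   packing is an internal convention).
4. **Threshold**: an automatic selector picks a byte cut t on the brightness
   histogram, with the fixed convention *foreground = values > t*. Dark
   pigment on a white background is therefore the brightness PASS band
   [0, t]; light pigment on black is [t+1, 255]. Transparency uses no
   automatic selector: a circular hue band around the background colour
   (green ≈ 85, blue ≈ 148 on the byte circle) plus a saturation floor
   (default S ≥ 30, so achromatic glare is never counted as background).
5. **Particle analysis**: connected components of the mask (8-connectivity
   by default, labels in raster order), optional area filter (default
   min 1 px — no size exclusion), and

   PiC = Σ areas / ROI area,

   computed in integer arithmetic before the final division. Particles
   touching the ROI border are kept by default, since real covers include
   edge chromatosomes.

Every result row carries the bands actually applied, so a manual
(`MANUAL`) measurement is exactly reproducible from its output.

## Threshold selectors

* **IsoData / intermeans** — the fixed point of
  t ← round((μ_{≤t} + μ_{>t})/2). The update rounds halves down, which
  prevents oscillation between 127/128 on histograms symmetric about
  127.5; iteration starts at the midpoint of the occupied range, is capped
  at 256 steps, and t is clamped so both classes stay non-empty.
* **Default** — the same fixed-point update initialised at the rounded
  mean of the occupied extremes; on typical histograms it coincides with
  IsoData. This is the pipeline default.
* **Maximum entropy (Kapur–Sahoo–Wong)** — argmax over t of the summed
  Shannon entropies of the two class-conditional normalized histograms
  (natural log, 0·log 0 := 0, ties to the smallest t). The implementation
  is an exhaustive scan, so it equals brute-force search by construction.

Single-occupied-bin histograms are rejected as degenerate, and all
selectors are invariant to uniform scaling of the counts.

**A caution on maximum entropy.** On a histogram whose modes are separated
by an empty gap, every cut inside the gap scores identically (neither
class changes), so Kapur's objective is decided at the mode edges — and a
faint, spread-out noise tail adjacent to a gap is entropy-rich, so the
argmax systematically absorbs one mode's tail instead of cutting mid-gap.
On synthetic scenes whose background is a near-uniform spike this
misassigns up to several percent of the pixels (and can even split a broad
pigment mode); the intermeans selectors, which cut at the average of the
two class means, are immune. This is why the pipeline default is the
intermeans "Default" selector and why maximum entropy — useful on images
with broad, balanced modes — should be chosen per image set after checking
it against the histograms at hand.

## CI and the PiC ~ CI model

The Chromatophore Index of a region is the mean Hogben–Slome class
(1–5) of its chromatosomes. When dispersion is high enough that individual
chromatosomes overlap and cannot be counted, the region takes the maximum
index 5 — the saturation that motivates PiC in the first place.

PiC responses live in (0, 1) and are modelled with a beta regression:
PiC ~ Beta(μφ, (1−μ)φ), g(μ) = β₀ + β₁·CI, with g one of logit,
log, or log–log (taken as g(μ) = −ln(−ln μ), the convention of the
standard beta-regression software). Fitting is maximum likelihood:

* responses exactly 0 or 1 are first compressed with
  y* = (y(n−1) + 0.5)/n (the beta likelihood is undefined on the
  boundary); the compression is logged;
* starting values are OLS of g(y) on the predictor for β (each link on its
  own scale — a logit-scale start would be systematically wrong for the
  log and log–log links) and a method-of-moments estimate for φ;
* optimization is Nelder–Mead on (β₀, β₁, ln φ) with tight tolerances;
  invalid parameter regions (μ outside (0,1)) are penalized. The descent
  is deterministic, so refits of the same data are bit-identical;
* AIC = −2·loglik + 2·3, and pseudo-R² is the squared Pearson correlation
  between g(y*) and the fitted linear predictor (again the convention of
  the standard software).

The fit agrees with the independent statsmodels `BetaModel` implementation
to ~1e−6 in log-likelihood on test data. Link selection fits all three
links and ranks by AIC, with exact ties broken in the fixed order logit,
log, log–log.

The published shrimp calibration ln PiC = −3.362 + 0.659·CI is exposed by
`predict_pic_from_ci`, restricted to its stated validity domain
1 ≤ CI ≤ 5 and clamped to [0, 1] (clamping at CI = 5 does not occur:
exp(−0.067) ≈ 0.935).

## Comparison statistics

* **Friedman test** (inter-observer variation): within-block mid-ranks,
  tie-corrected form χ² = (k−1)·Σ(R_j − n(k+1)/2)²/(A − C), df = k−1.
  Unlike the common implementations this form also handles k = 2
  treatments, where it reduces to (Σ signs)²/n. A fully tied table with at
  least two distinct values returns χ² = 0; a constant table is rejected.
* **Wilcoxon signed-rank** (paired background comparison): zero
  differences dropped, mid-ranks of |d|, tie-corrected variance, normal
  approximation *without* continuity correction, reported as a signed Z
  with two-sided p. An exact enumeration variant is available
  (`method="exact"`, ≤ 20 pairs).
* **Linear concordance** (sRGB vs linearized measurements): OLS of y on x,
  reported as (slope, intercept, r²); slope ≈ 1 indicates the two
  pipelines agree up to an offset.

Asymptotic p-values of rank tests at very small n are coarse; the test
suite checks them against exhaustive permutation enumeration to the
resolution of the exact null distribution's atoms.

## Synthetic scenes

The generator emulates the structure of tail-fan photographs used in
shrimp colour-change work: a uniform background (white (255,255,255),
black, green (0,170,0) or blue (0,90,200) — the chromatic pair chosen
strongly saturated so hue-band transparency is well posed), dark
star/disk-shaped chromatosomes, and additive i.i.d. Gaussian camera noise
(default σ = 8 grey levels) applied after the ground-truth mask is frozen,
so the true cover is exact by construction.

Morphology convention: class 1 is a disk of 0.25·`base_radius`; classes
2–5 add `n_branches` radial rays of length scale(class)·`base_radius`
with the strictly increasing multipliers {0.25, 0.45, 0.65, 0.85, 1.0},
tapering from a quarter-radius half-width at the centre to ~1 px at the
tip. With a fixed centre and orientation, the class-k footprint is a
subset of the class-(k+1) footprint (longer rays only widen the taper at
any given distance), so cover is provably monotone in dispersion class —
the geometric skeleton of the CI-saturation argument: at high density
every chromatosome is class 5, mean CI is pinned at its ceiling, while
cover keeps varying with abundance and overlap.

Randomness: each scene in a simulated dataset gets its own generator
spawned from (seed, scene index), so any scene is reproducible in
isolation and prefixes of a dataset do not depend on its length.

What the simulator does **not** emulate: partial-transparency edges and
semi-transparent pigment, illumination gradients (available as an
optional linear ramp, default off), shot noise, vignetting, chromatic
camera response, or the irregular outlines of real chromatosomes. Passing
the synthetic recovery checks therefore demonstrates the correctness of
the segmentation arithmetic under the stated noise model — not robustness
to every property of real photographs, which is exactly why the protocol
retains per-image-set selector checks and optional manual band adaptation.

## Problem sizes in the validation suite

The simulation-based checks use sizes chosen to give stable statistics at
desk scale: 200 replicates of n = 50 for coefficient recovery (matching
the size of the original 50-image comparison), 100 seeds of n = 200 for
link selection, 50 rendered 200×200 scenes spanning covers ≈ 0.05–0.93
for end-to-end recovery, and exhaustive enumeration (≤ 8 blocks/pairs) for
the rank statistics.
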