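# Methods

## The detection model

`cnvscale` calls copy-number variants from a single per-base depth-of-coverage
track `c[i]`, with no matched control. The premise is that a CNV is a plateau
in expected depth — elevated for a gain, depressed for a loss — whose width is
unknown a priori, so no single smoothing window can both suppress noise and
resolve small events. The caller therefore builds a Gaussian scale-space: the
signal is smoothed at every scale `sigma_k = sigma0 * ratio^k`
(defaults `sigma0 = 1000` bp, `ratio = 1.1`, `l = 60` layers, i.e. 1 kb to
~277 kb), and events are searched at all scales simultaneously.

The pipeline is:

1. **Median filter** (window `w+1 = 151`). Suppresses isolated depth spikes
   without blurring CNV edges; `w` is ~15% of the smallest CNV of interest.
   On low-coverage integer tracks the filter is computed by cumulative
   counting over depth levels, which is exact and O(n) per level.
2. **Gaussian decomposition** into layers `c[i,k]`.
3. **Finger-print map**: per layer, the second-order difference
   `c'' [i,k] = c[i+1,k] - 2c[i,k] + c[i-1,k]` and its zero-crossing signal
   `z[i,k]` (+1 where `c''[i+1,k] > 0` and `c''[i-1,k] < 0`, −1 for the
   mirrored signs, 0 otherwise). Crossings bound concave-up/concave-down
   intervals; as `sigma` grows they can only disappear, never appear.
4. **Per-layer baselines**: the plain mean `m(k)` and population SD
   `delta(k)` of the layer define a normal range `m ± 2 delta`; the
   *effective* statistics `m*(k)`, `delta*(k)` are recomputed over the values
   inside that range, so the CNVs themselves are (ideally) excluded from the
   background estimate. The detection band is `m* ± d delta*` with `d = 3`.
5. **Top-down interval search**: for each layer with at least one crossing
   pair, coarsest first, every pair of *adjacent* opposite-sign crossings
   whose enclosed layer mean escapes the band is a putative CNV — above the
   band a gain, below it a loss. Its two boundaries are traced down the
   contour to layer 0 (greedy nearest same-sign crossing in the next layer,
   search radius `ceil(3 sigma_k)`, ties to the left), and the traced region
   becomes the call's coordinates. A candidate whose traced region overlaps
   any already-declared region is discarded, so each genomic region hosts at
   most one call and large CNVs (found at coarse scales) shadow their own
   fragments at finer scales.
6. Calls shorter than `min_call_length = 500` bp are dropped as
   sub-resolution artifacts of the `sigma0 = 1000` base scale.

The call score is `|mean - m*| / delta*` at the detection layer (reported in
BED as `100 * score`, capped at 1000).

### Choices the definitions leave open

* **"More than two non-zero elements"** for layer eligibility is read as
  *at least two*: an interval needs exactly two boundaries, and requiring
  three would veto a layer containing exactly one CNV.
* **Same-layer exclusion.** Region exclusion is stated across layers; we also
  add each accepted interval to the exclusion set immediately, so two
  candidates of one layer cannot map to overlapping traced regions. This is
  what makes the final call set provably pairwise disjoint.
* **Annihilated contours.** When a trace finds no same-sign crossing within
  the search radius in the layer below (the contour closed between the
  detection layer and layer 0, as happens when two nearby CNVs merge at
  coarse scale), the trace keeps its current position and continues.
* **Degenerate traces.** If the two traces of an interval cross
  (`l' >= u'`), the candidate is discarded.
* **Typing** uses the layer-`k` mean over the *untraced* interval, while the
  reported coordinates are the traced ones.
* The zero-crossing stencil consults `c''[i-1]` and `c''[i+1]` but not
  `c''[i]`; a sign change between two samples therefore marks *both* flanking
  positions. These double marks are harmless to the search (the adjacent
  opposite-sign pairing uses the inner positions); where crossings are
  counted (causality monitoring) adjacent same-sign marks are grouped into
  one event. For the same reason the raw mark sequence of a layer need not
  alternate in sign — a one-sample curvature excursion can suppress one
  mark of a pair — but grouped events on smooth curvature do alternate.

## Numerical design

**Spectral evaluation.** Convolution is done in the frequency domain. Two
transfer functions appear in the package, deliberately:

* `convolve_spectral` (the contract-level operation) multiplies by the DFT of
  the *truncated, renormalised sampled* kernel (`m = 3 sigma` taps per side),
  which makes it bit-comparable to `convolve_direct` on any input — each
  route is the other's oracle.
* the production engine multiplies by the *analytic periodized Gaussian*
  `G(w) = exp(-w^2 sigma^2 / 2)`.

The distinction matters more than it looks. The truncated kernel's cutoff
discontinuity (`g(3 sigma) ≈ 0.0111 / (sigma sqrt(2 pi))`) acts like a pair
of delta functions in the kernel's second difference, injecting *white* noise
of amplitude `~ sqrt(2 lambda) g(3 sigma)` into the curvature of a smoothed
depth track. Genuine curvature of smoothed noise falls as `sigma^-2.5` while
this term falls only as `sigma^-1`; they cross near `sigma ≈ 20` bp, so at
the caller's operating scales (1 kb and up) a truncated-kernel curvature
field would be pure truncation noise. The analytic transfer has no cutoff and
is numerically band-limited, which keeps the curvature meaningful at every
scale.

**Curvature in the frequency domain.** Even with a clean transfer, the second
difference of a heavily smoothed layer lies up to ~14 orders of magnitude
below the layer values, far under float64 round-off of the inverse FFT.
The engine therefore multiplies the spectrum by the exact circular
second-difference factor `2 cos(w) - 2` *before* inverse transforming, so the
round-off of the result is relative to the curvature itself. Differencing
after the transform would bury the coarse layers in numerical sign noise.

**Scale-adaptive decimation.** A layer smoothed at scale `sigma` is
band-limited to `|w| ≲ 12 / sigma` in practice, so it is fully determined by
samples every `sigma/1000` positions (a vastly denser grid than needed).
Each layer is evaluated on a power-of-two stride near `sigma / 1000`
(stride 1 for `sigma < 2000`, capped so at least ~4096 samples remain) by
inverse-transforming only the occupied low-frequency block at reduced
length — mathematically exact subsampling for a band-limited spectrum.
Layers are grouped by power-of-two FFT length with a reflect pad of
~3.5 sigma (capped at `2n`; beyond that the periodized Gaussian correctly
drives the layer to the padded-signal mean), one forward transform per
group. A 60-layer decomposition of a 1 Mbp track takes ~1.5 s on one core.
Crossing positions are reported in base coordinates (`stride *` sample
index); the per-layer snap error is at most the stride, i.e. ≤ sigma/1000,
and is erased as the trace re-snaps on each finer layer.

**Padding** is half-sample symmetric (`numpy` "symmetric"): the even periodic
extension makes a unit-sum symmetric kernel conserve the interior mean
exactly, so every layer of a constant signal is exactly constant and layer
means match the signal mean to round-off.

**Spurious-crossing guard.** In the dense (textbook) path,
`build_fingerprint_map` treats second differences below `1e-12` of the
layer's peak as zero, so exactly flat layers computed through an FFT yield
empty maps. The production engine needs no such guard.

## The simulation benchmark

The generator emulates a shotgun-sequencing benchmark at two levels.

*Sequence level* (`make_sequences`, `simulate_reads`): a uniform-random ATCG
reference of length `n` (default 1 Mbp); a test sequence with tandem-
duplicated gains, deleted losses, SNPs (default 1/kb, always to a different
base) and short indels (default 1/10 kb, ≤ 10 bp, outside CNVs); paired
36 bp reads drawn uniformly at fold coverage C (insert 200 ± 20 bp) with
per-base error rate E.

*Coverage level* (`simulate_coverage`): the depth track is drawn directly.
Read starts form a Poisson process with rate `C * rho(E) * r(x) / 36` per bp
and each read adds one unit of depth over 36 bp, so depth at any base is
marginally Poisson with mean `C * rho(E) * r(x)` while retaining the 36 bp
span autocorrelation of aligned reads. That autocorrelation is not a
nicety: a 151-point median of *independent* sub-unit-mean Poisson draws is
almost surely zero, which would erase the signal below ~1x coverage, whereas
span-correlated depth behaves like a median of ~5 effective values and
keeps the coverage contrast, as real alignments do.

`rho(E) = P[Binomial(36, E) <= 2]` models aligner attrition — a read with
more than 2 mismatches is unmapped and lost. `rho(0.02) = 0.9650`,
`rho(0.10) = 0.2879`: a 10% error rate silently turns a 1x experiment into
an effective 0.29x one, which is the dominant difficulty of the high-error
cells.

The copy ratios default to **gain 2.0 / loss 0.0**, mirroring the haploid
substitution semantics of the sequence level (a deleted region yields no
reads; a tandem duplication doubles the dosage mapped onto its reference
locus). A diploid single-copy-change model (1.5 / 0.5) is a configuration
away.

The CNV size pool is a synthetic 17-length geometric ladder
(1024 … 70613 bp) constructed to match the published summary statistics of
the benchmark's candidate set exactly (min 1024, max 70613, total 318750,
mean 18750 bp); the individual lengths are not public. Each replicate
plants 10 of the 17 without replacement, uniformly placed, disjoint, typed
gain/loss by fair coin.

**What the generator does not emulate:** GC bias, mappability structure of a
real reference (repeats, multi-mapping), quality-dependent error profiles,
insert-size artifacts. Passing benchmarks here demonstrate the detector's
statistical behaviour under idealised coverage, not performance on real
libraries.

## Scoring

FNR/FPR are base-pair rates: every base is classified by intersecting calls
with truth. `FNR = 100 fn / (tp + fn)`; `FPR = 100 fp / (fp + tn)` with
non-CNV bases as denominator (a called-bases denominator is available).
Type-strict matching is the default: a gain called over a planted loss
recovers nothing and counts against both rates. Sweeps derive per-replicate
seeds deterministically from a master seed and the cell/replicate indices.

## Known limitations

* **Small CNVs.** With `sigma0 = 1000` and `d = 3`, an event of length `L`
  at copy contrast `h` contributes an interval-mean deviation of roughly
  `h * L * 0.68 / (2 sigma0)` at the finest layer; events below ~1.5–2 kb
  fall under the `3 delta*` band at any realistic coverage and are
  undetectable. At the benchmark's size mix this imposes an FNR floor of
  roughly 0.5–1% whenever the 1–2 kb pool members are drawn.
* **Baseline breakdown under heavy contamination.** The `m ± 2 delta` trim
  isolates the background only while the one-sided CNV fraction `f` of the
  genome satisfies `(1-f) > 2 sqrt(f(1-f))`, i.e. `f < 20%`. On a 1 Mbp
  genome the benchmark plants ~19% CNV mass on average; replicates whose
  random typing concentrates most of that mass on one side cross the
  threshold, the trimmed SD stays contaminated at every layer, and most
  events in such replicates are missed. This is a property of the
  trimmed-baseline design at high planted density, not of the
  implementation; at a several-fold lower CNV fraction (larger genome, same
  planted set) the trim operates in its intended regime.
* **Merged neighbours.** Two large same-type CNVs closer than the scale at
  which they are detected can be declared as one interval spanning the gap;
  the exclusion rule then prevents their separate re-detection at finer
  layers.
* **Boundary precision** is noise-limited to roughly ±100–300 bp at the
  default base scale (inflection jitter of the sigma = 1 kb layer plus up to
  ±75 bp of median-filter shift). For events not much larger than `sigma0`
  there is also a *systematic* outward displacement even without noise: the
  inflections of a smoothed boxcar of half-width `a` solve
  `(x+a) phi((x+a)/sigma) = (x-a) phi((x-a)/sigma)`, which puts the layer-0
  crossings ~200 bp outside the true edges of a 2 kb event at
  `sigma0 = 1000` (150 bp at 2.2 kb, 31 bp at 3 kb, negligible beyond
  ~5 kb). Tracing cannot undo this: layer 0 is the finest scale there is.
* Depth is modelled per contig; multi-contig data are processed one contig
  at a time, and no GC or mappability correction is applied.
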