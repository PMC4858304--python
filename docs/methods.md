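# Methods

`dropstat` implements the end-point statistical analysis of droplet digital
PCR (dPCR): categorizing droplet fluorescence into negative, positive, and
"rain" populations; Poisson quantification of the mean target occupancy per
partition; transgene:endogene ratio estimation with Fieller confidence
intervals; assay performance parameters with acceptance limits; and the
in-silico studies that motivate those limits. This note describes the
models, the defaults, and the numerical choices.

## Statistical model of a digital PCR reaction

A reaction is split into `n_t` partitions; target molecules distribute
across partitions as a Poisson process with mean occupancy λ. With `n_⊖`
negative partitions after end-point read-out,

    p̂₀ = n_⊖ / n_t        λ̂ = −ln p̂₀

and the 95% confidence bounds on λ̂ are

    λ̂ ± 1.96 · sqrt((n_t − n_⊖) / (n_t · n_⊖)).

Copy concentration follows from the partition volume (copies/µl = λ̂ /
v_partition). The transgene:endogene copy ratio ("GM ratio", in haploid
genome equivalents) is r̂ = λ̂_tr / λ̂_en; it needs no volume.

Reactions assumed to share λ may be *merged* by summing their positive and
negative counts; `merge_reactions` is exactly `estimate_poisson` on the
pooled counts. Saturated reactions (no negatives) raise an error whose
message suggests merging, rather than returning an infinite estimate. The
all-negative boundary returns λ̂ = 0 flagged one-sided, with an upper bound
computed from one phantom positive partition (the bound formula is
undefined at the boundary; one positive is the smallest detectable
departure).

### Fieller ratio intervals

Each λ̂ is treated as approximately normal with standard error equal to its
Poisson confidence half-width divided by 1.96, independent between
channels. The 95% interval for the ratio a/b with standard errors (s_a,
s_b) is the classic Fieller segment

    [ (r ± (z/b)·sqrt(s_a² + r²·s_b² − g·s_a²)) / (1 − g) ],
    r = a/b,  g = (z·s_b/b)²,  z = 1.96.

When g ≥ 1 (the denominator interval reaches 0) the interval is not a
finite segment; the result is flagged unbounded. As both standard errors
shrink, the interval converges to the delta-method interval and ultimately
to the point ratio (verified in tests).

### Replicate-based intervals

Poisson bounds describe partition-sampling variability only. The full
analytical chain adds dilution and preparation variance (σ²_total ≈
σ²_Pois + σ²_prep), which dominates at high occupancy, so Poisson
intervals under-cover there and merging makes the under-coverage worse.
`replicate_ci` implements the recommended alternative: quantify the sample
as two sub-samples analysed in duplicate (A₁, A₂, B₁, B₂) and report
mean ± 1.96·sd over the per-reaction estimates (sample sd, n−1). The
synthetic replicate study in the acceptance suite reproduces the contrast:
with 5% preparation noise at λ = 3, replicate intervals cover the true
occupancy far more often than Poisson intervals.

## Droplet categorization

The classifier takes the per-droplet end-point fluorescence as its only
input.

1. **Density estimation.** Gaussian KDE with bandwidth
   `max(50, bw.nrd0)` — 50 fluorescence units is a floor below which
   instrument noise produces spurious modes; `bw.nrd0` is Silverman's
   rule, `0.9·min(sd, IQR/1.349)·n^(−1/5)`. Evaluated on a 512-point grid
   extended three bandwidths past the data range. Constant input raises a
   degenerate-input error.
2. **Peak finding.** A point is a peak if it is the density maximum within
   a sliding window spanning 1/20 of the fluorescence range and exceeds 1%
   of the global maximum (the window fraction and prominence floor are
   parameters). Flat-topped runs collapse to their center.
3. **Seeding populations.** With ≥ 2 peaks, the lowest peak seeds the
   negative population and the highest the positive; interior peaks count
   as extra populations (they fail the single-amplification-product
   criterion and are never merged into the positives). With one peak, the
   peak is negative when it lies below the grid midpoint plus one
   bandwidth, else positive — the bandwidth of slack breaks the exact tie
   that occurs for a lone cloud (its data range is symmetric around it),
   and the bias toward "negative" is deliberate: an all-negative well is
   the common single-population case and the opposite miscall would invert
   every count. Initial scale is half the peak width at 60.65% of peak
   height — the exp(−1/2) level, which for a Gaussian falls exactly one σ
   from the mode. Note the KDE convolution inflates this seed by the
   bandwidth in quadrature; the refinement step removes that bias.
4. **Robust refinement** (3 iterations, enough for first-decimal
   stability): select droplets within μ ± a·σ (a = 4 initially); update μ
   ← median, σ ← 1.4826·MAD, k ← Pearson (non-excess) kurtosis of the
   members; update the bound multiplier

       a = 4.55 + 0.35·ln k + 0.045·(ln k)²,

   an empirical map from kurtosis to the number of robust σ needed to
   cover ~99% of a population (a(3) ≈ 4.99 for Gaussian clouds; heavier
   tails widen the bounds). Natural logarithm and non-excess kurtosis are
   the consistent reading: excess kurtosis would put ln(0) at normality.
   k is floored at 1.05 against tiny-sample pathologies, which also keeps
   a ≥ 4.57. Windows with fewer than 5 members freeze the estimates and
   set a fallback flag.
5. **Threshold and rain.** The quantification threshold is
   θ = μ_n + 1.5·a_n·σ_n, strictly above the negative population's upper
   bound, placed to make miscounting a negative droplet as positive
   vanishingly rare. Droplets between the negative upper bound and the
   positive lower bound are labelled rain. Rain droplets overwhelmingly
   contain target (their counts track the positives across dilution
   series), so quantification counts are set by θ alone — the bulk of the
   rain lies above θ and counts positive — and rain is reported separately
   for QC. If the population bounds overlap, or θ lands inside the
   positive population, the offending boundary/threshold is replaced by
   the kernel-density minimum between the peaks and `fallback_used` is
   set.

Classification is invariant under affine rescaling of the fluorescence
axis up to the fixed bandwidth floor (tested).

## Assay performance parameters

Measured at the validation condition λ ≈ 0.7 (about half the partitions
positive, so rain and dispersion are visible without one population
dwarfing the other; the pass window is declared as λ̂ ∈ [0.5, 0.9] since no
tolerance is standard):

* **Single amplification product** — exactly two fluorescence populations.
  Co-amplified products appear as interior populations and fail this
  check.
* **Resolution** — Rs = 2·(t_p − t_n)/(w_p + w_n) with t the population
  center and w the base width 2·a·σ (the population range limits are its
  peak base). Rs = 2 is complete separation; the limit Rs ≥ 2.5 leaves
  headroom for degraded samples. Strict at the boundary: 2.49 fails.
* **Rain** — n_rain/n_t ≤ 2.5%. The limit comes from the worst-case
  budget below.
* **Compartmentalization** — accepted volume over loaded volume
  (n·v_partition/v_loaded): ≥ 30% for quantification down to 1% analyte,
  ≥ 50% down to 0.5% (level selected by the plate config).
* **Dynamic range** — measured copies must fall inside the platform's
  bootstrap range (below).

## In-silico studies

**Optimal load.** The relative CI width `2·1.96·sqrt((n−n₀)/(n·n₀))/λ`
with expected negatives n₀ = n·e^(−λ) is minimized at the root of
λ = 2·(1 − e^(−λ)), λ* ≈ 1.594, independent of n. At 0.85 nl partitions
this is ≈ 1 870 copies/µl; at 6 nl, ≈ 265 copies/µl.

**Misclassification tolerance.** If a share f of all partitions are true
transgene positives relabelled negative (endogene exact), the observed
positive fraction is p′ = p − f and the ratio error is
(λ_tr − (−ln(1−p′)))/λ_tr. Inverting at 25% error gives the closed form
f* = e^(−0.75·λ_tr) − e^(−λ_tr); f is defined on all partitions, the only
reading that yields the canonical droplet counts (658 of 20 000 at
λ_en = 3 and a 5% ratio; 146 at 1%; 50 at λ_en = 1 and 1%; 15 at 0.1%).
The **hidden-rain budget** assumes a worst case where 10% of rain is
concealed inside the negative cloud and thus always misclassified: the
reaction then tolerates 1/0.10 times the misclassification budget in
total rain — 50 × 10 = 500 droplets ≈ 2.5% of 20 000 at the 1% level with
λ_en = 1, the origin of the rain limit.

**Dynamic range bootstrap.** For each λ on a log grid, 2 000 bootstrap
reactions draw negatives ~ Binomial(n, e^(−λ)); repeats are combined by
pooling counts (averaging observed empty fractions). Pooling, rather than
averaging per-repeat λ̂, is deliberate: with λ̂-averaging a single
saturated repeat (λ̂ undefined, counted as failure) makes the upper bound
*shrink* as repeats are added, while pooling widens the range at both
ends — upper bound ≈ ln(n·r/3) — which is both the behaviour a
practitioner exploits and the published behaviour of such tables. The
range bounds are the outermost occupancies at which ≥ 95% of bootstraps
quantify within 25% relative error.

Numerical details that matter here: the true error-fraction curve is
*saw-toothed*, because the acceptable negative count is an integer window
that jumps along the grid. The curve is therefore smoothed with a small
(5-point) moving average — wide enough to damp bootstrap noise
(sd ≈ 0.5 pp at 2 000 boots), narrow enough to keep the genuine dips of
the sawtooth — and the bounds are read as the first/last grid point at or
below the 5% level, refined by log-interpolation. A strictly monotone
(isotonic) smooth was rejected: it pools the final sub-5% dip of the
sawtooth into the preceding hump and clips the upper bound by ~7% on
small-partition systems. Default grids put 75 log-spaced points around the
analytic crossings (≈ 60 expected positives at the low end, ≈ 3 expected
negatives at the high end, totals across pooled repeats), spanning ×2
below/above at the low end and ×1.5 at the high end, i.e. ~1–2% grid
resolution; the crossing cannot be localized finer than the smoothing
window (~5 grid steps). Bootstrap draws with zero negatives count as
exceeding the error criterion (conservative). For a 20 000-partition
single reaction the range is λ ∈ (≈0.0030, ≈8.8), i.e. ≈61–176 000 copies;
for 765 partitions (≈0.083, ≈5.5). The lower bound of small-partition
systems is resolution-limited: near the crossing the sawtooth teeth are
spaced ~2% in λ with amplitude ~1 pp, so estimates of that bound carry a
few-percent irreducible spread (quantified against the exact binomial
curve during development).

**Sub-sampling.** A duplex reaction on a QX200-like platform (23 530
droplets of 0.85 nl from 20 µl) is simulated with only a fraction of the
generated droplets accepted: full positive counts are binomial, the
accepted subset hypergeometric, and the ratio is re-estimated from the
subset; 10 000 bootstraps per point; subsets with no positives or no
negatives on either channel count as failures. At λ_en = 3 and 1% analyte,
30% compartmentalization keeps P(ratio error > 25%) well under 5%,
supporting the 30%/50% compartmentalization limits.

## Synthetic data generator

`synth` emulates the statistical structure of droplet read-outs, not PCR
kinetics: per-droplet occupancy is Poisson(λ); empty droplets draw from
the negative fluorescence cloud, occupied droplets from the positive
cloud, except a `rain_fraction` share drawn uniformly over the gap
between the cloud edges (μ ± 4σ) — matching the roughly uniform spread of
real rain — and an optional interior population emulating a co-amplified
product. Clouds are two-component normal scale mixtures: a `tail_weight`
share at 3× scale raises kurtosis above 3, as commonly observed in real
fluorescence populations; `tail_weight = 0` gives exactly Gaussian clouds.
Defaults (20 000 droplets, centers 1000/5000, scales 100/150, λ = 0.7)
describe a clean validation-condition run on a droplet platform.

Replicate studies draw each dilution's occupancy as λ·(1+ε),
ε ~ N(0, σ_prep) truncated at 0, and give each repeat within a dilution
one further independent (1+ε) preparation factor — each repeat is a
separately pipetted reaction mix, and without per-repeat noise the
repeat-to-repeat spread would be Poisson-only and replicate intervals
could not capture preparation variance at all. σ_prep has no established
value; it is a free parameter (0.05 is used in the coverage study).

What passing tests on this generator do *not* show: robustness to drifting
baselines, correlated droplet volumes, non-uniform rain shapes, or
multi-channel crosstalk — none of which the generator emulates (droplet
volume is treated as constant throughout).

## Reproducibility and problem sizes

All stochastic routines take explicit integer seeds and are
bit-reproducible; a single root seed expands into independent per-reaction
streams, so studies can be regenerated reaction-by-reaction. The shipped
studies use the canonical sizes: 2 000 bootstraps × 75-point grids for the
dynamic range, 10 000 bootstraps for sub-sampling, 48 dilutions × 4
repeats for the coverage study, 100 seeds for classifier parameter
recovery, and 2 000 simulated duplex reactions for Fieller coverage.

## Known limitations

* One fluorescence channel per classification; duplex analysis classifies
  each channel independently (no 2-D cluster calling).
* The 1.5·a·σ threshold distance is treated as a universal default; the
  original calibration was data-set specific.
* The dynamic-range bounds of small-partition systems (hundreds of
  partitions) are irreducibly fuzzy at the few-percent level — see the
  sawtooth discussion above.
* Vendor cluster labels are parsed and retained but never consulted.
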