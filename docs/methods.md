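# Methods

## Model

Genus richness per time bin is modeled as

    N(t) = Γ_SN(t) · (A(t)/A₀)^α + ε(t),

with Γ_SN the exponential-memory supernova forcing

    Γ_SN(t) = c ∫₋∞^t SN(t′) exp(−(t−t′)/λ) dt′,

λ ∈ [10, 40] Myr the diversity rebound time scale, α the species–area
exponent (default 0.8, the inter-province regime), and A(t)/A₀ the
relative shallow-marine shelf area. All ages are Ma before present,
larger = older; every curve, bin scheme and output follows that
convention.

The package estimates N(t) from occurrence data, reconstructs
(A(t)/A₀)^α by two routes, evaluates Γ_SN, and correlates the two sides
of the rearranged model N·(A/A₀)^(−α) = cΓ + ε′ over a (λ, α) grid.

## Diversity estimation

Occurrence records (genus, class, collection, age interval, optional
paleolatitude) are filtered to a fourteen-class major-marine-animal
list, optionally restricted by hemisphere or to the open tropics band
(−30, 30) — paleolatitude exactly 0 belongs to neither hemisphere —
and assigned to time bins. The default binning rule ("contained") keeps
a record only if its age interval lies entirely inside one bin;
"midpoint" assignment is available. The default bin scheme is uniform
5-Myr bins; stage-level schemes can be loaded from CSV.

Coverage-standardized richness (shareholder quorum subsampling): within
a bin, occurrences are drawn without replacement in uniform random
order; a genus contributes its frequency share to a running coverage on
first appearance; drawing stops once coverage reaches the quorum
q (default 0.5), and richness is the number of genera seen. The mean
and SD over 1000 trials give the curve and its error bars. Bins with a
single occurrence return richness 1 with SD 0; empty bins are missing,
not zero.

By default the frequency shares are multiplied by Good's coverage
estimate u = 1 − singletons/occurrences, so the quorum is expressed in
estimated *true* coverage. Without this correction the quorum refers to
sample coverage and the estimate acquires a systematic dependence on
per-bin sampling intensity (clearly visible on constant-richness
simulations), which is exactly the failure mode subsampling is meant to
remove; the correction is also the default behaviour of the standard
SQS implementations in the field. The flag can be switched off, as can
a dominant-genus exclusion (off by default). If the quorum exceeds the
attainable coverage (e.g. an all-singleton bin under the correction),
the bin falls back to raw richness with a warning.

Implementation: trials use an exact distributional shortcut. In a
uniform random permutation of occurrences, the order in which genera
first appear is distributed as the ascending order of independent
exponential keys with rate N_g (genus g's count), because the minimum
of N_g i.i.d. uniform keys decides g's first appearance and minima
commute with monotone maps. Richness at the stopping draw depends only
on that first-appearance order, so a trial costs O(#genera) rather than
O(#occurrences). The test suite verifies the shortcut against exact
enumeration over all draw orders for every composition with ≤ 7
occurrences. Collection-unit subsampling (drawing whole collections) is
implemented as a direct permutation loop.

Classical rarefaction at fixed occurrence count n is provided both as a
Monte-Carlo subsampler and as the exact hypergeometric expectation
E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)].

Per-bin RNG streams are derived from (seed, bin index), so a bin's
result does not depend on which other bins are evaluated.

## Shelf area

Route 1 (sea level): with the hypsometric gradient k = 2.02×10⁸ km²/km,
A = k·σ, where σ is sea level above the zero-area datum. The datum is
fixed by the present-day shallow-marine area A₀ (default 2.7×10⁷ km²,
configurable), giving σ₀ = A₀/k ≈ 134 m; curves quoted relative to
present are shifted by +σ₀. Then (A/A₀)^α = (σ/σ₀)^α. Exxon/Haq-style
sea-level curves overstate amplitudes by about a factor of two and can
be rescaled (default factor 0.5 when enabled; the rescale is applied
before normalization). Base ratios at or below 0.05 are clipped and
logged so later normalization cannot divide by ~0.

Route 2 (paleogeographic maps): fractional shallow-marine-area series
per region, normalized to their youngest value. Both routes store the
α = 1 ratio and the exponent separately, so grid scans re-exponentiate
without reloading.

Resampling between grids is linear interpolation with endpoint values
held (and a warning) outside the support. The comparison grid is always
the diversity bin midpoints — the scarcest series — with area and
forcing interpolated onto it.

## Forcing

Γ_SN is evaluated on a uniform 1-Myr age grid. The integral is
discretized by the trapezoid rule with the kernel *normalized* so that
Γ = c·λ·(kernel-weighted mean of SN): the discrete operator is exact on
constants (steady state Γ = cλ·SN), linear, converges to the continuous
integral as the step shrinks, and remains meaningful even when λ is
comparable to the grid step. The finite record is padded beyond its
oldest point with the oldest value and the pad's infinite exponential
tail is added in closed form, so the −∞ lower limit introduces no
truncation error; the first ~2λ of the output can be flagged as burn-in
but is not dropped by default. A direct double-loop oracle in the test
suite reproduces the operator to 1×10⁻¹².

The scale c is not identified by the model and defaults to the
least-squares fit through the origin, c = Σγy/Σγ², recomputed per
comparison and recorded in outputs.

Uncertainty propagation: the SN curve's 1σ band feeds a Monte-Carlo
envelope (normal perturbations clipped at zero, or scaled-count Poisson
resampling matched to the stated variance); the band is the per-age
mean ± SD over draws around the unperturbed Γ.

## Correlation and the (λ, α) scan

Pearson r between the area-normalized diversity and Γ, on paired
non-missing bins (≥ 4 required). Variance explained is exactly 100·r².
The default 1σ interval is the Fisher z-transform with SE 1/√(n−3); a
Monte-Carlo alternative perturbs both sides (per-bin diversity SD;
SN noise model, with Γ recomputed per draw) and takes the 16th/84th
percentiles. Neither interval claims to reproduce any externally
published interval construction, which is under-specified; no
autocorrelation correction is applied by default, though a lag-1
effective-sample-size adjustment is available.

The grid scan evaluates every (diversity curve, area source, λ, α)
cell: re-exponentiate the area, normalize, evaluate Γ at λ, fit c,
correlate. Zero-variance forcing (constant SN) yields flagged rows with
NaN r rather than an exception. `ScanResult.rank_of` reports the
1-based rank of any cell within a curve's rows.

The regional test normalizes each region's diversity by its own area
history and compares the across-region dispersion before and after:
the statistic is the mean over ages of the across-region SD of curves
first scaled by their own time-mean, making regions of different
absolute richness comparable (the package's choice; the raw curves
could equally be compared by shape). An optional linear trend, fit by
least squares to the residual between the mean normalized curve and
the scaled forcing, can be added to the forcing outline.

## Synthetic data generator

The generator runs the model forward to occurrence level with recorded
ground truth. Defaults are the study conditions; where a quantity had
to be invented it was set once to a value realistic for this record and
is documented here.

* **SN history**: 1 + 12 Gaussian bumps (amplitude SD 0.5, widths
  10–60 Myr), clipped positive and renormalized to mean 1, with a 15%
  proportional 1σ band. This reproduces the observed character of
  open-cluster-based reconstructions: relative rates spanning roughly
  0.3–1.9 with jagged 10–20 Myr features. (Amplitude matters: a much
  smoother history makes the λ cells of the scan nearly
  indistinguishable.)
* **Sea level**: Gaussian-bump curve (amplitude SD 100 m, widths
  30–100 Myr) anchored to 0 at present, floored at 0.2σ₀ —
  Haq-scale swings. Global map fractions are derived from this curve
  through the hypsometric relation (so the two global area routes agree
  by construction); NH/SH/tropics fractions multiply the global one by
  independent smooth factors (SD 0.3).
* **Richness truth**: N = round(c·Γ_λ·(A/A₀)^α·e^η), floored at 1,
  with log-normal noise η (SD = noise_cv, default 0.1) — multiplicative
  because richness is positive and its errors scale with level. Truth
  defaults: λ = 20 Myr, α = 0.8, c = 6 (≈ 120 genera per bin), 100
  5-Myr bins over 0–500 Ma.
* **Sampling**: a persistent genus pool with 20% per-bin turnover;
  geometric relative abundances with shape parameter θ = 6 *scaled to
  pool size* (shares ∝ e^(−θi/G)), so the abundance profile — not the
  evenness — is richness-invariant and coverage-standardized richness
  stays proportional to true richness; Poisson occurrence counts with
  log-uniform intensity spanning a 10× heterogeneity factor around a
  mean of 2700 occurrences/bin (the per-bin scale of the real
  major-animal extract); grouping into ~5-occurrence collections dated
  by intervals jittered inside the bin; paleolatitudes drawn inside the
  region's band. An `exhaustive` flag guarantees every pool genus at
  least one occurrence (the infinite-intensity limit), used by
  noise-free end-to-end tests.

What the generator does *not* emulate: birth–death phylogenetic
structure, taphonomic and lithologic biases beyond intensity
heterogeneity, taxonomic synonymy noise, spatially structured sampling,
or autocorrelated residual noise. Passing recovery tests therefore
show that the pipeline's machinery is correct and that the scan can
recover its own generating parameters at realistic noise and sampling
levels — not that the real fossil record satisfies the model.

### Problem sizes in the shipped studies

The recovery study uses 50 replicates of the default configuration
(100 bins, 3×3 grid); the regional study 20 replicates over three
regions; the sampling-standardization contrast uses constant richness
2400 (c = 120 under flat forcing), which places occurrences-per-genus
in the realistic unsaturated regime of fossil sampling at the default
intensity — at the default richness of 120 the record is effectively
exhaustively sampled and raw richness is insensitive to sampling, a
regime that needs no standardization and demonstrates nothing. The
acceptance script runs 20 recovery replicates and 5 regional seeds.

## Numerical choices

* Coverage comparisons use ≥ with a 10⁻¹² tolerance; draw-order ties
  have probability zero under the exponential-key construction.
* Trial SDs use ddof = 1; a single trial reports SD 0.
* Fisher intervals clip |r| at 1 − 10⁻¹⁵ before the z-transform.
* The zero-variance guard in the correlation treats a relative SD
  below 10⁻¹² as constant (the discretized Γ of a constant SN is
  constant only to machine precision).
* Area base ratios are clipped at 0.05 (logged); sea levels below the
  zero-area datum clip to zero area in the hypsometric helper.
* Derived per-bin RNG streams come from `SeedSequence([seed, bin_i])`;
  the pipeline's single seed determines every stochastic stage.

## Known limitations

* The (λ, α) scan compares Pearson correlations, not a likelihood; the
  α axis in particular is weakly constrained (coverage-standardized
  richness compresses the diversity scale slightly — log-log slope
  ≈ 0.95 against truth — biasing the preferred α a few percent low).
* The regional dispersion statistic assumes comparable bin coverage
  across regions; regions with many empty bins propagate NaNs into the
  across-region SD, which is then averaged over the remaining ages.
* Correlation intervals ignore temporal autocorrelation unless the
  effective-sample-size adjustment is requested.
* The collection-unit subsampler is a reference implementation (plain
  Python loop) and is markedly slower than the occurrence-unit path.
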