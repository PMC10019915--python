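# paleosn

Tools for testing whether the long-term history of nearby supernovae
left a trace in Phanerozoic marine biodiversity, once changes in the
area of shallow marine shelves are accounted for.

## The scientific problem

Genus-level diversity of marine animals over the last ~500 Myr is shaped
by at least two slow drivers:

1. **Shelf area.** Most marine benthic life lives on flooded continental
   shelves. The species–area law, N ∝ A^α with α ≈ 0.8 for
   province-scale areas, predicts that diversity tracks the relative
   shelf area (A(t)/A₀)^α. Shelf area itself follows sea level through a
   linearized hypsometric relation A = k·σ with k = 2.02×10⁸ km²/km.
2. **Supernova-modulated climate.** The local core-collapse supernova
   rate SN(t) modulates the cosmic-ray flux and, through it, climate and
   ocean nutrient circulation. Because biodiversity can respond only to
   *past* forcing, with a rebound time scale λ of 10–40 Myr, the relevant
   quantity is the exponential-memory functional

   Γ_SN(t) = c ∫₋∞^t SN(t′) · exp(−(t−t′)/λ) dt′.

The combined model is N(t) = Γ_SN(t)·(A(t)/A₀)^α + ε(t). Dividing
diversity by the area factor isolates the astrophysical side,
N(t)·(A(t)/A₀)^(−α) ≈ Γ_SN(t), which is tested by Pearson correlation
over a grid of (λ, α) values.

Diversity itself must first be estimated from a heterogeneously sampled
fossil record. The package implements coverage-standardized subsampling
(shareholder quorum subsampling at quorum q, with Good's-u coverage
correction and 1000 subsampling trials per bin) and classical
rarefaction, applied to Paleobiology-Database-style occurrence tables.

Because the archived inputs of the original study live in external
repositories, the package ships a forward simulator that generates
fossil occurrence tables, sea-level curves, regional shelf-area
fractions, and supernova-rate curves from the model above with known
ground truth, so the entire pipeline is testable offline — including
recovering (λ, α) from synthetic data.

## Worked example

Simulate a 500-Myr global fossil record with truth λ = 20 Myr, α = 0.8,
build the coverage-standardized diversity curve, normalize by shelf
area, and scan the (λ, α) grid:

```python
import paleosn as p

cfg = p.GeneratorConfig(seed=42)
ds = p.gen_dataset(cfg)
binned = p.bin_occurrences(ds.occurrences["global"], cfg.scheme())
div = p.diversity_curve(binned, p.QuorumConfig(seed=42), method="sqs")
area = p.area_from_fraction(ds.fractions["global"], cfg.true_alpha)
scan = p.grid_scan({"global": div}, {"maps": area}, ds.sn)
best = scan.best()
print(scan.rows[["lambda_Myr", "alpha", "r", "var_explained_pct"]]
      .round(3).to_string(index=False))
print(f"best cell: lambda={best['lambda_Myr']:g} Myr, "
      f"alpha={best['alpha']:g}, r={best['r']:.3f} "
      f"({best['var_explained_pct']:.1f}% variance explained)")
```

Output:

```
 lambda_Myr  alpha     r  var_explained_pct
       10.0    0.6 0.895             80.042
       10.0    0.8 0.909             82.683
       10.0    1.0 0.916             83.974
       20.0    0.6 0.920             84.619
       20.0    0.8 0.926             85.794
       20.0    1.0 0.926             85.730
       40.0    0.6 0.872             76.051
       40.0    0.8 0.867             75.230
       40.0    1.0 0.858             73.570
best cell: lambda=20 Myr, alpha=0.8, r=0.926 (85.8% variance explained)
```

Each row is one (λ, α) cell: the correlation r between the area-
normalized diversity curve and Γ_SN at that λ, with 100·r² as variance
explained. The scan peaks at the generating values (λ = 20 Myr,
α = 0.8): the truth cell is recovered. (At α the surface is shallow —
0.8 and 1.0 are nearly tied here, which mirrors how weakly the data
constrain the species–area exponent.)

The same pipeline runs from the shell:

```sh
paleosn simulate --config run.yaml
paleosn scan     --config run.yaml
paleosn regional --config run.yaml   # NH/SH/tropics convergence test
paleosn recover  --config run.yaml   # compare scan argmax to the truth
```

To analyse real data instead, point the config's `inputs:` block at
occurrence CSVs (PBDB flat-file columns), a sea-level CSV
(`age_Ma, level_m`), fractional-area CSVs (`age_Ma, fraction, region`)
and a supernova-rate CSV (`age_Ma, rate, sigma`).

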