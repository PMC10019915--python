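"""Forward simulation of the diversity model down to occurrence data.

The generative chain mirrors the scientific model end to end: a smooth
relative supernova-rate history SN(t) drives the exponential-memory
forcing Gamma(t); a smooth sea-level history sets the relative
shallow-shelf area A(t)/A0; true genus richness per time bin is

    N(t) = round( c * Gamma(t) * (A(t)/A0)^alpha * exp(eta_t) ),

with multiplicative log-normal noise eta (richness is positive and its
errors scale with level).  Fossil sampling is then emulated at the
occurrence level: a persistent genus pool with per-bin turnover, a
geometric relative-abundance profile, Poisson occurrence counts whose
intensity varies across bins by a heterogeneity factor (some bins are
10x better sampled than others), grouping into collections, and age
jitter inside each bin.  Every generated table round-trips through the
package's own readers, and the (lambda, alpha, c) truth is recorded for
parameter-recovery tests.

The abundance profile is held fixed *relative to pool size* (the
geometric parameter is abundance_param / pool size), so richer bins are
not automatically more even and coverage-standardized richness stays
proportional to true richness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import (OccurrenceTable, TimeBinScheme, MAJOR_MARINE_TAXA,
                          ConfigurationError)
from .area import AreaCurve, SeaLevelCurve, sigma0_from_area, DEFAULT_ALPHA
from .forcing import SNRateCurve, exp_memory_forcing

logger = logging.getLogger(__name__)

_TAXA = sorted(MAJOR_MARINE_TAXA)

#: Paleolatitude bands used to tag generated occurrences per region.
_LAT_RANGES = {"global": (-60.0, 60.0), "NH": (2.0, 65.0),
               "SH": (-65.0, -2.0), "tropics": (-28.0, 28.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the forward model; defaults are the study conditions.

    Span 0-500 Ma in 5-Myr bins (100 bins); truth lambda = 20 Myr,
    alpha = 0.8, multiplicative noise CV 0.1.  Sampling: 2700 occurrences
    per bin on average with a 10x heterogeneity factor, geometric
    abundance shape parameter 6 (relative to pool size), collections of
    ~5 occurrences, 20% genus-pool turnover per bin.
    """

    age_oldest: float = 500.0
    age_youngest: float = 0.0
    bin_width: float = 5.0
    true_lambda: float = 20.0
    true_alpha: float = DEFAULT_ALPHA
    true_c: float = 6.0
    noise_cv: float = 0.1
    sn_knots: int = 12
    sn_bump_amp: float = 0.5
    sn_sigma_frac: float = 0.15
    sealevel_knots: int = 8
    sealevel_bump_amp: float = 100.0
    region_mult_amp: float = 0.3
    mean_occurrences: float = 2700.0
    heterogeneity: float = 10.0
    abundance_param: float = 6.0
    collection_mean: float = 5.0
    pool_turnover: float = 0.2
    exhaustive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0 <= self.pool_turnover <= 1:
            raise ConfigurationError("pool_turnover must be in [0, 1]")
        for name in ("bin_width", "true_lambda", "true_alpha", "true_c",
                     "mean_occurrences", "heterogeneity", "abundance_param",
                     "collection_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.sn_knots < 3:
            raise ConfigurationError("sn_knots must be >= 3")

    def scheme(self) -> TimeBinScheme:
        return TimeBinScheme.uniform(self.age_oldest, self.bin_width,
                                     self.age_youngest)


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated fossil record."""

    scheme: TimeBinScheme
    richness: np.ndarray           # per bin, old -> young
    lam: float
    alpha: float
    c: float
    region: str = "global"

    def __post_init__(self) -> None:
        self.richness = np.asarray(self.richness, dtype=np.int64)
        if np.any(self.richness < 1):
            raise ConfigurationError("true richness must be >= 1")

    def to_sidecar(self, path) -> None:
        """Key-value text sidecar for recovery tests."""
        payload = {
            "true_lambda_Myr": self.lam, "true_alpha": self.alpha,
            "true_c": self.c, "region": self.region,
            "bin_labels": self.scheme.labels,
            "richness": self.richness.tolist(),
            "bin_age_older_Ma": [b.age_older for b in self.scheme.bins],
            "bin_age_younger_Ma": [b.age_younger for b in self.scheme.bins],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_sidecar(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            p = json.load(fh)
        from .occurrences import TimeBin
        scheme = TimeBinScheme([
            TimeBin(l, o, y) for l, o, y in
            zip(p["bin_labels"], p["bin_age_older_Ma"],
                p["bin_age_younger_Ma"])])
        return cls(scheme, np.array(p["richness"]), p["true_lambda_Myr"],
                   p["true_alpha"], p["true_c"], p.get("region", "global"))


def _bumps(grid: np.ndarray, n: int, amp: float, width_range: tuple,
           rng: np.random.Generator) -> np.ndarray:
    """Sum of random Gaussian bumps over the age grid."""
    total = np.zeros_like(grid)
    lo, hi = grid[0], grid[-1]
    for _ in range(n):
        center = rng.uniform(lo, hi)
        width = rng.uniform(*width_range)
        total += rng.normal(0.0, amp) * \
            np.exp(-0.5 * ((grid - center) / width) ** 2)
    return total


def gen_sn_curve(cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> SNRateCurve:
    """Smooth positive relative SN-rate history, renormalized to mean 1,
    with a 1-sigma band equal to a fixed fraction of the rate."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    grid = np.arange(cfg.age_youngest, cfg.age_oldest + 0.5, 1.0)
    rate = 1.0 + _bumps(grid, cfg.sn_knots, cfg.sn_bump_amp, (10.0, 60.0),
                        rng)
    rate = np.clip(rate, 0.05, None)
    rate = rate / rate.mean()
    return SNRateCurve(grid, rate, sigma=cfg.sn_sigma_frac * rate)


def gen_sealevel_and_areas(cfg: GeneratorConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[SeaLevelCurve, dict[str, pd.DataFrame]]:
    """Sea level plus consistent regional fractional-area series.

    The global fraction is proportional to the flooded-shelf area implied
    by the linearized hypsometric relation applied to the sea level, so
    the two global reconstructions coincide by construction; regional
    fractions multiply the global one by smooth region-specific factors.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    grid = np.arange(cfg.age_youngest, cfg.age_oldest + 0.5, 1.0)
    sigma0 = sigma0_from_area()
    level = _bumps(grid, cfg.sealevel_knots, cfg.sealevel_bump_amp,
                   (30.0, 100.0), rng)
    level = level - level[0]  # relative to present
    sigma = np.clip(level + sigma0, 0.2 * sigma0, None)
    level = sigma - sigma0
    sealevel = SeaLevelCurve(grid, level)

    frac_global = 0.15 * sigma / sigma0
    fractions: dict[str, pd.DataFrame] = {}
    for region in ("global", "NH", "SH", "tropics"):
        if region == "global":
            frac = frac_global
        else:
            mult = 1.0 + _bumps(grid, cfg.sealevel_knots,
                                cfg.region_mult_amp, (40.0, 120.0), rng)
            frac = frac_global * np.clip(mult, 0.2, None)
        fractions[region] = pd.DataFrame(
            {"age_Ma": grid, "fraction": frac, "region": region})
    return sealevel, fractions


def area_from_fraction(frac: pd.DataFrame, alpha: float,
                       region: str = "global") -> AreaCurve:
    """AreaCurve (base normalized at the youngest age) from a generated
    fractional-area frame."""
    df = frac.sort_values("age_Ma")
    f = df["fraction"].to_numpy(float)
    return AreaCurve(df["age_Ma"].to_numpy(float), f / f[0], alpha=alpha,
                     region=region, source="maps")


def gen_true_richness(cfg: GeneratorConfig, sn: SNRateCurve,
                      area: AreaCurve,
                      rng: np.random.Generator | None = None,
                      region: str = "global") -> SyntheticTruth:
    """Per-bin true richness from the forward model (rounded, floored
    at one genus)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    scheme = cfg.scheme()
    mid = scheme.midpoints
    fc = exp_memory_forcing(sn, cfg.true_lambda, c=1.0)
    gamma = np.interp(mid, fc.ages, fc.gamma)
    base = area.resampled(mid).base
    eta = rng.normal(0.0, cfg.noise_cv, size=mid.size) \
        if cfg.noise_cv > 0 else np.zeros(mid.size)
    n_true = np.round(cfg.true_c * gamma * base ** cfg.true_alpha *
                      np.exp(eta))
    return SyntheticTruth(scheme, np.maximum(n_true, 1).astype(np.int64),
                          cfg.true_lambda, cfg.true_alpha, cfg.true_c,
                          region=region)


def gen_occurrences(truth: SyntheticTruth, cfg: GeneratorConfig,
                    rng: np.random.Generator | None = None,
                    region: str | None = None) -> OccurrenceTable:
    """Sample a fossil occurrence table from a richness truth.

    Genus pools persist between bins with ``pool_turnover`` replacement;
    relative abundances follow a geometric profile with parameter
    abundance_param / pool size; per-bin occurrence counts are Poisson
    with log-uniform intensity spanning the heterogeneity factor;
    occurrences are grouped into collections of ~collection_mean and
    dated by intervals jittered inside the bin.  With ``cfg.exhaustive``
    every pool genus is guaranteed at least one occurrence (the
    infinite-intensity limit with a cap).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    region = region or truth.region
    lat_lo, lat_hi = _LAT_RANGES[region]
    counter = 0
    pool: list[str] = []
    taxon_of: dict[str, str] = {}

    def fresh() -> str:
        nonlocal counter
        name = f"G{counter:05d}"
        taxon_of[name] = _TAXA[rng.integers(len(_TAXA))]
        counter += 1
        return name

    half_h = np.sqrt(cfg.heterogeneity)
    frames = []
    coll_counter = 0
    for b, n_true in zip(truth.scheme.bins, truth.richness):
        n_true = int(n_true)
        # turnover, then resize the persistent pool to the bin's richness
        n_replace = int(round(cfg.pool_turnover * len(pool)))
        if n_replace:
            drop = rng.choice(len(pool), size=n_replace, replace=False)
            keep = np.ones(len(pool), bool)
            keep[drop] = False
            pool = [g for g, k in zip(pool, keep) if k]
            pool += [fresh() for _ in range(n_replace)]
        if len(pool) < n_true:
            pool += [fresh() for _ in range(n_true - len(pool))]
        elif len(pool) > n_true:
            keep_idx = rng.choice(len(pool), size=n_true, replace=False)
            pool = [pool[i] for i in sorted(keep_idx)]

        shares = np.exp(-cfg.abundance_param *
                        rng.permutation(n_true) / n_true)
        shares /= shares.sum()
        intensity = cfg.mean_occurrences * np.exp(
            rng.uniform(-np.log(half_h), np.log(half_h)))
        n_occ = rng.poisson(intensity)
        genus_idx = rng.choice(n_true, size=n_occ, p=shares) \
            if n_occ else np.empty(0, np.int64)
        if cfg.exhaustive:
            genus_idx = np.concatenate([np.arange(n_true), genus_idx])
        if genus_idx.size == 0:
            continue
        genus_idx = rng.permutation(genus_idx)

        # chunk into collections of ~Poisson(collection_mean)
        n = genus_idx.size
        est = int(np.ceil(n / cfg.collection_mean)) + 8
        sizes = np.maximum(1, rng.poisson(cfg.collection_mean, size=est))
        while sizes.sum() < n:
            sizes = np.concatenate(
                [sizes, np.maximum(1, rng.poisson(cfg.collection_mean,
                                                  size=8))])
        n_coll = int(np.searchsorted(np.cumsum(sizes), n) + 1)
        sizes = sizes[:n_coll]
        sizes[-1] -= sizes.sum() - n
        ends = np.sort(rng.uniform(b.age_younger, b.age_older,
                                   size=(n_coll, 2)), axis=1)
        lats = rng.uniform(lat_lo, lat_hi, size=n_coll)
        coll_ids = np.repeat(np.arange(coll_counter + 1,
                                       coll_counter + 1 + n_coll), sizes)
        coll_counter += n_coll
        pool_arr = np.array(pool)
        genera = pool_arr[genus_idx]
        frames.append(pd.DataFrame({
            "genus": genera,
            "higher_taxon": [taxon_of[g] for g in genera],
            "collection_id": coll_ids,
            "age_max": np.repeat(ends[:, 1].round(4), sizes),
            "age_min": np.repeat(ends[:, 0].round(4), sizes),
            "paleolat": np.repeat(lats.round(3), sizes),
        }))
    cols = ["genus", "higher_taxon", "collection_id", "age_max", "age_min",
            "paleolat"]
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=cols)
    return OccurrenceTable(df[cols])


@dataclass
class SyntheticDataset:
    """Everything one simulated study needs, with its ground truth."""

    cfg: GeneratorConfig
    sn: SNRateCurve
    sealevel: SeaLevelCurve
    fractions: dict[str, pd.DataFrame]
    truths: dict[str, SyntheticTruth]
    occurrences: dict[str, OccurrenceTable]


def gen_dataset(cfg: GeneratorConfig,
                regions: tuple[str, ...] = ("global",)) -> SyntheticDataset:
    """Run the full forward model for the requested regions.

    All regions share one SN history (one forcing) and one sea level but
    have distinct area histories; each region's richness truth and
    occurrence table are generated from its own area curve.
    """
    rng = np.random.default_rng(cfg.seed)
    sn = gen_sn_curve(cfg, rng)
    sealevel, fractions = gen_sealevel_and_areas(cfg, rng)
    truths, occs = {}, {}
    for region in regions:
        area = area_from_fraction(fractions[region], cfg.true_alpha, region)
        truths[region] = gen_true_richness(cfg, sn, area, rng, region=region)
        occs[region] = gen_occurrences(truths[region], cfg, rng,
                                       region=region)
    return SyntheticDataset(cfg, sn, sealevel, fractions, truths, occs)
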