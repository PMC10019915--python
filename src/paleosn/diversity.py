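"""Sampling-standardized genus richness per time bin.

Two estimators are provided alongside raw richness:

* **Coverage-standardized subsampling** (shareholder quorum subsampling,
  SQS): occurrences are drawn without replacement in uniform random order;
  each genus, on first appearance, contributes its frequency share
  (count / total occurrences) to a running *coverage*; drawing stops as
  soon as coverage reaches the quorum ``q``, and the trial's richness is
  the number of genera seen.  Repeating over many trials gives a mean
  richness at equal coverage rather than equal sample size.

* **Classical rarefaction**: richness in random subsamples of a fixed
  number of occurrences, with the exact hypergeometric expectation
  available in closed form.

The Monte-Carlo SQS loop is implemented through an exact distributional
shortcut: in a uniform random permutation of occurrences, the order in
which genera first appear equals the ascending order of independent
exponential keys with rate equal to each genus's occurrence count, and
richness at the stopping draw depends only on that first-appearance
order.  This makes a trial O(#genera) instead of O(#occurrences).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .occurrences import BinnedOccurrences, ConfigurationError

logger = logging.getLogger(__name__)

_COVERAGE_TOL = 1e-12


@dataclass(frozen=True)
class QuorumConfig:
    """Configuration for coverage-standardized subsampling.

    Parameters
    ----------
    q : float
        Coverage quorum in (0, 1).
    trials : int
        Number of subsampling trials (>= 1).
    unit : {"occurrence", "collection"}
        Sampling unit: single occurrences, or whole fossil collections.
    goods_u_correction : bool
        Multiply frequency shares by Good's coverage estimate u so that
        the quorum is expressed in estimated true coverage rather than
        sample coverage (default on: without it the estimate acquires a
        systematic dependence on sampling intensity).
    exclude_dominant : bool
        The single most frequent genus contributes no coverage (but still
        counts toward richness when drawn before the quorum is reached).
    seed : int or None
        Seed for the subsampling RNG.
    """

    q: float = 0.5
    trials: int = 1000
    unit: str = "occurrence"
    goods_u_correction: bool = True
    exclude_dominant: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigurationError("quorum q must be in (0, 1)")
        if self.trials < 1:
            raise ConfigurationError("trials must be >= 1")
        if self.unit not in ("occurrence", "collection"):
            raise ConfigurationError(f"unknown sampling unit {self.unit!r}")


@dataclass
class DiversityCurve:
    """Per-bin subsampled richness with 1-sigma spread over trials.

    ``df`` columns: ``bin`` (label), ``age_Ma`` (bin midpoint), ``mean``,
    ``sd``, ``raw`` (distinct genera), ``n_occ``.  Empty bins carry NaN
    mean/sd/raw (missing, not zero) and ``n_occ`` = 0.
    """

    df: pd.DataFrame
    method: str = "sqs"
    region: str = "global"

    @property
    def ages(self) -> np.ndarray:
        return self.df["age_Ma"].to_numpy(float)

    @property
    def mean(self) -> np.ndarray:
        return self.df["mean"].to_numpy(float)

    @property
    def sd(self) -> np.ndarray:
        return self.df["sd"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, method: str = "sqs",
                 region: str = "global") -> "DiversityCurve":
        return cls(pd.read_csv(path), method=method, region=region)


def goods_u(counts) -> float:
    """Good's coverage estimate: 1 - singletons / total occurrences."""
    counts = np.asarray(list(counts.values()) if isinstance(counts, dict)
                        else counts, dtype=float)
    if counts.size == 0:
        raise ValueError("goods_u: empty counts")
    if np.any(counts < 1):
        raise ValueError("goods_u: counts must be >= 1")
    return 1.0 - np.count_nonzero(counts == 1) / counts.sum()


def _genus_counts(tokens: pd.DataFrame) -> pd.Series:
    return tokens["genus"].value_counts()


def _effective_shares(counts: np.ndarray, cfg: QuorumConfig) -> np.ndarray:
    """Per-genus coverage contribution on first appearance."""
    shares = counts / counts.sum()
    if cfg.goods_u_correction:
        shares = shares * goods_u(counts)
    if cfg.exclude_dominant and len(counts) > 1:
        shares = shares.copy()
        shares[np.argmax(counts)] = 0.0
    return shares


def sqs_bin(tokens: pd.DataFrame, cfg: QuorumConfig,
            rng: np.random.Generator | None = None
            ) -> tuple[float, float]:
    """Coverage-standardized richness of one bin: (mean, sd) over trials."""
    if len(tokens) == 0:
        raise ValueError("sqs_bin: empty bin")
    counts_s = _genus_counts(tokens)
    counts = counts_s.to_numpy(float)
    n_genera = len(counts)
    if n_genera == 1:
        return 1.0, 0.0  # singleton-genus bin: deterministic
    shares = _effective_shares(counts, cfg)
    attainable = shares.sum()
    if cfg.q > attainable + _COVERAGE_TOL:
        warnings.warn(
            f"quorum {cfg.q} exceeds attainable coverage {attainable:.3f}; "
            "returning raw richness", stacklevel=2)
        return float(n_genera), 0.0
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if cfg.unit == "collection":
        rich = _sqs_trials_collections(tokens, counts_s, shares, cfg, rng)
    else:
        rich = _sqs_trials_occurrences(counts, shares, cfg, rng)
    sd = float(rich.std(ddof=1)) if cfg.trials > 1 else 0.0
    return float(rich.mean()), sd


def _sqs_trials_occurrences(counts: np.ndarray, shares: np.ndarray,
                            cfg: QuorumConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized occurrence-unit trials via the minimum-key shortcut."""
    keys = rng.standard_exponential((cfg.trials, len(counts))) / counts
    order = np.argsort(keys, axis=1)
    cum = np.cumsum(shares[order], axis=1)
    # first index where coverage reaches q; richness = index + 1
    reached = cum >= cfg.q - _COVERAGE_TOL
    return reached.argmax(axis=1) + 1


def _sqs_trials_collections(tokens: pd.DataFrame, counts_s: pd.Series,
                            shares: np.ndarray, cfg: QuorumConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Collection-unit trials: permute whole collections, then their
    occurrences, stopping mid-collection once the quorum is reached."""
    share_of = dict(zip(counts_s.index, shares))
    groups = [g["genus"].to_numpy()
              for _, g in tokens.groupby("collection_id", sort=False)]
    rich = np.empty(cfg.trials, dtype=np.int64)
    for t in range(cfg.trials):
        seen: set = set()
        cov = 0.0
        stop = False
        for ci in rng.permutation(len(groups)):
            occs = groups[ci]
            for g in occs[rng.permutation(len(occs))]:
                if g not in seen:
                    seen.add(g)
                    cov += share_of[g]
                    if cov >= cfg.q - _COVERAGE_TOL:
                        stop = True
                        break
            if stop:
                break
        rich[t] = len(seen)
    return rich


def rarefy_bin(tokens: pd.DataFrame, n: int, trials: int = 1000,
               seed: int | None = None,
               rng: np.random.Generator | None = None
               ) -> tuple[float, float]:
    """Monte-Carlo classical rarefaction: richness in subsamples of n
    occurrences drawn without replacement; (mean, sd) over trials."""
    if n < 1:
        raise ValueError("rarefy_bin: n must be >= 1")
    if len(tokens) == 0:
        raise ValueError("rarefy_bin: empty bin")
    genus = pd.factorize(tokens["genus"])[0]
    total = len(genus)
    if n >= total:
        if n > total:
            logger.info("rarefy_bin: n=%d exceeds bin size %d; using all "
                        "occurrences", n, total)
        return float(np.unique(genus).size), 0.0
    if rng is None:
        rng = np.random.default_rng(seed)
    keys = rng.random((trials, total))
    picks = genus[np.argpartition(keys, n - 1, axis=1)[:, :n]]
    picks.sort(axis=1)
    rich = 1 + np.count_nonzero(np.diff(picks, axis=1), axis=1)
    sd = float(rich.std(ddof=1)) if trials > 1 else 0.0
    return float(rich.mean()), sd


def rarefy_expected(counts, n: int) -> float:
    """Exact hypergeometric expectation of rarefied richness:
    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]."""
    counts = np.asarray(list(counts.values()) if isinstance(counts, dict)
                        else counts, dtype=np.int64)
    total = int(counts.sum())
    if n >= total:
        return float(len(counts))

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    miss = np.zeros(len(counts))
    ok = total - counts >= n
    miss[ok] = np.exp(logc(total - counts[ok], n) - logc(total, n))
    return float(np.sum(1.0 - miss))


def diversity_curve(binned: BinnedOccurrences, cfg: QuorumConfig,
                    method: str = "sqs",
                    rarefy_n: int | None = None) -> DiversityCurve:
    """Apply an estimator per bin to produce a diversity curve.

    method: "sqs" (coverage-standardized), "cr" (classical rarefaction at
    ``rarefy_n`` occurrences), or "raw" (distinct genera).  Empty bins are
    carried as missing.  Each bin gets its own RNG stream derived from
    (cfg.seed, bin index), so results do not depend on evaluation order.
    """
    if method not in ("sqs", "cr", "raw"):
        raise ConfigurationError(f"unknown diversity method {method!r}")
    if method == "cr" and rarefy_n is None:
        raise ConfigurationError("method 'cr' requires rarefy_n")
    rows = []
    base_seed = cfg.seed if cfg.seed is not None else 0
    for i, b in enumerate(binned.scheme.bins):
        tokens = binned.tokens.get(b.label, pd.DataFrame(columns=["genus"]))
        n_occ = len(tokens)
        if n_occ == 0:
            rows.append((b.label, b.midpoint, np.nan, np.nan, np.nan, 0))
            continue
        raw = tokens["genus"].nunique()
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, i]))
        if method == "raw":
            mean, sd = float(raw), 0.0
        elif method == "sqs":
            mean, sd = sqs_bin(tokens, cfg, rng=rng)
        else:
            mean, sd = rarefy_bin(tokens, rarefy_n, trials=cfg.trials,
                                  rng=rng)
        rows.append((b.label, b.midpoint, mean, sd, float(raw), n_occ))
    df = pd.DataFrame(rows, columns=["bin", "age_Ma", "mean", "sd", "raw",
                                     "n_occ"])
    return DiversityCurve(df, method=method, region=binned.region)
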