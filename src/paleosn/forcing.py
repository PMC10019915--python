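"""Exponential-memory supernova forcing.

Diversity can only respond to past supernova activity, with a rebound
time scale lambda of 10-40 Myr.  The forcing functional is the causal
exponential-memory convolution

    Gamma(t) = c * integral_{t' <= t} SN(t') exp(-(t - t') / lambda) dt'

evaluated here in age coordinates (a = -t, larger = older), so the
integral runs over ages a' >= a.  The record is finite while the integral
is not: ages older than the oldest datum are padded with the oldest value
(steady-state padding), with the pad's analytic exponential tail added in
closed form, so there is no truncation error.

Discretization: the integrand is integrated by the trapezoid rule on a
uniform age grid, and the discrete kernel is normalized so that a
constant input S yields exactly Gamma = c * lambda * S (the continuous
steady state).  Equivalently, Gamma = c * lambda * (kernel-weighted mean
of SN).  The normalization keeps the operator linear and exact on
constants at any grid step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .occurrences import ConfigurationError
from .area import _interp

logger = logging.getLogger(__name__)

#: Pad the grid this many e-folding times beyond the oldest datum before
#: switching to the closed-form tail.
PAD_EFOLDS = 10.0


@dataclass
class SNRateCurve:
    """Relative supernova frequency vs age, with optional 1-sigma band."""

    ages: np.ndarray
    rate: np.ndarray
    sigma: np.ndarray | None = None
    noise_model: str = "normal"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.diff(self.ages) > 0):
            raise ConfigurationError("SN curve: ages must be increasing")
        if np.any(self.rate < 0):
            raise ConfigurationError("SN curve: negative rates")
        if self.noise_model not in ("normal", "poisson"):
            raise ConfigurationError(
                f"unknown noise model {self.noise_model!r}")

    @classmethod
    def from_csv(cls, path, noise_model: str = "normal") -> "SNRateCurve":
        df = pd.read_csv(path).sort_values("age_Ma")
        sigma = df["sigma"].to_numpy(float) if "sigma" in df.columns else None
        return cls(df["age_Ma"].to_numpy(float), df["rate"].to_numpy(float),
                   sigma, noise_model)

    def to_csv(self, path) -> None:
        out = {"age_Ma": self.ages, "rate": self.rate}
        if self.sigma is not None:
            out["sigma"] = self.sigma
        pd.DataFrame(out).to_csv(path, index=False)

    def resampled(self, grid) -> "SNRateCurve":
        grid = np.asarray(grid, dtype=float)
        sigma = (_interp(grid, self.ages, self.sigma)
                 if self.sigma is not None else None)
        return SNRateCurve(grid, _interp(grid, self.ages, self.rate),
                           sigma, self.noise_model)


@dataclass
class ForcingCurve:
    """Gamma(t) on an age grid, with the parameters that produced it."""

    ages: np.ndarray
    gamma: np.ndarray
    lam: float
    c: float = 1.0
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None

    def resampled(self, grid) -> "ForcingCurve":
        grid = np.asarray(grid, dtype=float)
        out = replace(self, ages=grid,
                      gamma=_interp(grid, self.ages, self.gamma))
        if self.band_lo is not None:
            out.band_lo = _interp(grid, self.ages, self.band_lo)
            out.band_hi = _interp(grid, self.ages, self.band_hi)
        return out

    def scaled(self, c: float) -> "ForcingCurve":
        out = replace(self, gamma=self.gamma * (c / self.c), c=c)
        if self.band_lo is not None:
            out.band_lo = self.band_lo * (c / self.c)
            out.band_hi = self.band_hi * (c / self.c)
        return out

    def to_csv(self, path) -> None:
        out = {"age_Ma": self.ages, "gamma": self.gamma}
        if self.band_lo is not None:
            out["band_lo"], out["band_hi"] = self.band_lo, self.band_hi
        df = pd.DataFrame(out)
        df["lambda_Myr"] = self.lam
        df["c"] = self.c
        df.to_csv(path, index=False)


class ForcingOperator:
    """Precomputed linear map from an SN series to Gamma on a grid.

    Builds the kernel-normalized trapezoid discretization once; applying
    it to one draw or a stack of Monte-Carlo draws is then a single
    matrix product.  The input series is padded beyond its oldest point
    with its oldest value, and the pad's infinite tail enters analytically.
    """

    def __init__(self, ages: np.ndarray, lam: float, grid_step: float = 1.0):
        if not lam > 0:
            raise ConfigurationError("lambda must be > 0")
        ages = np.asarray(ages, dtype=float)
        if not np.allclose(np.diff(ages), grid_step, rtol=0, atol=1e-9):
            raise ConfigurationError("ForcingOperator needs a uniform grid")
        self.ages = ages
        self.lam = float(lam)
        h = float(grid_step)
        n = len(ages)
        n_pad = int(np.ceil(PAD_EFOLDS * lam / h))
        m = n + n_pad
        ext = ages[0] + h * np.arange(m)  # ages[..] increasing old-ward
        # kernel K[i, j] = exp(-(a_j - a_i)/lam) for j >= i (causal)
        d = (ext[None, :] - ext[:n, None]) / lam
        K = np.where(d >= 0, np.exp(-np.clip(d, 0, None)), 0.0)
        w = np.full(m, h)
        w[-1] = h / 2.0
        W = K * w
        ii = np.arange(n)
        W[ii, ii] = h / 2.0  # half weight at each row's own (young) endpoint
        tail = lam * np.exp(-(ext[-1] - ext[:n]) / lam)
        denom = W.sum(axis=1) + tail
        # rows map an extended SN vector to lam * weighted mean
        self._W = (self.lam / denom)[:, None] * W
        self._tail = self.lam * tail / denom
        self._n = n
        self._n_pad = n_pad

    def _extend(self, sn_values: np.ndarray) -> np.ndarray:
        pad = np.repeat(sn_values[..., -1:], self._n_pad, axis=-1)
        return np.concatenate([sn_values, pad], axis=-1)

    def apply(self, sn_values: np.ndarray, c: float = 1.0) -> np.ndarray:
        """Gamma for one series (shape n) or a stack (draws, n)."""
        sn_values = np.asarray(sn_values, dtype=float)
        ext = self._extend(sn_values)
        tail = sn_values[..., -1:] * self._tail[None, :] \
            if sn_values.ndim > 1 else sn_values[-1] * self._tail
        return c * (ext @ self._W.T + tail)


def exp_memory_forcing(sn: SNRateCurve, lam: float, c: float = 1.0,
                       grid_step: float = 1.0) -> ForcingCurve:
    """Evaluate the exponential-memory forcing on a uniform grid.

    The SN curve is resampled to a uniform grid of ``grid_step`` Myr
    spanning its support; Gamma(a) = c * lambda * (exponential-kernel
    weighted mean of SN over ages >= a), which for constant SN equals
    the steady state c * lambda * SN.
    """
    if not lam > 0:
        raise ConfigurationError("lambda must be > 0")
    grid = np.arange(sn.ages[0], sn.ages[-1] + grid_step / 2, grid_step)
    snu = sn.resampled(grid)
    op = ForcingOperator(grid, lam, grid_step)
    gamma = op.apply(snu.rate, c=c)
    return ForcingCurve(grid, gamma, lam=lam, c=c)


def fit_scale_c(gamma_unit: np.ndarray, target: np.ndarray) -> float:
    """Least-squares scale through the origin: c = sum(g*y) / sum(g^2).

    ``gamma_unit`` is Gamma computed with c = 1; NaN pairs are ignored.
    """
    g = np.asarray(gamma_unit, dtype=float)
    y = np.asarray(target, dtype=float)
    ok = np.isfinite(g) & np.isfinite(y)
    g, y = g[ok], y[ok]
    if g.size < 2:
        raise ValueError("fit_scale_c: need at least 2 paired points")
    denom = float(np.sum(g * g))
    if denom == 0.0:
        raise ValueError("fit_scale_c: gamma is identically zero")
    return float(np.sum(g * y) / denom)


def perturb_sn(sn: SNRateCurve, n_draws: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw perturbed SN series (n_draws, n) under the curve's noise model.

    normal: rate + sigma * z, clipped at 0.  poisson: scaled-count
    resampling with the count scale chosen so the variance matches
    sigma^2 (draw ~ Poisson(rate^2 / sigma^2) * sigma^2 / rate).
    """
    if sn.sigma is None:
        raise ConfigurationError("perturb_sn: SN curve has no sigma band")
    rate, sigma = sn.rate, sn.sigma
    if sn.noise_model == "normal":
        draws = rate + sigma * rng.standard_normal((n_draws, rate.size))
        return np.clip(draws, 0.0, None)
    # poisson
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(sigma > 0, rate / sigma ** 2, np.inf)
    draws = np.empty((n_draws, rate.size))
    finite = np.isfinite(kappa) & (rate > 0)
    draws[:, ~finite] = rate[~finite]
    lam_counts = (rate * kappa)[finite]
    draws[:, finite] = rng.poisson(lam_counts,
                                   (n_draws, int(finite.sum()))
                                   ) / kappa[finite]
    return draws


def mc_forcing_band(sn: SNRateCurve, lam: float, c: float = 1.0,
                    n_draws: int = 500, seed: int | None = None,
                    grid_step: float = 1.0) -> ForcingCurve:
    """Monte-Carlo 1-sigma envelope of Gamma from the SN uncertainty band.

    Each draw perturbs the SN curve under its noise model and recomputes
    Gamma; the band is the per-age mean +/- SD over draws.  The central
    ``gamma`` is the unperturbed evaluation.
    """
    if sn.sigma is None:
        raise ConfigurationError("mc_forcing_band: SN curve has no sigma")
    if n_draws < 2:
        warnings.warn("mc_forcing_band: n_draws < 2 gives a degenerate band",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    grid = np.arange(sn.ages[0], sn.ages[-1] + grid_step / 2, grid_step)
    snu = sn.resampled(grid)
    op = ForcingOperator(grid, lam, grid_step)
    gamma = op.apply(snu.rate, c=c)
    draws = perturb_sn(snu, max(n_draws, 1), rng)
    gdraws = op.apply(draws, c=c)
    mu = gdraws.mean(axis=0)
    sd = gdraws.std(axis=0, ddof=1) if n_draws > 1 else np.zeros_like(mu)
    return ForcingCurve(grid, gamma, lam=lam, c=c,
                        band_lo=mu - sd, band_hi=mu + sd)
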