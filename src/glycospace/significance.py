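"""Statistical significance of glycan structural similarity.

The null model for the pairwise RMSD of one glycan sequence is its random
conformer background, fitted with the three-parameter generalized extreme
value (GEV) family

    F(x; mu, sigma, xi) = exp{ -[1 + xi (x - mu)/sigma]^(-1/xi) },

with location mu, scale sigma > 0 and shape xi (Gumbel limit as xi -> 0).
The p-value of an observed pair is the lower tail F(observed): the
probability that a random conformer pair is at least as similar. TM-score
significance uses the upper tail (1 - F) through the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class GEVFitError(RuntimeError):
    pass


@dataclass
class GEVParams:
    """Fitted GEV null distribution: location/scale/shape in the standard
    extreme-value convention (scipy's genextreme uses c = -shape), plus the
    empirical-vs-model CDF correlation as fit quality."""

    location: float
    scale: float
    shape: float
    fit_quality: float | None = None

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("GEV scale must be positive")

    @property
    def scipy_c(self) -> float:
        return -self.shape


def fit_gev(samples) -> GEVParams:
    """Maximum-likelihood GEV fit of a background distance sample.

    Initialised from the method-of-moments Gumbel fit; requires at least
    100 samples with positive spread.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"need at least 100 samples, got {x.size}")
    sd = x.std()
    if sd <= 0:
        raise ValueError("samples have zero spread; cannot fit a GEV")
    # Gumbel moment estimates as the starting point
    scale0 = sd * np.sqrt(6.0) / np.pi
    loc0 = x.mean() - np.euler_gamma * scale0
    try:
        c, loc, scale = stats.genextreme.fit(x, 0.0, loc=loc0, scale=scale0)
    except Exception as exc:  # scipy raises bare Exceptions from optimizers
        raise GEVFitError(f"GEV fit did not converge: {exc}") from exc
    if not np.isfinite([c, loc, scale]).all() or scale <= 0:
        raise GEVFitError(
            f"GEV fit did not converge: last iterate c={c}, loc={loc}, scale={scale}"
        )
    params = GEVParams(location=float(loc), scale=float(scale), shape=float(-c))
    # fit quality: correlation of empirical and model CDF on sorted samples
    xs = np.sort(x)
    emp = (np.arange(1, x.size + 1) - 0.5) / x.size
    model = gev_cdf(xs, params)
    params.fit_quality = float(np.corrcoef(emp, model)[0, 1])
    return params


def gev_cdf(x, params: GEVParams):
    """GEV cumulative distribution; continuous Gumbel limit for |shape|
    below 1e-9."""
    if abs(params.shape) < 1e-9:
        z = (np.asarray(x, dtype=float) - params.location) / params.scale
        return np.exp(-np.exp(-z))
    return stats.genextreme.cdf(x, params.scipy_c, loc=params.location, scale=params.scale)


@dataclass
class PValueRecord:
    observed: float
    p: float
    tail: str = "lower"


def p_value(observed, params: GEVParams, tail: str = "lower") -> PValueRecord:
    """Probability that a random background pair is at least as similar.

    Lower tail (RMSD: smaller is more similar) by default; ``tail='upper'``
    gives 1 - F for scores where larger means more similar (TM-score).
    """
    cdf = float(np.clip(gev_cdf(observed, params), 0.0, 1.0))
    if tail == "lower":
        p = cdf
    elif tail == "upper":
        p = 1.0 - cdf
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return PValueRecord(observed=float(observed), p=p, tail=tail)


def p_values(observed, params: GEVParams, tail: str = "lower") -> np.ndarray:
    """Vectorised :func:`p_value` returning a bare probability array."""
    cdf = np.clip(gev_cdf(np.asarray(observed, dtype=float), params), 0.0, 1.0)
    return cdf if tail == "lower" else 1.0 - cdf


@dataclass
class CumulativeFractionCurve:
    """Non-decreasing step curve: fraction of pairs with p-value <= t."""

    thresholds: np.ndarray  # sorted p-values
    fractions: np.ndarray

    def fraction_at(self, p: float = 0.05) -> float:
        k = np.searchsorted(self.thresholds, p, side="right")
        return float(self.fractions[k - 1]) if k > 0 else 0.0


def cumulative_fraction(pvalues) -> CumulativeFractionCurve:
    """Cumulative fraction of structure pairs below each p-value threshold
    (the curves of the significance analysis); reports the fraction at
    p = 0.05 via ``fraction_at``."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value list")
    frac = np.arange(1, p.size + 1) / p.size
    return CumulativeFractionCurve(thresholds=p, fractions=frac)
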