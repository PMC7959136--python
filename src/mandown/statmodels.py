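"""Normal and Gumbel extreme-value models with RML family selection.

Extreme-value features are modelled either by a normal distribution
``N(mu, sigma^2)`` or by the Gumbel distribution ``G(u, beta)`` (the type-I
generalized extreme-value distribution, max-stable right-skewed form)

.. math::

    pdf(x) = (1/beta) \\exp(-(x - u)/beta) \\exp(-\\exp(-(x - u)/beta)).

Both fits are maximum likelihood: the normal uses the sample mean and the
MLE standard deviation (divisor n), and the Gumbel solves the 1-D profile
fixed-point equation

.. math::

    beta = \\bar x - \\sum_i x_i e^{-x_i/beta} / \\sum_i e^{-x_i/beta},
    \\qquad u = -beta \\ln\\big( n^{-1} \\sum_i e^{-x_i/beta} \\big)

by bracketed root finding.  The family choice uses the logarithm of the
ratio of maximized likelihoods (RML): a positive value selects the normal
distribution, otherwise (ties included) the Gumbel.

For likelihood fusion the densities are normalized to unit scale by their
analytic maxima, ``1/(sigma sqrt(2 pi))`` for the normal and ``1/(beta e)``
for the Gumbel, so each feature contributes a weight in (0, 1] that equals
1 exactly at the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import FitFailureError, InsufficientDataError, ZeroScaleError

NORMAL = "normal"
GUMBEL = "gumbel"


@dataclass(frozen=True)
class DistributionModel:
    """A fitted location-scale model for one extreme-value feature."""

    family: str
    loc: float
    scale: float

    def __post_init__(self):
        if self.family not in (NORMAL, GUMBEL):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ZeroScaleError("scale must be positive")

    @property
    def pdf_max(self) -> float:
        """Analytic maximum density (at the mode)."""
        if self.family == NORMAL:
            return 1.0 / (self.scale * math.sqrt(2.0 * math.pi))
        return 1.0 / (self.scale * math.e)

    def logpdf(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.loc) / self.scale
        if self.family == NORMAL:
            return -0.5 * z * z - math.log(self.scale) \
                - 0.5 * math.log(2.0 * math.pi)
        return -z - np.exp(-z) - math.log(self.scale)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def loglik(self, x) -> float:
        return float(np.sum(self.logpdf(x)))

    def to_dict(self) -> dict:
        return {"family": self.family, "loc": float(self.loc),
                "scale": float(self.scale)}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionModel":
        return cls(family=d["family"], loc=float(d["loc"]),
                   scale=float(d["scale"]))


def _validated(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError("need at least two observations")
    if np.ptp(x) == 0.0:
        raise ZeroScaleError("constant sample has zero scale")
    return x


def fit_normal(x) -> DistributionModel:
    """Maximum-likelihood normal fit: mean and divisor-n standard deviation."""
    x = _validated(x)
    return DistributionModel(NORMAL, float(x.mean()), float(x.std(ddof=0)))


def _gumbel_profile(x: np.ndarray):
    """Profile score function g(beta); the MLE beta is its root."""
    xbar = x.mean()
    z = x - x.min()  # shift keeps exp(-z/beta) in (0, 1]

    def g(beta: float) -> float:
        w = np.exp(-z / beta)
        return xbar - beta - float((x * w).sum() / w.sum())

    return g


def fit_gumbel(x, tol: float = 1e-10) -> DistributionModel:
    """Maximum-likelihood Gumbel fit by bracketed root finding.

    The root bracket starts at [sd/10, sd*10] around the sample standard
    deviation and expands geometrically if the profile score does not
    change sign there.
    """
    x = _validated(x)
    sd = x.std(ddof=0)
    g = _gumbel_profile(x)
    lo, hi = sd / 10.0, sd * 10.0
    for _ in range(8):
        if g(lo) * g(hi) < 0:
            break
        lo /= 10.0
        hi *= 10.0
    else:
        raise FitFailureError("no sign change found when bracketing beta")
    beta = float(brentq(g, lo, hi, xtol=tol))
    z = x - x.min()
    w = np.exp(-z / beta)
    u = float(x.min() - beta * math.log(w.mean()))
    return DistributionModel(GUMBEL, u, beta)


def rml_statistic(x) -> float:
    """Log ratio of maximized likelihoods, normal over Gumbel."""
    x = _validated(x)
    return fit_normal(x).loglik(x) - fit_gumbel(x).loglik(x)


def rml_select(x) -> str:
    """Family selection: ``normal`` iff the RML statistic is > 0, else
    ``gumbel`` (ties go to the Gumbel)."""
    return NORMAL if rml_statistic(x) > 0.0 else GUMBEL


def fit_auto(x) -> DistributionModel:
    """Fit the family selected by the RML test."""
    family = rml_select(x)
    return fit_normal(x) if family == NORMAL else fit_gumbel(x)


def normalized_pdf(model: DistributionModel, x) -> np.ndarray:
    """Density normalized to unit scale: ``pdf(x) / pdf_max`` in (0, 1]."""
    log_max = math.log(model.pdf_max)
    return np.exp(model.logpdf(x) - log_max)
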