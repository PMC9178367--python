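"""Closed-form moments of the habitat-averaged interaction matrix.

Averaging G habitat matrices shrinks the spread of interaction strengths,
and the spread (sigma_bar) is the May-style complexity proxy that controls
richness of the coherent metacommunity.  The three correlation structures
give:

independent habitats (connectance c, entry moments mu, sigma):
    mean   mu_bar  = c * mu
    var    sigma_bar^2 = (c / G) * (sigma^2 + mu^2 * (1 - c))
    (the mu^2(1-c) term comes from the Bernoulli presence/absence mixture)

equicorrelated habitats (pairwise correlation rho, full shared mask):
    sigma_bar^2 = (sigma^2 / G) * (1 + (G - 1) * rho)
    which saturates at rho * sigma^2 as G -> infinity.

nearest-neighbor chain (correlation rho_nn**lag between habitats):
    sigma_bar^2 = sigma^2 * (G + 2 * sum_{eta=1}^{G-1} rho_nn^eta (G - eta)) / G^2
    which tends to 0 as G -> infinity (distant habitats decorrelate).

All formulas return variances; standard deviations are derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .interactions import CorrelationSpec

__all__ = [
    "TheoryPrediction",
    "moments_independent",
    "variance_equicorrelated",
    "variance_nn_chain",
    "large_G_limit",
    "complexity_proxy",
]


@dataclass(frozen=True)
class TheoryPrediction:
    """Predicted mean and variance of the averaged interaction matrix."""

    mu_bar: float
    var_bar: float
    regime: CorrelationSpec
    G: int

    def __post_init__(self):
        if self.var_bar < 0:
            raise ValueError("var_bar must be nonnegative")

    @property
    def sigma_bar(self) -> float:
        return math.sqrt(self.var_bar)


def _check_G(G) -> int:
    if int(G) < 1:
        raise ValueError("G must be a positive integer")
    return int(G)


def moments_independent(c: float, mu: float, sigma: float, G) -> TheoryPrediction:
    """Moments of the average of G independent habitat matrices."""
    if not 0.0 < c <= 1.0:
        raise ValueError("connectance c must lie in (0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    G = _check_G(G)
    var_bar = (c / G) * (sigma**2 + mu**2 * (1.0 - c))
    return TheoryPrediction(mu_bar=c * mu, var_bar=var_bar,
                            regime=CorrelationSpec("independent"), G=G)


def variance_equicorrelated(sigma: float, G, rho: float) -> TheoryPrediction:
    """Variance of the average of G equicorrelated habitat matrices (c=1)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    G = _check_G(G)
    var_bar = (sigma**2 / G) * (1.0 + (G - 1) * rho)
    return TheoryPrediction(mu_bar=np.nan, var_bar=var_bar,
                            regime=CorrelationSpec("equicorrelated", rho=rho), G=G)


def variance_nn_chain(sigma: float, G, rho_nn: float) -> TheoryPrediction:
    """Variance of the average over a nearest-neighbor-correlated chain (c=1)."""
    if not 0.0 <= rho_nn < 1.0:
        raise ValueError("rho_nn must lie in [0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    G = _check_G(G)
    eta = np.arange(1, G)
    tail = 2.0 * np.sum(rho_nn**eta * (G - eta))
    var_bar = sigma**2 * (G + tail) / G**2
    return TheoryPrediction(mu_bar=np.nan, var_bar=float(var_bar),
                            regime=CorrelationSpec("nn_chain", rho_nn=rho_nn), G=G)


def large_G_limit(spec: CorrelationSpec, sigma: float, c: float = 1.0,
                  mu: float = 0.0) -> float:
    """Limit of the averaged-matrix variance as the habitat count grows.

    Independent and nearest-neighbor-correlated habitats both average out
    (limit 0); equicorrelated habitats retain a floor of rho * sigma^2.
    """
    if spec.kind == "equicorrelated":
        return spec.rho * sigma**2
    return 0.0


def complexity_proxy(sigma: float, c: float, N: int) -> float:
    """May-scaling complexity sigma * sqrt(c * N).

    At fixed c*N this is the control parameter for stability and feasibility
    of a large random community; richness sweeps fix it rather than sigma.
    """
    return sigma * math.sqrt(c * N)
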