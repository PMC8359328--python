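"""Gauss-Hermite quadrature over (bivariate) standard-normal latent densities.

The latent population is N(0, 1) per dimension with a free correlation rho in
the two-dimensional models.  Integration uses a fixed product Gauss-Hermite
grid; the correlation enters through the weights, which are the product-normal
Gauss-Hermite weights reweighted by the ratio of the correlated to the
independent bivariate-normal density and then normalized to sum to one.  With
fixed nodes, rho can be updated in an EM M-step by a one-dimensional search
that is decoupled from the item parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray


@dataclass
class QuadratureSpec:
    """Quadrature settings for marginal-likelihood integration.

    ``nodes_per_dim`` Gauss-Hermite nodes per latent dimension (>= 11).
    """

    nodes_per_dim: int = 21

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 11:
            raise ValueError("nodes_per_dim must be at least 11")


def gh_normal(n: int) -> tuple[NDArray, NDArray]:
    """Gauss-Hermite nodes/weights rescaled for the standard normal density."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def grid_1d(spec: QuadratureSpec) -> tuple[NDArray, NDArray]:
    """Nodes (Q, 1) and normalized weights (Q,) for a single N(0,1) latent."""
    x, w = gh_normal(spec.nodes_per_dim)
    return x[:, None], w / w.sum()


def grid_2d(spec: QuadratureSpec) -> tuple[NDArray, NDArray]:
    """Product grid (Q, 2) and independent product weights (Q,), Q = n^2."""
    x, w = gh_normal(spec.nodes_per_dim)
    t1, t2 = np.meshgrid(x, x, indexing="ij")
    nodes = np.column_stack([t1.ravel(), t2.ravel()])
    weights = np.outer(w, w).ravel()
    return nodes, weights / weights.sum()


def weights_2d(nodes: NDArray, base_weights: NDArray, rho: float) -> NDArray:
    """Reweight product-normal weights for a latent correlation ``rho``.

    Multiplies by phi2(theta; rho) / (phi(theta1) phi(theta2)) and normalizes.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    z1, z2 = nodes[:, 0], nodes[:, 1]
    om = 1.0 - rho * rho
    log_ratio = -0.5 * np.log(om) - (rho * rho * (z1 * z1 + z2 * z2) - 2.0 * rho * z1 * z2) / (
        2.0 * om
    )
    w = base_weights * np.exp(log_ratio)
    return w / w.sum()
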