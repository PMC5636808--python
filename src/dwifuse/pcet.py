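"""Polar complex exponential transform (PCET) moments of projected patches.

The PCET basis on the unit disc is ``H_{n,l}(rho, theta) = exp(i 2 pi n rho^2)
exp(i l theta)``; moments are

    M_{n,l} = (1/pi) int [H_{n,l}]* S(rho, theta) rho drho dtheta.

The basis is orthogonal under the 1/pi disc measure, and the moment magnitudes
are invariant to in-plane rotations of the patch, which is what makes them
usable for matching q-space patches regardless of their local orientation.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

from .patches import PolarGridSpec, ProjectedPatch

__all__ = [
    "PCETFeatures",
    "pcet_basis",
    "pcet_order_pairs",
    "pcet_moment_matrix",
    "pcet_moments",
    "feature_distance",
]


def pcet_basis(n: int, l: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Basis function ``H_{n,l}`` — always unit modulus."""
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return np.exp(1j * (2.0 * np.pi * n * rho**2 + l * theta))


def pcet_order_pairs(m: int) -> list[tuple[int, int]]:
    """(n, l) pairs with ``-m <= n, l <= m`` in lexicographic order."""
    return [(n, l) for n in range(-m, m + 1) for l in range(-m, m + 1)]


@functools.lru_cache(maxsize=32)
def _moment_matrix_cached(n_rings: int, n_angles: int, m: int) -> np.ndarray:
    grid = PolarGridSpec(n_rings, n_angles)
    rho, theta = grid.nodes
    w = grid.weights
    rows = [np.conj(pcet_basis(n, l, rho, theta)) * w for n, l in pcet_order_pairs(m)]
    mat = np.array(rows)
    mat.setflags(write=False)
    return mat


def pcet_moment_matrix(grid: PolarGridSpec, m: int) -> np.ndarray:
    """Quadrature operator mapping flattened grid signals to PCET moments.

    ``moments = matrix @ grid_signal.ravel()`` — rows follow
    :func:`pcet_order_pairs`.
    """
    return _moment_matrix_cached(grid.n_rings, grid.n_angles, m)


@dataclasses.dataclass(frozen=True)
class PCETFeatures:
    """Complex PCET moments and the rotation-invariant magnitude vector.

    ``moments`` has length ``(2 m + 1)^2`` in lexicographic (n, l) order; both
    (n, l) and (-n, -l) are kept even though their magnitudes coincide for real
    signals.
    """

    moments: np.ndarray
    order: int

    def __post_init__(self) -> None:
        expected = (2 * self.order + 1) ** 2
        if self.moments.shape != (expected,):
            raise ValueError(f"expected {expected} moments for order {self.order}")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.moments)

    @property
    def feature_count(self) -> int:
        return (2 * self.order + 1) ** 2


def pcet_moments(patch: ProjectedPatch, m: int = 4) -> PCETFeatures:
    """Compute PCET moments of a projected patch up to maximum order ``m``."""
    if patch.grid_signal.size == 0:
        raise ValueError("projected patch has an empty polar grid")
    mat = pcet_moment_matrix(patch.grid_spec, m)
    return PCETFeatures(moments=mat @ patch.grid_signal.ravel(), order=m)


def feature_distance(a: PCETFeatures, b: PCETFeatures) -> float:
    """Squared Euclidean distance between magnitude feature vectors."""
    if a.order != b.order:
        raise ValueError("feature vectors have different maximum orders")
    d = a.magnitudes - b.magnitudes
    return float(d @ d)
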