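"""Real symmetric spherical harmonics on the single shell.

Diffusion signals are antipodally symmetric, so only even-order harmonics are
used.  The basis is the real orthonormal combination of complex harmonics
(cosine for m > 0, sine for m < 0), fit by regularized least squares with a
Laplace-Beltrami penalty — the standard single-shell representation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "sh_degrees",
    "sh_basis",
    "sh_fit_matrix",
    "legendre_p0",
    "qball_odf_coefficients",
]


def sh_degrees(order: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index arrays of the even-order basis up to ``order``."""
    ls, ms = [], []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the real even-order SH basis at unit ``directions`` (n, 3).

    Returns an ``(n, n_coef)`` design matrix, orthonormal w.r.t. the uniform
    measure on the sphere.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle
    phi = np.arctan2(y, x)
    ls, ms = sh_degrees(order)
    out = np.empty((directions.shape[0], len(ls)))
    for j, (l, m) in enumerate(zip(ls, ms)):
        if m == 0:
            out[:, j] = np.real(sph_harm_y(l, 0, theta, phi))
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * np.real(sph_harm_y(l, m, theta, phi))
        else:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * np.imag(sph_harm_y(l, -m, theta, phi))
    return out


def sh_fit_matrix(
    directions: np.ndarray,
    order: int = 8,
    lambda_lb: float = 0.006,
) -> np.ndarray:
    """Least-squares fit operator ``P`` with Laplace-Beltrami regularization.

    Coefficients of a sampled signal ``s`` are ``P @ s`` where
    ``P = (B^T B + lambda * diag((l (l+1))^2))^-1 B^T``.

    Raises if the direction set cannot resolve the requested order.
    """
    B = sh_basis(order, directions)
    n, ncoef = B.shape
    if n < ncoef or np.linalg.matrix_rank(B) < ncoef:
        raise ValueError(
            f"direction set too sparse for SH order {order}: "
            f"{n} samples for {ncoef} coefficients"
        )
    ls, _ = sh_degrees(order)
    reg = lambda_lb * np.diag((ls * (ls + 1.0)) ** 2)
    return np.linalg.solve(B.T @ B + reg, B.T)


def legendre_p0(l: int) -> float:
    """Legendre polynomial at zero, ``P_l(0)``; vanishes for odd ``l``."""
    if l % 2 == 1:
        return 0.0
    half = l // 2
    val = 1.0
    for j in range(1, half + 1):  # (-1)^half * (l-1)!! / l!!
        val *= (2 * j - 1) / (2 * j)
    return (-1.0) ** half * val


def qball_odf_coefficients(signal_coeffs: np.ndarray, order: int) -> np.ndarray:
    """Analytical Q-ball (Funk-Radon) transform in the SH domain.

    Each SH coefficient of the signal is scaled by ``2 pi P_l(0)`` to give the
    SH coefficients of the orientation distribution function.
    """
    ls, _ = sh_degrees(order)
    scale = 2.0 * np.pi * np.array([legendre_p0(int(l)) for l in ls])
    return np.asarray(signal_coeffs) * scale
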