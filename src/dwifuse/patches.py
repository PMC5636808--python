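"""q-space spherical patches and their projection to the unit disc.

A patch collects the gradient axes within a neighborhood angle ``alpha_p`` of a
center direction.  Because diffusion signals are antipodally symmetric, member
axes are first mapped to the hemisphere of the center; the patch is then
flattened with the azimuthal equidistant projection (AEP), which preserves the
angular distance ``rho`` to the center and the azimuth ``theta`` about it:

    cos rho   = sin phi0 sin phi + cos phi0 cos phi cos(lambda - lambda0)
    tan theta = cos phi sin(lambda - lambda0) /
                (cos phi0 sin phi - sin phi0 cos phi cos(lambda - lambda0))

with ``phi`` latitude and ``lambda`` longitude.  Radii are normalized by
``alpha_p`` so every projected patch fills the unit disc expected by the
polar complex exponential transform.

Scattered shell samples are turned into a continuous integrand by fitting an
antipodally symmetric spherical-harmonic expansion to the whole shell and
evaluating it at polar grid nodes pulled back onto the sphere by the inverse
projection.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

from .gradients import GradientScheme
from .sh import sh_basis, sh_fit_matrix

__all__ = [
    "SphericalPatch",
    "ProjectedPatch",
    "PolarGridSpec",
    "antipodal_canonicalize",
    "aep_project",
    "aep_unproject",
    "extract_patch",
    "resample_to_polar_grid",
]


def antipodal_canonicalize(axes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip axes so every output lies on the hemisphere of ``reference``."""
    reference = np.asarray(reference, dtype=float)
    if np.linalg.norm(reference) == 0:
        raise ValueError("reference must be non-zero")
    axes = np.atleast_2d(np.asarray(axes, dtype=float)).copy()
    flip = axes @ reference < 0
    axes[flip] *= -1.0
    return axes


def _cart_to_latlon(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.atleast_2d(v)
    lat = np.arcsin(np.clip(v[:, 2], -1.0, 1.0))
    lon = np.arctan2(v[:, 1], v[:, 0])
    return lat, lon


def aep_project(center: np.ndarray, axes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal equidistant projection about ``center``.

    Returns ``(rho, theta)`` in radians: ``rho`` is the great-circle distance
    from the center, ``theta`` the azimuth in [0, 2 pi).  Axes must already lie
    on the center's hemisphere; the center itself maps to ``(0, 0)``.
    """
    center = np.asarray(center, dtype=float)
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    dots = axes @ center
    if np.any(dots < -1e-9):
        raise ValueError("axes must be antipodally canonicalized to the center hemisphere")
    rho = np.arccos(np.clip(dots, -1.0, 1.0))
    (phi0,), (lam0,) = _cart_to_latlon(center[None, :])
    phi, lam = _cart_to_latlon(axes)
    dlam = lam - lam0
    num = np.cos(phi) * np.sin(dlam)
    den = np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    theta = np.mod(np.arctan2(num, den), 2.0 * np.pi)
    theta[rho < 1e-12] = 0.0
    return rho, theta


def aep_unproject(center: np.ndarray, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Inverse projection: polar disc coordinates back to unit vectors."""
    center = np.asarray(center, dtype=float)
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    (phi0,), (lam0,) = _cart_to_latlon(center[None, :])
    phi = np.arcsin(
        np.clip(np.cos(rho) * np.sin(phi0) + np.sin(rho) * np.cos(phi0) * np.cos(theta), -1, 1)
    )
    lam = lam0 + np.arctan2(
        np.sin(rho) * np.sin(theta),
        np.cos(rho) * np.cos(phi0) - np.sin(rho) * np.sin(phi0) * np.cos(theta),
    )
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


@dataclasses.dataclass(frozen=True)
class SphericalPatch:
    """Scheme axes within ``alpha_p`` degrees of a center direction."""

    scheme: GradientScheme
    center_index: int
    member_indices: np.ndarray
    member_axes: np.ndarray  # canonicalized to the center hemisphere
    alpha_p: float

    @property
    def center(self) -> np.ndarray:
        return self.scheme.directions[self.center_index]

    @property
    def is_singleton(self) -> bool:
        return len(self.member_indices) == 1


def extract_patch(scheme: GradientScheme, center_index: int, alpha_p: float) -> SphericalPatch:
    """Collect the scheme axes whose canonicalized angle to the center is <= alpha_p (deg)."""
    if not 0.0 < alpha_p < 90.0:
        raise ValueError("alpha_p must be in (0, 90) degrees")
    center = scheme.directions[center_index]
    canon = antipodal_canonicalize(scheme.directions, center)
    ang = np.degrees(np.arccos(np.clip(canon @ center, -1.0, 1.0)))
    members = np.flatnonzero(ang <= alpha_p + 1e-12)
    return SphericalPatch(
        scheme=scheme,
        center_index=int(center_index),
        member_indices=members,
        member_axes=canon[members],
        alpha_p=float(alpha_p),
    )


@dataclasses.dataclass(frozen=True)
class PolarGridSpec:
    """Fixed polar quadrature grid on the unit disc.

    Rings are placed at midpoints in ``rho^2`` (equal-area rings), which makes
    the radial quadrature of the PCET factor ``exp(i 2 pi n rho^2) rho d rho``
    exact for ``|n| < n_rings``; angles are uniform midpoints, exact for
    azimuthal harmonics ``|l| < n_angles``.  Cell weights are normalized to the
    ``1/pi`` disc measure, so they sum to 1.
    """

    n_rings: int = 8
    n_angles: int = 16

    def __post_init__(self) -> None:
        if self.n_rings < 1 or self.n_angles < 1:
            raise ValueError("grid must have at least one ring and one angle")

    @functools.cached_property
    def rho_nodes(self) -> np.ndarray:
        u = (np.arange(self.n_rings) + 0.5) / self.n_rings
        return np.sqrt(u)

    @functools.cached_property
    def theta_nodes(self) -> np.ndarray:
        return (np.arange(self.n_angles) + 0.5) * 2.0 * np.pi / self.n_angles

    @functools.cached_property
    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (rho, theta) node arrays, ring-major."""
        rr, tt = np.meshgrid(self.rho_nodes, self.theta_nodes, indexing="ij")
        return rr.ravel(), tt.ravel()

    @functools.cached_property
    def weights(self) -> np.ndarray:
        """Quadrature weights of the 1/pi-normalized disc measure (sum to 1)."""
        du = 1.0 / self.n_rings
        dtheta = 2.0 * np.pi / self.n_angles
        w = np.full(self.n_rings * self.n_angles, 0.5 * du * dtheta / np.pi)
        return w


@dataclasses.dataclass(frozen=True)
class ProjectedPatch:
    """A spherical patch flattened to the unit disc.

    ``polar_coords`` holds the projected member samples as ``(rho_norm, theta)``
    with ``rho_norm = rho / alpha_p in [0, 1]``; ``grid_signal`` is the
    spherical-harmonic interpolant of the shell evaluated on ``grid_spec``
    (shape ``(n_rings, n_angles)``).
    """

    polar_coords: np.ndarray
    member_signals: np.ndarray
    grid_signal: np.ndarray
    grid_spec: PolarGridSpec
    center_index: int
    alpha_p: float


def _grid_directions(center: np.ndarray, alpha_p: float, grid: PolarGridSpec) -> np.ndarray:
    rho, theta = grid.nodes
    return aep_unproject(center, rho * np.radians(alpha_p), theta)


def resample_to_polar_grid(
    patch: SphericalPatch,
    signal: np.ndarray,
    grid: PolarGridSpec | None = None,
    sh_order: int = 8,
    sh_lambda: float = 0.006,
) -> ProjectedPatch:
    """Interpolate a shell signal onto the patch's polar grid.

    A real antipodally symmetric SH expansion (even orders up to ``sh_order``,
    Laplace-Beltrami regularization ``sh_lambda``) is least-squares fit to the
    full shell and evaluated at the grid nodes pulled back through the inverse
    projection about the patch center.
    """
    if grid is None:
        grid = PolarGridSpec()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (patch.scheme.count,):
        raise ValueError("signal length must match the gradient scheme")
    fit = sh_fit_matrix(patch.scheme.directions, sh_order, sh_lambda)
    coeffs = fit @ signal
    dirs = _grid_directions(patch.center, patch.alpha_p, grid)
    grid_signal = (sh_basis(sh_order, dirs) @ coeffs).reshape(grid.n_rings, grid.n_angles)

    rho, theta = aep_project(patch.center, patch.member_axes)
    polar = np.stack([rho / np.radians(patch.alpha_p), theta], axis=1)
    return ProjectedPatch(
        polar_coords=polar,
        member_signals=signal[patch.member_indices],
        grid_signal=grid_signal,
        grid_spec=grid,
        center_index=patch.center_index,
        alpha_p=patch.alpha_p,
    )
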