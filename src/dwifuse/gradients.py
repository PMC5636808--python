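"""Single-shell gradient schemes.

A gradient scheme is the set of unit wavevector directions (one per
diffusion-weighted volume) together with the shared b-value.  Directions are
treated as *axes*: ``g`` and ``-g`` sample the same diffusion measurement, so
all angular comparisons below use ``arccos |g_i . g_j|``.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np

__all__ = ["GradientScheme", "axis_angle", "default_scheme", "repulsion_energy"]


@dataclasses.dataclass(frozen=True)
class GradientScheme:
    """Unit gradient directions plus the b-value shared by all subjects.

    Parameters
    ----------
    directions
        ``(K, 3)`` array of unit vectors.
    b_value
        Diffusion weighting in s/mm^2.
    """

    directions: np.ndarray
    b_value: float

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be a (K, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("gradient directions must have unit norm (1e-12)")
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        if np.any(dots >= 1.0 - 1e-12):
            raise ValueError("gradient directions must be pairwise non-collinear axes")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "b_value", float(self.b_value))

    @property
    def count(self) -> int:
        return self.directions.shape[0]

    def min_axis_angle(self) -> float:
        """Minimum pairwise axis angle in degrees."""
        dots = np.abs(self.directions @ self.directions.T)
        np.fill_diagonal(dots, 0.0)
        return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))

    def cache_key(self) -> tuple:
        return (self.count, self.b_value, self.directions.tobytes())


def axis_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle in degrees between axes (antipodally symmetric metric)."""
    dot = np.abs(np.sum(np.asarray(a) * np.asarray(b), axis=-1))
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def repulsion_energy(axes: np.ndarray) -> float:
    """Electrostatic energy of a set of axes (each axis counts as a charge pair)."""
    axes = np.asarray(axes, dtype=float)
    diff = axes[:, None, :] - axes[None, :, :]
    summ = axes[:, None, :] + axes[None, :, :]
    dist_d = np.linalg.norm(diff, axis=-1)
    dist_s = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(len(axes), k=1)
    return float(np.sum(1.0 / dist_d[iu]) + np.sum(1.0 / dist_s[iu]))


@functools.lru_cache(maxsize=16)
def _dispersed_axes(K: int, seed: int, n_iter: int) -> bytes:
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((K, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    p[p[:, 2] < 0] *= -1.0

    step = 0.05
    energy = _energy_arr(p)
    for _ in range(n_iter):
        f = _forces(p)
        # keep only the tangential component so the step stays near the sphere
        f -= np.sum(f * p, axis=1, keepdims=True) * p
        fmax = np.max(np.linalg.norm(f, axis=1))
        if fmax == 0:
            break
        cand = p + step / fmax * f
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        cand_energy = _energy_arr(cand)
        if cand_energy < energy:
            p, energy = cand, cand_energy
            step *= 1.05
        else:
            step *= 0.5
            if step < 1e-12:
                break
    p[p[:, 2] < 0] *= -1.0
    return p.tobytes()


def _energy_arr(p: np.ndarray) -> float:
    return repulsion_energy(p)


def _forces(p: np.ndarray) -> np.ndarray:
    diff = p[:, None, :] - p[None, :, :]
    summ = p[:, None, :] + p[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    f = np.sum(diff / dd[..., None] ** 3, axis=1)
    f += np.sum(summ / ds[..., None] ** 3, axis=1)
    return f


def default_scheme(
    K: int = 81,
    b_value: float = 3000.0,
    seed: int = 0,
    n_iter: int = 2000,
) -> GradientScheme:
    """Quasi-uniform hemisphere scheme by electrostatic-repulsion minimization.

    Axes (with their antipodes) repel each other with a Coulomb potential; a
    projected gradient descent from a seeded random start spreads them over the
    hemisphere.  For ``K = 81`` the minimum pairwise axis angle lands around
    15 degrees, matching typical single-shell acquisition schemes.
    """
    if K < 6:
        raise ValueError("need at least 6 directions")
    axes = np.frombuffer(_dispersed_axes(int(K), int(seed), int(n_iter)), dtype=float)
    return GradientScheme(axes.reshape(K, 3).copy(), b_value)
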