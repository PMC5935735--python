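"""Chain-of-states minimum-energy-path optimization with climbing-image refinement.

The band is optimized as a hybrid of the nudged elastic band and the string
method: NEB force projection (perpendicular true force plus tangential
spring force, with the energy-weighted upwind tangent) alternated with
equal-arc-length reparameterization of the interior images every
``reparam_every`` iterations.  The optimizer is FIRE (fast inertial
relaxation engine), which is deterministic for identical inputs.  After the
band has converged, the highest image can be refined to the saddle point by
the climbing-image procedure: the force component along the tangent is
inverted so the image moves uphill along the path and downhill in all
perpendicular directions.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

__all__ = [
    "EnergySurface",
    "CallableSurface",
    "Path",
    "SaddleResult",
    "BarrierSummary",
    "init_path",
    "optimize_path",
    "climbing_image_refine",
    "path_barrier",
]


class EnergySurface(abc.ABC):
    """A differentiable energy surface: ``energy(x)`` scalar, ``gradient(x)`` vector."""

    #: coordinate dimension
    dimension: int

    @abc.abstractmethod
    def energy(self, x: np.ndarray) -> float: ...

    @abc.abstractmethod
    def gradient(self, x: np.ndarray) -> np.ndarray: ...

    def numeric_gradient(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Central finite-difference gradient (used to validate analytic gradients)."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for k in range(x.size):
            e = np.zeros_like(x)
            e[k] = h
            g[k] = (self.energy(x + e) - self.energy(x - e)) / (2 * h)
        return g


class CallableSurface(EnergySurface):
    """Wrap plain ``energy``/``gradient`` callables as an :class:`EnergySurface`."""

    def __init__(self, dimension: int, energy: Callable, gradient: Callable):
        self.dimension = dimension
        self._energy = energy
        self._gradient = gradient

    def energy(self, x):
        return float(self._energy(np.asarray(x, dtype=float)))

    def gradient(self, x):
        return np.asarray(self._gradient(np.asarray(x, dtype=float)), dtype=float)


@dataclass
class Path:
    """An ordered chain of images with per-image energies.

    The first and last images are the fixed endpoints; only interior images
    move during optimization.
    """

    images: List[np.ndarray]
    energies: Optional[np.ndarray] = None
    converged: bool = False
    n_iterations: int = 0

    def __post_init__(self):
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        dims = {im.shape for im in self.images}
        if len(dims) != 1:
            raise ValueError("all images must share one dimension")

    @property
    def n_images(self) -> int:
        return len(self.images)

    def coordinates(self) -> np.ndarray:
        return np.array(self.images)

    def highest_index(self) -> int:
        if self.energies is None:
            raise ValueError("path has no energies")
        return int(np.argmax(self.energies))


@dataclass
class SaddleResult:
    coords: np.ndarray
    energy: float
    grad_norm: float
    converged: bool
    n_iterations: int = 0


@dataclass
class BarrierSummary:
    """Barrier bookkeeping relative to the reactant (first image)."""

    activation: float  # max(E) − E[0]
    reaction: float  # E[last] − E[0]


def init_path(start: np.ndarray, end: np.ndarray, n_images: int = 20) -> Path:
    """Linear-interpolation initial path with ``n_images`` equally spaced images."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if start.shape != end.shape:
        raise ValueError("start and end must have the same dimension")
    if n_images < 2:
        raise ValueError("a path needs at least the two endpoints")
    ts = np.linspace(0.0, 1.0, n_images)
    images = [(1 - t) * start + t * end for t in ts]
    images[0] = start.copy()
    images[-1] = end.copy()
    return Path(images=images)


def _tangents(images: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Energy-weighted upwind tangents (improved-tangent scheme) for interior images."""
    n = len(images)
    taus = np.zeros_like(images)
    for i in range(1, n - 1):
        dplus = images[i + 1] - images[i]
        dminus = images[i] - images[i - 1]
        e_prev, e_i, e_next = energies[i - 1], energies[i], energies[i + 1]
        if e_next > e_i and e_i > e_prev:
            tau = dplus
        elif e_next < e_i and e_i < e_prev:
            tau = dminus
        else:
            dmax = max(abs(e_next - e_i), abs(e_prev - e_i))
            dmin = min(abs(e_next - e_i), abs(e_prev - e_i))
            if e_next > e_prev:
                tau = dplus * dmax + dminus * dmin
            else:
                tau = dplus * dmin + dminus * dmax
        norm = np.linalg.norm(tau)
        taus[i] = tau / norm if norm > 0 else tau
    return taus


def _neb_forces(surface: EnergySurface, images: np.ndarray, energies: np.ndarray,
                gradients: np.ndarray, spring_k: float,
                climb_index: Optional[int] = None) -> np.ndarray:
    taus = _tangents(images, energies)
    n = len(images)
    forces = np.zeros_like(images)
    for i in range(1, n - 1):
        tau = taus[i]
        f_true = -gradients[i]
        if climb_index is not None and i == climb_index:
            forces[i] = f_true - 2.0 * np.dot(f_true, tau) * tau
            continue
        f_perp = f_true - np.dot(f_true, tau) * tau
        f_spring = spring_k * (
            np.linalg.norm(images[i + 1] - images[i])
            - np.linalg.norm(images[i] - images[i - 1])
        ) * tau
        forces[i] = f_perp + f_spring
    return forces


def _reparameterize(images: np.ndarray) -> np.ndarray:
    """String-method step: redistribute interior images to equal arc length.

    Uses a natural cubic spline through the current images so the
    redistribution error is O(Δs⁴) and does not stall band convergence.
    """
    from scipy.interpolate import CubicSpline

    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return images
    # arc must be strictly increasing for the spline; nudge duplicate knots
    for i in range(1, len(arc)):
        if arc[i] <= arc[i - 1]:
            arc[i] = arc[i - 1] + 1e-12 * total
    spline = CubicSpline(arc, images, axis=0)
    targets = np.linspace(0.0, arc[-1], len(images))
    out = spline(targets)
    out[0] = images[0]
    out[-1] = images[-1]
    return out


class _Fire:
    """FIRE minimizer state (Bitzek et al. parameters, conservative step cap)."""

    def __init__(self, n_dof: int, dt: float = 0.05, dt_max: float = 0.25,
                 f_inc: float = 1.1, f_dec: float = 0.5, alpha0: float = 0.1,
                 f_alpha: float = 0.99, n_min: int = 5, max_step: float = 0.1):
        self.v = np.zeros(n_dof)
        self.dt = dt
        self.dt_max = dt_max
        self.f_inc, self.f_dec = f_inc, f_dec
        self.alpha = self.alpha0 = alpha0
        self.f_alpha = f_alpha
        self.n_min = n_min
        self.n_pos = 0
        self.max_step = max_step

    def step(self, forces: np.ndarray) -> np.ndarray:
        f = forces.ravel()
        p = float(np.dot(f, self.v))
        if p > 0:
            fn = np.linalg.norm(f)
            vn = np.linalg.norm(self.v)
            if fn > 0:
                self.v = (1 - self.alpha) * self.v + self.alpha * vn * f / fn
            self.n_pos += 1
            if self.n_pos > self.n_min:
                self.dt = min(self.dt * self.f_inc, self.dt_max)
                self.alpha *= self.f_alpha
        else:
            self.v[:] = 0.0
            self.dt *= self.f_dec
            self.alpha = self.alpha0
            self.n_pos = 0
        self.v = self.v + self.dt * f
        dx = self.dt * self.v
        norm = np.linalg.norm(dx)
        if norm > self.max_step:
            dx = dx * (self.max_step / norm)
        return dx.reshape(forces.shape)


def _eval_band(surface: EnergySurface, images: np.ndarray):
    energies = np.empty(len(images))
    gradients = np.empty_like(images)
    for i, im in enumerate(images):
        e = surface.energy(im)
        g = surface.gradient(im)
        if not (np.isfinite(e) and np.all(np.isfinite(g))):
            raise ValueError(f"non-finite energy or gradient at image {i}")
        energies[i] = e
        gradients[i] = g
    return energies, gradients


def optimize_path(
    surface: EnergySurface,
    path: Path,
    spring_k: float = 1.0,
    force_tol: float = 1e-4,
    max_iter: int = 5000,
    reparam_every: int = 10,
) -> Path:
    """Relax a chain of states to the minimum-energy path.

    Converged when the RMS of the perpendicular true force over interior
    images falls below ``force_tol``.  Endpoints never move.  Returns a new
    :class:`Path` with energies populated; ``converged`` records whether the
    tolerance was met within ``max_iter``.
    """
    images = path.coordinates()
    if images.ndim != 2:
        raise ValueError("path images must be 1-D coordinate vectors")
    if getattr(surface, "dimension", images.shape[1]) != images.shape[1]:
        raise ValueError(
            f"surface dimension {surface.dimension} does not match path dimension {images.shape[1]}"
        )
    start = images[0].copy()
    end = images[-1].copy()

    fire = _Fire(images.size)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        energies, gradients = _eval_band(surface, images)
        taus = _tangents(images, energies)
        # convergence measured on the projected true force only
        f_perp_sq = 0.0
        for i in range(1, len(images) - 1):
            f_true = -gradients[i]
            fp = f_true - np.dot(f_true, taus[i]) * taus[i]
            f_perp_sq += float(np.dot(fp, fp))
        rms = np.sqrt(f_perp_sq / max(len(images) - 2, 1) / images.shape[1])
        if rms < force_tol:
            converged = True
            break
        forces = _neb_forces(surface, images, energies, gradients, spring_k)
        images = images + fire.step(forces)
        images[0] = start
        images[-1] = end
        if reparam_every > 0 and it % reparam_every == 0:
            images = _reparameterize(images)
    energies, _ = _eval_band(surface, images)
    return Path(
        images=[im.copy() for im in images],
        energies=energies,
        converged=converged,
        n_iterations=it,
    )


def climbing_image_refine(
    surface: EnergySurface,
    path: Path,
    tol: float = 1e-6,
    max_iter: int = 20000,
    divergence_energy: float = 1e8,
) -> SaddleResult:
    """Drive the highest image to the saddle point (climbing-image refinement).

    The highest-energy image moves uphill along the band tangent and
    downhill perpendicular to it until the true gradient norm falls below
    ``tol``.  The band itself is kept fixed apart from the climbing image;
    the returned energy is never below the pre-refinement path maximum
    minus ``tol``.
    """
    if path.energies is None:
        raise ValueError("path must be optimized (energies populated) before refinement")
    images = path.coordinates()
    hi = path.highest_index()
    if hi in (0, len(images) - 1):
        # barrier-less profile: the maximum is an endpoint, nothing to climb
        x = images[hi]
        g = surface.gradient(x)
        return SaddleResult(coords=x.copy(), energy=float(surface.energy(x)),
                            grad_norm=float(np.linalg.norm(g)),
                            converged=bool(np.linalg.norm(g) <= tol), n_iterations=0)
    e_max_pre = float(path.energies[hi])

    fire = _Fire(images.shape[1], max_step=0.05)
    x = images[hi].copy()
    it = 0
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        g = surface.gradient(x)
        e = surface.energy(x)
        if not np.isfinite(e) or e > divergence_energy:
            raise RuntimeError(f"climbing image diverged at iteration {it} (E={e})")
        grad_norm = float(np.linalg.norm(g))
        if grad_norm <= tol:
            break
        local = np.array([images[hi - 1], x, images[hi + 1]])
        e_loc = np.array([surface.energy(images[hi - 1]), e, surface.energy(images[hi + 1])])
        tau = _tangents(local, e_loc)[1]
        f_true = -g
        f_climb = f_true - 2.0 * np.dot(f_true, tau) * tau
        x = x + fire.step(f_climb).ravel()
    energy = float(surface.energy(x))
    return SaddleResult(
        coords=x,
        energy=energy,
        grad_norm=grad_norm,
        converged=grad_norm <= tol,
        n_iterations=it,
    )


def path_barrier(path: Path) -> BarrierSummary:
    """Activation (max − reactant) and reaction (product − reactant) energies."""
    if path.energies is None or len(path.energies) == 0:
        raise ValueError("path has no energies")
    e = np.asarray(path.energies, dtype=float)
    return BarrierSummary(
        activation=float(e.max() - e[0]),
        reaction=float(e[-1] - e[0]),
    )
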