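"""Synthetic fixtures with known exact answers.

Every generator here is a pure function of its arguments and seed, drawing
from one named ``numpy.random.default_rng`` stream, so identical inputs give
bitwise-identical outputs.  The fixtures are designed so each downstream
estimator has a sharp correctness oracle:

* Born ions — closed-form continuum solvation energy for the PB solver.
* Toy titratable sites — a serine-ester / amino / tyrosine-hydroxyl triad
  mimic with two disjoint charge perturbations, exercising the four-state
  protonation bookkeeping.
* Linear-response ensembles — per-atom potentials drawn from equal-variance
  Gaussians, the regime where the LRA estimate is exact.
* Analytic 2-D energy surfaces — the Müller–Brown benchmark and a
  direct-versus-relay proton-transfer pair sharing endpoints, where the
  relay channel has the lower barrier by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .lra import EnsemblePotentials
from .neb import EnergySurface
from .structures import Atom, Structure, TitratableSite

__all__ = [
    "LinearResponseSpec",
    "born_ion",
    "toy_titratable_site",
    "make_linear_response_ensemble",
    "muller_brown",
    "proton_transfer_surfaces",
    "MullerBrown",
    "TwoChannelSurface",
]


def born_ion(q: float, radius: float) -> Structure:
    """A single ion at the origin — the closed-form validation fixture.

    The continuum solvation energy is −k_e·q²·(1/ε_in − 1/ε_out)/(2·radius).
    """
    if radius <= 0:
        raise ValueError("Born radius must be positive")
    atom = Atom(index=0, name="ION", residue_label="ION",
                position=np.zeros(3), charge=float(q), radius=float(radius))
    return Structure(atoms=[atom], title=f"Born ion q={q} a={radius}")


def toy_titratable_site(seed: int = 0) -> Tuple[Structure, TitratableSite, TitratableSite]:
    """A small active-site mimic with two disjoint titratable groups.

    Emulates the two ionisable groups of a dipeptidyl-enzyme active site: a
    tyrosine-like hydroxyl (2-atom δq set) and an N-terminal amino group
    (4-atom δq set), embedded in a ~20-atom neutral scaffold.  Both sites
    satisfy Σδq = +1, so the four (de)protonation combinations carry net
    charges {0, +1, +1, +2}.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    atoms = []

    def add(name, res, pos, q, r):
        atoms.append(Atom(index=len(atoms), name=name, residue_label=res,
                          position=np.asarray(pos, dtype=float), charge=q, radius=r))

    # tyrosine-like hydroxyl: O–H pair (deprotonated reference charges)
    add("OH", "TYR", [0.0, 0.0, 0.0], -0.60, 1.6)
    add("HH", "TYR", [0.95, 0.0, 0.0], 0.00, 0.8)
    # amino group: N + 3 H (deprotonated NH2 reference; one dummy proton site)
    add("N", "NTR", [2.8, 0.5, 0.2], -0.90, 1.7)
    add("H1", "NTR", [3.4, 1.2, 0.2], 0.30, 0.9)
    add("H2", "NTR", [3.2, -0.3, 0.5], 0.30, 0.9)
    add("H3", "NTR", [2.5, 0.7, 1.1], 0.00, 0.9)
    # serine-ester carbonyl mimic
    add("C", "SER", [1.5, -1.8, 0.0], 0.55, 1.9)
    add("O", "SER", [1.5, -2.9, 0.3], -0.55, 1.5)
    # neutral scaffold shell: carbons packed 4.5–7 Å from the site centroid,
    # rejected if they clash with anything already placed
    n_scaffold = 12
    centre = np.mean([a.position for a in atoms], axis=0)
    placed = 0
    while placed < n_scaffold:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = centre + direction * rng.uniform(4.5, 7.0)
        if min(np.linalg.norm(pos - a.position) for a in atoms) < 2.8:
            continue
        add(f"C{placed}", "SCF", pos, 0.15 if placed % 2 == 0 else -0.15, 1.9)
        placed += 1

    structure = Structure(atoms=atoms, title=f"toy titratable site (seed={seed})")

    # protonated-minus-deprotonated charge differences; each sums to +1
    hydroxyl = TitratableSite(
        label="Y-OH", atom_indices=[0, 1], delta_q=[0.57, 0.43], model_pka=10.1
    )
    amino = TitratableSite(
        label="N-term", atom_indices=[2, 3, 4, 5], delta_q=[0.40, 0.13, 0.13, 0.34],
        model_pka=8.0,
    )
    return structure, hydroxyl, amino


@dataclass(frozen=True)
class LinearResponseSpec:
    """Ground truth for a Gaussian linear-response ensemble.

    Per-atom potentials are Normal(v_A, σ) in the protonated-state ensemble
    and Normal(v_B, σ) in the deprotonated one; with equal variances the
    exact free energy of the charge change is Σ δq·(v_A + v_B)/2.
    """

    v_A: np.ndarray
    v_B: np.ndarray
    sigma: float
    delta_q: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "v_A", np.asarray(self.v_A, dtype=float))
        object.__setattr__(self, "v_B", np.asarray(self.v_B, dtype=float))
        object.__setattr__(self, "delta_q", np.asarray(self.delta_q, dtype=float))
        if not (self.v_A.shape == self.v_B.shape == self.delta_q.shape):
            raise ValueError("v_A, v_B and delta_q must have one length")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def exact_dg(self) -> float:
        return float(np.sum(self.delta_q * (self.v_A + self.v_B) / 2.0))


def make_linear_response_ensemble(
    spec: LinearResponseSpec, n: int, seed: int = 0
) -> Tuple[EnsemblePotentials, float]:
    """Draw an equal-variance Gaussian potential ensemble; returns (potentials, exact ΔG)."""
    if n < 1:
        raise ValueError("need at least one sample per state")
    rng = np.random.default_rng(seed)
    n_atoms = spec.v_A.size
    samples_A = rng.normal(loc=spec.v_A, scale=spec.sigma, size=(n, n_atoms))
    samples_B = rng.normal(loc=spec.v_B, scale=spec.sigma, size=(n, n_atoms))
    pots = EnsemblePotentials(
        site_label="linear-response",
        mean_V_A=samples_A.mean(axis=0),
        mean_V_B=samples_B.mean(axis=0),
        n_A=n,
        n_B=n,
        samples_A=samples_A,
        samples_B=samples_B,
    )
    return pots, spec.exact_dg


# ---------------------------------------------------------------------------
# Analytic 2-D surfaces
# ---------------------------------------------------------------------------


class MullerBrown(EnergySurface):
    """The standard four-term exponential Müller–Brown surface with analytic gradient."""

    dimension = 2

    _A = np.array([-200.0, -100.0, -170.0, 15.0])
    _a = np.array([-1.0, -1.0, -6.5, 0.7])
    _b = np.array([0.0, 0.0, 11.0, 0.6])
    _c = np.array([-10.0, -10.0, -6.5, 0.7])
    _x0 = np.array([1.0, 0.0, -0.5, -1.0])
    _y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, x):
        dx = x[0] - self._x0
        dy = x[1] - self._y0
        return dx, dy, self._A * np.exp(self._a * dx**2 + self._b * dx * dy + self._c * dy**2)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return float(self._terms(x)[2].sum())

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        dx, dy, t = self._terms(x)
        gx = np.sum(t * (2 * self._a * dx + self._b * dy))
        gy = np.sum(t * (self._b * dx + 2 * self._c * dy))
        return np.array([gx, gy])


def muller_brown() -> MullerBrown:
    """The Müller–Brown benchmark surface (two deep minima, two saddles)."""
    return MullerBrown()


class TwoChannelSurface(EnergySurface):
    """A 2-D proton-transfer surface: transfer coordinate x, relay coordinate y.

    E(x, y) = A(x) + W(x)·S(y) + k·y²

    where A is a skewed double well with exact minima at x = ±1, W = (1−x²)²
    is the transfer barrier hump (zero value *and* slope at the wells), and
    S(y) modulates the hump along the relay coordinate.  With S constant the
    only channel is the direct one at y = 0; lowering S near y = 1 opens a
    relay channel that detours through the relay coordinate.  Both wells
    (±1, 0) are exact minima with zero gradient for any S with S'(0) finite,
    because W and W' vanish there.
    """

    dimension = 2

    def __init__(self, barrier_scale: float, relay_depth: float = 0.0,
                 relay_width: float = 0.7, confinement: float = 0.4,
                 asymmetry: float = -0.15):
        if barrier_scale <= 0:
            raise ValueError("barrier scale must be positive")
        self.barrier_scale = barrier_scale
        self.relay_depth = relay_depth  # reduction of the hump at y = 1
        self.relay_width = relay_width
        self.confinement = confinement
        self.asymmetry = asymmetry  # inner stationary point of A, in (−1, 1)

    # skewed double well: A'(x) = x³ − x_b·x² − x + x_b has roots −1, x_b, +1
    def _A(self, x):
        xb = self.asymmetry
        # constant shifts the reactant well A(−1) to zero
        return x**4 / 4 - xb * x**3 / 3 - x**2 / 2 + xb * x + (1.0 / 4 + 2.0 * xb / 3)

    def _A_prime(self, x):
        xb = self.asymmetry
        return x**3 - xb * x**2 - x + xb

    def _S(self, y):
        g = np.exp(-((y - 1.0) ** 2) / (2 * self.relay_width**2))
        return self.barrier_scale - self.relay_depth * g

    def _S_prime(self, y):
        g = np.exp(-((y - 1.0) ** 2) / (2 * self.relay_width**2))
        return self.relay_depth * g * (y - 1.0) / self.relay_width**2

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        W = (1 - x[0] ** 2) ** 2
        return float(self._A(x[0]) + W * self._S(x[1]) + self.confinement * x[1] ** 2)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        W = (1 - x[0] ** 2) ** 2
        W_prime = -4 * x[0] * (1 - x[0] ** 2)
        gx = self._A_prime(x[0]) + W_prime * self._S(x[1])
        gy = W * self._S_prime(x[1]) + 2 * self.confinement * x[1]
        return np.array([gx, gy])

    @property
    def reactant(self) -> np.ndarray:
        return np.array([-1.0, 0.0])

    @property
    def product(self) -> np.ndarray:
        return np.array([1.0, 0.0])


def proton_transfer_surfaces(
    direct_barrier_scale: float = 5.0,
    relay_barrier_scale: float = 1.0,
    seed: Optional[int] = None,
) -> Tuple[TwoChannelSurface, TwoChannelSurface]:
    """Direct-vs-relay proton-transfer surface pair sharing both endpoints.

    The two surfaces have identical wells at (±1, 0) with identical energies
    (so equal reaction energies); the direct surface has a single channel at
    y = 0 with hump height ~``direct_barrier_scale``, while the relay
    surface opens a low channel near y = 1 whose hump is reduced to
    ~``relay_barrier_scale``, so the relay activation energy is strictly
    smaller.  ``seed`` is accepted for generator-API uniformity; the
    surfaces are fully analytic and deterministic.
    """
    if direct_barrier_scale <= 0 or relay_barrier_scale <= 0:
        raise ValueError("barrier scales must be positive")
    if direct_barrier_scale <= relay_barrier_scale:
        raise ValueError(
            "direct_barrier_scale must exceed relay_barrier_scale (the relay is "
            "the low-barrier route by contract)"
        )
    direct = TwoChannelSurface(barrier_scale=direct_barrier_scale, relay_depth=0.0)
    relay = TwoChannelSurface(
        barrier_scale=direct_barrier_scale,
        relay_depth=direct_barrier_scale - relay_barrier_scale,
    )
    return direct, relay
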