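"""Free-energy perturbation along a fixed reaction path, plus the RRHO correction.

The free-energy change between adjacent path images i and i+1 is estimated
with the one-sided (Zwanzig) exponential average

    ΔA(i→i+1) = −(1/β) · ln ⟨ exp(−β·ΔE_pert) ⟩_i

where ΔE_pert is the perturbation energy: the coupled energy evaluated with
the environment (MM) configuration drawn from the ensemble of image i but
the frozen internal (QM-region) coordinates of image i+1, minus the same
with the coordinates of image i.  The exponential average is evaluated in
the log domain (shift-by-max), so finite samples can never overflow.

Harmonic vibrational free energies of the frozen region come from
mass-weighted normal-mode analysis of a Hessian in kcal/mol/Å² with masses
in amu; imaginary modes are counted and excluded from the sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .lra import ThermoConfig
from .neb import Path

__all__ = [
    "PerturbationSamples",
    "FreeEnergyProfile",
    "RrhoResult",
    "fep_increment",
    "fep_profile",
    "rrho_vibrational_free_energy",
]

# sqrt(kcal/mol/Å²/amu) -> cm⁻¹ for harmonic frequencies
_SQRT_KCAL_TO_WAVENUMBER = 108.5914
# 1 cm⁻¹ in kcal/mol
_WAVENUMBER_TO_KCAL = 2.85911e-3


@dataclass
class PerturbationSamples:
    """Per-snapshot perturbation energies ΔE_pert for one image pair, kcal/mol."""

    values: np.ndarray
    image_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("at least one perturbation sample is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("perturbation samples must be finite")


@dataclass
class FreeEnergyProfile:
    """Per-pair FEP increments and the cumulative profile relative to image 0."""

    increments: np.ndarray
    cumulative: np.ndarray
    std_errors: np.ndarray

    def __post_init__(self):
        self.increments = np.asarray(self.increments, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        self.std_errors = np.asarray(self.std_errors, dtype=float)


@dataclass
class RrhoResult:
    """Normal-mode frequencies (cm⁻¹) and harmonic vibrational free energy."""

    frequencies: np.ndarray
    zero_point: float
    g_vib: float
    n_imaginary: int


def _zwanzig(values: np.ndarray, beta: float) -> float:
    # −(1/β)·ln⟨exp(−β·ΔE)⟩ via logsumexp: immune to overflow for finite input
    n = values.size
    return float(-(logsumexp(-beta * values) - np.log(n)) / beta)


def fep_increment(samples: PerturbationSamples, beta: float,
                  n_blocks: int = 5) -> tuple:
    """One-sided FEP estimate ΔA and its block-averaged standard error, kcal/mol.

    β must be positive, in (kcal/mol)⁻¹.  The standard error uses 5-block
    averaging by default; with fewer samples than blocks it is reported as 0.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    values = samples.values
    delta_a = _zwanzig(values, beta)
    if values.size >= n_blocks:
        blocks = np.array_split(values, n_blocks)
        estimates = np.array([_zwanzig(b, beta) for b in blocks])
        se = float(estimates.std(ddof=1) / np.sqrt(n_blocks))
    else:
        se = 0.0
    return delta_a, se


def fep_profile(
    images: Path,
    ensemble_source: Callable[[int, np.random.Generator], Sequence],
    coupled_energy: Callable[[np.ndarray, object], float],
    beta: float,
    rng: Optional[np.random.Generator] = None,
) -> FreeEnergyProfile:
    """Assemble the free-energy profile along a fixed path by per-pair FEP.

    Parameters
    ----------
    images : Path
        The optimized path; its coordinates are the frozen internal
        (QM-region) geometries.
    ensemble_source : callable(image_index, rng) -> sequence of MM configurations
        Draws the environment ensemble of one image.  Snapshots may be any
        objects ``coupled_energy`` understands.
    coupled_energy : callable(image_coords, mm_configuration) -> kcal/mol
        The coupled internal/environment energy.
    beta : float
        1/(R·T), (kcal/mol)⁻¹.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    rng = rng or np.random.default_rng(0)
    coords = images.coordinates()
    n = len(coords)
    increments = np.zeros(n - 1)
    std_errors = np.zeros(n - 1)
    for i in range(n - 1):
        configs = ensemble_source(i, rng)
        if len(configs) == 0:
            raise ValueError(f"ensemble source returned no configurations for image {i}")
        values = np.empty(len(configs))
        for k, mm in enumerate(configs):
            e1 = coupled_energy(coords[i + 1], mm)
            e0 = coupled_energy(coords[i], mm)
            values[k] = e1 - e0
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite perturbation energy at image {i}")
        increments[i], std_errors[i] = fep_increment(
            PerturbationSamples(values=values, image_index=i), beta
        )
    cumulative = np.concatenate([[0.0], np.cumsum(increments)])
    return FreeEnergyProfile(
        increments=increments, cumulative=cumulative, std_errors=std_errors
    )


def rrho_vibrational_free_energy(
    hessian: np.ndarray,
    masses: Sequence[float],
    thermo: ThermoConfig = ThermoConfig(),
) -> RrhoResult:
    """Harmonic vibrational free energy from a Cartesian Hessian.

    ``hessian`` is symmetric, kcal/mol/Å², with one row/column per Cartesian
    degree of freedom; ``masses`` holds one amu value per degree of freedom
    (repeat each atomic mass three times for x/y/z).  Frequencies come from
    the mass-weighted eigenproblem; for each real mode

        g = hω/2 + k_B·T·ln(1 − e^{−hω/k_BT})        [kcal/mol]

    and the total is the sum over real modes.  Negative-eigenvalue
    (imaginary) modes are counted and excluded.
    """
    H = np.asarray(hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("hessian must be a square matrix")
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("hessian must be symmetric (1e-8 tolerance)")
    m = np.asarray(masses, dtype=float)
    if m.shape != (H.shape[0],):
        raise ValueError("need one mass per Hessian degree of freedom")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")

    inv_sqrt_m = 1.0 / np.sqrt(m)
    Hmw = H * np.outer(inv_sqrt_m, inv_sqrt_m)
    eigvals = np.linalg.eigvalsh(Hmw)

    # near-zero eigenvalues are roto-translational: excluded, not imaginary
    zero_tol = 1e-12 * max(float(np.abs(eigvals).max()), 1.0)
    n_imag = int(np.sum(eigvals < -zero_tol))
    pos = eigvals[eigvals > zero_tol]
    freqs = _SQRT_KCAL_TO_WAVENUMBER * np.sqrt(pos)  # cm⁻¹

    hw = freqs * _WAVENUMBER_TO_KCAL  # mode quanta, kcal/mol
    zero_point = float(0.5 * hw.sum())
    kt = thermo.R * thermo.T
    with np.errstate(divide="ignore"):
        thermal = kt * np.log1p(-np.exp(-hw / kt))
    g_vib = float(zero_point + thermal.sum())
    return RrhoResult(
        frequencies=freqs, zero_point=zero_point, g_vib=g_vib, n_imaginary=n_imag
    )
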