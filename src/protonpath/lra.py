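"""Linear-response protonation free energies, pKa shifts, and state ranking.

The linear response approximation (LRA) estimates the free energy of a
charge perturbation δq from the average electrostatic potentials of the two
end states:

    ΔG = Σ_i δq_i · (⟨V_i⟩_A + ⟨V_i⟩_B) / 2

where state A is protonated and state B deprotonated, and ⟨V_i⟩ is the
potential on atom i averaged over an ensemble of conformations of that
state.  When the potential fluctuations are Gaussian with equal variance in
both states this estimate is exact, which is precisely the regime the
synthetic generator in :mod:`protonpath.synth` realises.

The pKa of the group in the protein follows from comparing the same charge
perturbation in the protein and in solvent:

    pKa(prot) = pKa(solv) + (ΔG_prot − ΔG_solv) / (2.303·R·T)

with ΔG the *deprotonation* free energy (charge change protonated →
deprotonated) in each medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .pb import PBConfig, R_KCAL, auto_grid, build_maps, potential_at_atoms, solve_lpb
from .structures import FrameSet, Structure, TitratableSite, apply_charge_state

__all__ = [
    "ThermoConfig",
    "EnsemblePotentials",
    "LraResult",
    "PkaResult",
    "StateRanking",
    "ensemble_mean_potentials",
    "lra_free_energy",
    "pka_in_protein",
    "rank_protonation_states",
    "absolute_protonation_free_energy",
]

LN10 = 2.302585092994046


@dataclass(frozen=True)
class ThermoConfig:
    """Temperature/pH context.  R is the molar gas constant, kcal/(mol·K)."""

    T: float = 300.0
    R: float = R_KCAL
    pH: float = 7.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """1/(R·T), (kcal/mol)⁻¹."""
        return 1.0 / (self.R * self.T)

    @property
    def rt_ln10(self) -> float:
        """2.303·R·T, kcal/mol per pKa unit."""
        return LN10 * self.R * self.T


@dataclass
class EnsemblePotentials:
    """Per-site-atom mean potentials over the two protonation-state ensembles."""

    site_label: str
    mean_V_A: np.ndarray  # protonated-state ensemble, kcal/(mol·e)
    mean_V_B: np.ndarray  # deprotonated-state ensemble
    n_A: int
    n_B: int
    #: per-frame potentials (n_frames × n_site_atoms), kept for block averaging
    samples_A: Optional[np.ndarray] = None
    samples_B: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mean_V_A = np.asarray(self.mean_V_A, dtype=float)
        self.mean_V_B = np.asarray(self.mean_V_B, dtype=float)
        if self.mean_V_A.shape != self.mean_V_B.shape:
            raise ValueError("state A and B mean potentials must have equal atom count")
        if self.n_A < 1 or self.n_B < 1:
            raise ValueError("snapshot counts must be >= 1")


@dataclass
class LraResult:
    """ΔG of the charge change A→B (deprotonation), with per-atom decomposition."""

    delta_g: float
    per_atom_terms: np.ndarray
    site_label: str
    std_error: float = 0.0


@dataclass
class PkaResult:
    pka_prot: float
    pka_solv: float
    dG_prot: float
    dG_solv: float
    T: float


@dataclass
class StateRanking:
    """Protonation states sorted by relative free energy, minimum re-referenced to 0."""

    states: List[Tuple[str, float, float]]  # (label, ΔG rel. to minimum, uncertainty)


def ensemble_mean_potentials(
    template: Structure,
    frames_A: FrameSet,
    frames_B: FrameSet,
    site: TitratableSite,
    pb_config: PBConfig = None,
    solver: Optional[Callable[[Structure], np.ndarray]] = None,
) -> EnsemblePotentials:
    """Average per-site-atom electrostatic potentials over two state ensembles.

    State-A frames are solved with the site protonated, state-B frames with
    it deprotonated; charges and radii come from ``template``, coordinates
    from the frames.  ``solver`` may override the PB solve (it receives a
    Structure and returns per-atom potentials) — used for testing and for
    analytic ensembles.
    """
    if frames_A.n_atoms != len(template) or frames_B.n_atoms != len(template):
        raise ValueError("frame atom counts must match the template structure")
    pb_config = pb_config or PBConfig()

    def default_solver(struct: Structure) -> np.ndarray:
        grid = auto_grid(struct, spacing=pb_config.spacing)
        diel, kap = build_maps(
            struct, grid,
            probe_radius=pb_config.probe_radius,
            eps_in=pb_config.eps_in, eps_out=pb_config.eps_out,
            ionic_strength=pb_config.ionic_strength,
            ion_exclusion=pb_config.ion_exclusion,
            temperature=pb_config.temperature,
        )
        field = solve_lpb(diel, kap, struct, tol=pb_config.tol, max_iter=pb_config.max_iter)
        return potential_at_atoms(field, struct)

    solve = solver or default_solver
    idx = np.asarray(site.atom_indices, dtype=int)

    def state_means(frames: FrameSet, state: str) -> np.ndarray:
        charged = apply_charge_state(template, site, state)
        rows = []
        for coords in frames.frames:
            struct = charged.with_positions(coords)
            rows.append(np.asarray(solve(struct), dtype=float)[idx])
        return np.array(rows)

    samples_A = state_means(frames_A, "protonated")
    samples_B = state_means(frames_B, "deprotonated")
    return EnsemblePotentials(
        site_label=site.label,
        mean_V_A=samples_A.mean(axis=0),
        mean_V_B=samples_B.mean(axis=0),
        n_A=len(frames_A),
        n_B=len(frames_B),
        samples_A=samples_A,
        samples_B=samples_B,
    )


def _block_se(samples: np.ndarray, weights: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of Σ_i w_i·⟨V_i⟩/2 by block averaging over snapshots."""
    n = samples.shape[0]
    if n < n_blocks:
        return 0.0
    blocks = np.array_split(np.arange(n), n_blocks)
    vals = np.array([samples[b].mean(axis=0) @ weights / 2.0 for b in blocks])
    return float(vals.std(ddof=1) / np.sqrt(n_blocks))


def lra_free_energy(site: TitratableSite, pots: EnsemblePotentials,
                    n_blocks: int = 5) -> LraResult:
    """LRA free energy ΔG = Σ_i δq_i·(⟨V_i⟩_A + ⟨V_i⟩_B)/2, kcal/mol.

    Sign convention: δq is the protonated-minus-deprotonated charge
    difference, so a positive ΔG means the environment stabilises the
    protonated state (deprotonation is unfavourable).  Comparing the same
    site in protein and solvent through :func:`pka_in_protein` then raises
    the in-protein pKa when ΔG_prot > ΔG_solv.
    """
    dq = np.asarray(site.delta_q, dtype=float)
    if dq.shape != pots.mean_V_A.shape:
        raise ValueError(
            f"delta_q length {dq.shape} does not match potentials {pots.mean_V_A.shape}"
        )
    per_atom = dq * (pots.mean_V_A + pots.mean_V_B) / 2.0
    se = 0.0
    if pots.samples_A is not None and pots.samples_B is not None:
        se_A = _block_se(pots.samples_A, dq, n_blocks)
        se_B = _block_se(pots.samples_B, dq, n_blocks)
        se = float(np.hypot(se_A, se_B))
    return LraResult(
        delta_g=float(per_atom.sum()),
        per_atom_terms=per_atom,
        site_label=pots.site_label,
        std_error=se,
    )


def pka_in_protein(dG_prot: float, dG_solv: float, pka_solv: float,
                   thermo: ThermoConfig = ThermoConfig()) -> PkaResult:
    """pKa of a titratable group in the protein from the PB/LRA free energies.

    pKa(prot) = pKa(solv) + (ΔG_prot − ΔG_solv)/(2.303·R·T), with ΔG the
    deprotonation free energy in each medium.
    """
    shift = (dG_prot - dG_solv) / thermo.rt_ln10
    return PkaResult(
        pka_prot=pka_solv + shift,
        pka_solv=pka_solv,
        dG_prot=dG_prot,
        dG_solv=dG_solv,
        T=thermo.T,
    )


def rank_protonation_states(
    states: Sequence[Tuple[str, float, float]]
) -> StateRanking:
    """Sort protonation states by free energy, re-referenced to the minimum.

    Ties are broken by lexicographic label order.  ``states`` holds
    (label, ΔG kcal/mol, uncertainty) triples.
    """
    if not states:
        raise ValueError("at least one state is required")
    ref = min(g for _, g, _ in states)
    shifted = [(lab, g - ref, u) for lab, g, u in states]
    shifted.sort(key=lambda t: (t[1], t[0]))
    return StateRanking(states=shifted)


def absolute_protonation_free_energy(
    ddg: float, model_pka: float, thermo: ThermoConfig = ThermoConfig()
) -> float:
    """Combine a relative in-protein ΔΔG with a model-compound pKa, kcal/mol.

    Convention: ΔG_abs = ΔΔG + 2.303·R·T·(pKa_model − pH).  A positive value
    means the protonated form is disfavoured at the reference pH.
    """
    return ddg + thermo.rt_ln10 * (model_pka - thermo.pH)
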