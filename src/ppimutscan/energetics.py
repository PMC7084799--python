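"""MM/PBSA-style binding free energy for a two-chain complex.

Single-trajectory end-state estimate: the complex and both unbound chains
are evaluated on identical coordinates, so every bonded and intra-chain
nonbonded term cancels exactly and the binding energy reduces to

    dG_bind = dE_vdW + dE_elec + dG_polar + dG_nonpolar

* dE_vdW / dE_elec — Lennard-Jones 12-6 (Lorentz–Berthelot combining) and
  Coulomb sums over all cross-chain atom pairs, no cutoff, vacuum
  dielectric 1.
* dG_polar — finite-difference linearized Poisson–Boltzmann reaction-field
  energies, complex minus isolated chains, all on the complex-extent grid
  (see :mod:`ppimutscan.pbsolver`).
* dG_nonpolar — gamma * SASA + offset from Shrake–Rupley solvent-accessible
  surface areas.

No entropy term is computed.  Energies in kJ/mol, lengths in Å, charges
in elementary charge units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .ensemble_io import Ensemble, FrameWindow, Structure, select_frames
from . import pbsolver
from .pbsolver import (
    COULOMB_CONSTANT,
    GridSpec,
    PBSettings,
    PotentialGrid,
    grid_for,
)

__all__ = [
    "EnergyTerms",
    "BindingEnergyResult",
    "PBSettings",
    "mm_interaction_energy",
    "mm_interaction_per_atom",
    "shrake_rupley_sasa",
    "nonpolar_solvation",
    "solve_lpb",
    "polar_solvation",
    "frame_binding_energy",
    "ensemble_binding_energy",
]


def solve_lpb(
    structure: Structure,
    settings: PBSettings = PBSettings(),
    grid: GridSpec | None = None,
    reference: bool = False,
) -> PotentialGrid:
    """Solve the linearized PB equation for a parameterized structure."""
    structure.require_parameterized()
    return pbsolver.solve_lpb(
        structure.positions,
        structure.charges,
        structure.vdw_radii,
        settings,
        grid=grid,
        reference=reference,
    )


def polar_solvation(
    structure: Structure,
    settings: PBSettings = PBSettings(),
    grid: GridSpec | None = None,
) -> float:
    """Polar (reaction-field) solvation free energy of a structure, kJ/mol."""
    structure.require_parameterized()
    return pbsolver.polar_solvation(
        structure.positions, structure.charges, structure.vdw_radii, settings, grid=grid
    )


@dataclass(frozen=True)
class EnergyTerms:
    """MM/PBSA components (kJ/mol).

    ``E_MM = E_vdW + E_elec`` (bonded part identically zero in the
    single-trajectory scheme), ``G_solvation = G_polar + G_nonpolar`` and
    ``total = E_MM + G_solvation``; :meth:`from_components` enforces the
    additivity exactly.
    """

    E_vdW: float
    E_elec: float
    E_MM: float
    G_polar: float
    G_nonpolar: float
    G_solvation: float
    total: float

    @classmethod
    def from_components(
        cls, E_vdW: float, E_elec: float, G_polar: float, G_nonpolar: float
    ) -> "EnergyTerms":
        e_mm = E_vdW + E_elec
        g_solv = G_polar + G_nonpolar
        return cls(
            E_vdW=E_vdW,
            E_elec=E_elec,
            E_MM=e_mm,
            G_polar=G_polar,
            G_nonpolar=G_nonpolar,
            G_solvation=g_solv,
            total=e_mm + g_solv,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "E_vdW": self.E_vdW,
            "E_elec": self.E_elec,
            "E_MM": self.E_MM,
            "G_polar": self.G_polar,
            "G_nonpolar": self.G_nonpolar,
            "G_solvation": self.G_solvation,
            "total": self.total,
        }


@dataclass
class BindingEnergyResult:
    """Per-frame terms, their ensemble mean and a bootstrap standard error."""

    per_frame: list[EnergyTerms]
    times: np.ndarray  # ps
    mean: EnergyTerms
    uncertainty: EnergyTerms  # bootstrap SE per component


# ---------------------------------------------------------------------------
# Vacuum molecular mechanics cross-interaction


def _mm_pair_energies(structure: Structure, ia: np.ndarray, ib: np.ndarray):
    """(n_a, n_b) matrices of LJ and Coulomb pair energies, no cutoff."""
    pa, pb = structure.positions[ia], structure.positions[ib]
    d = cdist(pa, pb)
    if np.any(d < 1e-6):
        raise ValueError("overlapping atoms across chains (d < 1e-6 Å)")
    qa, qb = structure.charges[ia], structure.charges[ib]
    sa, sb = structure.lj_sigmas[ia], structure.lj_sigmas[ib]
    ea, eb = structure.lj_epsilons[ia], structure.lj_epsilons[ib]
    sig = 0.5 * (sa[:, None] + sb[None, :])  # Lorentz
    eps = np.sqrt(ea[:, None] * eb[None, :])  # Berthelot
    sr6 = (sig / d) ** 6
    vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    elec = COULOMB_CONSTANT * qa[:, None] * qb[None, :] / d
    return vdw, elec


def mm_interaction_energy(
    structure: Structure, chain_a: str, chain_b: str
) -> tuple[float, float]:
    """Cross-chain vacuum MM interaction: (E_vdW, E_elec) in kJ/mol.

    All atom pairs between the chains are summed without a distance cutoff;
    electrostatics use vacuum dielectric 1.
    """
    structure.require_parameterized()
    ia, ib = structure.chain_indices(chain_a), structure.chain_indices(chain_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty chain selection")
    vdw, elec = _mm_pair_energies(structure, ia, ib)
    return float(vdw.sum()), float(elec.sum())


def mm_interaction_per_atom(
    structure: Structure, chain_a: str, chain_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom cross-chain MM ledger (full pair value booked to both ends).

    Returns (vdw, elec) arrays over all atoms of the structure; summing the
    entries of either single chain reproduces the total cross interaction,
    summing both chains double-counts by construction.
    """
    structure.require_parameterized()
    ia, ib = structure.chain_indices(chain_a), structure.chain_indices(chain_b)
    vdw_m, elec_m = _mm_pair_energies(structure, ia, ib)
    vdw = np.zeros(structure.n_atoms)
    elec = np.zeros(structure.n_atoms)
    vdw[ia], elec[ia] = vdw_m.sum(axis=1), elec_m.sum(axis=1)
    vdw[ib], elec[ib] = vdw_m.sum(axis=0), elec_m.sum(axis=0)
    return vdw, elec


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    structure: Structure, probe: float = 1.4, n_points: int = 512
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²).

    Test points are placed on each atom's expanded sphere (r + probe) and
    counted as accessible when outside every neighbour's expanded sphere;
    the accessible fraction times the sphere area gives the per-atom SASA.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if np.isnan(structure.vdw_radii).any():
        raise ValueError("structure has unparameterized vdW radii")
    pos = structure.positions
    rad = structure.vdw_radii + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(pos)
    areas = np.empty(structure.n_atoms)
    rmax = float(rad.max())
    for i in range(structure.n_atoms):
        nbr = tree.query_ball_point(pos[i], rad[i] + rmax)
        nbr = [j for j in nbr if j != i]
        sphere = pos[i] + rad[i] * pts
        if nbr:
            d2 = np.sum((sphere[:, None, :] - pos[nbr][None, :, :]) ** 2, axis=2)
            accessible = np.all(d2 > (rad[nbr] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * rad[i] ** 2
    return areas


def nonpolar_solvation(sasa_total: float, settings: PBSettings) -> float:
    """Surface-area nonpolar solvation: gamma * SASA + offset (kJ/mol)."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return settings.nonpolar_gamma * sasa_total + settings.nonpolar_offset


# ---------------------------------------------------------------------------
# Binding free energy


@dataclass
class FrameEnergyDetail:
    """Per-atom binding-energy ledgers for one frame (kJ/mol per atom)."""

    vdw: np.ndarray
    elec: np.ndarray
    polar: np.ndarray
    nonpolar: np.ndarray


def _frame_polar_nonpolar(
    structure: Structure,
    ia: np.ndarray,
    ib: np.ndarray,
    settings: PBSettings,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Binding dG_polar / dG_nonpolar plus per-atom ledgers for one frame.

    All three polar states share the complex-extent grid.  Reference
    (uniform-dielectric) solves are done once per chain; by linearity of the
    uniform operator the complex reference is their superposition, so five
    LPB solves cover the six states.
    """
    pos, q, r = structure.positions, structure.charges, structure.vdw_radii
    grid = grid_for(pos, r, settings)

    polar = np.zeros(structure.n_atoms)
    if not np.any(q != 0):  # no charges: reaction field identically zero
        return _nonpolar_part(structure, ia, ib, settings, polar)

    _solve = pbsolver.solve_lpb
    solv_c = _solve(pos, q, r, settings, grid=grid, reference=False)
    solv_a = _solve(pos[ia], q[ia], r[ia], settings, grid=grid, reference=False)
    solv_b = _solve(pos[ib], q[ib], r[ib], settings, grid=grid, reference=False)
    ref_a = _solve(pos[ia], q[ia], r[ia], settings, grid=grid, reference=True)
    ref_b = _solve(pos[ib], q[ib], r[ib], settings, grid=grid, reference=True)

    # atom in A: 1/2 q [phi_solv_complex - phi_ref_complex - phi_solv_A + phi_ref_A]
    #          = 1/2 q [phi_solv_complex - phi_solv_A - phi_ref_B]   (superposition)
    polar[ia] = 0.5 * q[ia] * (
        solv_c.interpolate(pos[ia])
        - solv_a.interpolate(pos[ia])
        - ref_b.interpolate(pos[ia])
    )
    polar[ib] = 0.5 * q[ib] * (
        solv_c.interpolate(pos[ib])
        - solv_b.interpolate(pos[ib])
        - ref_a.interpolate(pos[ib])
    )

    return _nonpolar_part(structure, ia, ib, settings, polar)


def _nonpolar_part(
    structure: Structure,
    ia: np.ndarray,
    ib: np.ndarray,
    settings: PBSettings,
    polar: np.ndarray,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    sasa_c = shrake_rupley_sasa(structure, probe=settings.probe_radius)
    sasa_a = shrake_rupley_sasa(structure.subset(ia), probe=settings.probe_radius)
    sasa_b = shrake_rupley_sasa(structure.subset(ib), probe=settings.probe_radius)
    nonpolar = np.zeros(structure.n_atoms)
    nonpolar[ia] = settings.nonpolar_gamma * (sasa_c[ia] - sasa_a)
    nonpolar[ib] = settings.nonpolar_gamma * (sasa_c[ib] - sasa_b)
    # the constant offset enters the three states as c - a - b
    g_nonpolar = float(nonpolar.sum()) - settings.nonpolar_offset
    return float(polar.sum()), g_nonpolar, polar, nonpolar


def frame_binding_energy(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    settings: PBSettings = PBSettings(),
    include_solvation: bool = True,
    details: bool = False,
) -> EnergyTerms | tuple[EnergyTerms, FrameEnergyDetail]:
    """Single-frame binding free energy dG = G(complex) - G(A) - G(B).

    Complex and isolated chains use identical coordinates (single-trajectory
    approach): the MM part reduces to the cross-chain interaction, the polar
    part to reaction-field differences on a shared grid, the nonpolar part
    to SASA differences.  ``include_solvation=False`` evaluates the vacuum
    MM terms only.
    """
    structure.require_parameterized()
    ch_a, ch_b = structure.require_two_chains()
    if {chain_a, chain_b} != {ch_a, ch_b}:
        raise ValueError(f"chains {chain_a}/{chain_b} not the structure's {ch_a}/{ch_b}")
    ia, ib = structure.chain_indices(chain_a), structure.chain_indices(chain_b)
    vdw_atoms, elec_atoms = mm_interaction_per_atom(structure, chain_a, chain_b)
    e_vdw, e_elec = float(vdw_atoms[ia].sum()), float(elec_atoms[ia].sum())
    if include_solvation:
        g_pol, g_np, pol_atoms, np_atoms = _frame_polar_nonpolar(
            structure, ia, ib, settings
        )
    else:
        g_pol, g_np = 0.0, 0.0
        pol_atoms = np.zeros(structure.n_atoms)
        np_atoms = np.zeros(structure.n_atoms)
    terms = EnergyTerms.from_components(e_vdw, e_elec, g_pol, g_np)
    if details:
        return terms, FrameEnergyDetail(
            vdw=vdw_atoms, elec=elec_atoms, polar=pol_atoms, nonpolar=np_atoms
        )
    return terms


_COMPONENTS = ("E_vdW", "E_elec", "E_MM", "G_polar", "G_nonpolar", "G_solvation", "total")


def _bootstrap_se(values: np.ndarray, n_resamples: int, seed: int) -> np.ndarray:
    """Bootstrap standard error of the column means of (n_frames, k) data."""
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_resamples, n))
    means = values[idx].mean(axis=1)
    return means.std(axis=0, ddof=1)


def ensemble_binding_energy(
    ensemble: Ensemble,
    window: FrameWindow | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
    settings: PBSettings = PBSettings(),
    include_solvation: bool = True,
    bootstrap_resamples: int = 1000,
    seed: int = 0,
) -> BindingEnergyResult:
    """Ensemble-averaged binding free energy with bootstrap uncertainties.

    Every selected frame is evaluated by :func:`frame_binding_energy`; the
    mean is the arithmetic per-component mean and the uncertainty a seeded
    bootstrap standard error of that mean (default 1000 resamples).
    """
    if window is not None:
        ensemble = select_frames(ensemble, window)
    if ensemble.n_frames < 1:
        raise ValueError("no frames selected")
    if chain_a is None or chain_b is None:
        chain_a, chain_b = ensemble.topology.require_two_chains()
    per_frame = [
        frame_binding_energy(
            frame, chain_a, chain_b, settings, include_solvation=include_solvation
        )
        for frame in ensemble
    ]
    mat = np.array([[getattr(t, c) for c in _COMPONENTS] for t in per_frame])
    mean_vals = mat.mean(axis=0)
    mean = EnergyTerms(**dict(zip(_COMPONENTS, map(float, mean_vals))))
    if ensemble.n_frames > 1:
        se = _bootstrap_se(mat, bootstrap_resamples, seed)
    else:
        se = np.zeros(len(_COMPONENTS))
    unc = EnergyTerms(**dict(zip(_COMPONENTS, map(float, se))))
    return BindingEnergyResult(
        per_frame=per_frame, times=ensemble.times.copy(), mean=mean, uncertainty=unc
    )
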