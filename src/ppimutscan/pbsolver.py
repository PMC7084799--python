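"""Finite-difference linearized Poisson–Boltzmann (LPB) solver.

Solves, on a uniform Cartesian node grid,

    div( eps(x) grad phi ) - lambda(x) phi = -4 pi f rho(x)

with ``f = 1389.35458 kJ mol^-1 Å e^-2`` (so phi is in kJ/mol/e when
lengths are in Å and charges in e), ``eps`` the position-dependent relative
dielectric and ``lambda = eps_solvent * kappa^2`` the Debye–Hückel screening
coefficient, nonzero only in the solvent region.

Numerical scheme
----------------
* Solute region = union of atomic vdW spheres; each grid-cell *face* is
  classified solute/solvent by its midpoint (sharp boundary).  An optional
  harmonic sub-sampled smoothing of face dielectrics is available.
* Charges spread to the eight surrounding nodes by trilinear weights.
* Dirichlet boundary values from the Debye-screened Coulomb sum of all
  charges in the exterior dielectric.
* The symmetric positive-definite 7-point system is solved by conjugate
  gradients with a Jacobi preconditioner to a relative residual tolerance.

The electrostatic (polar) solvation free energy is obtained as
``G = 1/2 sum_i q_i (phi_solv(x_i) - phi_ref(x_i))`` where the reference
solve uses the solute dielectric everywhere and no screening on the
*identical* grid, cancelling the grid self-energy of the spread charges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.constants as const
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "PBSettings",
    "GridSpec",
    "PotentialGrid",
    "COULOMB_CONSTANT",
    "debye_kappa2",
    "grid_for",
    "solve_lpb",
    "polar_solvation",
    "polar_solvation_per_atom",
]

#: Coulomb constant in kJ/mol * Å / e^2
COULOMB_CONSTANT = 1389.35458


@dataclass(frozen=True)
class PBSettings:
    """Implicit-solvent model settings.

    The solute dielectric defaults to 2 (polarizable protein interior); the
    solvent is water at 80 with 150 mM monovalent salt at body temperature.
    ``nonpolar_gamma``/``nonpolar_offset`` parameterize the surface-area
    nonpolar term; the defaults are the g_mmpbsa-compatible constants with a
    zero offset so far-separated neutral chains have zero binding energy.
    """

    solute_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    ionic_strength: float = 150.0  # mM
    temperature: float = 310.15  # K
    grid_spacing: float = 0.5  # Å
    grid_padding: float = 10.0  # Å
    solver_tolerance: float = 1e-6
    nonpolar_gamma: float = 0.0226778  # kJ/mol/Å^2
    nonpolar_offset: float = 0.0  # kJ/mol
    probe_radius: float = 1.4  # Å
    boundary_smoothing: int = 0  # sub-samples for harmonic face smoothing (0 = sharp)

    def __post_init__(self) -> None:
        if self.solute_dielectric < 1 or self.solvent_dielectric < 1:
            raise ValueError("dielectrics must be >= 1")
        if self.grid_spacing <= 0 or self.grid_padding <= 0:
            raise ValueError("grid spacing and padding must be positive")


#: g_mmpbsa's published nonpolar SASA model constants (kJ/mol/Å^2, kJ/mol).
GMXPBSA_NONPOLAR = {"nonpolar_gamma": 0.0226778, "nonpolar_offset": 3.84928}


def debye_kappa2(settings: PBSettings) -> float:
    """Squared inverse Debye length (Å^-2) for a 1:1 salt."""
    if settings.ionic_strength <= 0:
        return 0.0
    ion_m3 = settings.ionic_strength * const.Avogadro  # mM -> mol/m^3 * N_A
    k2 = (
        2.0
        * const.elementary_charge**2
        * ion_m3
        / (
            const.epsilon_0
            * settings.solvent_dielectric
            * const.Boltzmann
            * settings.temperature
        )
    )
    return k2 * 1e-20  # m^-2 -> Å^-2


@dataclass(frozen=True)
class GridSpec:
    """Node-grid geometry: origin (Å), spacing h (Å) and node counts."""

    origin: np.ndarray  # (3,)
    spacing: float
    shape: tuple[int, int, int]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)
        )


@dataclass
class PotentialGrid:
    """Solved potential phi (kJ/mol/e) on a :class:`GridSpec`."""

    spec: GridSpec
    phi: np.ndarray  # shape = spec.shape
    iterations: int
    residual: float

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at Cartesian points (Å)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        f = (pts - self.spec.origin) / self.spec.spacing
        i0 = np.floor(f).astype(int)
        for a in range(3):
            i0[:, a] = np.clip(i0[:, a], 0, self.spec.shape[a] - 2)
        w = f - i0
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = (
                        (w[:, 0] if dx else 1 - w[:, 0])
                        * (w[:, 1] if dy else 1 - w[:, 1])
                        * (w[:, 2] if dz else 1 - w[:, 2])
                    )
                    out += wt * self.phi[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        return out


class PBSolverError(RuntimeError):
    """Iterative LPB solve failed to converge."""


def grid_for(
    coords: np.ndarray, radii: np.ndarray, settings: PBSettings
) -> GridSpec:
    """Grid covering the atoms plus their radii plus the padding."""
    coords = np.atleast_2d(coords)
    lo = coords.min(axis=0) - float(np.max(radii)) - settings.grid_padding
    hi = coords.max(axis=0) + float(np.max(radii)) + settings.grid_padding
    n = np.ceil((hi - lo) / settings.grid_spacing).astype(int) + 1
    return GridSpec(origin=lo, spacing=settings.grid_spacing, shape=(int(n[0]), int(n[1]), int(n[2])))


def _face_dielectric(
    spec: GridSpec,
    axis: int,
    coords: np.ndarray,
    radii: np.ndarray,
    eps_in: float,
    eps_out: float,
    smoothing: int,
) -> np.ndarray:
    """Dielectric on the faces normal to ``axis`` (between nodes i and i+1)."""
    shape = list(spec.shape)
    shape[axis] -= 1
    ax = [spec.origin[a] + spec.spacing * np.arange(shape[a]) for a in range(3)]
    ax[axis] = ax[axis] + spec.spacing / 2.0
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")

    def inside_at(px, py, pz):
        inside = np.zeros(px.shape, dtype=bool)
        for c, r in zip(coords, radii):
            inside |= (px - c[0]) ** 2 + (py - c[1]) ** 2 + (pz - c[2]) ** 2 <= r * r
        return inside

    if smoothing and smoothing > 1:
        inv = np.zeros(gx.shape)
        for off in np.linspace(-spec.spacing / 2, spec.spacing / 2, smoothing):
            p = [gx, gy, gz]
            p[axis] = p[axis] + off
            inside = inside_at(*p)
            inv += np.where(inside, 1.0 / eps_in, 1.0 / eps_out)
        return smoothing / inv
    inside = inside_at(gx, gy, gz)
    return np.where(inside, eps_in, eps_out)


def solve_lpb(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    settings: PBSettings,
    grid: GridSpec | None = None,
    reference: bool = False,
    max_iterations: int = 20000,
) -> PotentialGrid:
    """Solve the LPB equation for a set of parameterized atoms.

    With ``reference=True`` the solute dielectric fills all space and
    screening is off — the homogeneous companion solve used for self-energy
    cancellation.  Pass an explicit ``grid`` to keep several solves (complex
    and isolated chains) on identical nodes.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.isnan(charges).any() or np.isnan(radii).any():
        raise ValueError("charges/radii not assigned")
    if grid is None:
        grid = grid_for(coords, radii, settings)
    nx, ny, nz = grid.shape
    h = grid.spacing
    eps_in = settings.solute_dielectric
    eps_out = settings.solvent_dielectric
    kappa2 = 0.0 if reference else debye_kappa2(settings)

    if reference:
        ex = np.full((nx - 1, ny, nz), eps_in)
        ey = np.full((nx, ny - 1, nz), eps_in)
        ez = np.full((nx, ny, nz - 1), eps_in)
        lam = np.zeros((nx, ny, nz))
    else:
        ex = _face_dielectric(grid, 0, coords, radii, eps_in, eps_out, settings.boundary_smoothing)
        ey = _face_dielectric(grid, 1, coords, radii, eps_in, eps_out, settings.boundary_smoothing)
        ez = _face_dielectric(grid, 2, coords, radii, eps_in, eps_out, settings.boundary_smoothing)
        if kappa2 > 0:
            X, Y, Z = grid.axes()
            gx, gy, gz = np.meshgrid(X, Y, Z, indexing="ij")
            inside = np.zeros((nx, ny, nz), dtype=bool)
            for c, r in zip(coords, radii):
                inside |= (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r * r
            lam = np.where(inside, 0.0, eps_out * kappa2)
        else:
            lam = np.zeros((nx, ny, nz))

    # trilinear charge spreading to nodes
    rho = np.zeros((nx, ny, nz))
    f = (coords - grid.origin) / h
    i0 = np.floor(f).astype(int)
    w = f - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = (
                    (w[:, 0] if dx else 1 - w[:, 0])
                    * (w[:, 1] if dy else 1 - w[:, 1])
                    * (w[:, 2] if dz else 1 - w[:, 2])
                )
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), charges * wt)

    # Dirichlet boundary: screened Coulomb sum
    phi = np.zeros((nx, ny, nz))
    bmask = np.zeros((nx, ny, nz), dtype=bool)
    bmask[0], bmask[-1] = True, True
    bmask[:, 0], bmask[:, -1] = True, True
    bmask[:, :, 0], bmask[:, :, -1] = True, True
    bidx = np.argwhere(bmask)
    bpts = grid.origin + h * bidx
    eps_b = eps_in if reference else eps_out
    kap = np.sqrt(kappa2)
    pot = np.zeros(len(bidx))
    for c, q in zip(coords, charges):
        d = np.linalg.norm(bpts - c, axis=1)
        d = np.maximum(d, 1e-6)
        pot += COULOMB_CONSTANT * q * np.exp(-kap * d) / (eps_b * d)
    phi[bmask] = pot

    # assemble the interior SPD system
    interior = ~bmask
    idx = -np.ones((nx, ny, nz), dtype=int)
    ii = np.argwhere(interior)
    idx[interior] = np.arange(len(ii))
    I, J, K = ii[:, 0], ii[:, 1], ii[:, 2]
    myid = idx[I, J, K]
    rows, cols, vals = [], [], []
    b = 4.0 * np.pi * COULOMB_CONSTANT * rho[interior] / h
    diag = lam[interior] * h * h
    for axis, earr in ((0, ex), (1, ey), (2, ez)):
        for sgn in (+1, -1):
            In, Jn, Kn = I, J, K
            if axis == 0:
                In = I + sgn
            elif axis == 1:
                Jn = J + sgn
            else:
                Kn = K + sgn
            if axis == 0:
                ef = earr[np.minimum(I, In), J, K]
            elif axis == 1:
                ef = earr[I, np.minimum(J, Jn), K]
            else:
                ef = earr[I, J, np.minimum(K, Kn)]
            diag = diag + ef
            nb = idx[In, Jn, Kn]
            m = nb >= 0
            rows.append(myid[m])
            cols.append(nb[m])
            vals.append(-ef[m])
            b[~m] += ef[~m] * phi[In[~m], Jn[~m], Kn[~m]]
    rows.append(myid)
    cols.append(myid)
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(ii), len(ii)),
    )
    M = sp.diags(1.0 / A.diagonal())
    n_iter = 0

    def _cb(_):
        nonlocal n_iter
        n_iter += 1

    x, info = spla.cg(
        A, b, rtol=settings.solver_tolerance, maxiter=max_iterations, M=M, callback=_cb
    )
    res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
    if info != 0:
        raise PBSolverError(
            f"LPB CG did not converge in {max_iterations} iterations "
            f"(relative residual {res:.3e})"
        )
    phi[interior] = x
    return PotentialGrid(spec=grid, phi=phi, iterations=n_iter, residual=res)


def polar_solvation_per_atom(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    settings: PBSettings,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Per-atom polar solvation contributions g_i = q_i (phi_s - phi_ref)_i / 2.

    The reference solve reuses the identical grid with the solute dielectric
    everywhere and no screening, so the grid self-energy of the spread
    charges cancels and the sum of the returned array is the reaction-field
    (polar solvation) free energy in kJ/mol.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if grid is None:
        grid = grid_for(coords, radii, settings)
    solv = solve_lpb(coords, charges, radii, settings, grid=grid, reference=False)
    ref = solve_lpb(coords, charges, radii, settings, grid=grid, reference=True)
    dphi = solv.interpolate(coords) - ref.interpolate(coords)
    return 0.5 * np.asarray(charges, dtype=float) * dphi


def polar_solvation(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    settings: PBSettings,
    grid: GridSpec | None = None,
) -> float:
    """Polar (reaction-field) solvation free energy, kJ/mol."""
    if not np.any(np.asarray(charges) != 0):
        return 0.0
    return float(np.sum(polar_solvation_per_atom(coords, charges, radii, settings, grid)))
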