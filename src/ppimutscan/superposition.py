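"""Least-squares superposition and ensemble geometry statistics.

Rigid-body fitting uses the Kabsch algorithm (SVD of the cross-covariance,
with the reflection branch excluded so the rotation is always proper).  On
top of it sit the two standard trajectory descriptors:

* an RMSD time series — every frame least-squares fitted to a reference
  frame over a fit selection, deviation measured over a (possibly different)
  measure selection, by default the protein backbone (N, CA, C, O);
* per-residue RMSF — root-mean-square fluctuation of each residue's atoms
  about their time-average position after fitting, optionally with each
  chain fitted independently so inter-chain rigid motion does not inflate
  the per-protein fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Ensemble, FrameWindow, select_frames

__all__ = ["FitResult", "kabsch_superpose", "rmsd_series", "rmsf_per_residue"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class FitResult:
    """Optimal proper rigid transform mobile -> reference and its RMSD (Å).

    ``transform`` maps mobile coordinates x to ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3,3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_selection(sel: np.ndarray, n: int) -> np.ndarray:
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if sel.min() < 0 or sel.max() >= n:
        raise IndexError("selection index out of range")
    return sel


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> FitResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation and translation minimizing the RMSD over the
    selected atoms (all atoms when ``selection`` is None).  Reflections are
    excluded by flipping the sign of the smallest singular direction when
    needed.  Requires at least 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    if selection is None:
        selection = np.arange(len(mobile))
    sel = _check_selection(selection, len(mobile))
    x = mobile[sel]
    y = reference[sel]
    if len(x) < 3:
        raise ValueError("superposition needs at least 3 points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # rank < 2 => collinear (or coincident) points: rotation underdetermined
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise ValueError("degenerate fit: selected points are collinear")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = y.mean(axis=0) - x.mean(axis=0) @ rotation.T
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return FitResult(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_series(
    ensemble: Ensemble,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> np.ndarray:
    """RMSD of every frame from a reference frame after least-squares fitting.

    Default fit and measure selections are the backbone atoms (N, CA, C, O).
    Returns an array of shape (n_frames, 2): columns (time ps, RMSD Å).
    """
    n = ensemble.topology.n_atoms
    if not (0 <= reference_frame < ensemble.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    if fit_selection is None:
        fit_selection = ensemble.topology.backbone_indices(BACKBONE_NAMES)
        if fit_selection.size == 0:  # bead-level topologies without N/CA/C/O
            fit_selection = np.arange(n)
    if measure_selection is None:
        measure_selection = fit_selection
    fit_sel = _check_selection(fit_selection, n)
    meas_sel = _check_selection(measure_selection, n)
    ref = ensemble.coordinates[reference_frame]
    out = np.empty((ensemble.n_frames, 2))
    for k in range(ensemble.n_frames):
        fit = kabsch_superpose(ensemble.coordinates[k], ref, fit_sel)
        moved = fit.transform(ensemble.coordinates[k][meas_sel])
        out[k, 0] = ensemble.times[k]
        out[k, 1] = np.sqrt(np.mean(np.sum((moved - ref[meas_sel]) ** 2, axis=1)))
    return out


def _fitted_coordinates(
    coords: np.ndarray, fit_sel: np.ndarray, atom_subset: np.ndarray
) -> np.ndarray:
    """Fit every frame to the running mean over ``fit_sel``; return
    transformed coordinates of ``atom_subset``.

    Two-pass: frames are first fitted to the raw coordinate mean (which is
    frame-order independent), a fitted mean structure is formed, then frames
    are refitted to that mean (the standard fluctuation reference).
    """
    n_frames = coords.shape[0]
    ref = coords.mean(axis=0)
    for _ in range(2):
        moved = np.empty((n_frames, len(atom_subset), 3))
        moved_fit = np.empty((n_frames, len(fit_sel), 3))
        for k in range(n_frames):
            fit = kabsch_superpose(coords[k], ref, fit_sel)
            moved[k] = fit.transform(coords[k][atom_subset])
            moved_fit[k] = fit.transform(coords[k][fit_sel])
        new_ref = ref.copy()
        new_ref[fit_sel] = moved_fit.mean(axis=0)
        ref = new_ref
    return moved


def rmsf_per_residue(
    ensemble: Ensemble,
    fit_selection: np.ndarray | None = None,
    group_by_chain: bool = False,
    window: FrameWindow | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (Å) about the time-average structure after fitting.

    RMSF_i = sqrt( mean over frames and over residue-i atoms of the squared
    deviation from each atom's time-average position ).  With
    ``group_by_chain`` each chain is fitted independently before averaging,
    so rigid inter-chain motion does not contribute.  Requires >= 2 frames.
    """
    if window is not None:
        ensemble = select_frames(ensemble, window)
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = ensemble.topology
    coords = ensemble.coordinates
    if fit_selection is None:
        fit_selection = top.backbone_indices(BACKBONE_NAMES)
        if fit_selection.size == 0:
            fit_selection = np.arange(top.n_atoms)
    fit_sel = _check_selection(fit_selection, top.n_atoms)

    groups: list[np.ndarray]
    if group_by_chain:
        groups = [top.chain_indices(c) for c in top.chains]
    else:
        groups = [np.arange(top.n_atoms)]

    msf = np.zeros(top.n_atoms)
    for grp in groups:
        grp_fit = np.intersect1d(fit_sel, grp)
        if grp_fit.size < 3:
            grp_fit = grp
        moved = _fitted_coordinates(coords, grp_fit, grp)
        mean_pos = moved.mean(axis=0)
        msf[grp] = np.mean(np.sum((moved - mean_pos) ** 2, axis=2), axis=0)

    out: dict[tuple[str, int], float] = {}
    for key, idx in top.residue_atom_indices().items():
        out[key] = float(np.sqrt(np.mean(msf[idx])))
    return out
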