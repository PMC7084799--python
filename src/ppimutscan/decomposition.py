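"""Per-residue and per-domain attribution of the binding free energy.

The MM part of the binding energy is an exact sum over cross-chain atom
pairs, so it can be booked residue-by-residue without approximation: each
pair's full value is credited to the residue on its *own* chain, making each
chain's ledger complete (chain-A rows sum to dE_MM, and so do chain-B rows;
summing both sides double-counts).  Polar and nonpolar contributions are
read off the per-atom ledgers of the frame calculation (potential
differences at charge sites, per-atom SASA changes) — no extra PB solves per
residue.  In this scheme the solvation rows of one chain also sum to the
respective binding totals; tools that decompose differently need not have
that property.

Domain aggregation sums member-residue rows under a
:class:`~ppimutscan.ensemble_io.DomainMap`; declared domain *pairs* (e.g.
prodomain + β-propeller) are reported as the sum of their two rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import BindingEnergyResult, PBSettings, frame_binding_energy
from .ensemble_io import DomainMap, Ensemble, FrameWindow, select_frames

__all__ = [
    "PerResidueEnergy",
    "per_residue_decomposition",
    "domain_aggregate",
    "interaction_type_table",
]

_RES_COLS = ["chain", "residue_number", "residue_name",
             "E_vdW", "E_elec", "G_polar_contrib", "G_nonpolar_contrib", "total"]


@dataclass
class PerResidueEnergy:
    """Ensemble-averaged per-residue binding-energy ledger (kJ/mol)."""

    rows: pd.DataFrame  # columns _RES_COLS

    def chain_sum(self, chain: str, column: str) -> float:
        sub = self.rows[self.rows["chain"] == chain]
        return float(sub[column].sum())

    def residue_row(self, chain: str, residue_number: int) -> pd.Series:
        m = (self.rows["chain"] == chain) & (self.rows["residue_number"] == residue_number)
        return self.rows[m].iloc[0]

    def sorted_by_magnitude(self) -> pd.DataFrame:
        return self.rows.reindex(
            self.rows["total"].abs().sort_values(ascending=False).index
        )


def per_residue_decomposition(
    ensemble: Ensemble,
    window: FrameWindow | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
    settings: PBSettings = PBSettings(),
    include_solvation: bool = True,
) -> PerResidueEnergy:
    """Ensemble-averaged per-residue binding-energy contributions.

    MM terms: sum over cross-chain atom pairs involving the residue (full
    pair value on its own chain's side).  Polar/nonpolar terms: per-atom
    grid and SASA ledgers summed over the residue's atoms.  Averaged over
    the selected frames.
    """
    if window is not None:
        ensemble = select_frames(ensemble, window)
    top = ensemble.topology
    if chain_a is None or chain_b is None:
        chain_a, chain_b = top.require_two_chains()
    res_idx = top.residue_atom_indices()
    keys = top.residue_keys()
    acc = {k: np.zeros(4) for k in keys}  # vdw, elec, polar, nonpolar
    for frame in ensemble:
        _, det = frame_binding_energy(
            frame, chain_a, chain_b, settings,
            include_solvation=include_solvation, details=True,
        )
        for k in keys:
            idx = res_idx[k]
            acc[k] += (
                det.vdw[idx].sum(),
                det.elec[idx].sum(),
                det.polar[idx].sum(),
                det.nonpolar[idx].sum(),
            )
    records = []
    for (chain, resnum) in keys:
        vdw, elec, pol, nonp = acc[(chain, resnum)] / ensemble.n_frames
        records.append(
            {
                "chain": chain,
                "residue_number": resnum,
                "residue_name": top.residue_name_of(chain, resnum),
                "E_vdW": vdw,
                "E_elec": elec,
                "G_polar_contrib": pol,
                "G_nonpolar_contrib": nonp,
                "total": vdw + elec + pol + nonp,
            }
        )
    return PerResidueEnergy(rows=pd.DataFrame.from_records(records, columns=_RES_COLS))


def domain_aggregate(
    per_res: PerResidueEnergy,
    domains: DomainMap,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Aggregate per-residue rows into domain rows (+ declared pair rows).

    Residues not covered by any domain are pooled under ``other``.  A pair
    row is exactly the sum of its two domain rows, mirroring combined
    interface rows such as prodomain/β-propeller.
    """
    chains = set(per_res.rows["chain"])
    for name, chain, _, _ in domains.entries:
        if chain not in chains:
            raise ValueError(f"domain {name!r} references missing chain {chain!r}")
    cols = ["E_vdW", "E_elec", "G_polar_contrib", "G_nonpolar_contrib", "total"]
    sums: dict[str, np.ndarray] = {name: np.zeros(len(cols)) for name in domains.names()}
    sums["other"] = np.zeros(len(cols))
    for _, row in per_res.rows.iterrows():
        name = domains.domain_of(row["chain"], int(row["residue_number"])) or "other"
        sums[name] += row[cols].to_numpy(dtype=float)
    records = [{"domain": name, **dict(zip(cols, v))} for name, v in sums.items()]
    if pairs:
        for d1, d2 in pairs:
            if d1 not in sums or d2 not in sums:
                raise ValueError(f"pair ({d1}, {d2}) references unknown domain")
            v = sums[d1] + sums[d2]
            records.append({"domain": f"{d1}/{d2}", **dict(zip(cols, v))})
    return pd.DataFrame.from_records(records, columns=["domain", *cols])


_TYPE_ROWS = [
    ("van der Waals", "E_vdW"),
    ("Electrostatic", "E_elec"),
    ("Polar Solvation", "G_polar"),
    ("Non-polar", "G_nonpolar"),
    ("Total", "total"),
]


def interaction_type_table(
    results: dict[str, BindingEnergyResult], formatted: bool = False
) -> pd.DataFrame:
    """Interaction-type comparison table, one column per variant.

    Rows: van der Waals, Electrostatic, Polar Solvation, Non-polar, Total
    (the Total row is the exact sum of the four components).  With
    ``formatted=True`` each cell is a string "value (uncertainty)"; otherwise
    the numeric means with a parallel ``<name>_se`` column per variant.
    """
    if not results:
        raise ValueError("at least one variant result required")
    data: dict[str, list] = {}
    for name, res in results.items():
        if formatted:
            data[name] = [
                f"{getattr(res.mean, attr):.1f} ({getattr(res.uncertainty, attr):.3g})"
                for _, attr in _TYPE_ROWS
            ]
        else:
            data[name] = [getattr(res.mean, attr) for _, attr in _TYPE_ROWS]
            data[f"{name}_se"] = [getattr(res.uncertainty, attr) for _, attr in _TYPE_ROWS]
    return pd.DataFrame(data, index=[label for label, _ in _TYPE_ROWS])
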