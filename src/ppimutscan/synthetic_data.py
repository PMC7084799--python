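"""Synthetic two-chain complexes and ensembles with planted, known structure.

Real wild-type-vs-mutant trajectory comparisons hinge on three effects: a
mutation that gains interface contacts (raising its residue's network degree
and improving binding), a charge change at a *non*-interface residue that
leaves the contact network untouched while shifting the long-range
electrostatics, and localized thermal flexibility.  This module builds
bead-level two-chain complexes in which each of those effects is planted by
construction and recorded in a :class:`SyntheticTruth`, so the downstream
network, energetics and fluctuation analyses can be tested against known
answers.

Geometry: two parallel bead chains (one residue every 6 Å, three beads per
residue) separated by 16 Å.  Declared interface residue pairs point
"side-chain" beads at each other across the gap (bead–bead distance ≈ 3 Å,
comfortably inside the −0.4 Å overlap criterion); every other cross-chain
residue pair stays > 8 Å apart.  A five-element mini force field is shipped
as a parameter table so structures are parameterized through the same
assignment path as real input.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .contact_network import ContactCriterion, residue_contacts_frame
from .ensemble_io import (
    DomainMap,
    Ensemble,
    ParameterTable,
    Structure,
    assign_parameters,
    write_ensemble,
    write_structure,
)

__all__ = [
    "SyntheticTruth",
    "mini_force_field",
    "write_mini_force_field",
    "make_toy_complex",
    "make_ensemble",
    "make_variant_suite",
    "VariantSuite",
    "write_fixture_suite",
    "toy_domain_map",
]

CHAIN_A, CHAIN_B = "A", "B"
RES_SPACING = 6.0  # Å between consecutive residues along x
CHAIN_GAP = 16.0  # Å between the two backbones
SC_CONTACT_A, SC_CONTACT_B = 6.6, 9.6  # y of contacting side beads (d = 3.0)
# resting side beads sit close to their backbone so every non-interface
# cross-chain atom pair keeps > 8 Å clearance even when one residue across
# the gap has its bead raised into contact position
SC_REST_A, SC_REST_B = 1.2, CHAIN_GAP - 1.1
PLACEMENT_NOISE = 0.05  # Å, deterministic seed-dependent de-symmetrization
MIN_FAR_SEPARATION = 8.0  # Å, required clearance of non-interface pairs


class ConstructionError(ValueError):
    """Requested synthetic geometry cannot be realized."""


@dataclass
class SyntheticTruth:
    """Record of what was planted into a synthetic ensemble/suite.

    ``planted_contacts`` are (chain-A residue, chain-B residue) number pairs
    meant to persist in a fraction ``persistence_target`` of frames;
    ``planted_hotspot`` names the interface residue given strong favorable
    cross-chain charges (with the sign of its expected contribution);
    ``charge_edit`` is a (residue number, Δcharge in e) edit applied to a
    non-interface chain-A residue in the charge-edit variant.
    """

    planted_contacts: list[tuple[int, int]] = field(default_factory=list)
    planted_hotspot: tuple[int, int] | None = None  # (A-residue, sign)
    charge_edit: tuple[int, float] | None = None  # (A-residue, dq)
    jitter_sigma: float = 0.25  # Å
    seed: int = 0
    persistence_target: float = 1.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Mini force field


def mini_force_field() -> ParameterTable:
    """Five-element bead force field with residue-specific charged beads.

    Element defaults carry neutral Lennard-Jones beads; named residues give
    their SC bead a net charge (ARG/GLU ±0.5 e, LYS/ASP ±1.0 e, TRP 0).
    ALA's CA offsets the oxygen bead so plain residues are neutral.
    """
    t = ParameterTable()
    # element: (charge e, vdW radius Å, epsilon kJ/mol, sigma Å)
    t.by_element = {
        "C": (0.0, 1.70, 0.30, 3.00),
        "O": (-0.10, 1.52, 0.25, 2.96),
        "N": (0.0, 1.55, 0.35, 2.90),
        "H": (0.0, 1.20, 0.10, 2.00),
        "S": (0.0, 1.80, 0.50, 3.20),
    }
    t.specific = {
        ("ALA", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("ARG", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("GLU", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("LYS", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("ASP", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("TRP", "CA"): (0.10, 1.70, 0.30, 3.00),
        ("ARG", "CB"): (0.50, 1.70, 0.30, 3.00),
        ("GLU", "CB"): (-0.50, 1.70, 0.30, 3.00),
        ("LYS", "CB"): (1.00, 1.70, 0.30, 3.00),
        ("ASP", "CB"): (-1.00, 1.70, 0.30, 3.00),
        ("TRP", "CB"): (0.00, 1.70, 0.30, 3.00),
    }
    return t


def write_mini_force_field(path: str | Path) -> None:
    """Write the mini force field as the TSV dialect read_parameter_table reads."""
    t = mini_force_field()
    lines = ["residue\tatom\telement\tcharge\tradius\tepsilon\tsigma"]
    for el, (q, r, e, s) in t.by_element.items():
        lines.append(f"\t\t{el}\t{q}\t{r}\t{e}\t{s}")
    for (res, atom), (q, r, e, s) in t.specific.items():
        el = atom[0]
        lines.append(f"{res}\t{atom}\t{el}\t{q}\t{r}\t{e}\t{s}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Structure construction


def make_toy_complex(
    n_res_a: int,
    n_res_b: int,
    interface_pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
    residue_types: dict[tuple[str, int], str] | None = None,
    validate: bool = True,
) -> Structure:
    """Bead-level two-chain complex with declared interface residue pairs.

    Chains A and B run parallel along x; each residue contributes a CA bead,
    an O bead and a CB side bead.  For every ``(res_a, res_b)`` interface
    pair the two CB beads face each other across the inter-chain gap at
    ≈3 Å (vdW overlap +0.4 Å, a contact at the −0.4 Å criterion); all other
    cross-chain residue pairs are kept > 8 Å apart (validated, raising
    :class:`ConstructionError` if the request is infeasible).

    ``residue_types`` overrides residue names (e.g. charged bead types) by
    (chain, residue number).  The same seed yields a bit-identical structure.
    """
    if n_res_a < 1 or n_res_b < 1:
        raise ConstructionError("need at least one residue per chain")
    interface_pairs = list(interface_pairs or [])
    for ra, rb in interface_pairs:
        if not (1 <= ra <= n_res_a and 1 <= rb <= n_res_b):
            raise ConstructionError(f"interface pair ({ra},{rb}) out of range")
    partners_of_a: dict[int, list[int]] = {}
    for ra, rb in interface_pairs:
        partners_of_a.setdefault(ra, []).append(rb)
    b_used: set[int] = set()
    for ra, rbs in partners_of_a.items():
        if len(rbs) > 2:
            raise ConstructionError(f"residue A:{ra} cannot contact >2 partners")
        for rb in rbs:
            if rb in b_used:
                raise ConstructionError(f"residue B:{rb} used in multiple pairs")
            b_used.add(rb)

    residue_types = residue_types or {}
    rng = np.random.default_rng(seed)

    names, elements, chain_ids, res_numbers, res_names, positions = [], [], [], [], [], []

    def add_atom(name: str, element: str, chain: str, resnum: int, pos):
        names.append(name)
        elements.append(element)
        chain_ids.append(chain)
        res_numbers.append(resnum)
        res_names.append(residue_types.get((chain, resnum), "ALA"))
        positions.append(pos)

    # chain A
    a_x = {r: RES_SPACING * (r - 1) for r in range(1, n_res_a + 1)}
    b_x = {r: RES_SPACING * (r - 1) for r in range(1, n_res_b + 1)}
    # side-bead targets for interface pairs
    sc_a: dict[int, np.ndarray] = {}
    sc_b: dict[int, np.ndarray] = {}
    for ra, rbs in partners_of_a.items():
        offsets = [0.0] if len(rbs) == 1 else [-1.5, +1.5]
        sc_a[ra] = np.array([a_x[ra], SC_CONTACT_A, 0.0])
        for off, rb in zip(offsets, sorted(rbs)):
            sc_b[rb] = np.array([a_x[ra] + off, SC_CONTACT_B, 0.0])

    for r in range(1, n_res_a + 1):
        x = a_x[r]
        add_atom("CA", "C", CHAIN_A, r, [x, 0.0, 0.0])
        add_atom("O", "O", CHAIN_A, r, [x + 1.3, 0.0, 0.9])
        add_atom("CB", "C", CHAIN_A, r, sc_a.get(r, np.array([x, SC_REST_A, 0.0])))
    for r in range(1, n_res_b + 1):
        x = b_x[r]
        add_atom("CA", "C", CHAIN_B, r, [x, CHAIN_GAP, 0.0])
        add_atom("O", "O", CHAIN_B, r, [x + 1.3, CHAIN_GAP, 0.9])
        add_atom("CB", "C", CHAIN_B, r, sc_b.get(r, np.array([x, SC_REST_B, 0.0])))

    pos = np.asarray(positions, dtype=float)
    pos = pos + rng.normal(0.0, PLACEMENT_NOISE, size=pos.shape)
    structure = Structure(
        atom_ids=list(range(1, len(names) + 1)),
        names=names,
        elements=elements,
        chain_ids=chain_ids,
        residue_numbers=res_numbers,
        residue_names=res_names,
        positions=pos,
    )
    structure = assign_parameters(structure, mini_force_field())
    if validate:
        _validate_geometry(structure, interface_pairs)
    return structure


def _validate_geometry(structure: Structure, interface_pairs: list[tuple[int, int]]) -> None:
    planted = {
        ((CHAIN_A, ra), (CHAIN_B, rb)) for ra, rb in interface_pairs
    }
    contacts = set(residue_contacts_frame(structure, ContactCriterion()).keys())
    if contacts != planted:
        raise ConstructionError(
            f"constructed contact set {sorted(contacts)} != planted {sorted(planted)}"
        )
    # clearance of all non-planted cross-chain residue pairs
    ia = structure.chain_indices(CHAIN_A)
    ib = structure.chain_indices(CHAIN_B)
    d = np.linalg.norm(
        structure.positions[ia][:, None, :] - structure.positions[ib][None, :, :], axis=2
    )
    ra = structure.residue_numbers[ia]
    rb = structure.residue_numbers[ib]
    for i, a_res in enumerate(ra):
        for j, b_res in enumerate(rb):
            if (int(a_res), int(b_res)) in set(interface_pairs):
                continue
            if d[i, j] <= MIN_FAR_SEPARATION:
                raise ConstructionError(
                    f"non-interface pair A:{a_res}/B:{b_res} only {d[i, j]:.2f} Å apart"
                )


# ---------------------------------------------------------------------------
# Ensembles


def make_ensemble(
    structure: Structure,
    n_frames: int,
    truth: SyntheticTruth,
    dt: float = 200.0,
    sigma_overrides: dict[tuple[str, int], float] | None = None,
) -> Ensemble:
    """Jittered ensemble around ``structure`` with planted contact persistence.

    Frames are the base coordinates plus isotropic Gaussian jitter of width
    ``truth.jitter_sigma`` (per-residue overrides allowed).  Each planted
    contact is kept within the contact criterion in a
    ``truth.persistence_target`` fraction of frames (clamped back into range
    if jitter carries it out) and broken deliberately in the rest by swinging
    the chain-A side bead away.  Same truth/seed => identical trajectory.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(truth.seed)
    top = structure
    res_idx = top.residue_atom_indices()
    sigma = np.full(top.n_atoms, float(truth.jitter_sigma))
    for key, s in (sigma_overrides or {}).items():
        sigma[res_idx[key]] = s

    def bead(chain: str, resnum: int, name: str) -> int:
        idx = res_idx[(chain, resnum)]
        for i in idx:
            if top.names[i] == name:
                return int(i)
        raise KeyError((chain, resnum, name))

    planted = [
        (bead(CHAIN_A, ra, "CB"), bead(CHAIN_B, rb, "CB"))
        for ra, rb in truth.planted_contacts
    ]
    crit = ContactCriterion()
    coords = np.empty((n_frames, top.n_atoms, 3))
    for k in range(n_frames):
        frame = top.positions + rng.normal(0.0, 1.0, size=(top.n_atoms, 3)) * sigma[:, None]
        keep = rng.random(len(planted)) < truth.persistence_target
        for (ai, bi), kp in zip(planted, keep):
            if kp:
                # clamp the pair back inside the criterion if jitter broke it
                r_sum = top.vdw_radii[ai] + top.vdw_radii[bi]
                v = frame[bi] - frame[ai]
                d = np.linalg.norm(v)
                dmax = r_sum - crit.overlap_threshold - 0.2
                if d > dmax:
                    frame[bi] = frame[ai] + v * (dmax / d)
            else:
                frame[ai] = frame[ai] + np.array([0.0, -2.6, 0.0])
        coords[k] = frame
    times = dt * np.arange(n_frames, dtype=float)
    return Ensemble(top, coords, times)


# ---------------------------------------------------------------------------
# Variant suite


@dataclass
class VariantSuite:
    """Wild-type plus the two planted variants and their truth records."""

    wild_type: Ensemble
    contact_gain: Ensemble
    charge_edit: Ensemble
    truth: SyntheticTruth
    gain_residue: int  # chain-A residue whose degree rises in contact_gain
    gain_pairs: list[tuple[int, int]]  # contacts added in contact_gain


def _apply_charge_edit(structure: Structure, residue: int, dq: float) -> Structure:
    out = structure.copy()
    idx = out.residue_atom_indices()[(CHAIN_A, residue)]
    cb = [i for i in idx if out.names[i] == "CB"]
    out.charges[cb[0]] += dq
    return out


def make_variant_suite(
    base_truth: SyntheticTruth,
    n_res: int = 10,
    n_frames: int = 40,
    dt: float = 200.0,
) -> VariantSuite:
    """Wild-type, contact-gain and charge-edit ensembles with shared truth.

    Wild type: 10+10 residues with interface pairs (3,3) [the charged
    hotspot, LYS/ASP ±1 e] and (7,7) [ARG/GLU ±0.5 e]; residue A:9 is a
    +0.5 e ARG away from the interface.  Contact-gain variant: residue A:5
    (an ARG) gains two planted contacts to B:4 and B:6 (GLUs), raising its
    degree and adding favorable interface electrostatics.  Charge-edit
    variant: identical coordinates to wild type, with only A:9's side-bead
    charge shifted by ``base_truth.charge_edit`` (default −1.0 e) — the
    network is untouched while the long-range electrostatics move.
    """
    if n_res < 9:
        raise ConstructionError("variant suite needs chains of >= 9 residues")
    wt_pairs = [(3, 3), (7, 7)]
    gain_residue = 5
    gain_pairs = [(5, 4), (5, 6)]
    charge_res, dq = base_truth.charge_edit or (9, -1.0)
    types_wt = {
        (CHAIN_A, 3): "LYS",
        (CHAIN_B, 3): "ASP",
        (CHAIN_A, 7): "ARG",
        (CHAIN_B, 7): "GLU",
        (CHAIN_A, charge_res): "ARG",
    }
    types_gain = dict(types_wt)
    types_gain[(CHAIN_A, gain_residue)] = "ARG"
    types_gain[(CHAIN_B, 4)] = "GLU"
    types_gain[(CHAIN_B, 6)] = "GLU"

    s_wt = make_toy_complex(n_res, n_res, wt_pairs, seed=base_truth.seed,
                            residue_types=types_wt)
    s_gain = make_toy_complex(n_res, n_res, wt_pairs + gain_pairs,
                              seed=base_truth.seed, residue_types=types_gain)
    s_edit = _apply_charge_edit(s_wt, charge_res, dq)

    truth_wt = SyntheticTruth(
        planted_contacts=wt_pairs,
        planted_hotspot=(3, -1),
        charge_edit=(charge_res, dq),
        jitter_sigma=base_truth.jitter_sigma,
        seed=base_truth.seed,
        persistence_target=base_truth.persistence_target,
    )
    truth_gain = SyntheticTruth(
        planted_contacts=wt_pairs + gain_pairs,
        planted_hotspot=(3, -1),
        charge_edit=(charge_res, dq),
        jitter_sigma=base_truth.jitter_sigma,
        seed=base_truth.seed,
        persistence_target=base_truth.persistence_target,
    )
    wt = make_ensemble(s_wt, n_frames, truth_wt, dt=dt)
    gain = make_ensemble(s_gain, n_frames, truth_gain, dt=dt)
    edit = Ensemble(s_edit, wt.coordinates.copy(), wt.times.copy())
    return VariantSuite(
        wild_type=wt,
        contact_gain=gain,
        charge_edit=edit,
        truth=truth_wt,
        gain_residue=gain_residue,
        gain_pairs=gain_pairs,
    )


def toy_domain_map() -> DomainMap:
    """Two domains per toy chain (N- and C-terminal halves)."""
    return DomainMap(
        entries=[
            ("a_nterm", CHAIN_A, 1, 5),
            ("a_cterm", CHAIN_A, 6, 10),
            ("b_nterm", CHAIN_B, 1, 5),
            ("b_cterm", CHAIN_B, 6, 10),
        ]
    )


def write_fixture_suite(directory: str | Path, seed: int = 0, n_frames: int = 40) -> Path:
    """Write a complete on-disk fixture set for the variant suite.

    Multi-model PDBs for the three ensembles, a PQR of the wild-type frame 0,
    the parameter TSV, a domains YAML and the truth JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suite = make_variant_suite(SyntheticTruth(seed=seed), n_frames=n_frames)
    write_ensemble(suite.wild_type, directory / "wild_type.pdb")
    write_ensemble(suite.contact_gain, directory / "contact_gain.pdb")
    write_ensemble(suite.charge_edit, directory / "charge_edit.pdb")
    write_structure(suite.wild_type.topology, directory / "wild_type_frame0.pqr", format="pqr")
    write_mini_force_field(directory / "parameters.tsv")
    dm = toy_domain_map()
    (directory / "domains.yaml").write_text(
        yaml.safe_dump(
            {
                "domains": [
                    {"name": n, "chain": c, "first": f, "last": l}
                    for n, c, f, l in dm.entries
                ]
            }
        )
    )
    (directory / "truth.json").write_text(suite.truth.to_json() + "\n")
    return directory
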