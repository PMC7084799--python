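"""Residue interaction networks from a van-der-Waals overlap contact criterion.

Two atoms are in contact when their vdW spheres approach closer than a
tolerance: ``overlap = r_i + r_j - d_ij > threshold`` (default threshold
-0.4 Å, strict inequality).  Two residues are in contact in a frame when at
least one of their atom pairs satisfies the predicate.  Aggregating over an
ensemble yields a residue interaction network (RIN) whose edges carry

* ``persistence`` — the fraction of analysed frames in which the residue
  pair is in contact, and
* ``mean_atom_pairs`` — the mean number of qualifying atom pairs per frame
  (zeros included), a contact-multiplicity measure of interaction strength.

Node degree is the number of distinct partner residues.  By default only
inter-chain (receptor–ligand) contacts are considered, so the network is
bipartite.  The neighbour search is k-d-tree pruned but exactly equivalent
to the all-pairs brute force.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .ensemble_io import (
    DomainMap,
    Ensemble,
    FrameWindow,
    Structure,
    select_frames,
)

__all__ = [
    "ContactCriterion",
    "ContactGraph",
    "RinDifference",
    "atom_overlap",
    "residue_contacts_frame",
    "build_rin",
    "compare_rins",
    "export_rin",
    "import_rin_graphml",
]

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class ContactCriterion:
    """Parameters of the overlap contact predicate."""

    overlap_threshold: float = -0.4  # Å; contact iff overlap > threshold (strict)
    include_hydrogens: bool = True
    interchain_only: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.overlap_threshold):
            raise ValueError("overlap threshold must be finite")


def atom_overlap(r_i: float, r_j: float, d_ij: float) -> float:
    """vdW overlap of two atoms: ``r_i + r_j - d_ij`` (Å).

    Positive values mean interpenetrating spheres; the contact predicate is
    ``overlap > threshold`` with strict inequality.
    """
    if r_i <= 0 or r_j <= 0:
        raise ValueError("vdW radii must be positive")
    if d_ij < 0:
        raise ValueError("distance must be non-negative")
    return r_i + r_j - d_ij


def _atom_subset(structure: Structure, criterion: ContactCriterion) -> np.ndarray:
    idx = np.arange(structure.n_atoms)
    if not criterion.include_hydrogens:
        keep = np.array([e != "H" for e in structure.elements])
        idx = idx[keep]
    return idx


def residue_contacts_frame(
    structure: Structure, criterion: ContactCriterion
) -> dict[tuple[ResidueKey, ResidueKey], int]:
    """Residue pairs in contact in one frame, with qualifying atom-pair counts.

    A residue pair is present iff at least one of its atom pairs satisfies
    ``r_i + r_j - d > threshold``; the value is the number of such atom
    pairs.  Keys are ordered (chain A residue, chain B residue) in
    inter-chain mode, else sorted.
    """
    if np.isnan(structure.vdw_radii).any():
        raise ValueError("structure has unparameterized vdW radii")
    idx = _atom_subset(structure, criterion)
    pos = structure.positions[idx]
    rad = structure.vdw_radii[idx]
    chains = structure.chain_ids[idx]
    resnum = structure.residue_numbers[idx]

    # Prune with a k-d tree at the largest possible contact distance.
    cutoff = 2.0 * float(rad.max()) - criterion.overlap_threshold
    if cutoff <= 0:
        return {}
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    if len(pairs) == 0:
        return counts
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(pos[i] - pos[j], axis=1)
    hit = (rad[i] + rad[j] - d) > criterion.overlap_threshold
    for a, b in pairs[hit]:
        ra: ResidueKey = (str(chains[a]), int(resnum[a]))
        rb: ResidueKey = (str(chains[b]), int(resnum[b]))
        if ra == rb:
            continue
        if criterion.interchain_only and ra[0] == rb[0]:
            continue
        key = (ra, rb) if ra < rb else (rb, ra)
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class ContactGraph:
    """Residue interaction network aggregated over an ensemble window."""

    graph: nx.Graph
    criterion: ContactCriterion
    n_frames: int

    # -- node/edge views ---------------------------------------------------
    def degree(self, residue: ResidueKey) -> int:
        return self.graph.degree[residue] if residue in self.graph else 0

    def degrees(self) -> dict[ResidueKey, int]:
        return {n: d for n, d in self.graph.degree}

    def edges(self) -> dict[tuple[ResidueKey, ResidueKey], dict]:
        out = {}
        for u, v, data in self.graph.edges(data=True):
            key = (u, v) if u < v else (v, u)
            out[key] = dict(data)
        return out

    def persistence(self, u: ResidueKey, v: ResidueKey) -> float:
        return float(self.graph.edges[u, v]["persistence"])

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_rin(
    ensemble: Ensemble,
    window: FrameWindow | None = None,
    criterion: ContactCriterion = ContactCriterion(),
    min_persistence: float = 0.0,
) -> ContactGraph:
    """Build the residue interaction network over the selected frames.

    Edge persistence = (frames with >= 1 qualifying atom pair) / (frames
    analysed); ``mean_atom_pairs`` averages the per-frame atom-pair count
    with zeros included.  Edges never observed are absent; an optional
    ``min_persistence`` filter drops rarely-seen edges (off by default).
    """
    if window is not None:
        ensemble = select_frames(ensemble, window)
    if ensemble.n_frames == 0:
        raise ValueError("no frames selected")
    frames_seen: dict[tuple[ResidueKey, ResidueKey], int] = {}
    pair_sum: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for frame in ensemble:
        contacts = residue_contacts_frame(frame, criterion)
        for key, cnt in contacts.items():
            frames_seen[key] = frames_seen.get(key, 0) + 1
            pair_sum[key] = pair_sum.get(key, 0) + cnt
    g = nx.Graph()
    top = ensemble.topology
    for (u, v), seen in frames_seen.items():
        pers = seen / ensemble.n_frames
        if pers < min_persistence:
            continue
        g.add_edge(u, v, persistence=pers, mean_atom_pairs=pair_sum[(u, v)] / ensemble.n_frames)
    for node in g.nodes:
        g.nodes[node]["chain"] = node[0]
        g.nodes[node]["residue_number"] = node[1]
        try:
            g.nodes[node]["residue_name"] = top.residue_name_of(*node)
        except KeyError:
            g.nodes[node]["residue_name"] = "UNK"
    for node, deg in g.degree:
        g.nodes[node]["degree"] = deg
    return ContactGraph(graph=g, criterion=criterion, n_frames=ensemble.n_frames)


@dataclass
class RinDifference:
    """Differences between two RINs built with the same criterion."""

    degree_delta: dict[ResidueKey, int] = field(default_factory=dict)
    gained_edges: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    lost_edges: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    persistence_delta: dict[tuple[ResidueKey, ResidueKey], float] = field(
        default_factory=dict
    )
    domain_degree: dict[str, tuple[int, int]] = field(default_factory=dict)

    def top_degree_gains(self) -> list[tuple[ResidueKey, int]]:
        return sorted(self.degree_delta.items(), key=lambda kv: -kv[1])


def compare_rins(
    g1: ContactGraph, g2: ContactGraph, domains: DomainMap | None = None
) -> RinDifference:
    """Compare two RINs: degree deltas (g2 - g1), gained/lost edges and
    persistence deltas on shared edges; per-domain degree totals when a
    domain map is supplied.  Refuses graphs built under different criteria.
    """
    if g1.criterion != g2.criterion:
        raise ValueError(
            "cannot compare RINs built with different contact criteria: "
            f"{g1.criterion} vs {g2.criterion}"
        )
    e1, e2 = g1.edges(), g2.edges()
    diff = RinDifference()
    diff.gained_edges = sorted(set(e2) - set(e1))
    diff.lost_edges = sorted(set(e1) - set(e2))
    for key in set(e1) & set(e2):
        diff.persistence_delta[key] = e2[key]["persistence"] - e1[key]["persistence"]
    d1, d2 = g1.degrees(), g2.degrees()
    for node in set(d1) | set(d2):
        diff.degree_delta[node] = d2.get(node, 0) - d1.get(node, 0)
    if domains is not None:
        for name in domains.names():
            t1 = sum(d for n, d in d1.items() if domains.domain_of(*n) == name)
            t2 = sum(d for n, d in d2.items() if domains.domain_of(*n) == name)
            diff.domain_degree[name] = (t1, t2)
    return diff


# ---------------------------------------------------------------------------
# Export / import


def _node_id(node: ResidueKey) -> str:
    return f"{node[0]}:{node[1]}"


def export_rin(graph: ContactGraph, path: str | Path, format: str | None = None) -> None:
    """Export a RIN as GraphML, SIF (Cytoscape) or a CSV edge table.

    GraphML carries node degree and edge persistence/mean_atom_pairs as
    attributes and round-trips through :func:`import_rin_graphml`.
    """
    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".sif": "sif", ".csv": "csv"}.get(
            path.suffix.lower(), ""
        )
    if graph.n_edges == 0:
        raise ValueError("refusing to export an empty contact graph")
    if format == "graphml":
        g = nx.relabel_nodes(graph.graph, {n: _node_id(n) for n in graph.graph.nodes})
        g.graph["overlap_threshold"] = graph.criterion.overlap_threshold
        g.graph["n_frames"] = graph.n_frames
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for (u, v) in graph.edges():
                fh.write(f"{_node_id(u)}\tcontact\t{_node_id(v)}\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["chain_a", "residue_a", "chain_b", "residue_b", "persistence", "mean_atom_pairs"]
            )
            for (u, v), data in sorted(graph.edges().items()):
                w.writerow(
                    [u[0], u[1], v[0], v[1], f"{data['persistence']:.6g}",
                     f"{data['mean_atom_pairs']:.6g}"]
                )
    else:
        raise ValueError(f"unknown RIN export format {format!r}")


def import_rin_graphml(path: str | Path) -> ContactGraph:
    """Read back a GraphML export (inverse of export_rin for that format)."""
    g0 = nx.read_graphml(Path(path))
    mapping = {}
    for n in g0.nodes:
        chain, num = str(n).rsplit(":", 1)
        mapping[n] = (chain, int(num))
    g = nx.relabel_nodes(g0, mapping)
    crit = ContactCriterion(overlap_threshold=float(g.graph.get("overlap_threshold", -0.4)))
    return ContactGraph(graph=g, criterion=crit, n_frames=int(g.graph.get("n_frames", 1)))
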