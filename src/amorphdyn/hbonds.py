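"""Hydrogen-bond detection, cluster partitioning and topology statistics.

Carboxylic OH groups donate; both the carbonyl and the hydroxyl oxygen of
other molecules accept.  A bond is recorded when the minimum-image
O(donor)...O(acceptor) distance is at most ``r_max`` (default 3.5 A) and
the O-H...O angle at the hydrogen is at least ``theta_min`` (default
150 deg); each donor hydrogen binds at most its closest valid acceptor, so
bifurcated contacts are never double counted.

Clusters are connected components of the undirected donor-acceptor graph.
Topology labels: a dimer held by mutual donor/acceptor bonds is cyclic,
otherwise linear; larger clusters are cyclic (the undirected simple graph
contains a ring), chains (acyclic, max degree 2) or branched.  The
low-molecular-cluster fraction is the share of clusters of 2-4 molecules
among all clusters of size >= 2 (a molecule-weighted variant is also
reported, since both conventions appear in practice).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures import Configuration, angle_deg, minimum_image_vector

R_MAX_DEFAULT = 3.5  # A, O...O cutoff
THETA_MIN_DEFAULT = 150.0  # deg, O-H...O angle
ACCEPTOR_ROLES = ("O_carbonyl", "O_hydroxyl")

LOW_CLUSTER_SIZES = (2, 3, 4)


@dataclass(frozen=True)
class HBond:
    donor_mol: int
    acceptor_mol: int
    d_oo_angstrom: float
    angle_deg: float
    acceptor_role: str = "O_carbonyl"


@dataclass(frozen=True)
class Cluster:
    members: tuple[int, ...]
    n_edges: int
    topology: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    n_monomers: int
    n_molecules: int

    def __post_init__(self) -> None:
        covered = sum(c.size for c in self.clusters) + self.n_monomers
        if covered != self.n_molecules:
            raise ValueError("clusters + monomers must partition all molecules")


@dataclass(frozen=True)
class EnergyRecord:
    e_total: float
    e_parts: tuple[float, ...]
    e_int: float

    @property
    def magnitude_kJmol(self) -> float:
        return abs(self.e_int)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_hbonds(
    config: Configuration,
    r_max_angstrom: float = R_MAX_DEFAULT,
    theta_min_deg: float = THETA_MIN_DEFAULT,
) -> list[HBond]:
    """Geometric H-bond detection under the minimum-image convention."""
    box = config.box_angstrom
    if r_max_angstrom >= 0.5 * box.min():
        raise ValueError("cutoff must be below half the smallest box length")
    mols = config.molecules
    if not mols:
        return []

    acc_pos, acc_mol, acc_role = [], [], []
    for m in mols:
        for role in ACCEPTOR_ROLES:
            acc_pos.append(m.atom(role).xyz)
            acc_mol.append(m.molecule_id)
            acc_role.append(role)
    acc_pos = np.array(acc_pos)
    acc_mol = np.array(acc_mol)

    bonds: list[HBond] = []
    for m in mols:
        o_d = m.atom("O_hydroxyl").xyz
        h_d = m.atom("H_hydroxyl").xyz
        dr = minimum_image_vector(acc_pos - o_d, box)
        d = np.linalg.norm(dr, axis=1)
        cand = np.nonzero((d <= r_max_angstrom) & (acc_mol != m.molecule_id))[0]
        best: HBond | None = None
        for i in cand[np.argsort(d[cand])]:
            # acceptor image closest to the donor oxygen
            acc_img = o_d + dr[i]
            ang = angle_deg(o_d, h_d, acc_img)
            if ang >= theta_min_deg:
                best = HBond(donor_mol=m.molecule_id, acceptor_mol=int(acc_mol[i]),
                             d_oo_angstrom=float(d[i]), angle_deg=float(ang),
                             acceptor_role=acc_role[i])
                break  # closest valid acceptor only
        if best is not None:
            bonds.append(best)
    return bonds


# ---------------------------------------------------------------------------
# clustering & topology
# ---------------------------------------------------------------------------

def classify_topology(nodes, edges) -> str:
    """Label a connected H-bond cluster by its graph shape.

    ``edges`` are directed donor->acceptor pairs; a mutual pair on two
    molecules forms a cyclic dimer, otherwise cyclicity is judged on the
    undirected simple graph.
    """
    nodes = list(nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("topology defined for clusters of size >= 2")
    directed = set((a, b) for a, b in edges)
    und = set(frozenset(e) for e in directed)
    g = nx.Graph(tuple(e) for e in und)
    g.add_nodes_from(nodes)
    if not nx.is_connected(g):
        raise ValueError("cluster subgraph must be connected")

    if n == 2:
        mutual = any((a, b) in directed and (b, a) in directed for a, b in directed)
        return "cyclic_dimer" if mutual else "linear_dimer"

    has_ring = g.number_of_edges() >= n  # connected => ring iff edges >= nodes
    max_deg = max(d for _, d in g.degree())
    if n == 3:
        if has_ring:
            return "cyclic_trimer"
        return "linear_trimer" if max_deg <= 2 else "branched_trimer"
    if has_ring:
        return "cyclic_n"
    return "chain_n" if max_deg <= 2 else "branched_n"


def build_clusters(hbonds, n_molecules: int,
                   molecule_ids=None) -> ClusterSet:
    """Partition molecules into H-bond clusters (connected components)."""
    if molecule_ids is None:
        molecule_ids = range(n_molecules)
    ids = list(molecule_ids)
    if len(ids) != n_molecules:
        raise ValueError("molecule_ids length must equal n_molecules")
    known = set(ids)
    directed = [(b.donor_mol, b.acceptor_mol) if isinstance(b, HBond) else tuple(b)
                for b in hbonds]
    for a, b in directed:
        if a not in known or b not in known:
            raise ValueError(f"bond references unknown molecule ({a}, {b})")

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(directed)
    clusters: list[Cluster] = []
    n_monomers = 0
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            n_monomers += 1
            continue
        comp_edges = [(a, b) for a, b in directed if a in comp and b in comp]
        und_edges = len(set(frozenset(e) for e in comp_edges))
        clusters.append(Cluster(
            members=tuple(sorted(comp)),
            n_edges=und_edges,
            topology=classify_topology(comp, comp_edges),
        ))
    clusters.sort(key=lambda c: c.members)
    return ClusterSet(clusters=clusters, n_monomers=n_monomers,
                      n_molecules=n_molecules)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def cluster_size_histogram(cs: ClusterSet) -> dict:
    """Cluster-size histogram plus low-molecular (2-4) cluster fractions."""
    hist = Counter(c.size for c in cs.clusters)
    n_clusters = len(cs.clusters)
    if n_clusters == 0:
        low_cluster = None
        low_molecule = None
    else:
        low = [c for c in cs.clusters if c.size in LOW_CLUSTER_SIZES]
        low_cluster = len(low) / n_clusters
        mol_in_clusters = sum(c.size for c in cs.clusters)
        low_molecule = sum(c.size for c in low) / mol_in_clusters
    return {
        "histogram": dict(sorted(hist.items())),
        "low_fraction": low_cluster,            # cluster-weighted (default)
        "low_fraction_molecule_weighted": low_molecule,
        "n_clusters": n_clusters,
        "n_monomers": cs.n_monomers,
    }


def topology_fractions(cs: ClusterSet) -> dict:
    """Shares of topologies within each cluster-size class (None when empty)."""
    dimers = [c for c in cs.clusters if c.size == 2]
    trimers = [c for c in cs.clusters if c.size == 3]
    larger = [c for c in cs.clusters if c.size >= 4]

    def share(group, label):
        if not group:
            return None
        return sum(1 for c in group if c.topology == label) / len(group)

    out = {
        "cyclic_dimer_share_of_dimers": share(dimers, "cyclic_dimer"),
        "linear_dimer_share_of_dimers": share(dimers, "linear_dimer"),
        "cyclic_trimer_share_of_trimers": share(trimers, "cyclic_trimer"),
        "linear_trimer_share_of_trimers": share(trimers, "linear_trimer"),
        "branched_trimer_share_of_trimers": share(trimers, "branched_trimer"),
        "counts": dict(Counter(c.topology for c in cs.clusters)),
        "n_dimers": len(dimers),
        "n_trimers": len(trimers),
        "n_larger": len(larger),
    }
    return out


def interaction_energy(e_total: float, e_parts) -> EnergyRecord:
    """E_int = E_T - sum(E_i): complex energy minus its isolated parts, kJ/mol."""
    parts = tuple(float(x) for x in e_parts)
    if len(parts) < 1:
        raise ValueError("need at least one isolated-part energy")
    return EnergyRecord(e_total=float(e_total), e_parts=parts,
                        e_int=float(e_total) - sum(parts))


def analyze_configuration(config: Configuration,
                          r_max_angstrom: float = R_MAX_DEFAULT,
                          theta_min_deg: float = THETA_MIN_DEFAULT) -> dict:
    """One-call cluster report for a configuration (JSON-ready)."""
    bonds = detect_hbonds(config, r_max_angstrom, theta_min_deg)
    cs = build_clusters(bonds, config.n_molecules,
                        [m.molecule_id for m in config.molecules])
    report = {
        "n_molecules": config.n_molecules,
        "n_hbonds": len(bonds),
        **cluster_size_histogram(cs),
        "topology": topology_fractions(cs),
    }
    return report
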