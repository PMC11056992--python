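"""H-bond detection under PBC, cluster partitioning, topology statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amorphdyn import synth
from amorphdyn.hbonds import (
    Cluster, ClusterSet, build_clusters, classify_topology,
    cluster_size_histogram, detect_hbonds, interaction_energy,
    topology_fractions,
)
from amorphdyn.structures import Atom, Configuration, Molecule


def place_molecule(mol_id, o_h, direction, chirality="S"):
    """A template molecule rigidly moved so its hydroxyl O sits at ``o_h``
    with the O->H bond along ``direction`` (rotation about z only)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # template O->H is along -x; rotate -x onto direction (in-plane)
    ang = np.arctan2(direction[1], direction[0]) - np.pi
    R = np.array([[np.cos(ang), -np.sin(ang), 0],
                  [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
    o_t = synth._T_XYZ[synth._I_OH]
    atoms = [Atom(el, role, R @ (xyz - o_t) + np.asarray(o_h, float))
             for (el, role, _), xyz in zip(synth._TEMPLATE, synth._T_XYZ)]
    return Molecule(mol_id, chirality, atoms)


def pair_config(d_oo, box=40.0):
    """Donor at the origin pointing +x at an acceptor's hydroxyl O."""
    a = place_molecule(0, (10.0, 10.0, 10.0), (1, 0, 0))
    # acceptor oriented so its own H points away (+x as well)
    b = place_molecule(1, (10.0 + d_oo, 10.0, 10.0), (1, 0, 0))
    return Configuration(np.array([box] * 3), [a, b])


def brute_force_hbonds(config, r_max=3.5, theta_min=150.0):
    """Oracle: enumerate all 27 periodic images explicitly."""
    box = config.box_angstrom
    shifts = [np.array([i, j, k]) * box for i in (-1, 0, 1)
              for j in (-1, 0, 1) for k in (-1, 0, 1)]
    bonds = []
    for m in config.molecules:
        o_d, h_d = m.atom("O_hydroxyl").xyz, m.atom("H_hydroxyl").xyz
        best = None
        for other in config.molecules:
            if other.molecule_id == m.molecule_id:
                continue
            for role in ("O_carbonyl", "O_hydroxyl"):
                for s in shifts:
                    acc = other.atom(role).xyz + s
                    d = np.linalg.norm(acc - o_d)
                    if d > r_max:
                        continue
                    v1, v2 = o_d - h_d, acc - h_d
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang < theta_min:
                        continue
                    if best is None or d < best[0]:
                        best = (d, other.molecule_id)
        if best is not None:
            bonds.append((m.molecule_id, best[1]))
    return sorted(bonds)


def union_find_components(n, edges):
    """Independent union-find oracle for the cluster partition."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestDetectHBonds:
    def test_good_geometry_yields_one_bond(self):
        bonds = detect_hbonds(pair_config(2.8))
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_mol, b.acceptor_mol) == (0, 1)
        assert b.d_oo_angstrom == pytest.approx(2.8, abs=1e-9)
        assert b.angle_deg == pytest.approx(180.0, abs=1e-6)

    def test_distance_criterion_rejects_far_pair(self):
        assert detect_hbonds(pair_config(5.0)) == []

    def test_angle_criterion(self):
        a = place_molecule(0, (10, 10, 10), (1, 0, 0))
        # acceptor 2.8 A away but perpendicular to the O-H direction
        b = place_molecule(1, (10, 12.8, 10), (0, 1, 0))
        cfg = Configuration(np.array([40.0] * 3), [a, b])
        assert all(bond.donor_mol != 0 for bond in detect_hbonds(cfg))

    def test_bond_across_periodic_boundary(self):
        a = place_molecule(0, (1.0, 10.0, 10.0), (-1, 0, 0))
        b = place_molecule(1, (18.2, 10.0, 10.0), (-1, 0, 0))
        cfg = Configuration(np.array([20.0, 30.0, 30.0]), [a, b])
        bonds = detect_hbonds(cfg)
        assert [(b_.donor_mol, b_.acceptor_mol) for b_ in bonds] == [(0, 1)]
        assert bonds[0].d_oo_angstrom == pytest.approx(2.8, abs=1e-9)

    def test_matches_27_image_oracle_on_random_boxes(self, rng):
        for trial in range(30):
            box = rng.uniform(12.0, 16.0)
            mols = [place_molecule(i, rng.uniform(0, box, 3),
                                   rng.normal(size=2).tolist() + [0.0])
                    for i in range(6)]
            cfg = Configuration(np.array([box] * 3), mols)
            got = sorted((b.donor_mol, b.acceptor_mol)
                         for b in detect_hbonds(cfg))
            assert got == brute_force_hbonds(cfg), f"trial {trial}"

    def test_invariant_under_translation_and_wrapping(self, rng):
        box = 15.0
        mols = [place_molecule(i, rng.uniform(0, box, 3),
                               rng.normal(size=2).tolist() + [0.0])
                for i in range(8)]
        cfg = Configuration(np.array([box] * 3), mols)
        ref = sorted((b.donor_mol, b.acceptor_mol) for b in detect_hbonds(cfg))
        shift = np.array([4.7, -2.2, 9.9])
        for wrap in (False, True):
            moved = []
            for m in cfg.molecules:
                atoms = []
                for a in m.atoms:
                    xyz = a.xyz + shift
                    if wrap:
                        xyz = xyz % box
                    atoms.append(Atom(a.element, a.role, xyz))
                moved.append(Molecule(m.molecule_id, m.chirality, atoms))
            got = sorted((b.donor_mol, b.acceptor_mol)
                         for b in detect_hbonds(
                             Configuration(np.array([box] * 3), moved)))
            assert got == ref

    def test_cutoff_exceeding_half_box_raises(self):
        cfg = pair_config(2.8, box=6.0)
        with pytest.raises(ValueError):
            detect_hbonds(cfg, r_max_angstrom=3.5)


class TestClusters:
    def test_mutual_dimer_plus_monomers(self):
        cs = build_clusters([(1, 2), (2, 1)], 4, molecule_ids=[1, 2, 3, 4])
        assert len(cs.clusters) == 1
        assert cs.clusters[0].topology == "cyclic_dimer"
        assert cs.n_monomers == 2

    def test_path_is_linear_trimer(self):
        cs = build_clusters([(1, 2), (2, 3)], 3, molecule_ids=[1, 2, 3])
        assert cs.clusters[0].topology == "linear_trimer"

    def test_unknown_molecule_id_raises(self):
        with pytest.raises(ValueError):
            build_clusters([(0, 9)], 2)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_partition_matches_union_find_oracle(self, data):
        n = data.draw(st.integers(4, 24))
        edges = data.draw(st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1))
            .filter(lambda e: e[0] != e[1]), max_size=30))
        cs = build_clusters(edges, n)
        got = sorted([list(c.members) for c in cs.clusters]
                     + [[i] for i in range(n)
                        if not any(i in c.members for c in cs.clusters)])
        assert got == union_find_components(n, edges)


class TestTopology:
    @pytest.mark.parametrize("nodes,edges,label", [
        ([0, 1], [(0, 1)], "linear_dimer"),
        ([0, 1], [(0, 1), (1, 0)], "cyclic_dimer"),
        ([0, 1, 2], [(0, 1), (1, 2)], "linear_trimer"),
        ([0, 1, 2], [(0, 1), (1, 2), (2, 0)], "cyclic_trimer"),
        ([0, 1, 2, 3], [(0, 1), (0, 2), (0, 3)], "branched_n"),
        ([0, 1, 2, 3], [(0, 1), (1, 2), (2, 3)], "chain_n"),
        ([0, 1, 2, 3], [(0, 1), (1, 2), (2, 3), (3, 0)], "cyclic_n"),
    ])
    def test_graph_shapes(self, nodes, edges, label):
        assert classify_topology(nodes, edges) == label

    def test_disconnected_raises(self):
        with pytest.raises(ValueError):
            classify_topology([0, 1, 2, 3], [(0, 1), (2, 3)])

    def test_branched_trimer(self):
        # a 3-cluster with one doubly-bonded pair does not count as a cycle;
        # max degree 2 keeps it a linear trimer on the simple graph
        assert classify_topology([0, 1, 2], [(0, 1), (1, 0), (1, 2)]) \
            == "linear_trimer"


class TestStatistics:
    def make_clusterset(self, sizes_topologies, n_monomers=0):
        clusters, next_id = [], 0
        for size, topo in sizes_topologies:
            members = tuple(range(next_id, next_id + size))
            clusters.append(Cluster(members=members, n_edges=size - 1,
                                    topology=topo))
            next_id += size
        return ClusterSet(clusters=clusters, n_monomers=n_monomers,
                          n_molecules=next_id + n_monomers)

    def test_low_fraction_counts_clusters(self):
        cs = self.make_clusterset(
            [(2, "linear_dimer")] * 5 + [(3, "linear_trimer")] * 3
            + [(6, "chain_n")] * 2)
        stats = cluster_size_histogram(cs)
        assert stats["histogram"] == {2: 5, 3: 3, 6: 2}
        assert stats["low_fraction"] == pytest.approx(0.8)
        assert stats["low_fraction_molecule_weighted"] == \
            pytest.approx(19 / 31)

    def test_all_monomers_reports_missing(self):
        cs = self.make_clusterset([], n_monomers=7)
        stats = cluster_size_histogram(cs)
        assert stats["histogram"] == {}
        assert stats["low_fraction"] is None

    def test_topology_shares(self):
        cs = self.make_clusterset(
            [(2, "cyclic_dimer")] + [(2, "linear_dimer")] * 9)
        tf = topology_fractions(cs)
        assert tf["cyclic_dimer_share_of_dimers"] == pytest.approx(0.10)
        assert tf["cyclic_trimer_share_of_trimers"] is None

    def test_shares_within_class_sum_to_one(self):
        cs = self.make_clusterset(
            [(2, "cyclic_dimer")] * 2 + [(2, "linear_dimer")] * 5
            + [(3, "cyclic_trimer")] + [(3, "linear_trimer")] * 3)
        tf = topology_fractions(cs)
        assert tf["cyclic_dimer_share_of_dimers"] \
            + tf["linear_dimer_share_of_dimers"] == pytest.approx(1.0)
        assert tf["cyclic_trimer_share_of_trimers"] \
            + tf["linear_trimer_share_of_trimers"] \
            + tf["branched_trimer_share_of_trimers"] == pytest.approx(1.0)


class TestInteractionEnergy:
    def test_difference(self):
        rec = interaction_energy(-1.0, [-0.4, -0.5])
        assert rec.e_int == pytest.approx(-0.1)
        assert rec.magnitude_kJmol == pytest.approx(0.1)

    def test_single_zero_part(self):
        assert interaction_energy(-2.5, [0.0]).e_int == pytest.approx(-2.5)

    def test_empty_parts_rejected(self):
        with pytest.raises(ValueError):
            interaction_energy(-1.0, [])

    def test_splitting_a_part_leaves_e_int_unchanged(self):
        a = interaction_energy(-3.0, [-1.2, -0.8])
        b = interaction_energy(-3.0, [-0.7, -0.5, -0.8])
        assert a.e_int == pytest.approx(b.e_int)
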