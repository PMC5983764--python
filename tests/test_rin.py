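"""Interaction detectors against brute-force geometric oracles.

The oracles below recompute each interaction criterion directly from raw
coordinates with plain numpy (no shared code path with the detectors
beyond the published chemistry tables), over every residue pair.
"""

import math
from itertools import combinations

import numpy as np
import pytest

import rinclique.rin as rin
from rinclique.rin import (
    InteractionParams,
    build_network,
    find_disulfide,
    find_hbonds,
    find_ionic,
    find_pication,
    find_pipi,
    find_vdw,
    network_distance,
    params_from_file,
)
from rinclique.structure_io import residue_key
from rinclique.synthetic import ToySpec, make_structure

from conftest import make_residue, snapshot_of

import networkx as nx


# ---------------------------------------------------------------------------
# oracle helpers


def pair_set(edges):
    return {e.pair for e in edges}


def oracle_hbond_pairs(snap, p):
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        found = False
        for da, ab in ((ra, rb), (rb, ra)):
            donors = set(rin._SIDECHAIN_DONORS.get(da.res_name, set()))
            if da.res_name != "PRO":
                donors.add("N")
            acceptors = set(rin._SIDECHAIN_ACCEPTORS.get(ab.res_name, set())) | {"O", "OXT"}
            for x in da.heavy_atoms():
                for y in ab.heavy_atoms():
                    if x.name in donors and y.name in acceptors:
                        if np.linalg.norm(x.coord - y.coord) <= p.hbond_cutoff:
                            found = True
        if found:
            pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def oracle_vdw_pairs(snap, p):
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        for x in ra.heavy_atoms():
            for y in rb.heavy_atoms():
                rx = p.vdw_radii.get(x.element.upper())
                ry = p.vdw_radii.get(y.element.upper())
                if rx is None or ry is None:
                    continue
                if np.linalg.norm(x.coord - y.coord) - rx - ry <= p.vdw_surface_cutoff:
                    pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def random_cluster(rng, n_residues=8, box=8.0):
    """Random GLY-like blobs of C/N/O atoms in a small box."""
    residues = []
    for i in range(n_residues):
        n_atoms = int(rng.integers(1, 4))
        atoms = [("CA", "C", rng.uniform(0, box, 3))]
        for j in range(n_atoms):
            el = rng.choice(["C", "N", "O"])
            atoms.append((f"X{j}", el, rng.uniform(0, box, 3)))
        residues.append(make_residue(i + 1, atoms=atoms))
    return snapshot_of(*residues)


# ---------------------------------------------------------------------------
# hydrogen bonds


class TestHbond:
    def test_below_cutoff_gives_edge(self, params):
        s = snapshot_of(
            make_residue(1, atoms=[("N", "N", (0, 0, 0)), ("CA", "C", (20, 0, 0))]),
            make_residue(2, atoms=[("O", "O", (3.4, 0, 0)), ("CA", "C", (30, 0, 0))]),
        )
        edges = find_hbonds(s, params)
        assert pair_set(edges) == {(residue_key("A", 1), residue_key("A", 2))}

    def test_above_cutoff_no_edge(self, params):
        s = snapshot_of(
            make_residue(1, atoms=[("N", "N", (0, 0, 0))]),
            make_residue(2, atoms=[("O", "O", (3.6, 0, 0))]),
        )
        assert find_hbonds(s, params) == []

    def test_energy_tiers_on_distance(self, params):
        for d, expected in [(2.4, 115.0), (2.9, 40.0), (3.4, 17.0)]:
            s = snapshot_of(
                make_residue(1, atoms=[("N", "N", (0, 0, 0))]),
                make_residue(2, atoms=[("O", "O", (d, 0, 0))]),
            )
            (edge,) = find_hbonds(s, params)
            assert edge.energy == expected

    def test_proline_backbone_n_does_not_donate(self, params):
        s = snapshot_of(
            make_residue(1, "PRO", atoms=[("N", "N", (0, 0, 0))]),
            make_residue(2, atoms=[("O", "O", (3.0, 0, 0))]),
        )
        assert find_hbonds(s, params) == []

    def test_helix_fixture_matches_all_pairs_scan(self, params):
        """20-residue helix with N/O atoms equals the exhaustive scan."""
        rng = np.random.default_rng(42)
        residues = []
        for i in range(20):
            base = np.array(
                [2.3 * math.cos(i * 1.745), 2.3 * math.sin(i * 1.745), 1.5 * i]
            )
            residues.append(
                make_residue(
                    i + 1,
                    atoms=[
                        ("CA", "C", base),
                        ("N", "N", base + rng.normal(0, 0.8, 3)),
                        ("O", "O", base + rng.normal(0, 0.8, 3)),
                    ],
                )
            )
        s = snapshot_of(*residues)
        assert pair_set(find_hbonds(s, params)) == oracle_hbond_pairs(s, params)


class TestVdw:
    def test_surface_gap_arithmetic(self, params):
        s = snapshot_of(
            make_residue(1, atoms=[("CB", "C", (0, 0, 0))]),
            make_residue(2, atoms=[("CB", "C", (3.8, 0, 0))]),
        )
        (edge,) = find_vdw(s, params)
        assert edge.distance == pytest.approx(3.8 - 3.4)

    def test_gap_above_cutoff_no_edge(self, params):
        s = snapshot_of(
            make_residue(1, atoms=[("CB", "C", (0, 0, 0))]),
            make_residue(2, atoms=[("CB", "C", (4.0, 0, 0))]),
        )
        assert find_vdw(s, params) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_cluster_matches_oracle(self, params, seed):
        s = random_cluster(np.random.default_rng(seed))
        assert pair_set(find_vdw(s, params)) == oracle_vdw_pairs(s, params)


class TestDisulfide:
    def test_cys_pair_in_range(self, params):
        s = snapshot_of(
            make_residue(1, "CYS", atoms=[("SG", "S", (0, 0, 0))]),
            make_residue(2, "CYS", atoms=[("SG", "S", (2.0, 0, 0))]),
        )
        (edge,) = find_disulfide(s, params)
        assert edge.distance == pytest.approx(2.0)

    def test_out_of_range_and_non_cys_sulfur(self, params):
        far = snapshot_of(
            make_residue(1, "CYS", atoms=[("SG", "S", (0, 0, 0))]),
            make_residue(2, "CYS", atoms=[("SG", "S", (2.6, 0, 0))]),
        )
        assert find_disulfide(far, params) == []
        met = snapshot_of(
            make_residue(1, "MET", atoms=[("SD", "S", (0, 0, 0))]),
            make_residue(2, "MET", atoms=[("SD", "S", (2.0, 0, 0))]),
        )
        assert find_disulfide(met, params) == []


class TestIonic:
    def test_lys_asp_salt_bridge(self, params):
        s = snapshot_of(
            make_residue(1, "LYS", atoms=[("NZ", "N", (0, 0, 0))]),
            make_residue(
                2,
                "ASP",
                atoms=[
                    ("CG", "C", (3.5, 0, 0)),
                    ("OD1", "O", (3.5, 1.1, 0)),
                    ("OD2", "O", (3.5, -1.1, 0)),
                ],
            ),
        )
        (edge,) = find_ionic(s, params)
        assert edge.distance == pytest.approx(3.5)

    def test_same_sign_pair_excluded(self, params):
        s = snapshot_of(
            make_residue(1, "LYS", atoms=[("NZ", "N", (0, 0, 0))]),
            make_residue(2, "ARG", atoms=[("NE", "N", (3.5, 0, 0)),
                                          ("CZ", "C", (3.6, 0, 0)),
                                          ("NH1", "N", (3.5, 1, 0)),
                                          ("NH2", "N", (3.5, -1, 0))]),
        )
        assert find_ionic(s, params) == []

    def test_his_cation_configurable(self):
        his_atoms = [("CG", "C", (3.5, 0, 0)), ("ND1", "N", (3.5, 1, 0)),
                     ("CD2", "C", (3.5, -1, 0)), ("CE1", "C", (4.5, 1, 0)),
                     ("NE2", "N", (4.5, -1, 0))]
        s = snapshot_of(
            make_residue(1, "ASP", atoms=[("CG", "C", (0, 0, 0)),
                                          ("OD1", "O", (0, 1.1, 0)),
                                          ("OD2", "O", (0, -1.1, 0))]),
            make_residue(2, "HIS", atoms=his_atoms),
        )
        assert len(find_ionic(s, InteractionParams())) == 1
        assert find_ionic(s, InteractionParams(his_is_cation=False)) == []


class TestAromatic:
    @staticmethod
    def phe(seq, center, radius=1.39):
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        atoms = [
            (n, "C", (center[0] + radius * math.cos(a),
                      center[1] + radius * math.sin(a), center[2]))
            for n, a in zip(names, np.linspace(0, 2 * math.pi, 6, endpoint=False))
        ]
        return make_residue(seq, "PHE", atoms=atoms)

    def test_pipi_ring_center_distance(self, params):
        s = snapshot_of(self.phe(1, (0, 0, 0)), self.phe(2, (5.0, 0, 0)))
        (edge,) = find_pipi(s, params)
        assert edge.distance == pytest.approx(5.0, abs=1e-6)

    def test_pipi_beyond_cutoff(self, params):
        s = snapshot_of(self.phe(1, (0, 0, 0)), self.phe(2, (6.6, 0, 0)))
        assert find_pipi(s, params) == []

    def test_incomplete_ring_skipped(self, params):
        broken = make_residue(2, "PHE", atoms=[("CG", "C", (5, 0, 0))])
        s = snapshot_of(self.phe(1, (0, 0, 0)), broken)
        assert find_pipi(s, params) == []

    def test_trp_uses_closest_of_both_rings(self, params):
        # 5-ring atoms proper to the pyrrole sit ~12 Å out, the fused
        # 6-ring sits ~5 Å out; the closest ring center decides.
        atoms = [
            ("CG", "C", (12.0, 0.3, 0)),
            ("CD1", "C", (12.0, -0.3, 0)),
            ("NE1", "N", (12.3, 0, 0)),
            ("CD2", "C", (5.0, 0.7, 0)),
            ("CE2", "C", (5.0, -0.7, 0)),
            ("CE3", "C", (4.3, 0.7, 0)),
            ("CZ2", "C", (5.7, -0.7, 0)),
            ("CZ3", "C", (4.3, -0.7, 0)),
            ("CH2", "C", (5.7, 0.7, 0)),
        ]
        trp = make_residue(2, "TRP", atoms=atoms)
        s = snapshot_of(self.phe(1, (0, 0, 0)), trp)
        (edge,) = find_pipi(s, params)
        # 6-ring center exactly (5, 0, 0); 5-ring center ~9.2 Å out
        assert edge.distance == pytest.approx(5.0, abs=0.1)

    def test_pication_in_and_out_of_range(self, params):
        lys_close = make_residue(2, "LYS", atoms=[("NZ", "N", (4.0, 0, 0))])
        s = snapshot_of(self.phe(1, (0, 0, 0)), lys_close)
        (edge,) = find_pication(s, params)
        assert edge.distance == pytest.approx(4.0, abs=1e-6)
        lys_far = make_residue(2, "LYS", atoms=[("NZ", "N", (5.1, 0, 0))])
        assert find_pication(snapshot_of(self.phe(1, (0, 0, 0)), lys_far), params) == []

    def test_his_not_a_pication_cation(self, params):
        his = make_residue(2, "HIS", atoms=[("CG", "C", (4, 0, 0)),
                                            ("ND1", "N", (4, 1, 0)),
                                            ("CD2", "C", (4, -1, 0)),
                                            ("CE1", "C", (5, 1, 0)),
                                            ("NE2", "N", (5, -1, 0))])
        s = snapshot_of(self.phe(1, (0, 0, 0)), his)
        # pipi yes (two aromatic rings), pication no (His not cationic here)
        assert find_pication(s, params) == []
        assert len(find_pipi(s, params)) == 1


# ---------------------------------------------------------------------------
# network assembly


class TestBuildNetwork:
    def test_single_planted_hbond(self, params):
        snap = make_structure(ToySpec(n_residues=4, planted_interactions=(((1, 3), "hbond"),)))
        g = build_network(snap, params)
        assert set(g.edges()) == {(residue_key("A", 1), residue_key("A", 3))}
        assert "hbond" in g.edges[residue_key("A", 1), residue_key("A", 3)]["types"]

    def test_parallel_interactions_collapse(self, params):
        # planted disulfide at 2.0 Å is also a vdW contact: one graph edge
        snap = make_structure(ToySpec(n_residues=2, planted_interactions=(((1, 2), "ssbond"),)))
        g = build_network(snap, params)
        assert g.number_of_edges() == 1
        detail = g.edges[residue_key("A", 1), residue_key("A", 2)]
        assert set(detail["types"]) == {"ssbond", "vdw"}
        assert len(detail["interactions"]) == 2
        assert detail["energy"] == pytest.approx(167.0 + 6.0)

    def test_union_equals_independent_detectors(self, params):
        snap = make_structure(
            ToySpec(
                n_residues=30,
                planted_interactions=(
                    ((1, 5), "hbond"), ((2, 8), "vdw"), ((3, 9), "ssbond"),
                    ((4, 12), "ionic"), ((6, 14), "pipi"), ((7, 15), "pication"),
                    ((10, 20), "hbond"), ((11, 25), "ionic"),
                ),
            )
        )
        g = build_network(snap, params)
        union = set()
        for det in (find_hbonds, find_vdw, find_disulfide, find_ionic,
                    find_pipi, find_pication):
            union |= pair_set(det(snap, params))
        assert set(frozenset(e) for e in g.edges()) == set(frozenset(e) for e in union)

    def test_isolated_nodes_kept(self, params):
        snap = make_structure(ToySpec(n_residues=5, planted_interactions=(((1, 2), "vdw"),)))
        g = build_network(snap, params)
        assert g.number_of_nodes() == 5
        assert g.degree[residue_key("A", 4)] == 0

    def test_min_seq_separation_filter(self, params):
        snap = make_structure(ToySpec(n_residues=4, planted_interactions=(((1, 2), "vdw"),)))
        p2 = InteractionParams(min_seq_separation=2)
        assert build_network(snap, p2).number_of_edges() == 0

    def test_empty_snapshot_rejected(self, params):
        with pytest.raises(ValueError):
            build_network(snapshot_of(), params)

    def test_every_edge_satisfies_its_own_criterion(self, params):
        """Re-measure each reported interaction from raw coordinates."""
        snap = make_structure(
            ToySpec(
                n_residues=12,
                planted_interactions=(
                    ((1, 5), "hbond"), ((2, 8), "ssbond"), ((3, 9), "ionic"),
                    ((4, 12), "pipi"), ((6, 10), "pication"), ((7, 11), "vdw"),
                ),
            )
        )
        g = build_network(snap, params)
        for a, b, data in g.edges(data=True):
            for e in data["interactions"]:
                assert e.distance <= params.cutoff(e.itype)

    def test_rigid_motion_invariance(self, params):
        spec = ToySpec(
            n_residues=8,
            planted_interactions=(((1, 4), "hbond"), ((2, 6), "ionic")),
        )
        snap = make_structure(spec)
        g1 = build_network(snap, params)
        rng = np.random.default_rng(5)
        m = rng.normal(size=(3, 3))
        q, _ = np.linalg.qr(m)
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-20, 20, 3)
        rotated = snapshot_of(
            *[
                make_residue(
                    r.seq_index,
                    r.res_name,
                    atoms=[(a.name, a.element, q @ a.coord + shift) for a in r.atoms],
                )
                for r in snap
            ]
        )
        g2 = build_network(rotated, params)
        assert set(g1.edges()) == set(g2.edges())

    def test_cutoff_monotonicity(self):
        """Raising a cutoff never removes an edge of that type."""
        snap = make_structure(
            ToySpec(n_residues=10, planted_interactions=(((1, 5), "hbond"), ((2, 8), "ionic")))
        )
        tight = InteractionParams()
        loose = InteractionParams(hbond_cutoff=4.5, ionic_cutoff=5.5)
        assert pair_set(find_hbonds(snap, tight)) <= pair_set(find_hbonds(snap, loose))
        assert pair_set(find_ionic(snap, tight)) <= pair_set(find_ionic(snap, loose))

    def test_degree_sum_is_twice_edges(self, params):
        snap = make_structure(
            ToySpec(n_residues=10, planted_interactions=(((1, 5), "vdw"), ((5, 9), "vdw")))
        )
        g = build_network(snap, params)
        assert sum(dict(g.degree).values()) == 2 * g.number_of_edges()


class TestNetworkDistance:
    def test_trivial_cases(self):
        g = nx.Graph()
        a, b, c = (residue_key("A", i) for i in (1, 2, 3))
        g.add_edge(a, b)
        g.add_node(c)
        assert network_distance(g, a, a) == 0
        assert network_distance(g, a, b) == 1
        assert network_distance(g, a, c) == math.inf

    def test_unknown_node_raises(self):
        g = nx.Graph()
        g.add_node(residue_key("A", 1))
        with pytest.raises(KeyError):
            network_distance(g, residue_key("A", 1), residue_key("A", 9))

    def test_matches_bfs_oracle_on_random_graph(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(50, 0.08, seed=99)
        for _ in range(25):
            a, b = rng.integers(0, 50, 2)
            # plain BFS oracle
            frontier, seen, depth, found = {int(a)}, {int(a)}, 0, None
            while frontier:
                if int(b) in frontier:
                    found = depth
                    break
                frontier = {
                    n for f in frontier for n in g.neighbors(f) if n not in seen
                }
                seen |= frontier
                depth += 1
            expected = math.inf if found is None else found
            assert network_distance(g, int(a), int(b)) == expected


class TestParamsConfig:
    def test_json_and_keyvalue_round_trip(self, tmp_path):
        j = tmp_path / "p.json"
        j.write_text('{"hbond_cutoff": 4.0, "min_seq_separation": 2}')
        p = params_from_file(j)
        assert p.hbond_cutoff == 4.0 and p.min_seq_separation == 2
        kv = tmp_path / "p.cfg"
        kv.write_text("hbond_cutoff = 4.0\nmin_seq_separation = 2  # comment\n")
        assert params_from_file(kv) == p

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            InteractionParams(hbond_cutoff=-1.0)
        with pytest.raises(ValueError):
            InteractionParams(min_seq_separation=0)
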