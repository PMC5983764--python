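"""Synthetic structures, ensembles and graph streams with known ground truth.

These generators stand in for molecular-dynamics conformer ensembles: toy
"proteins" whose interaction edges are known by construction, and ensembles
in which a designated residue triple closes into a mutual-contact triangle
in a controlled fraction f of snapshots.  Structures are chemically minimal
— the interaction detectors only read distances, so correctness needs
geometry, not stereochemistry.  Planted interactions satisfy their cutoff
with at least a 0.2 Å margin; residues are spaced so that non-planted
pairs miss every cutoff with a comfortable gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .structure_io import AtomRecord, Ensemble, Residue, ResidueKey, Snapshot
from .structure_io import residue_key, write_pdb  # re-export: write_pdb

__all__ = [
    "ToySpec",
    "make_structure",
    "make_ensemble",
    "make_graph_ensemble",
    "write_pdb",
]

#: documented anchor seed for the repository's fixtures
DEFAULT_SEED = 20180510

#: inter-residue Cα spacing, Å — large enough that backbone Cα carbons
#: never fall within the van der Waals contact cutoff of one another
_CA_SPACING = 6.0

# planted-atom center separations per interaction type (cutoff, margin):
#   hbond   N..O        3.0  (cutoff 3.5, margin 0.5)
#   vdw     C..C gap    0.2  (cutoff 0.5, margin 0.3)
#   ssbond  SG..SG      2.0  (cutoff 2.5, margin 0.5)
#   ionic   centers     3.5  (cutoff 4.0, margin 0.5)
#   pipi    centers     5.0  (cutoff 6.5, margin 1.5)
#   pication centers    4.0  (cutoff 5.0, margin 1.0)
_PLANT_SEPARATION = {
    "hbond": 3.0,
    "vdw": 3.6,  # C-C centers: surface gap 3.6 - 2*1.70 = 0.2
    "ssbond": 2.0,
    "ionic": 3.5,
    "pipi": 5.0,
    "pication": 4.0,
}


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy structure / ensemble with known interactions."""

    n_residues: int
    backbone: str = "extended"  # extended | helix | ring
    planted_interactions: tuple = ()  # ((i, j), itype) with 1-based sites
    jitter_sigma: float = 0.1  # Å, per coordinate
    event: tuple | None = None  # ((a, b, c), f)
    seed: int = DEFAULT_SEED
    chain: str = "A"

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        for (i, j), itype in self.planted_interactions:
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise ValueError(f"planted pair ({i}, {j}) outside 1..{self.n_residues}")
            if i == j:
                raise ValueError("cannot plant a self-interaction")
            if itype not in _PLANT_SEPARATION:
                raise ValueError(f"unknown interaction type {itype!r}")
        if self.event is not None:
            (a, b, c), f = self.event
            if len({a, b, c}) != 3:
                raise ValueError("event triple must be three distinct sites")
            for s in (a, b, c):
                if not 1 <= s <= self.n_residues:
                    raise ValueError(f"event site {s} outside 1..{self.n_residues}")
            if not 0.0 <= f <= 1.0:
                raise ValueError("event fraction must lie in [0, 1]")

    def key(self, site: int) -> ResidueKey:
        return residue_key(self.chain, site)


def _backbone_positions(spec: ToySpec) -> np.ndarray:
    n = spec.n_residues
    if spec.backbone == "extended":
        return np.array([[i * _CA_SPACING, 0.0, 0.0] for i in range(n)])
    if spec.backbone == "helix":
        # widened helical CA trace (radius chosen to keep the ~6 Å spacing)
        rise, turn, radius = 3.0, math.radians(100.0), 4.8
        return np.array(
            [
                [radius * math.cos(i * turn), radius * math.sin(i * turn), i * rise]
                for i in range(n)
            ]
        )
    if spec.backbone == "ring":
        radius = n * _CA_SPACING / (2 * math.pi)
        return np.array(
            [
                [
                    radius * math.cos(2 * math.pi * i / n),
                    radius * math.sin(2 * math.pi * i / n),
                    0.0,
                ]
                for i in range(n)
            ]
        )
    raise ValueError(f"unknown backbone {spec.backbone!r}")


def _perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, probe)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, probe)
    return v / np.linalg.norm(v)


def _hexagon(center: np.ndarray, normal: np.ndarray, radius: float = 1.39):
    """Six carbon positions of a benzene-like ring perpendicular to normal."""
    e1 = _perpendicular(normal)
    e2 = np.cross(normal, e1)
    e2 /= np.linalg.norm(e2)
    return [
        center + radius * (math.cos(a) * e1 + math.sin(a) * e2)
        for a in np.linspace(0.0, 2 * math.pi, 6, endpoint=False)
    ]


class _Builder:
    """Accumulates atoms per residue while checking for planting conflicts."""

    def __init__(self, spec: ToySpec, ca: np.ndarray):
        self.spec = spec
        self.res_names = ["GLY"] * spec.n_residues
        self.atoms: list[list[AtomRecord]] = [
            [AtomRecord(name="CA", element="C", coord=ca[i].copy())]
            for i in range(spec.n_residues)
        ]

    def set_res_name(self, site: int, name: str) -> None:
        current = self.res_names[site - 1]
        if current not in ("GLY", name):
            raise ValueError(
                f"infeasible planting: residue {site} must be both {current} and {name}"
            )
        self.res_names[site - 1] = name

    def add_atom(self, site: int, name: str, element: str, coord: np.ndarray) -> None:
        if any(a.name == name for a in self.atoms[site - 1]):
            raise ValueError(
                f"infeasible planting: atom {name} of residue {site} placed twice"
            )
        self.atoms[site - 1].append(
            AtomRecord(name=name, element=element, coord=np.asarray(coord, float))
        )

    def snapshot(self, model_index: int = 1) -> Snapshot:
        residues = [
            Residue(
                chain=self.spec.chain,
                seq_index=i + 1,
                res_name=self.res_names[i],
                atoms=list(self.atoms[i]),
            )
            for i in range(self.spec.n_residues)
        ]
        return Snapshot(residues=residues, model_index=model_index)


def _plant(
    builder: _Builder, i: int, j: int, itype: str, center: np.ndarray, index: int
) -> None:
    u = np.array([1.0, 0.0, 0.0])
    half = 0.5 * _PLANT_SEPARATION[itype]
    pi, pj = center - half * u, center + half * u
    if itype == "hbond":
        builder.add_atom(i, "N", "N", pi)  # backbone amide donor
        builder.add_atom(j, "O", "O", pj)  # backbone carbonyl acceptor
    elif itype == "vdw":
        # indexed probe names: one residue may carry several vdW plantings
        builder.add_atom(i, f"CB{index}", "C", pi)
        builder.add_atom(j, f"CB{index}", "C", pj)
    elif itype == "ssbond":
        builder.set_res_name(i, "CYS")
        builder.set_res_name(j, "CYS")
        builder.add_atom(i, "SG", "S", pi)
        builder.add_atom(j, "SG", "S", pj)
    elif itype == "ionic":
        builder.set_res_name(i, "LYS")
        builder.set_res_name(j, "ASP")
        builder.add_atom(i, "NZ", "N", pi)
        perp = _perpendicular(u)
        # carboxylate with mass center exactly at pj (OD1/OD2 symmetric)
        builder.add_atom(j, "CG", "C", pj)
        builder.add_atom(j, "OD1", "O", pj + 1.1 * perp)
        builder.add_atom(j, "OD2", "O", pj - 1.1 * perp)
    elif itype == "pipi":
        builder.set_res_name(i, "PHE")
        builder.set_res_name(j, "PHE")
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        for site, center in ((i, pi), (j, pj)):
            for name, coord in zip(ring_names, _hexagon(center, u)):
                builder.add_atom(site, name, "C", coord)
    elif itype == "pication":
        builder.set_res_name(i, "LYS")
        builder.set_res_name(j, "PHE")
        builder.add_atom(i, "NZ", "N", pi)
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        for name, coord in zip(ring_names, _hexagon(pj, u)):
            builder.add_atom(j, name, "C", coord)


def make_structure(spec: ToySpec) -> Snapshot:
    """Build a toy snapshot realising every planted interaction.

    Each planted interaction is realised by placing the minimal atoms its
    detector needs at a separation that satisfies the cutoff with
    >= 0.2 Å margin.  Every planted interaction gets its own site well
    away from the backbone and from the other planted sites, so the only
    contacts between two residues are the planted one itself plus, for
    tight plantings, an unavoidable van der Waals contact of the same
    atom pair (which collapses onto the same graph edge).  Contradictory
    plantings (same atom needed twice, or one residue required to be two
    amino-acid types) raise ``ValueError``.
    """
    ca = _backbone_positions(spec)
    builder = _Builder(spec, ca)
    y_off = float(ca[:, 1].max()) + 10.0
    for t, ((i, j), itype) in enumerate(spec.planted_interactions):
        center = np.array([15.0 * t, y_off, 0.0])
        _plant(builder, i, j, itype, center, t)
    return builder.snapshot()


# contact-atom geometry for ensemble event triangles: plain carbon probes
_EVENT_CLOSED = 3.4   # C..C centers, surface gap 0.0 (cutoff 0.5, margin 0.5)
_EVENT_BROKEN = 5.4   # surface gap 2.0, misses the cutoff by 1.5 Å


def make_ensemble(spec: ToySpec, n_snapshots: int) -> tuple[Ensemble, np.ndarray]:
    """Generate an ensemble with a Bernoulli(f) triangle event.

    Every snapshot is the base structure with Gaussian coordinate jitter
    (``spec.jitter_sigma``, applied to the base atoms).  When
    ``spec.event = ((a, b, c), f)`` is set, a seeded Bernoulli(f) draw
    decides per snapshot whether the triple closes into a mutual-contact
    triangle: three pairwise carbon-probe contacts are placed exactly (the
    probes are not jittered, so the realised event indicator is exact);
    in non-event snapshots the a-b contact is broken (probes pulled 2.0 Å
    outside the contact cutoff) while b-c and a-c stay closed, leaving no
    triangle through a and b.

    Returns the ensemble and the realised per-snapshot event indicators.
    """
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    rng = np.random.default_rng(spec.seed)
    base = make_structure(replace(spec, event=None))

    if spec.event is not None:
        (a, b, c), f = spec.event
        events = rng.random(n_snapshots) < f
        triple_edges = [(a, b), (b, c), (a, c)]
    else:
        events = np.zeros(n_snapshots, dtype=bool)
        triple_edges = []

    # Each triangle edge gets its own probe-pair site, well away from the
    # backbone and from the other probe pairs, so closing/breaking one
    # contact can never create a contact between other residues.  (With
    # collinear Cα triples, probes placed on the Cα-Cα lines would collide.)
    all_y = [a.coord[1] for r in base.residues for a in r.atoms]
    probe_y = (max(all_y) if all_y else 0.0) + 15.0
    probe_centers = [np.array([12.0 * t, probe_y, 0.0]) for t in range(3)]
    probe_axis = np.array([1.0, 0.0, 0.0])

    snapshots = []
    for m in range(n_snapshots):
        residues = []
        for res in base.residues:
            atoms = [
                AtomRecord(
                    name=atom.name,
                    element=atom.element,
                    coord=atom.coord + rng.normal(0.0, spec.jitter_sigma, 3),
                )
                for atom in res.atoms
            ]
            residues.append(
                Residue(
                    chain=res.chain,
                    seq_index=res.seq_index,
                    res_name=res.res_name,
                    atoms=atoms,
                )
            )
        snap = Snapshot(residues=residues, model_index=m + 1)
        for t, (x, y) in enumerate(triple_edges):
            broken = t == 0 and not events[m]
            sep = _EVENT_BROKEN if broken else _EVENT_CLOSED
            mid = probe_centers[t]
            for site, coord in (
                (x, mid - 0.5 * sep * probe_axis),
                (y, mid + 0.5 * sep * probe_axis),
            ):
                snap.residues[site - 1].atoms.append(
                    AtomRecord(name=f"CP{t + 1}", element="C", coord=coord)
                )
        snapshots.append(snap)
    return Ensemble(snapshots=snapshots), events


def make_graph_ensemble(
    n_nodes: int,
    edge_prob: float,
    event: tuple | None,
    n_graphs: int,
    seed: int = DEFAULT_SEED,
) -> tuple[list[nx.Graph], np.ndarray]:
    """Random-graph stream with a forced/broken event triangle.

    Each graph is G(n, p); with ``event = ((a, b, c), f)``, a seeded
    Bernoulli(f) draw forces the triangle a-b-c complete (all three edges
    added) or broken (edge a-b removed) per graph.  Same seed, same
    sequence — bitwise identical edge lists.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if event is not None:
        (a, b, c), f = event
        events = rng.random(n_graphs) < f
    else:
        events = np.zeros(n_graphs, dtype=bool)
    graphs = []
    for m in range(n_graphs):
        g = nx.gnp_random_graph(
            n_nodes, edge_prob, seed=int(rng.integers(0, 2**31 - 1))
        )
        if event is not None:
            if events[m]:
                g.add_edges_from([(a, b), (b, c), (a, c)])
            elif g.has_edge(a, b):
                g.remove_edge(a, b)
        graphs.append(g)
    return graphs, events
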