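"""Non-covalent interaction detection and residue interaction networks.

Six interaction types are detected from heavy-atom geometry — hydrogen
bonds, van der Waals contacts, disulfide bonds, ionic (electrostatic)
interactions, π-π stacking and π-cation interactions — each with its own
distance definition and cutoff.  The union of the detected contacts over
all residue pairs gives a simple undirected graph on the residues of a
snapshot: the residue interaction network (RIN).  Nodes are placed at the
Cα atoms; edge energies are stored as annotations only and play no role
in the downstream graph topology (shortest paths, cliques, communities),
which is purely unweighted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import networkx as nx
import numpy as np

from .structure_io import Residue, ResidueKey, Snapshot

logger = logging.getLogger(__name__)

INTERACTION_TYPES = ("hbond", "vdw", "ssbond", "ionic", "pipi", "pication")

#: Bondi van der Waals radii, Å (heavy atoms; H listed for completeness).
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

_ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}

# Hydrogen-bond chemistry: heavy-atom donors carry an implicit H.  The
# backbone amide N donates (except proline, which has no amide H) and the
# backbone carbonyl O accepts, for every residue type.
_SIDECHAIN_DONORS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}

# Charged-group and ring atom compositions (group centers are
# mass-weighted over whichever of these atoms are present).
_POSITIVE_GROUPS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),  # guanidinium
    "LYS": ("NZ",),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),  # imidazole (if protonated)
}
_NEGATIVE_GROUPS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
}
_AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}
#: π-cation donor groups: Arg guanidinium and Lys ammonium.  His is treated
#: as cationic for ionic edges but not as a π-cation cation (configurable).
_PICATION_CATIONS = ("ARG", "LYS")


@dataclass(frozen=True)
class InteractionParams:
    """Distance cutoffs (Å) and annotation energies (kJ/mol) per type."""

    hbond_cutoff: float = 3.5
    vdw_surface_cutoff: float = 0.5
    ssbond_cutoff: float = 2.5
    ionic_cutoff: float = 4.0
    pipi_cutoff: float = 6.5
    pication_cutoff: float = 5.0
    # H-bond energies are tiered on donor-acceptor distance; the other
    # types carry one average value each.
    hbond_energies: tuple[float, float, float] = (115.0, 40.0, 17.0)
    hbond_energy_bins: tuple[float, float] = (2.5, 3.0)
    vdw_energy: float = 6.0
    ssbond_energy: float = 167.0
    ionic_energy: float = 20.0
    pipi_energy: float = 9.4
    pication_energy: float = 9.6
    vdw_radii: dict = field(default_factory=lambda: dict(BONDI_RADII))
    min_seq_separation: int = 1
    his_is_cation: bool = True  # His counts as positive in ionic edges

    def __post_init__(self):
        for name in (
            "hbond_cutoff",
            "vdw_surface_cutoff",
            "ssbond_cutoff",
            "ionic_cutoff",
            "pipi_cutoff",
            "pication_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_seq_separation < 1:
            raise ValueError("min_seq_separation must be >= 1")

    def cutoff(self, itype: str) -> float:
        return {
            "hbond": self.hbond_cutoff,
            "vdw": self.vdw_surface_cutoff,
            "ssbond": self.ssbond_cutoff,
            "ionic": self.ionic_cutoff,
            "pipi": self.pipi_cutoff,
            "pication": self.pication_cutoff,
        }[itype]

    def hbond_energy(self, distance: float) -> float:
        lo, hi = self.hbond_energy_bins
        strong, medium, weak = self.hbond_energies
        if distance <= lo:
            return strong
        if distance <= hi:
            return medium
        return weak


def params_from_file(path) -> InteractionParams:
    """Load interaction parameters from a JSON or ``key=value`` file."""
    text = open(path).read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = json.loads(value.strip())
    return replace(InteractionParams(), **data)


@dataclass(frozen=True)
class InteractionEdge:
    a: ResidueKey
    b: ResidueKey
    itype: str
    distance: float  # per-type distance definition, Å
    energy: float  # annotation, kJ/mol

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("self-interaction")

    @property
    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


def _dist(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(x - y))


def _mass_center(atoms) -> np.ndarray:
    coords = np.array([a.coord for a in atoms])
    masses = np.array([_ATOMIC_MASS.get(a.element.upper(), 12.011) for a in atoms])
    return coords.T @ masses / masses.sum()


def _edge(a: Residue, b: Residue, itype: str, d: float, e: float) -> InteractionEdge:
    ka, kb = sorted((a.key, b.key))
    return InteractionEdge(a=ka, b=kb, itype=itype, distance=d, energy=e)


# ---------------------------------------------------------------------------
# per-type detectors — each returns at most one edge per residue pair,
# carrying the minimal qualifying distance


def _donor_atoms(res: Residue):
    names = set(_SIDECHAIN_DONORS.get(res.res_name, ()))
    if res.res_name != "PRO":
        names.add("N")
    return [a for a in res.heavy_atoms() if a.name in names]


def _acceptor_atoms(res: Residue):
    names = set(_SIDECHAIN_ACCEPTORS.get(res.res_name, ()))
    names.update({"O", "OXT"})
    return [a for a in res.heavy_atoms() if a.name in names]


def find_hbonds(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """Hydrogen bonds: donor heavy atom within cutoff of an acceptor."""
    edges = []
    residues = s.residues
    for ra, rb in combinations(residues, 2):
        best = math.inf
        for da, ab in ((ra, rb), (rb, ra)):
            for don in _donor_atoms(da):
                for acc in _acceptor_atoms(ab):
                    d = _dist(don.coord, acc.coord)
                    if d < best:
                        best = d
        if best <= p.hbond_cutoff:
            edges.append(_edge(ra, rb, "hbond", best, p.hbond_energy(best)))
    return edges


def find_vdw(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """Van der Waals contacts: surface gap (center distance minus the two
    Bondi radii) within the cutoff, minimised over heavy-atom pairs."""
    edges = []
    warned: set[str] = set()

    def radii_and_coords(res):
        out = []
        for a in res.heavy_atoms():
            r = p.vdw_radii.get(a.element.upper())
            if r is None:
                if a.element not in warned:
                    logger.warning("no vdW radius for element %r; skipped", a.element)
                    warned.add(a.element)
                continue
            out.append((a.coord, r))
        return out

    cached = [radii_and_coords(r) for r in s.residues]
    for (ia, ra), (ib, rb) in combinations(enumerate(s.residues), 2):
        best = math.inf
        for ca, radius_a in cached[ia]:
            for cb, radius_b in cached[ib]:
                gap = _dist(ca, cb) - radius_a - radius_b
                if gap < best:
                    best = gap
        if best <= p.vdw_surface_cutoff:
            edges.append(_edge(ra, rb, "vdw", best, p.vdw_energy))
    return edges


def find_disulfide(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """Disulfide bridges: CYS SG-SG distance within the cutoff."""
    cys = [(r, r.atom("SG")) for r in s.residues if r.res_name == "CYS"]
    cys = [(r, a) for r, a in cys if a is not None]
    edges = []
    for (ra, sa), (rb, sb) in combinations(cys, 2):
        d = _dist(sa.coord, sb.coord)
        if d <= p.ssbond_cutoff:
            edges.append(_edge(ra, rb, "ssbond", d, p.ssbond_energy))
    return edges


def _charged_centers(res: Residue, table) -> list[np.ndarray]:
    names = table.get(res.res_name)
    if names is None:
        return []
    atoms = [a for a in res.heavy_atoms() if a.name in names]
    if not atoms:
        return []
    return [_mass_center(atoms)]


def find_ionic(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """Salt bridges: mass centers of oppositely charged groups in range."""
    pos_table = dict(_POSITIVE_GROUPS)
    if not p.his_is_cation:
        pos_table.pop("HIS", None)
    edges = []
    for ra, rb in combinations(s.residues, 2):
        best = math.inf
        for first, second in ((ra, rb), (rb, ra)):
            for cp in _charged_centers(first, pos_table):
                for cn in _charged_centers(second, _NEGATIVE_GROUPS):
                    d = _dist(cp, cn)
                    if d < best:
                        best = d
        if best <= p.ionic_cutoff:
            edges.append(_edge(ra, rb, "ionic", best, p.ionic_energy))
    return edges


def _ring_centers(res: Residue) -> list[np.ndarray]:
    rings = _AROMATIC_RINGS.get(res.res_name, ())
    centers = []
    for ring in rings:
        atoms = [res.atom(n) for n in ring]
        if any(a is None for a in atoms):
            logger.warning("incomplete %s ring in %s; skipped", res.res_name, res.key)
            continue
        centers.append(_mass_center(atoms))
    return centers


def find_pipi(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """π-π stacking: aromatic ring centers within the cutoff (closest
    ring pair for Trp, which contributes both rings)."""
    aromatic = [(r, _ring_centers(r)) for r in s.residues]
    aromatic = [(r, c) for r, c in aromatic if c]
    edges = []
    for (ra, ca), (rb, cb) in combinations(aromatic, 2):
        best = min(_dist(x, y) for x in ca for y in cb)
        if best <= p.pipi_cutoff:
            edges.append(_edge(ra, rb, "pipi", best, p.pipi_energy))
    return edges


def find_pication(s: Snapshot, p: InteractionParams) -> list[InteractionEdge]:
    """π-cation: cationic group center within cutoff of a ring center."""
    cation_table = {k: _POSITIVE_GROUPS[k] for k in _PICATION_CATIONS}
    edges = []
    aromatic = [(r, _ring_centers(r)) for r in s.residues]
    aromatic = [(r, c) for r, c in aromatic if c]
    cations = [(r, _charged_centers(r, cation_table)) for r in s.residues]
    cations = [(r, c) for r, c in cations if c]
    for ra, rings in aromatic:
        for rb, cats in cations:
            if ra.key == rb.key:
                continue
            best = min(_dist(x, y) for x in rings for y in cats)
            if best <= p.pication_cutoff:
                edges.append(_edge(ra, rb, "pication", best, p.pication_energy))
    return edges


_DETECTORS = {
    "hbond": find_hbonds,
    "vdw": find_vdw,
    "ssbond": find_disulfide,
    "ionic": find_ionic,
    "pipi": find_pipi,
    "pication": find_pication,
}


# ---------------------------------------------------------------------------
# network assembly


def build_network(s: Snapshot, p: InteractionParams | None = None) -> nx.Graph:
    """Assemble the residue interaction network of one snapshot.

    Returns a simple undirected :class:`networkx.Graph` whose nodes are
    :class:`ResidueKey` values (every residue of the snapshot, so isolated
    nodes are kept) and whose edges collapse all detected interactions of
    a pair.  Edge attributes:

    ``interactions``
        list of :class:`InteractionEdge` (one per detected type),
    ``types``
        sorted tuple of interaction type names,
    ``min_distance``
        minimum per-type distance over the pair's interactions,
    ``energy``
        sum of the annotation energies (annotation only; the graph is
        treated as unweighted everywhere downstream).

    Pairs closer in sequence than ``min_seq_separation`` on the same
    chain are excluded (default 1: only self-pairs are excluded).
    """
    if p is None:
        p = InteractionParams()
    if len(s.residues) == 0:
        raise ValueError("empty snapshot")
    g = nx.Graph()
    g.add_nodes_from(s.residue_keys())
    for detector in _DETECTORS.values():
        for e in detector(s, p):
            a, b = e.pair
            if a.chain == b.chain and abs(a.seq_index - b.seq_index) < p.min_seq_separation:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["interactions"].append(e)
            else:
                g.add_edge(a, b, interactions=[e])
    for a, b, data in g.edges(data=True):
        inter = data["interactions"]
        data["types"] = tuple(sorted(e.itype for e in inter))
        data["min_distance"] = min(e.distance for e in inter)
        data["energy"] = sum(e.energy for e in inter)
    return g


def network_distance(g: nx.Graph, a: ResidueKey, b: ResidueKey) -> float:
    """Unweighted shortest-path length between two residues.

    Returns 0 for ``a == b`` and ``math.inf`` when the residues lie in
    different connected components.
    """
    for node in (a, b):
        if node not in g:
            raise KeyError(f"node {node} not in network")
    try:
        return nx.shortest_path_length(g, a, b)
    except nx.NetworkXNoPath:
        return math.inf


def write_edge_list(g: nx.Graph, path, header_comment: str | None = None) -> None:
    """Write the network as a TSV edge list (plus isolated-node records)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("chain_a\tres_a\tchain_b\tres_b\ttypes\tmin_distance\tenergy\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(
                f"{a.chain}\t{a.seq_index}\t{b.chain}\t{b.seq_index}\t"
                f"{','.join(data['types'])}\t{data['min_distance']:.3f}\t"
                f"{data['energy']:.1f}\n"
            )


def read_edge_list(path) -> nx.Graph:
    """Read a TSV edge list written by :func:`write_edge_list`."""
    from .structure_io import residue_key

    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chain_a"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                continue
            a = residue_key(parts[0], int(parts[1]))
            b = residue_key(parts[2], int(parts[3]))
            attrs = {}
            if len(parts) >= 7:
                attrs = {
                    "types": tuple(parts[4].split(",")),
                    "min_distance": float(parts[5]),
                    "energy": float(parts[6]),
                }
            g.add_edge(a, b, **attrs)
    return g
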