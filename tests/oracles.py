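"""Brute-force geometric oracles shared by the acceptance checks.

Every oracle recomputes an interaction criterion directly from raw
coordinates with plain numpy over all residue/atom pairs.  Conventions
(donor/acceptor tables, group compositions, Bondi radii, His treated as
cationic for salt bridges but not for π-cation) follow the documented
chemistry of the detectors.
"""

from itertools import combinations

import numpy as np

MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}
RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}
POSITIVE = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
NEGATIVE = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}
RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}


def _heavy(res):
    return [a for a in res.atoms if a.element.upper() != "H"]


def _mass_center(atoms):
    coords = np.array([a.coord for a in atoms])
    m = np.array([MASS.get(a.element.upper(), 12.011) for a in atoms])
    return coords.T @ m / m.sum()


def _group_center(res, names):
    atoms = [a for a in _heavy(res) if a.name in names]
    return _mass_center(atoms) if atoms else None


def _ring_centers(res):
    out = []
    for ring in RINGS.get(res.res_name, ()):
        atoms = [res.atom(n) for n in ring]
        if all(a is not None for a in atoms):
            out.append(_mass_center(atoms))
    return out


def hbond_pairs(snap, p):
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        for da, ab in ((ra, rb), (rb, ra)):
            donors = set(DONORS.get(da.res_name, set()))
            if da.res_name != "PRO":
                donors.add("N")
            acceptors = set(ACCEPTORS.get(ab.res_name, set())) | {"O", "OXT"}
            for x in _heavy(da):
                for y in _heavy(ab):
                    if (
                        x.name in donors
                        and y.name in acceptors
                        and np.linalg.norm(x.coord - y.coord) <= p.hbond_cutoff
                    ):
                        pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def vdw_pairs(snap, p):
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        for x in _heavy(ra):
            for y in _heavy(rb):
                rx, ry = RADII.get(x.element.upper()), RADII.get(y.element.upper())
                if rx is None or ry is None:
                    continue
                if np.linalg.norm(x.coord - y.coord) - rx - ry <= p.vdw_surface_cutoff:
                    pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def ssbond_pairs(snap, p):
    pairs = set()
    cys = [r for r in snap.residues if r.res_name == "CYS" and r.atom("SG")]
    for ra, rb in combinations(cys, 2):
        d = np.linalg.norm(ra.atom("SG").coord - rb.atom("SG").coord)
        if d <= p.ssbond_cutoff:
            pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def ionic_pairs(snap, p):
    pos_table = dict(POSITIVE)
    if not p.his_is_cation:
        pos_table.pop("HIS")
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        for da, ab in ((ra, rb), (rb, ra)):
            cp = _group_center(da, pos_table.get(da.res_name, ()))
            cn = _group_center(ab, NEGATIVE.get(ab.res_name, ()))
            if cp is None or cn is None:
                continue
            if np.linalg.norm(cp - cn) <= p.ionic_cutoff:
                pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def pipi_pairs(snap, p):
    pairs = set()
    aromatic = [(r, _ring_centers(r)) for r in snap.residues]
    aromatic = [(r, c) for r, c in aromatic if c]
    for (ra, ca), (rb, cb) in combinations(aromatic, 2):
        if min(np.linalg.norm(x - y) for x in ca for y in cb) <= p.pipi_cutoff:
            pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


def pication_pairs(snap, p):
    pairs = set()
    for ra, rb in combinations(snap.residues, 2):
        for ar, cat in ((ra, rb), (rb, ra)):
            rings = _ring_centers(ar)
            center = (
                _group_center(cat, POSITIVE[cat.res_name])
                if cat.res_name in ("ARG", "LYS")
                else None
            )
            if not rings or center is None:
                continue
            if min(np.linalg.norm(x - center) for x in rings) <= p.pication_cutoff:
                pairs.add(tuple(sorted((ra.key, rb.key))))
    return pairs


ORACLES = {
    "hbond": hbond_pairs,
    "vdw": vdw_pairs,
    "ssbond": ssbond_pairs,
    "ionic": ionic_pairs,
    "pipi": pipi_pairs,
    "pication": pication_pairs,
}


# ---------------------------------------------------------------------------
# random protein-like test structures


def _hexagon(center, radius=1.39):
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    return [
        center + radius * np.array([np.cos(a), np.sin(a), 0.0]) for a in angles
    ]


def random_protein_like(rng, n_residues=14, box=14.0):
    """Random mix of residue types carrying every detector's chemistry."""
    from rinclique.structure_io import AtomRecord, Residue, Snapshot

    templates = ["GLY", "CYS", "LYS", "ASP", "GLU", "PHE", "HIS", "ARG",
                 "SER", "TRP"]
    residues = []
    for i in range(n_residues):
        name = templates[int(rng.integers(0, len(templates)))]
        base = rng.uniform(0, box, 3)
        atoms = [("CA", "C", base)]
        jig = lambda: base + rng.uniform(-1.5, 1.5, 3)  # noqa: E731
        if name == "CYS":
            atoms.append(("SG", "S", jig()))
        elif name == "LYS":
            atoms.append(("NZ", "N", jig()))
        elif name == "ASP":
            atoms += [("CG", "C", jig()), ("OD1", "O", jig()), ("OD2", "O", jig())]
        elif name == "GLU":
            atoms += [("CD", "C", jig()), ("OE1", "O", jig()), ("OE2", "O", jig())]
        elif name == "SER":
            atoms.append(("OG", "O", jig()))
        elif name == "ARG":
            atoms += [("NE", "N", jig()), ("CZ", "C", jig()),
                      ("NH1", "N", jig()), ("NH2", "N", jig())]
        elif name == "PHE":
            ring = _hexagon(jig())
            atoms += list(zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                              "CCCCCC", ring))
        elif name == "HIS":
            ring = _hexagon(jig())[:5]
            atoms += list(zip(("CG", "ND1", "CD2", "CE1", "NE2"),
                              "CNCCN", ring))
        elif name == "TRP":
            c5, c6 = jig(), jig()
            atoms += list(zip(("CG", "CD1", "NE1"), "CCN", _hexagon(c5, 1.2)[:3]))
            atoms += list(zip(("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
                              "CCCCCC", _hexagon(c6)))
        atoms.append(("N", "N", jig()))
        atoms.append(("O", "O", jig()))
        residues.append(
            Residue(
                chain="A",
                seq_index=i + 1,
                res_name=name,
                atoms=[AtomRecord(name=n, element=e, coord=np.asarray(c, float))
                       for n, e, c in atoms],
            )
        )
    return Snapshot(residues=residues)
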