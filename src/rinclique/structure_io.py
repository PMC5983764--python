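"""Coordinate data model and multi-model PDB input/output.

Structures are represented as :class:`Snapshot` objects (one conformer) and
:class:`Ensemble` objects (an ordered series of conformers, e.g. frames
saved from a molecular-dynamics trajectory as a multi-model PDB file).
Residues are identified everywhere by :class:`ResidueKey` — the author
chain id and author residue number, with no renumbering — so that network
nodes match the residue labels used in the mutagenesis literature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

#: standard amino-acid 3-letter codes; everything else (waters, ions,
#: ligands) is dropped by default when reading a PDB file.
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET
       PHE PRO SER THR TRP TYR VAL""".split()
)


class ResidueKey(NamedTuple):
    """Stable, hashable, order-comparable residue identifier.

    Ordering is (chain, seq_index), so keys sort by chain first and then
    by author residue number.
    """

    chain: str
    seq_index: int

    def __str__(self) -> str:  # "A:98"
        return f"{self.chain}:{self.seq_index}"


def residue_key(chain: str, seq_index: int) -> ResidueKey:
    """Return the canonical node identifier for a residue."""
    return ResidueKey(str(chain), int(seq_index))


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    chain: str
    seq_index: int
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return residue_key(self.chain, self.seq_index)

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Snapshot:
    """One conformer: an ordered list of residues with coordinates."""

    residues: list[Residue]
    model_index: int = 1

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not in snapshot {self.model_index}")

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]


@dataclass
class Ensemble:
    """Ordered conformer series; ``n`` is the snapshot count N."""

    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValueError("an ensemble needs at least one snapshot")
        keys = set(self.snapshots[0].residue_keys())
        for s in self.snapshots[1:]:
            if set(s.residue_keys()) != keys:
                raise ValueError(
                    "inconsistent residue sets across snapshots "
                    f"(model {s.model_index})"
                )

    @property
    def n(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)


# ---------------------------------------------------------------------------
# reading


def _pick_altloc(bp_atom):
    """Resolve a (possibly disordered) Biopython atom to one location.

    Policy: highest occupancy wins; ties broken in favour of altloc 'A'
    (then alphabetically) so that parsing is deterministic.
    """
    if not bp_atom.is_disordered():
        return bp_atom
    children = bp_atom.disordered_get_list()
    return max(
        children,
        key=lambda a: (a.get_occupancy() or 0.0, -ord((a.get_altloc() or "Z")[0])),
    )


def _convert_residue(bp_res) -> Residue:
    atoms = []
    for name, bp_atom in bp_res.child_dict.items():
        a = _pick_altloc(bp_atom)
        element = (a.element or "").strip() or name[0]
        atoms.append(
            AtomRecord(
                name=name.strip(),
                element=element,
                coord=np.asarray(a.get_coord(), dtype=float),
                altloc=(a.get_altloc() or "").strip(),
                occupancy=float(a.get_occupancy() or 1.0),
            )
        )
    het, seq, icode = bp_res.get_id()
    res = Residue(
        chain=bp_res.get_parent().get_id(),
        seq_index=int(seq),
        res_name=bp_res.get_resname().strip(),
        atoms=atoms,
    )
    return res


def read_structure(
    path,
    model: int | str = 1,
    keep_het: bool = False,
) -> Snapshot | Ensemble:
    """Read a (multi-model) PDB file.

    Parameters
    ----------
    path:
        PDB file with one or more MODEL records (a single implicit model
        is fine).
    model:
        1-based model number, or ``"all"`` to return an :class:`Ensemble`
        over every model in file order.
    keep_het:
        Keep waters/ions/heteroatom residues.  Off by default: the
        interaction network is defined over amino acids only.

    Residues without a CA atom are kept but a warning is logged; they are
    flagged via :attr:`Residue.has_ca`.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBConstructionWarning noise
        structure = PDBParser(QUIET=True).get_structure("s", str(path))

    snapshots: list[Snapshot] = []
    for i, bp_model in enumerate(structure):
        residues = []
        for bp_chain in bp_model:
            for bp_res in bp_chain:
                het, seq, icode = bp_res.get_id()
                if het.strip() and not keep_het:
                    continue
                if not keep_het and bp_res.get_resname().strip() not in AMINO_ACIDS:
                    continue
                res = _convert_residue(bp_res)
                if not res.has_ca:
                    logger.warning(
                        "residue %s has no CA atom (model %d)", res.key, i + 1
                    )
                residues.append(res)
        snapshots.append(Snapshot(residues=residues, model_index=i + 1))

    if not snapshots:
        raise ValueError(f"no models found in {path}")

    if model == "all":
        return Ensemble(snapshots=snapshots)
    m = int(model)
    if not 1 <= m <= len(snapshots):
        raise ValueError(f"model {m} not in file ({len(snapshots)} models)")
    return snapshots[m - 1]


# ---------------------------------------------------------------------------
# writing

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:^4s}{altloc:1s}{res_name:>3s} {chain:1s}"
    "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16: single-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(obj: Snapshot | Ensemble, path) -> None:
    """Write a Snapshot or Ensemble as a (multi-model) PDB file.

    Coordinates are written at 3 decimal places (the PDB fixed-width
    format), so round-trips are exact to 1e-3 Å.
    """
    snapshots = obj.snapshots if isinstance(obj, Ensemble) else [obj]
    multi = len(snapshots) > 1
    with open(path, "w") as fh:
        for s in snapshots:
            if multi:
                fh.write(f"MODEL     {s.model_index:>4d}\n")
            serial = 1
            for res in s.residues:
                for a in res.atoms:
                    fh.write(
                        _ATOM_FMT.format(
                            serial=serial,
                            name=_format_atom_name(a.name, a.element),
                            altloc=a.altloc or " ",
                            res_name=res.res_name,
                            chain=res.chain[:1] or "A",
                            seq=res.seq_index,
                            icode=" ",
                            x=a.coord[0],
                            y=a.coord[1],
                            z=a.coord[2],
                            occ=a.occupancy,
                            b=0.0,
                            element=a.element[:2].upper(),
                        )
                    )
                    serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
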