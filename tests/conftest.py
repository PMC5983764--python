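import numpy as np
import pytest

from rinclique.rin import InteractionParams
from rinclique.structure_io import AtomRecord, Residue, Snapshot


@pytest.fixture
def params():
    return InteractionParams()


def make_residue(seq, res_name="GLY", atoms=(), chain="A"):
    """Terse residue builder: atoms as (name, element, (x, y, z))."""
    return Residue(
        chain=chain,
        seq_index=seq,
        res_name=res_name,
        atoms=[
            AtomRecord(name=n, element=e, coord=np.asarray(c, float))
            for n, e, c in atoms
        ],
    )


def snapshot_of(*residues):
    return Snapshot(residues=list(residues))
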