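"""Curated published mutation data shipped with the package.

Three small tables of published T4 bacteriophage lysozyme and Eglin c
double-mutant data, typed in from the mutagenesis literature, are bundled
so the classification and correlation machinery can be exercised without
any downloads.  Real structure files (e.g. wild-type T4 lysozyme, PDB
2LZM) are not redistributed; :func:`fetch_pdb` downloads them from RCSB
when network access is available.
"""

from __future__ import annotations

import urllib.request
from importlib import resources
from pathlib import Path

import pandas as pd

RCSB_URL = "https://files.rcsb.org/download/{code}.pdb"


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_lysozyme_clique_probabilities() -> pd.DataFrame:
    """Clique co-membership probabilities for 13 T4 lysozyme site pairs.

    One row per double-mutation site pair; one column per structural
    model of the enzyme (wild type plus six single/double mutants) giving
    the reported P_ab of the pair over that model's conformational
    ensemble.
    """
    return _load_csv("t4_lysozyme_clique_probability.csv")


def load_lysozyme_dddg() -> pd.DataFrame:
    """Additivity deviations for 13 T4 lysozyme double mutants (kcal/mol).

    Columns: experimentally observed ΔΔΔG, the MAESTROweb-predicted
    ΔΔΔG, and the wild-type Cα-Cα distance (Å) between the two sites.
    """
    return _load_csv("t4_lysozyme_dddg.csv")


def load_eglinc_clique_probabilities() -> pd.DataFrame:
    """Eglin c double mutants: site distance, ΔΔΔG (kJ/mol) and P_ab."""
    return _load_csv("eglin_c_clique_probability.csv")


def fetch_pdb(code: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB into ``dest`` (requires network)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(code=code.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
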