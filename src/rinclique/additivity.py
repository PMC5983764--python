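"""Thermodynamic additivity of double-site mutations.

For a double mutant at sites i and j with measured unfolding free-energy
changes ΔΔG_i, ΔΔG_j (single mutants) and ΔΔG_ij (double mutant), the
ideal additive effect is ΔΔG_sum = ΔΔG_i + ΔΔG_j and the additivity
deviation is

    ΔΔΔG_ij = ΔΔG_ij − ΔΔG_sum.

|ΔΔΔG| near zero means the two single mutations act independently
(additive); a large |ΔΔΔG| signals thermodynamic coupling between the
sites.  No |ΔΔΔG| cutoff is imposed here — this module reports the
magnitudes and leaves labelling to the clique co-membership criterion or
to the user.  Units (kJ/mol vs kcal/mol) are carried as table metadata
and never converted: ΔΔΔG is unit-covariant and all comparisons are
within one table.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import ResidueKey, Snapshot

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("ddg_i", "ddg_j", "ddg_ij")


def compute_additivity(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill ``ddg_sum`` and ``dddg`` columns; drop incomplete rows.

    Rows missing any of ddg_i, ddg_j, ddg_ij are dropped (with the drop
    count returned and logged) — a double mutant is only analysable when
    both component single mutants were measured.  Non-numeric entries
    raise, naming the offending row.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    df = records.copy()
    for col in REQUIRED_COLUMNS:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric {col!r} entry in row {row}: {raw[row]!r}")
        df[col] = coerced
    complete = df[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete mutation records", n_dropped)
    df = df[complete].copy()
    df["ddg_sum"] = df["ddg_i"] + df["ddg_j"]
    df["dddg"] = df["ddg_ij"] - df["ddg_sum"]
    return df, n_dropped


def ca_distance(s: Snapshot, a: ResidueKey, b: ResidueKey) -> float:
    """Euclidean Cα-Cα distance (Å) between two residues of a snapshot."""
    dist_atoms = []
    for key in (a, b):
        res = s.residue(key)
        ca = res.atom("CA")
        if ca is None:
            raise ValueError(f"residue {key} has no CA atom")
        dist_atoms.append(ca.coord)
    return float(np.linalg.norm(dist_atoms[0] - dist_atoms[1]))


class CorrelationResult(NamedTuple):
    pearson: float
    spearman: float
    n: int


def compare_predictions(
    observed: Sequence[float], predicted: Sequence[float]
) -> CorrelationResult:
    """Correlate observed against predicted ΔΔΔG values.

    Pearson product-moment correlation is the primary statistic; the
    Spearman rank correlation is reported alongside as a robustness
    check.  Requires two equal-length finite lists of at least 3 values
    with nonzero variance.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and predicted must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 value pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    return CorrelationResult(float(pearson), float(spearman), int(x.size))
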