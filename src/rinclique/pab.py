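"""Ensemble clique co-membership probability and additivity classification.

For a residue pair (a, b) and a conformational ensemble of N snapshots,
the co-membership probability is

    P_ab = (1/N) * sum_i C_ab(i),

where C_ab(i) = 1 when a and b belong to the same 3-clique community of
the residue interaction network of snapshot i, else 0.  A pair with
P_ab >= 0.1 (inclusive) is classified as non-additive: the two sites sit
persistently inside one tightly interconnected triangle structure, so
mutations at the two sites are expected to couple.  Pairs below the
threshold are classified additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .cliquecomm import clique_percolation, enumerate_k_cliques, same_community
from .rin import InteractionParams, build_network
from .structure_io import Ensemble, ResidueKey

ADDITIVE = "additive"
NON_ADDITIVE = "non_additive"

DEFAULT_THRESHOLD = 0.1
DEFAULT_K = 3


def classify(p_ab: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Classify a co-membership probability (boundary inclusive)."""
    if not 0.0 <= p_ab <= 1.0:
        raise ValueError(f"p_ab must lie in [0, 1], got {p_ab}")
    return NON_ADDITIVE if p_ab >= threshold else ADDITIVE


@dataclass(frozen=True)
class PabResult:
    pair: tuple[ResidueKey, ResidueKey]
    p_ab: float
    n_snapshots: int
    n_events: int
    classification: str
    threshold: float = DEFAULT_THRESHOLD
    k: int = DEFAULT_K

    @property
    def se(self) -> float:
        """Binomial standard error sqrt(p(1-p)/N) of the estimate."""
        return math.sqrt(self.p_ab * (1.0 - self.p_ab) / self.n_snapshots)

    def to_dict(self) -> dict:
        return {
            "pair": [str(self.pair[0]), str(self.pair[1])],
            "p_ab": self.p_ab,
            "n_events": self.n_events,
            "N": self.n_snapshots,
            "se": self.se,
            "classification": self.classification,
            "threshold": self.threshold,
            "k": self.k,
        }


def _indicator(cset, cliques, a, b, strict_triangle: bool) -> int:
    if strict_triangle:
        return int(any(a in c and b in c for c in cliques))
    return same_community(cset, a, b)


def pab_from_networks(
    graphs: Iterable[nx.Graph],
    pairs: Sequence[tuple],
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    strict_triangle: bool = False,
) -> list[PabResult]:
    """Co-membership probabilities over an arbitrary network sequence.

    Building block shared by :func:`compute_pab` and :func:`pab_table`;
    also usable directly with graph-level ensembles where no geometry is
    involved.  ``strict_triangle=True`` counts only pairs inside one and
    the same k-clique, rather than the same k-clique community.
    """
    events = [0] * len(pairs)
    n = 0
    for g in graphs:
        cset = clique_percolation(g, k)
        cliques = enumerate_k_cliques(g, k) if strict_triangle else ()
        for j, (a, b) in enumerate(pairs):
            events[j] += _indicator(cset, cliques, a, b, strict_triangle)
        n += 1
    if n == 0:
        raise ValueError("empty network sequence")
    results = []
    for (a, b), ev in zip(pairs, events):
        p = ev / n
        results.append(
            PabResult(
                pair=(a, b),
                p_ab=p,
                n_snapshots=n,
                n_events=ev,
                classification=classify(p, threshold),
                threshold=threshold,
                k=k,
            )
        )
    return results


def _snapshot_networks(e: Ensemble, pairs, params, stride):
    for s in e.snapshots[::stride]:
        present = set(s.residue_keys())
        for a, b in pairs:
            for node in (a, b):
                if node not in present:
                    raise KeyError(
                        f"residue {node} missing from snapshot model {s.model_index}"
                    )
        yield build_network(s, params)


def compute_pab(
    e: Ensemble,
    pair: tuple,
    params: InteractionParams | None = None,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    stride: int = 1,
    strict_triangle: bool = False,
) -> PabResult:
    """P_ab for one residue pair over a conformational ensemble.

    Builds the residue interaction network and its k-clique communities
    for every snapshot (optionally every ``stride``-th snapshot) and
    averages the co-membership indicator.  Deterministic given the
    ensemble.
    """
    return pab_table(
        e, [pair], params=params, k=k, threshold=threshold, stride=stride,
        strict_triangle=strict_triangle,
    )[0]


def pab_table(
    e: Ensemble,
    pairs: Sequence[tuple],
    params: InteractionParams | None = None,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    stride: int = 1,
    strict_triangle: bool = False,
) -> list[PabResult]:
    """P_ab for many pairs; networks/communities computed once per snapshot."""
    if params is None:
        params = InteractionParams()
    if not pairs:
        return []
    graphs = _snapshot_networks(e, pairs, params, stride)
    return pab_from_networks(
        graphs, pairs, k=k, threshold=threshold, strict_triangle=strict_triangle
    )
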