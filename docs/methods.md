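# Methods

## Model

The predictor treats a protein conformational ensemble as a sequence of
residue interaction networks and asks a single topological question per
site pair (a, b): how often do the two residues sit inside the same
3-clique community? The statistic

P_ab = (1/N) Σᵢ C_ab(i)

is the mean over N snapshots of the indicator C_ab(i) that a and b share
a community of the snapshot-i network. The classification rule is
binary: P_ab ≥ 0.1 → non-additive, else additive, with the boundary
inclusive. The underlying assumption is that thermodynamic coupling
between mutation sites requires a persistent, tightly interconnected
local cluster — operationalised as a triangle (3-clique) of pairwise
non-covalent interactions that survives thermal fluctuation in a
substantial fraction of conformers. The model is deliberately blind to
interaction energies and physicochemical detail; all edges count
equally and only topology enters.

The thermodynamic reference statistic is ΔΔΔG_ij = ΔΔG_ij − (ΔΔG_i +
ΔΔG_j), computed by exact arithmetic on measured single- and
double-mutant free-energy changes. No |ΔΔΔG| cutoff is imposed: the
magnitude is reported and labelling is left to P_ab or the user. Units
(kJ/mol or kcal/mol) are table metadata and never converted, since ΔΔΔG
is unit-covariant and every comparison is within one table.

## Residue interaction network

Nodes are residues (identified by author chain and residue number,
conceptually placed at Cα); edges are the union of six detectors, each
with its own distance definition and default cutoff:

| type      | distance definition                         | cutoff (Å) | energy note (kJ/mol) |
|-----------|---------------------------------------------|-----------|----------------------|
| hbond     | donor heavy atom – acceptor heavy atom      | 3.5       | 115 / 40 / 17 tiered on distance (≤2.5 / ≤3.0 / else) |
| vdw       | atom-center distance − both Bondi radii     | 0.5       | 6.0 |
| ssbond    | CYS SG – SG                                 | 2.5       | 167.0 |
| ionic     | mass centers of oppositely charged groups   | 4.0       | 20.0 |
| pipi      | aromatic ring centers (closest pair; Trp has two rings) | 6.5 | 9.4 |
| pication  | cation group center – ring center           | 5.0       | 9.6 |

Numerical and chemical choices:

- **No explicit-hydrogen geometry.** Hydrogen bonds use the heavy-atom
  donor–acceptor distance only, with no angle term — the simplest
  reading of the stated criterion. Donor/acceptor assignments are the
  standard ones (backbone N donates except proline, backbone O accepts;
  Ser/Thr/Tyr hydroxyls both roles; Asn/Gln amides; Lys/Arg/Trp/His
  side-chain nitrogens donate; Asp/Glu carboxylates and His ring
  nitrogens accept).
- **Bondi radii** (C 1.70, N 1.55, O 1.52, S 1.80 Å), heavy atoms only;
  atoms of unknown element are skipped with a warning.
- **Histidine** counts as cationic for ionic edges (configurable via
  `his_is_cation`) and aromatic for π edges, but is excluded from the
  π-cation cation list — a fixed, documented convention.
- **Sequence separation**: only self-pairs are excluded by default
  (`min_seq_separation = 1`); sequence-adjacent residues may interact.
- Parallel interactions of one pair collapse to a single graph edge;
  the edge stores the full per-type detail, the minimum distance, and
  the *sum* of the per-type annotation energies. Energies are
  annotations only — every downstream algorithm treats the graph as
  unweighted and simple. Isolated nodes are kept.
- Edge sets are invariant under residue reordering and rigid-body
  motion, and monotone under cutoff increase (tested properties).

## Clique percolation

A k-clique is a complete subgraph on k nodes; two k-cliques are
adjacent when they share k−1 nodes, and a k-clique community is the
node union of a maximal chain-connected set of k-cliques. Since two
distinct k-cliques share at most k−1 nodes, adjacency is equivalent to
sharing some (k−1)-subset, so communities are computed with a
union-find keyed on (k−1)-subsets of the enumerated k-cliques — linear
in (number of cliques) × k rather than quadratic in the number of
cliques. k-cliques are enumerated by expanding maximal cliques
(Bron–Kerbosch) into k-subsets and deduplicating. Output is
deterministic: cliques in sorted node order, communities sorted by
smallest member. The implementation is validated against both an
explicit triangle-overlap/connected-components oracle and an
independent library implementation of the same method.

k defaults to 3 and the decision threshold to 0.1; both are exposed
(`--k`, `--threshold`) since the generalisation is free, but the
defaults are the studied operating point. C_ab is same-*community*
membership; strict same-*triangle* membership is available behind a
documented flag (`strict_triangle`), off by default.

## Synthetic data

The generator emulates what a dynamics ensemble provides to this
pipeline — a stream of conformers whose interaction topology fluctuates
— without any physics:

- **Toy structures** place Cα atoms on an extended chain (6 Å spacing),
  a widened helix, or a ring, and realise each requested interaction by
  adding the minimal atoms its detector needs (e.g. a CYS SG pair at
  2.0 Å, a PHE hexagon pair at 5.0 Å center separation). Each planted
  interaction satisfies its cutoff with ≥ 0.2 Å margin; planted atom
  groups are placed in mutually isolated regions so that no unplanned
  residue pair comes near any cutoff (the only side contact is an
  unavoidable vdW contact of the same atom pair for tight plantings,
  which collapses onto the same edge). Contradictory plantings raise.
- **Ensembles** add Gaussian jitter (default σ = 0.1 Å per coordinate)
  to the base atoms and, per snapshot, close or break a designated
  triangle (a, b, c) according to a seeded Bernoulli(f) draw: three
  carbon-probe contact pairs are placed exactly (probes are exempt from
  jitter so the realised indicator is exact by construction); in
  non-event snapshots the a–b contact is pulled 2.0 Å outside the
  cutoff while a–c and b–c stay closed, leaving edges but no triangle.
  The realised per-snapshot indicators are returned as ground truth,
  and the pipeline's P_ab equals their mean exactly.
- **Graph streams** (`make_graph_ensemble`) provide the same event
  logic directly at the network level for geometry-free tests.

What the generator does *not* emulate: real backbone stereochemistry,
correlated (autocorrelated) frames, solvent, or the dense ~2-edges-per-
residue connectivity of a folded protein. Passing the synthetic tests
therefore demonstrates correctness of detection, community logic and
the P_ab estimator — not that any particular protein's published P_ab
values would be reproduced, which requires the original long
trajectories. The anchor seed for fixtures is 20180510.

Statistical design of the recovery check: with N = 1000 snapshots the
estimator is Binomial(N, f)/N; runs are checked against the 3-sigma
band f ± 3·sqrt(f(1−f)/N) over f ∈ {0.05, 0.3, 0.7} with 20 seeds each,
alongside the exact-match assertion against the realised events.

## Published-data operations

Three curated tables (under `rinclique/data/`) carry the published
T4 lysozyme and Eglin c double-mutant results: per-model co-membership
probabilities for 13 lysozyme site pairs, observed and
predictor-reported ΔΔΔG with Cα distances for the same 13 double
mutants (kcal/mol), and the three Eglin c pairs (kJ/mol). In the
ΔΔΔG table the first value column is the experimental observation and
the second the structure-based predictor's estimate. Correlation
between observed and predicted values uses Pearson r as the primary
statistic with Spearman ρ reported alongside.

## Degenerate inputs and edge cases

- Residues without Cα are parsed, flagged and kept (they can still form
  side-chain contacts); Cα-distance queries on them raise.
- Alternate locations resolve to the highest occupancy, ties to 'A'.
- Waters, ions and other heteroatoms are dropped by default.
- Empty snapshots, empty ensembles, inconsistent residue sets across
  models, out-of-range probabilities and zero-variance correlation
  inputs raise informative errors rather than returning defaults.
- `same_community` returns 0 for unknown nodes and for nodes outside
  every community; for a = b it is 1 exactly when the node is in some
  community.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances — random graphs of ≤ 20 nodes for oracle comparisons (201
graphs), 6-residue toy ensembles of 1000 snapshots for recovery (60
ensembles) — chosen so the full suite completes in well under a minute
while exercising every code path at sizes where brute-force oracles are
exact. The library itself has no such limits; per-snapshot cost is
dominated by the all-pairs detector scans, O(n² · atoms²) per snapshot.

## Known limitations

- The predictor is topological only; it cannot separate pairs whose
  coupling is energetic rather than structural, and sparse networks
  yield few 3-cliques (false negatives by construction).
- Hydrogen bonds without an angle criterion over-count contacts
  relative to geometry-aware detectors.
- P_ab estimates from molecular-dynamics frames inherit frame
  autocorrelation; the binomial standard error reported alongside
  assumes independent snapshots and is therefore optimistic for dense
  trajectory sampling (no block-bootstrap correction is implemented).
- Exact reproduction of published per-protein P_ab tables requires the
  original 100 ns trajectories (10⁴ frames per system), which are not
  part of this package.
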