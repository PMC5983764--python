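# rinclique

Topology-based prediction of **double-mutant non-additivity** in proteins
from residue interaction networks and clique percolation.

When two sites of a protein are mutated simultaneously, the change in
unfolding free energy is often just the sum of the two single-mutant
effects (ΔΔG_ij ≈ ΔΔG_i + ΔΔG_j, an *additive* pair). Some pairs,
however, are thermodynamically coupled: the deviation

ΔΔΔG_ij = ΔΔG_ij − (ΔΔG_i + ΔΔG_j)

is far from zero (*non-additive*). Knowing in advance which site pairs
couple matters for enzyme design, where stabilising mutations are
combined under the assumption that their effects add.

`rinclique` implements a purely topological predictor of this coupling:

1. **Residue interaction network (RIN).** For each conformer of an
   ensemble (e.g. frames of an equilibrium molecular-dynamics
   trajectory, supplied as a multi-model PDB file), residues become
   nodes (placed at Cα) and edges connect residues with a detected
   non-covalent interaction — hydrogen bond (donor–acceptor ≤ 3.5 Å),
   van der Waals contact (surface gap ≤ 0.5 Å), disulfide bond
   (S–S ≤ 2.5 Å), ionic interaction (charged-group centers ≤ 4.0 Å),
   π-π stacking (ring centers ≤ 6.5 Å) and π-cation (≤ 5.0 Å).
2. **3-clique communities.** The k-clique (percolation) communities of
   each network are computed for k = 3: maximal unions of triangles
   chained through shared edges. A triangle of mutually interacting
   residues is the signature of a tight local interaction cluster.
3. **Co-membership probability.** For a site pair (a, b) over an
   ensemble of N snapshots,

   P_ab = (1/N) · Σᵢ C_ab(i),  C_ab(i) = 1 iff a and b share a
   3-clique community in snapshot i.

   Pairs with **P_ab ≥ 0.1** are predicted non-additive; pairs below the
   threshold additive. On the 13 published T4 phage lysozyme double
   mutants this rule isolates exactly the two experimentally coupled
   pairs, (117, 132) and (98, 152).

The package also ships the thermodynamic side (ΔΔG_sum/ΔΔΔG arithmetic,
Cα distances, observed-vs-predicted correlation), a synthetic-structure
generator with construction-time ground truth, and curated published
tables for T4 lysozyme and Eglin c.

Running molecular dynamics itself is out of scope: any conformer
ensemble readable as a multi-model PDB (or any iterable of `Snapshot`
objects) is accepted.

## Worked example

Generate a synthetic 200-frame ensemble in which residues 1, 3 and 5
close into a contact triangle in a random 40% of snapshots, then ask
whether sites (1,3) and (2,6) are predicted to couple:

```sh
$ rinclique synth --n-residues 6 --event 1:3:5:0.4 --n-snapshots 200 \
      --seed 11 --out demo.pdb
wrote 200 snapshots (89 events) -> demo.pdb

$ rinclique pab demo.pdb --pair A:1 A:3 --pair A:2 A:6
{
 "n_snapshots": 200,
 "results": [
  {"pair": ["A:1", "A:3"], "p_ab": 0.445, "n_events": 89, "N": 200,
   "se": 0.0351, "classification": "non_additive", ...},
  {"pair": ["A:2", "A:6"], "p_ab": 0.0, "n_events": 0, "N": 200,
   "se": 0.0, "classification": "additive", ...}
 ]
}
```

The pair (1,3) sat inside a 3-clique community in 89 of 200 snapshots
(P_ab = 0.445, matching the 89 generated events exactly), well above the
0.1 threshold — non-additive. The pair (2,6) never co-occurred in a
community — additive. The same is available from Python:

```python
from rinclique import read_structure, compute_pab, residue_key

ens = read_structure("demo.pdb", model="all")
r = compute_pab(ens, (residue_key("A", 1), residue_key("A", 3)))
print(r.p_ab, r.classification)   # 0.445 non_additive
```

Other subcommands: `build-network` (structure → edge-list TSV),
`cliques` (edge list → communities), `dddg` (mutation table → ΔΔΔG),
`distance`, `compare`, all documented via `rinclique COMMAND --help`.

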