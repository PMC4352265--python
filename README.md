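# rnaiface

Organism-comparative analysis of protein–RNA interfaces.

Protein–RNA complexes solved for the same protein in different organisms
(aminoacyl-tRNA synthetases, ribosomal proteins, signal-recognition
particles, …) do not use the same residues to grip their RNA. `rnaiface`
quantifies those differences from structure alone: it identifies binding-site
residues and nucleotides by a heavy-atom distance criterion, and compares
organism groups through normalized binding propensities, conservation-
restricted propensities, binding-segment length distributions, sequence-motif
statistics and residue–nucleotide pair potentials. It is aimed at structural
bioinformaticians studying protein–RNA recognition and at anyone who needs
interpretable, reproducible interface statistics over a curated set of
complexes.

## The statistics at the core

**Binding sites.** A residue and a nucleotide are in contact when any pair of
their heavy atoms is strictly closer than 3.5 Å; a residue (nucleotide) with
at least one contact is a binding site.

**Normalized binding propensity.** For each amino acid or nucleotide type i,
with f_b(i) occurrences at binding sites and f_t(i) overall,

```
P_bind(i) = 100 · f_b(i) / f_t(i)
Norm      = 100 · Σf_b / Σf_t
Pnorm(i)  = P_bind(i) / Norm
```

Pnorm is a dimensionless enrichment with neutral value 1 (its
composition-weighted mean is exactly 1); values above 2 indicate a strong
interface preference. Propensities can be pooled over a group or averaged
per complex (mean ± sample SD, skipping complexes where a type never binds),
and restricted to conserved positions (ConSurf-style grades 1–9, default
grade ≥ 8).

**Segments and motifs.** Binding segments are maximal runs of consecutive
binding residues along the observed sequence (runs break at chain boundaries
and at unresolved-residue gaps), binned 1–6 and >6. Motif statistics cover
tripeptides/trinucleotides under the \*B\* pattern (centre residue binding)
and ordered neighbour dipeptides under \*B and B\* (second or first residue
binding), with preferred pairs reported above a strict 75 % probability.

**Pair potentials.** For residue type i and nucleotide type j, with N_ij
contacting pairs at a group's interfaces and ΣN_i, ΣN_j total compositions,

```
Pair_org(i,j)  = N_ij / (ΣN_i + ΣN_j)
Propen(i,j)    = Pair_org(i,j) / Pair_all(i,j)
Potential(i,j) = −RT ln Propen(i,j)        [kcal/mol, T = 300 K]
```

Potentials below −0.5 kcal/mol mark preferred pairs, above +0.5 avoided
(strict inequalities).

A synthetic-complex generator with schematic geometry provides exact ground
truth (masks, segments, typed contacts) for every stage, so the entire
pipeline is testable without downloading structures.

## Worked example

Generate a two-group synthetic dataset — group `ecoli` carries a planted 3×
arginine interface enrichment, group `human` none — and run the full
comparative pipeline:

```python
import numpy as np
from rnaiface import SyntheticSpec, generate_group_dataset, run_pipeline, RunConfig
from rnaiface.alphabets import AMINO_ACIDS

e = np.ones(20)
e[AMINO_ACIDS.index("R")] = 3.0
specs = {
    "ecoli": SyntheticSpec(n_residues=150, n_nucleotides=40, seed=11, enrichment=e),
    "human": SyntheticSpec(n_residues=150, n_nucleotides=40, seed=22),
}
manifest = generate_group_dataset(specs, 10, "demo/structures")
report = run_pipeline(manifest, config=RunConfig(output_dir="demo/out"))
print(report.group_propensity["ecoli"].loc[["R", "K", "G"]].round(2))
```

```
   P_bind  Pnorm  Pnorm_mean  Pnorm_sd  n_complexes
R   60.26   3.01        3.06      0.98           10
K   12.68   0.63        1.37      0.40            4
G   15.38   0.77        1.21      0.63            7
```

Arginine's pooled Pnorm of 3.01 recovers the planted enrichment; lysine and
glycine sit near the neutral value. The bundle's ANOVA table confirms the
group difference is specific to arginine:

```
               F       p  n_groups
R        11.7403  0.0037         2
K         0.0126  0.9127         2
```

The output directory contains per-complex binding percentages and contact
lists, per-group propensity/segment/motif/dipeptide tables, 80-row pair
potential tables with preferred/avoided classes, and a machine-readable run
manifest. The same pipeline runs on real structures: point the manifest's
`pdb_id` rows at local PDB/mmCIF files with the protein and RNA chains to
analyse.

The `rnaiface` console script exposes the stages individually
(`contacts`, `propensity`, `segments`, `motifs`, `potentials`, `simulate`,
`report`); see `rnaiface --help`.

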