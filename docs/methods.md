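# Methods

## Structure model

Structures are read with gemmi from PDB or mmCIF and reduced to per-chain
ordered lists of observed residues with heavy atoms only. Three
normalisations are applied on load:

- **Models.** Only the first model is used. The intended inputs are
  crystallographic complexes; for NMR ensembles this means model 1.
- **Alternate locations.** For each residue the conformer with the highest
  mean occupancy is kept (first in file order on ties); unlabeled atoms are
  always kept.
- **Components.** Hydrogens/deuteriums, waters and non-polymer ligands are
  discarded. Modified polymer components are mapped to their standard parent
  through a small bundled table (common tRNA modifications such as PSU→U,
  1MA→A, 7MG→G, plus MSE→M and a few protein PTMs). Components without a
  bundled parent that gemmi tabulates as amino acids or nucleotides are kept
  as UNKNOWN: they participate in contact geometry but are excluded from
  every alphabet-indexed count, including percentage denominators.

Sequence positions are 0-based ordinals over the *observed* residues;
unresolved residues are simply absent. This choice makes coordinates the
single evidence base: a residue with no resolved heavy atoms has no known
binding status and cannot anchor a segment or motif window. The manifest
(TSV or JSON) names the chains to analyse; no automatic chain inference is
attempted, and organism grouping is entirely manifest-driven (the
conventional labels being ecoli, human, yeast, thermophile, archaea, other).

## Contact detection

Two heavy atoms interact when their Euclidean distance is strictly less than
the cutoff (default 3.5 Å); a residue–nucleotide pair with at least one
interacting atom pair is a contact. All heavy atoms participate — backbone,
side chain, sugar, phosphate and base — and only protein↔RNA pairs are
examined. The implementation queries a k-d tree (scipy cKDTree) and then
enforces the strict inequality explicitly, so atoms at exactly the cutoff
never count. An all-pairs brute-force oracle lives in the test suite and is
checked for exact set equality on hundreds of randomized complexes.

## Propensities

Counts f_b and f_t are tallied per standard symbol. The normalization
constant is written as `Norm = 100·Σf_b/Σf_t` so that Pnorm is a
dimensionless enrichment with neutral value 1 and an exact algebraic
identity: the f_t-weighted mean of Pnorm equals 1 (tested to 1e-12). Keeping
P_bind on the percentage scale and Norm as a percentage makes both readable
on their own while their ratio stays scale-free.

Per-complex averaging excludes, for each symbol, complexes where the symbol
does not occur; by default it also excludes complexes where it occurs but
never binds, so the mean describes complexes in which the residue
participates in the interface at all. The alternative (keeping
zero-propensity complexes) is available via `exclude="ft_zero"`. The spread
is the sample standard deviation (n−1); a symbol observed in one complex
gets SD 0 and its n is reported alongside.

Conservation-restricted propensities consume per-residue grades 1 (highly
variable) to 9 (highly conserved), supplied externally in a ConSurf-style
TSV; computing grades is out of scope. The default threshold for
"conserved" is grade ≥ 8 — the top two categories — and is configurable,
since no canonical cutoff exists; reports carry the threshold used.
Conservation applies to the protein side only.

## Segments

A binding segment is a maximal run of consecutive binding residues.
Consecutive means adjacent in the observed sequence *and* contiguous in
author numbering: a numbering jump greater than one indicates unresolved
residues, whose binding status is unknown, so runs are never merged across
such gaps. Lengths are binned 1–6 and >6 with two normalisations: the
fraction of segments per bin, and the fraction of all binding residues
accommodated per bin (using summed lengths for the >6 bin). The second
metric is the one used when quoting statements like "single-nucleotide
segments accommodate X % of the binding sites". Both vectors sum to 100 %
and the summed run lengths always equal the number of flagged residues.

## Motifs

Tripeptide/trinucleotide probabilities use the \*B\* pattern: a length-3
window counts as binding when its centre residue is flagged. The stricter
all-binding reading is available behind the `pattern="all_binding"` flag.
Neighbour dipeptides use \*B (second residue binding) and B\* (first residue
binding) over all 400 ordered pairs, pooled per group. Windows are taken
over contiguous observed stretches only — never across chain boundaries or
numbering gaps — and windows containing UNKNOWN residues are skipped.
Probabilities are computed whenever a k-mer occurs, but the preferred-pair
report requires at least 3 occurrences and a probability strictly above
75 %, so sparse groups cannot qualify on a single hit.

## Pair potentials

N_ij counts contacting residue–nucleotide *pairs* once, regardless of how
many atom pairs lie below the cutoff; an alternative residue-occurrence
counting would double-count promiscuous residues. ΣN_i and ΣN_j are full
compositions of the group's proteins and RNAs, binding or not. The global
reference Pair_all is the same quantity over every group pooled, which makes
self-normalization exact: when a group *is* the whole dataset, every defined
potential is identically 0. Cells unobserved in a group (N_ij = 0) are
labelled `unobserved` with NaN potential instead of +∞.

The temperature defaults to 300 K, giving RT ≈ 0.596 kcal/mol, with
R = 1.987×10⁻³ kcal/(mol·K); the ±0.5 kcal/mol classification thresholds
are strict inequalities on that scale. No pseudocounts are added — absent
pairs stay absent rather than acquiring an artificial potential.

## One-way ANOVA

Group differences in per-complex propensities are tested with a one-way
fixed-effects ANOVA computed from first principles (between/within sums of
squares); only the F tail probability comes from scipy's F distribution. The
implementation is cross-checked against `scipy.stats.f_oneway` to 1e-10 and
against a closed-form textbook example. When all values are identical the
test is degenerate and (F, p) = (0, 1) by convention.

Calibration note: with groups drawn from one common continuous distribution
the empirical type-I error sits at the nominal 0.05 (±0.01 over 2000
replicates). When the tested statistic is the per-complex Pnorm of a single
residue type from small complexes, the values are discrete ratios of small
counts (a 120-residue chain holds ~6 residues of a given type) and the
F-test runs mildly conservative (~0.04 observed). This is a property of the
statistic at that problem size, not of the implementation, and disappears as
complex size grows.

## Synthetic generator

The generator emulates exactly the features the statistics measure and
nothing else:

- **Sequences** are i.i.d. draws from the spec's composition vectors.
- **Interface structure.** The target number of interface residues is
  arranged into runs drawn from the segment-length bin distribution (>6 maps
  to lengths 7–9), placed with at least one non-binding residue between runs
  so extracted segments equal planted segments exactly. The same run logic
  shapes the RNA mask.
- **Enrichment.** Interface positions draw their residue type from
  p·e/Σ(p·e) and background positions from the complementary distribution,
  so the marginal composition stays p and P(binding | type i) = f·e_i/ē with
  ē = Σ_k p_k e_k. Because Pnorm has weighted mean 1 by construction, the
  expected recovered Pnorm of an enriched type is e_i/ē, not e_i — e.g. a
  planted 3× enrichment of one type on a uniform composition recovers as
  3/1.1 ≈ 2.73. Enrichment is therefore "relative to an unenriched
  background", and recovery tests use bands around the planted value wide
  enough to contain e_i/ē.
- **Geometry** is schematic: residues are 4–5-atom rigid clusters on a line,
  nucleotides 3-atom clusters on a parallel line. Each interface residue
  gets one designated atom placed exactly `contact_distance` (default
  3.2 Å) from its partner nucleotide's anchor atom, on a per-nucleotide
  spiral so that multiple residues can share a partner while staying > 3.5 Å
  from every other nucleotide; all other protein atoms stay ≥ `clearance`
  (default 5.0 Å) from all RNA atoms. Because 3.2 and 5.0 bracket the 3.5 Å
  cutoff with margin, detected masks and typed contacts equal the truth
  ledger *exactly*, not just statistically. Every flagged nucleotide is
  assigned at least one residue (their count is capped by the interface
  residue count), and extra residues choose partners by the optional 20×4
  pair-bias matrix.
- **Determinism.** All randomness flows from one seeded generator;
  identical (spec, seed) give byte-identical PDB output. Group datasets
  derive per-complex seeds from the group seed via SeedSequence.

What the generator does **not** emulate: real protein/RNA folds, secondary
structure, physically plausible packing, atom-level chemistry,
solvent, correlated composition along the chain, or unresolved-residue gaps.
Tests passing on synthetic data therefore validate the counting,
normalisation and statistical machinery — and exact geometric detection
around the cutoff — but say nothing about biological conclusions drawn from
real complexes.

## Problem sizes and numerical choices

Default analysis sizes used by the test suite and acceptance script:
oracle-equivalence over 200 complexes of 50–300 residues; identity checks
over 1000 random count tables; parameter recovery over 30 complexes of 200
residues; ANOVA calibration over 1000–2000 replicates of 2×20 values; power
over 100 replicate two-group datasets. These sizes give standard errors
comfortably inside the asserted bands while keeping a full run to seconds.

Ties and degenerate inputs: altloc ties resolve to file order; an all-zero
binding pool is an error for propensities (undefined), while an empty run
list yields an all-zero segment distribution with NaN fractions; ANOVA on
identical values returns (0, 1); unobserved potential cells are NaN-labelled
rather than infinite. Distances are compared with strict `<` everywhere the
3.5 Å and ±0.5 kcal/mol thresholds appear.
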