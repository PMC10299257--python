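# Methods

## Variant curation

Variants are identified by the key `(gene, protein_position, wt_aa,
mut_aa)` with 1-based positions and one-letter residue codes, parsed
from `R395H` / `p.R395H`-style notation. Transcript and isoform
identifiers are out of scope: every variant must map onto the gene's
canonical sequence (position in range and WT residue matching), and
unmapped records are discarded.

Labelling rules:

* `cancer_risk` — the key survives the COSMIC-like quality filter
  (confirmed somatic status, clear sample type, literature support)
  and the cBioPortal-like curated-set filter, and appears in **all
  three** cancer catalogues. Per-source filters are applied *before*
  the intersection; the alternative order is not distinguishable from
  the available description, and filters-then-intersection is the
  stricter reading.
* `benign` — gnomAD-like allele frequency **strictly greater** than
  the threshold (default 0.01). "Over 1%" is read as a strict
  inequality, so AF = 0.01 exactly is not benign. ClinVar-like records
  flagged benign with literature validation corroborate an existing
  population-benign key (sources merged, not double counted).
* `non_cancer_disease` — ClinVar-like records with pathogenic clinical
  significance and `literature_validated = true`. Literature
  validation is represented as a boolean input column; the package
  does no literature mining.

Keys carrying two or more distinct labels are removed entirely;
duplicates under one label collapse to a single record with merged
source sets. After curation each key is unique and single-labelled.

## Structure features

Structures are parsed from PDB files (via gemmi) into a flat atom
array with element-based van der Waals radii (C 1.7, N 1.55, O 1.52,
S 1.8, P 1.8, H 1.2 Å; unknown elements fall back to 1.7 Å with a
warning). HETATM residues named NAD/NAI and a configurable aldehyde
code (default `ALD`) populate ligand atom sets.

* **SASA** — Shrake–Rupley sampling with a deterministic golden-spiral
  point set, probe 1.4 Å, 960 points per atom by default. A single
  carbon atom reproduces the analytic sphere area 4π(1.7+1.4)² ≈
  120.76 Å² to better than 1%, and doubling the sampling changes it by
  < 0.5%.
* **RSA** — residue SASA divided by the theoretical maximum ASA per
  residue type (Tien et al. 2013 values), clipped to [0, 1].
* **Residue depth** — mean over the residue's atoms of the distance to
  the nearest *exposed* Shrake–Rupley sample point, minus the
  expanded-sphere offset (r_vdW + probe) and floored at zero, so
  solvent-exposed residues sit at depth ≈ 0. This is a deliberate
  stand-in for a molecular-surface (MSMS-style) depth; it preserves
  the buried-vs-exposed ordering on which the analysis relies but is
  not numerically identical to MSMS depth.
* **Dihedrals** — signed torsions by the atan2 convention, in
  (−180°, 180°]; φ from (C_prev, N, CA, C), ψ from (N, CA, C, N_next),
  with an undefined (NaN) sentinel at chain termini.
* **Secondary structure** — a Ramachandran-region heuristic: helix for
  φ ∈ [−100, −30] and ψ ∈ [−80, −5]; strand for φ ∈ [−180, −90] and
  ψ ∈ [90, 180]; otherwise coil. This replaces a hydrogen-bond-based
  (DSSP) assignment; externally computed codes can be supplied through
  the feature-assembly path and take precedence.
* **Graph signatures** — heavy atoms within a sphere (default 10 Å)
  of the site Cα are labelled with one of eight pharmacophore classes
  (hydrophobic, aromatic, positive, negative, acceptor, donor, sulfur,
  neutral) from a bundled residue/atom table with element fallbacks.
  For each distance cutoff in the ladder (default 4, 6, 8, 10 Å) and
  each unordered class pair, the number of atom pairs within that
  distance is counted; counts are cumulative along the ladder,
  giving 36 pairs × 4 cutoffs = 144 features named
  `sig_<c1>_<c2>_<cutoff>`. The ladder and sphere radius are
  configurable; the defaults span typical first- to fourth-shell
  contact distances.
* **Contacts** — a simplified typed contact count between the site
  residue and sequence-non-adjacent residues: hydrophobic pairs
  ≤ 4.5 Å, donor–acceptor ≤ 3.5 Å, positive–negative ≤ 4.0 Å,
  aromatic–aromatic ≤ 5.0 Å. This is a stand-in for a full
  interaction-type assignment (Arpeggio-style); externally computed
  contact tables can be ingested instead.
* **Distance gating** — binding-affinity change columns (dimer
  interface, NAD⁺, aldehyde) are zeroed for sites farther than the
  gate cutoff (default 10 Å, boundary inclusive: exactly 10 Å keeps
  the value) from the corresponding atom set. Interface distance is
  measured from the monomer-A site to all partner-chain heavy atoms.

## Sequence features

* Five-group side-chain classes (hydrophobic AFILMVWY, polar NQST,
  negative DE, positive HKR, special CGP) one-hot encoded for WT and
  mutant; substitution deltas (mutant − WT) of isoelectric point,
  molecular weight, and molecular volume from a bundled standard
  table.
* Neighbour-window frequencies over seven composition groups
  (hydrophobic ALM, aliphatic IV, aromatic FYW, long-polar EQKR,
  short-polar HSTC, short-charged/polar DN, structure-breaking GP):
  counts among up to seven residues either side of the site (site
  excluded, window truncated at termini) divided by the **full
  sequence length**. Normalising by protein length rather than window
  size is intentional — it matches the stated convention even though
  it is not scale-free across proteins of different length.
* PSSM: built from a user-supplied alignment whose first row is the
  query (query-gap columns dropped). Column frequencies use a Laplace
  pseudocount α = 1, f_a = (n_a + α)/(N + 20α), and scores are
  log₂(f_a / b_a) bits against a uniform background by default.
  PSI-BLAST-style sequence weighting and iteration are out of scope;
  externally produced profiles can be ingested. Per variant the WT
  score, mutant score, and their difference are all emitted, since the
  informative subset is not determinable a priori.
* AAindex flat-format records are parsed for both 20-vector indices
  (feature = value(mut) − value(wt), antisymmetric) and 20×20
  matrices (symmetric lookup with lower-triangle mirroring). The two
  specific accessions highlighted by the upstream analysis are not
  redistributed here for licensing reasons; tests use synthetic
  records in the same format.

## Driver screen

Two-group comparisons (cancer-risk vs benign, non-cancer vs benign)
use the **unpaired** two-sided Wilcoxon rank-sum (Mann–Whitney) test.
The source description names the signed-rank test but compares two
independent groups, which is internally inconsistent; the rank-sum
form is the coherent reading for unpaired groups and is what is
implemented. The exact method enumerates all C(n1+n2, n1) group
assignments and reports the fraction with |U − n1n2/2| at least the
observed deviation (used automatically for n1+n2 ≤ 12); otherwise a
tie-corrected normal approximation with continuity correction is used.
Constant features are skipped with a note. No multiplicity correction
is applied by default, mirroring the per-feature α = 0.05 convention;
a Benjamini–Hochberg mode is available.

## Classification

Task definitions: the cancer model classifies cancer_risk against
benign ∪ non_cancer_disease (gradient boosting); the non-cancer model
classifies non_cancer_disease against benign ∪ cancer_risk (adaptive
boosting). Ensembles are scikit-learn's; the package's own computation
is the splitting, pooling, metric formulas, selection, and
importances.

"Bootstrapped 10-CV" is implemented as repeated, reshuffled stratified
10-fold cross-validation (default 10 repetitions in the library API;
the pipeline default uses 5) with out-of-fold predictions pooled
within each repetition, metrics computed per repetition, and the mean
(± sd) reported. Jack-knife (leave-one-out) and LOPO (one fold per
gene, holding out every variant of that protein) pool across all
folds. AUROC uses the rank formula with midranks on pooled out-of-fold
scores; MCC is 0 when any confusion marginal is empty; undefined
precision/recall are reported as 0 with a flag.

Greedy forward selection adds, each round, the feature maximising the
cross-validated objective (default MCC), stopping when the improvement
is ≤ ε (default 0) or at `max_features` (default 10); ties break by
column order so the trace is deterministic per seed. PCA is an
eigendecomposition of the covariance with components ordered by
variance and a deterministic sign convention (largest-magnitude
loading positive); t-SNE and UMAP are delegated to scikit-learn and
umap-learn behind a seeded contract.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: per-gene label
counts reproducing the curated distribution (30/40/38 over 19 genes,
cancer-risk across 13 genes), a 35/35/30 adenocarcinoma / cutaneous
melanoma / other tumour-type mix, three ClinVar-benign overlap
records, planted effects (stability ΔΔG means −0.2/−0.7/−1.5 kcal/mol
with sd 0.6/0.8/0.8 for benign/cancer/non-cancer; MTR 0.95 ± 0.05
benign vs 0.70 ± 0.10 pathogenic, clipped to [0, 1]; RSA 0.45 ± 0.15
benign vs 0.25 ± 0.12 pathogenic, an invented quantification of
"pathogenic variants are more buried"), ligand-binding ΔΔG clipped to
|ΔΔG| < 1 kcal/mol, and ~80% of sites beyond the 10 Å ligand gate.
Sequences are random 120-mers; structures are ideal α-helices (φ =
−57°, ψ = −47°) built by internal-coordinate chaining, with a
translated copy as the dimer partner and small atom clusters as NAD⁺
and aldehyde ligands.

Passing tests on this material demonstrate that the *machinery* is
correct — curation rules, feature formulas, test statistics, and
validation schemes — not that the effect sizes, feature correlations,
or structures resemble real ALDH data. Real allele-frequency spectra,
predictor-score correlations, and protein folds are explicitly not
mimicked.

One consequence worth stating: at these default effect sizes the two
one-vs-rest classification tasks are **not** separable (cancer-risk
and non-cancer variants share the same MTR and RSA distributions and
their stability means differ by only one standard deviation), and
LOPO MCC on the default table is ≈ 0.3–0.4. The classifier sanity
test therefore uses an explicitly separable configuration (well-spaced
stability means per label), under which LOPO MCC reaches 1.0; the
default table remains the study condition for the screening and
bound-checking tests.

## Numerical choices and degenerate inputs

* Golden-spiral sphere sampling makes SASA deterministic (no RNG).
* Rank-sum exact p-values are computed by full enumeration, not
  network algorithms; identical pooled samples return p = 1 with a
  degenerate flag.
* Dihedral computation raises on coincident or collinear points;
  termini produce NaN sentinels that map to coil.
* PCA truncates with a warning when more components than rank are
  requested; all-constant candidate sets yield an empty selection
  trace with a flag.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); reruns with one seed are bit-identical
  apart from file timestamps.

## Problem sizes

The shipped tests and the acceptance script run at the study's own
scale (108 curated variants over 19 genes, 120-residue toy
structures), with 200-replicate screening simulations, a
1000-instance exact-test comparison, and two full pipeline runs for
the determinism check — the full suite completes in well under five
minutes on one CPU.

## Known limitations

* Secondary structure, contacts, and residue depth are simplified
  stand-ins (region heuristic, distance+class rules, sampled-surface
  depth) rather than DSSP/Arpeggio/MSMS re-implementations.
* PSSMs lack PSI-BLAST sequence weighting; conservation scores on
  shallow or biased alignments will differ from search-derived
  profiles.
* ΔΔG, MTR, and pLDDT are consumed as supplied columns, never
  predicted; absolute classifier performance on real data depends on
  those upstream predictors and cannot be reproduced from this
  repository alone.
* Mutant-structure contact features require a user-supplied mutant
  model; no side-chain rebuilding is performed.
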