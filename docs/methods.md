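# Methods

## Problem setting

COQ2 is an integral inner-mitochondrial-membrane prenyltransferase of the
UbiA family, predicted (with high per-residue confidence) to form a
channel-like bundle of nine transmembrane helices around a central cavity.
Its substrates — para-hydroxybenzoate and the decaprenyl diphosphate tail
precursor — have never been observed bound to it. The package operationalises
a homology strategy: solved UbiA-family structures that *do* carry chemically
similar ligands are superposed onto the predicted model and their ligands
carried into its frame, turning "which residues could bind the substrate"
into a geometric query.

## Hit filtering

A profile-HMM hit is retained when its probability is **strictly greater
than 50%** and the deposited entry has at least one hetero component bound
to the hit's own chain. "Bound to chain X" is made reproducible as: any
hetero heavy atom within **4.0 Å** of any polymer heavy atom of chain X
(curation of this point is otherwise manual and irreproducible). Waters
(HOH/DOD; deny list configurable) are never ligands; metal ions are, since
Mg²⁺ is a genuine UbiA cofactor. Multiple hits to one PDB entry collapse to
the best-probability one. Apo→holo substitutions are an explicit,
user-supplied alias map (`4OD4_A → 4OD5_A`) rather than any automated
same-protein search: the ambiguity in which entries were "disregarded"
versus "selected" in the source material is resolved by the user, not
guessed by the code.

## Fingerprints and similarity

Components are screened with the public 166-key MACCS structural-key set
(evaluated by RDKit on the SMILES graph, hydrogens implicit) and the
Tanimoto coefficient on key sets, defined as 0 when both sets are empty.
The pass threshold is **strict** (*T* > 0.3) by default; an inclusive
boundary is one flag away (`strict=False`), because prose descriptions of
the cutoff are ambiguous between "above" and "at least" — on the packaged
COQ2 catalog both conventions admit the same nine ligands (the lowest
passer scores 0.32). Ranking ties break lexicographically by component id.

The packaged catalog (`data/coq2_ligands.tsv`) carries SMILES
*reconstructed from each component's chemical identity*, not copied from
the dictionary; stereochemistry and acyl-chain details may differ, which
the 166 keys do not resolve. The reconstruction reproduces the reference
coefficients exactly (GPP 0.92, GST 0.81 vs 5TR, nine ligands ≥ 0.3), and
the digitonin reconstruction matches the exact molecular formula
C₅₆H₉₂O₂₉.

## Confidence trimming

Predicted models carry pLDDT (0–100) in the B-factor column; the Cα value
is taken as the residue's score. Trimming removes only the maximal
*terminal* runs below the threshold (default 90): deleting every
sub-threshold residue globally would fragment the chain, whereas the
disorder that motivates trimming is terminal. Interior dips are retained
and logged. The operation is idempotent and its output is always one
contiguous segment; an all-low-confidence model is a fatal error.

## Superposition

Correspondence comes from a global affine-gap alignment (Gotoh dynamic
programming, written in-package; gap of length *L* costs
`open + (L−1)·ext`). Defaults: BLOSUM62, −11/−1. When the sequence identity
(identities over aligned columns) is ≤ 0.30, the correspondence is
recomputed with each pair score augmented by a three-state
secondary-structure term (+2 match / −1 mismatch; states H/E/C assigned
from the Cα i→i+3 distance: < 6 Å helix, > 9.5 Å strand) and relaxed gaps
(−5/−0.5). This structure-aware alignment is a deliberate simplification of
fragment-assembly superposition — adequate for within-family comparisons at
these identity levels, and honest about not being a general fold aligner.
The in-package aligner is cross-checked against Biopython's
`PairwiseAligner` in the test suite.

The paired Cα sets are fitted by the Kabsch algorithm (centroid
subtraction, covariance SVD, determinant sign correction); near-collinear
point sets (second singular value ≈ 0) are rejected rather than silently
fitted. Outlier rejection drops pairs with residual > **2.0 Å** and refits,
up to **5 cycles** or until stable — mirroring common superposition-tool
defaults; both knobs are config keys. The headline RMSD is over retained
pairs, with the all-pair RMSD reported alongside, since published RMSDs
rarely state which convention they use. Optimality is tested against a
brute-force Euler-angle grid oracle at 10° resolution: a 1° SO(3) grid
(~2×10⁷ rotations) buys no additional discrimination for an inequality
check (`kabsch ≤ grid minimum` holds at any grid resolution) and would
dominate the suite's runtime.

## Ligand transfer, contacts, clashes

Transferred ligands are the homolog's heavy atoms moved by the fitted
transform; the homolog itself is never modified. Contacts use a **5.0 Å**
heavy-atom cutoff — a standard contact definition chosen because the source
material says only "close to"; it is configurable and validated on
synthetic pockets, not asserted as anyone's original value. Clashes use
**2.0 Å** (below van-der-Waals contact). Every clash pair is necessarily a
contact pair when the clash cutoff is below the contact cutoff; both sets
are monotone in their cutoffs, and centroid geometry is invariant under
joint rigid motion — all property-tested. Mg²⁺ and other metals are
reported in a separate *cofactor* category.

Annotation joins contacts against packaged tables for COQ2: membrane
topology, motifs, variants, the ApUbiA↔COQ2 correspondence, and the S1/S9
portal helices. The topology file is named `*_synthetic.tsv` because the
published helix boundaries exist only as a figure: the packaged intervals
are reconstructed to be consistent with every published variant location
label and motif/loop placement, and should be replaced wholesale when
working on another protein (all loaders take a path).

## Variant comparison

Variant structural models are consumed as files; running a structure
predictor is out of scope. The headline RMSD per variant is all-Cα after
sequence-dependent superposition **with rejection disabled** — a point
mutant aligns trivially, and rejection would discard exactly the residues
that moved. The rejection-on RMSD is computed alongside for transparency,
since either convention could be behind any published table. Local
alterations are flagged as maximal runs of ≥ 3 residues whose deviation
exceeds median + 2·MAD of the profile (robust statistics, because a point
mutant's deviation distribution is tightly concentrated with a few genuine
excursions); both the multiplier and run length are parameters. Ranking is
a stable ascending sort on RMSD. The pathogenicity/RMSD association is
tested with Spearman rank correlation on a binary label (pathogenic = 1);
on the packaged 12-variant table ρ = −0.28, far below the two-sided 5%
critical value 0.587 at n = 12 — i.e. no detectable correlation.

## Synthetic fixtures

The generator emulates the target fold class: ideal α-helices (1.5 Å rise,
100°/residue, 2.3 Å Cα radius) on a ring with 12 Å axis spacing, adjacent
helices antiparallel, one pseudo-Cβ per residue at 1.53 Å pointing away
from the helix axis. A homolog copy gets (i) sequence mutated to a target
identity, (ii) isotropic Gaussian coordinate noise, (iii) a known rigid
motion, and (iv) a linear ligand planted 3.5 Å from the inward-facing Cβ of
one mid-helix residue per pocket helix. Construction *verifies* its own
margins — every pocket residue within 4 Å of the ligand, every other
residue beyond 6 Å — and raises if they cannot be met, so recovery tests
measure the pipeline, not fixture luck. Default conditions (6 helices × 20
residues, σ = 0.3 Å, identity 0.6, 5 pocket residues) represent a clearly
solvable within-family case; σ = 0.3 Å is typical coordinate-level
disagreement between good models of the same fold. All randomness flows
from one seed; outputs are byte-reproducible.

What the fixtures do **not** emulate: real side-chain rotamers, loops and
irregular secondary structure, crystal-contact artefacts, missing residues
and altloc disorder in deposited entries, and genuinely different binding
poses between homologs. Passing the synthetic suite therefore demonstrates
correctness of the geometry/bookkeeping machinery, not biological accuracy
of any particular transferred site on real structures.

The toy ligand catalog holds eight auditable small molecules; its expected
pairwise Tanimoto matrix was computed with an independent structural-key
implementation (Open Babel) and frozen as packaged data, and a live
cross-check against `obabel` runs when the binary is available.

## Problem sizes and numerical choices

Test and acceptance runs use 120–200-residue bundles, 10–20 fixture seeds
per sweep, and a 10° rotation-grid oracle on ≤ 6-point sets — sizes chosen
so the whole suite runs in seconds while each check still has discriminating
power. Orthonormality of rotations is enforced at 1e−8; alignment traceback
resolves score ties toward the match state; equal-occupancy altlocs resolve
to the alphabetically first conformer; equal-RMSD variants keep input order
(stable sort).

## Known limitations

- The sequence-independent mode is alignment-based, not fragment-based: it
  will not rescue superpositions of genuinely different folds (a homolog
  from outside the family lands where it lands — usefully signalled by a
  very large RMSD, which the pipeline then excludes at the 10 Å default).
- Packaged SMILES are reconstructions (see above); for exact dictionary
  descriptors, point the catalog parser at a real CCD file.
- Contact/clash logic is heavy-atom distance only; no energies, no
  protonation, no docking refinement.
- The HHR parser reads the summary hit list (rank, id, probability,
  ranges), not the per-hit alignment blocks — the pipeline re-derives
  correspondences from structure, so the blocks are unnecessary.
- Variant wild-type consistency is checked against whatever wild-type
  sequence the user supplies; the package ships no reference proteome.
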