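# Methods

## Motif model

The CDGSH motif is modelled as a fixed-length 17-position pattern with
constrained positions {1, 2, 4, 7, 11, 12, 13, 14, 15, 16, 17} and free
(X) positions {3, 5, 6, 8, 9, 10}.  The hydrophobic class Φ defaults to
{A, C, F, I, L, M, P, V, W, Y}; observed occupants of Φ1/Φ12 in real
alignments include W, F, A and L, and the class is configurable because
no authoritative enumeration exists.  Ambiguity codes never satisfy a
constraint: 'X' matches nothing, and 'U' (selenocysteine) deliberately
does not satisfy a cysteine position, since selenocysteine ligation has
not been observed in these domains.

Scanning slides a 17-residue window over the de-gapped sequence and
counts mismatches at constrained positions only.  Hit status:

* `strict` — zero mismatches;
* `his_to_cys` — the single deviation is H17→C.  This substitution can
  retain cluster binding, so such hits still count as motif-bearing for
  classification;
* `disrupted` — any other constrained-position change within the
  `max_mismatch` budget (default 2 for degenerate-motif discovery).

A strict hit suppresses relaxed hits that share its C13 position, so a
degenerate window overlapping an intact motif is not double-reported.
All positions are reported 1-based in ungapped coordinates; the four
ligand positions are start + {1, 3, 12, 16}.  The P motif [GPΦXΦ] is
scanned strictly; its lid-proline sits at start + 1.

## Classification

Architecture takes precedence over taxonomy:

1. two motif-bearing windows separated by 5–40 residues (measured from
   motif end to next motif start; the biological spacing is about 20, and
   the wide default band absorbs insertion variability) → type 6, or
   type 5 when a C-terminal FMN-binding segment follows;
2. a DUF1271 segment → type 7, with subtype DC/DCC/CDC read from the
   linear order of DUF1271 and CISD segments;
3. a single motif → the taxon default (eukaryote→1, apicomplexa→2,
   archaea→3, bacteria→4), optionally overridden by homology;
4. no motif → orphan.

Annotated CISD-motif segments (user-supplied or generator truth) count as
motif evidence even when the underlying window is fully disrupted — a
tandem-motif domain that lost one motif is still a tandem-motif domain.
Domain annotations (DUF1271, FMN-binding) are inputs; the toolkit does
not bundle a domain-HMM engine.

The 2a-vs-2b split and the bacterial members of the archaeal-style type 3
have no architectural signature, so they are resolved — when the caller
supplies per-type seed sequence sets — by winner-takes-all ungapped
percent identity of a global alignment (biopython `PairwiseAligner`,
match 1 / mismatch 0 / gap −0.5 / extend −0.1, identity normalised by the
longer sequence).  Ties leave the taxonomic default standing and are
flagged in the evidence trail.  No identity threshold is imposed because
none is established; the rule is a documented stand-in and every call
carries its rule ids for audit.

## Phylogenetic profiling

Species keys are (superkingdom, phylum abbreviation, genus, species
epithet), case-insensitive.  Record names carry only the genus initial,
so initial collisions within a phylum collapse into one key; this is
accepted and inherent to the naming convention.  Multiple sequences of a
type within a species, and records from multiple strains, count once.
Type 2a/2b fold into column 2.

The distribution table counts species per taxon row and type column;
`Any` is species with ≥1 type; `CISD+` restricts to members of a
caller-supplied reference genome set when one is given (reference genome
totals are snapshot-specific constants supplied by the caller, never
recomputed); `percent` = 100·CISD+/Total, rounded to integer as
conventionally printed.

The gene-loss statistic averages, over genera with ≥5 sequenced genomes
(default) and ≥1 positive species, the percentage of positive species per
genus.  The headline SD uses the population (n) denominator; the sample
(n−1) SD is reported alongside because the convention is genuinely
ambiguous in this literature.

## Structural geometry

**Cluster detection** takes FES-type het-groups with 2 Fe + 2 S directly,
and otherwise assembles clusters from loose Fe and inorganic S atoms
within 3.5 Å.  **Ligand assignment** matches Cys Sγ and His Nδ1/Nε2
within 3.0 Å of either iron — typical Fe–Sγ is ≈2.3 Å and Fe–N ≈2.1 Å,
so 3.0 Å leaves margin for model error without reaching second-shell
atoms.  **Module extraction** anchors on the first cysteine ligand
(motif position 2) and takes Cα of residues C2−1 … C2+15, i.e. motif
positions 1–17; a chain break inside the window is an error naming the
missing residues.

**Superposition** is the closed-form Kabsch solution (SVD with a
determinant correction, so reflections are never returned); RMSD is the
residual after the optimal transform.  An independent quaternion
eigenvalue implementation serves as the test oracle.  Rotation angles are
extracted with atan2 of the skew-symmetric part against the trace, which
stays well-conditioned at 0° and 180° where arccos does not.

**Inter-module shift angle**: one module of the target structure is
superposed on one module of the reference (best of the up-to-four
pairings by 17-Cα rmsd, with a 10⁻⁹ Å tie tolerance so exactly
congruent synthetic modules pair deterministically), and the angle is
measured at the aligned cluster centroid between the vectors to the two
partner-cluster centroids.  The vertex and vector convention is a package
choice — published shift-angle figures do not state one — so literature
values are treated as approximate cross-checks, not exact targets.  The
**pseudo-dyad** superposes one module's 17 Cα + 4 cluster atoms onto the
other's and reports the residual and the rotation angle of the fitted
transform (180° for a true dyad).

**SASA** is Shrake–Rupley quadrature: 960 points per atom by default
(Fibonacci-spiral, which keeps the single-sphere quadrature error well
under 1%), probe 1.4 Å, Bondi van-der-Waals radii from the bundled
`cisd/data/vdw_radii.json` (Fe = 2.0 Å, a common metal choice absent from
Bondi's set).  Waters are excluded; het-group clusters included.  Buried
area per chain is SASA(chain alone) − SASA(chain in complex).  Because
quadrature directions are fixed in the world frame, SASA is
rigid-motion-invariant only to quadrature error (≲1–2%); published
interface areas also vary by a few percent across programs, hence the
±10% tolerance used when comparing to printed burial values.

**Hydrogen bonds** use the heavy-atom criterion: donor/acceptor N/O pairs
within 3.5 Å, excluding same-residue pairs and peptide-adjacent backbone
N/O pairs (through-bond neighbours).  Without hydrogens, donor vs
acceptor cannot be assigned chemically; pairs are reported symmetrically.
**Close contacts** are all inter-chain atom pairs within a caller-chosen
cutoff, with an optional atom filter (e.g. backbone only); a grid/k-d
tree accelerates the search and an O(n²) oracle verifies it in tests.

Crystallographic **symmetry-mate expansion** (for dimers whose asymmetric
unit holds one monomer) applies every spacegroup operator with unit-cell
translations in {−1,0,1}³ and keeps the non-clashing image with the most
polymer-atom contacts within 5 Å of the original; the operator used is
returned with the merged model.  Hydrogens are stripped on reading
everywhere; altlocs collapse to the highest-occupancy copy (first on
ties); residues keep author numbering and insertion codes, matching how
residues are cited in the structural literature.

## Synthetic data

`gen_sequences` plants motif instances drawn from the consensus
(constrained positions from their allowed sets, X positions from the
background) into i.i.d. background sequence.  Background frequencies are
uniform by default — no claim downstream depends on composition — and
configurable.  The default type mix is proportional to the observed
species counts per type (98:9:18:103:32:128:53:18 for types 1–7 and
orphan); tandem spacing is drawn uniformly from 15–25 residues (about
20); the tandem-motif degeneracy rate defaults to 0.17, the observed
fraction in the real type-5/6 families, with half the edits His→Cys and
half disrupting (Cys→Ser; His→Gly/Ser/Gln/Asn).  Type-7 architectures
place DUF1271 segments and space double CISDs 50–70 residues apart so
they never fall into the tandem band.  Record names follow the
underscore-joined convention, so the same outputs exercise name parsing
and profiling.

`gen_dimer` starts from a bundled idealized module template
(`cisd/data/module_template.csv`): a helical 17-point Cα trace at 3.77 Å
spacing around a planar 2Fe-2S rhombus (Fe–Fe 2.7 Å), **synthetic and not
derived from any deposited coordinates**.  Ligand side chains are
represented by single pseudo-atoms (Sγ/Nε2) placed 2.3 Å from the nearest
iron toward the ligand Cα.  The partner module is placed by a 180°
rotation about z through the interface midpoint (putting the cluster
centroids exactly `center_distance` apart), then rotated about z through
the first cluster centroid by `shift_angle` — exactly the angle the
shift-angle measurement recovers against the unshifted reference.
Gaussian noise is added last, independently per atom.  Everything is
deterministic for a fixed seed.

What the generator does *not* emulate: real side chains and packing,
sequence-dependent background composition, alignment errors, genuine
homology gradients (so homology-based 2a/2b calls are exercised only
structurally, not statistically), and crystallographic artefacts.
Passing tests therefore demonstrate correctness of the measurements and
decision rules under known truth, not robustness to every property of
real data — the deposited-structure and supplementary-collection checks
in `tests/test_acceptance.py` cover that end, given the external files.

## Problem sizes and numerical choices

Test and acceptance runs use 400–500 generated sequences, 1000 random
point sets for the superposition oracle, and 240–960 quadrature points
for SASA — sizes chosen so the full suite completes in seconds while
keeping binomial checks (e.g. the degeneracy-rate interval) adequately
powered.  Degenerate inputs are defined rather than crashed on: an empty
sequence scans to an empty hit list, a no-motif record classifies as
orphan with evidence `no_motif`, an empty genus set yields an empty
(NaN) loss statistic, and a cluster with no protein ligand within the
cutoff returns an empty ligand list with a warning.

## Known limitations

* The shift-angle and pseudo-dyad conventions are package definitions;
  published angle figures are approximate cross-checks.
* Percent-identity homology calls are a stand-in where the literature
  gives no quantitative criterion; calls made this way are labelled
  `homology` confidence with the identity in the evidence trail.
* SASA values are method-dependent at the few-percent level; comparisons
  to printed burial values use ±10%.
* Genus identity from record names collapses genera sharing an initial
  within a phylum.
* Symmetry expansion generates one mate (the largest-interface image),
  not the full crystal environment.
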