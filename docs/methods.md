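# Methods

This note documents the models, conventions and numerical choices behind
`protfeat`, in the spirit of a package's methods appendix: what each
calculator assumes, which constants it uses and why, what the synthetic
fixtures emulate (and do not), and where the design was genuinely open.

## Structure sanitization

A raw PDB file may contain several models (NMR ensembles), several chains,
alternate side-chain conformers and solvent. Sanitization keeps the first
model, the requested chain and the *first-listed* alternate location per
(residue, atom-name) slot, clears the altloc field, and drops waters
(HOH/WAT/DOD) and all other HETATM records unless asked to keep them. The
first-listed conformer is used rather than the highest-occupancy one: by
PDB convention the first altloc is the most populated conformer, and a
file-order rule is deterministic even when occupancies tie. Sanitization is
idempotent and never adds atoms.

Element symbols come from PDB columns 77–78 when present. For legacy files
they are inferred from the atom name: standard amino-acid atoms use the
first alphabetic character (so ` CA ` is a Cα carbon), while hetero records
whose name starts in the first column of the name field are checked against
a two-letter element table (so `CA` in a calcium ion is calcium). This
matches the behavior of mainstream PDB parsers on the fixtures we test.

Missing-residue modeling, rotamer repair, protonation and energy
minimization are exposed only as a no-op preparer hook: they require
third-party modeling engines and are outside this package's scope.

## Feature calculators

The feature set, levels and aggregation rules live in one machine-readable
table shipped with the package (`data/feature_schema.csv`, ~100 rows): for
each feature, its level (atom/residue), its voxel aggregation rule
(max/mean/sum/min), its residue rule (numeric roll-up, or map-down of a
residue-level value onto child atoms), its storage dtype and its source
calculator. The schema is the single source of truth and can be overridden
by path.

**Atom typing.** Atoms map deterministically onto a 23-name AutoDock-style
vocabulary (H, HD, HS, C, A, N, NA, NS, OA, OS, F, MG, P, SA, S, CL, CA,
MN, FE, ZN, BR, I, Unk_atom) from (residue, atom-name, element): ring
carbons of Phe/Tyr/Trp/His are aromatic `A`; all protein oxygens are
acceptors `OA`; His ND1 is an acceptor nitrogen `NA` (the NE2-protonated
tautomer convention); Met SD and Cys SG are weak acceptors `SA`; hydrogens
on N/O/S are polar `HD`. Five Boolean flags follow from the type alone:
hydrophobic {C, A}, aromatic {A}, acceptor {NA, NS, OA, OS, SA}, donor
{HD, HS}, metal {MG, CA, MN, FE, ZN}.

**Charges.** The built-in provider assigns simplified formal charges at
neutral pH: Asp/Glu carboxylates −0.5 per oxygen, Lys NZ +1, Arg NH1/NH2
+0.5 each, N-terminal amine +1, C-terminal carboxylate oxygens −0.5 each;
His neutral. Charges computed externally (e.g. by a Poisson–Boltzmann
preparation pipeline) can be ingested from PQR files instead, via the
`pqr-file` provider.

**Electrostatic potential.** A screened Coulomb sum with the classic
distance-dependent dielectric ε(r) = 4r:
φᵢ = 332.0636 · Σ_{j≠i} qⱼ / (4 rᵢⱼ²) in kcal/(mol·e). Pairs closer than
0.1 Å are excluded with a warning (they indicate a malformed structure).
This is a deliberately simple native model; a provider hook can ingest
grid-based potentials computed externally.

**Concavity.** For each atom, count neighbors within R = 10 Å (itself
included), take V_int = count × 20.1 Å³ and V_ext = (4/3)πR³ − V_int, and
report cx = V_ext/V_int clipped to [0, 15]. R, the per-atom volume and the
cap are the method's published defaults. Low cx means a buried/concave
environment; the `is_concave` Boolean uses cx ≤ 2.

**Solvent accessibility.** Classic Shrake–Rupley with 960 quasi-uniform
test points per atom (golden-spiral lattice) on the probe-expanded sphere
(r_vdW + 1.4 Å); the accessible fraction times the expanded-sphere area is
the atom ASA. An isolated atom therefore reproduces 4π(r+probe)² exactly,
which the tests assert. Residue relative accessibility divides the summed
atom ASA by the theoretical Gly-X-Gly maximum for that residue type (Tien
et al. 2013), clipped to [0, 1]. Van der Waals radii are Bondi-style
element radii with a 1.70 Å fallback.

**Torsions.** φ/ψ are standard four-point dihedrals in (−180°, 180°],
following the sign convention shared by biotite and Bio.PDB (verified
against both in the tests). φ is undefined at the N-terminus and ψ at the
C-terminus; undefined angles are stored as 0 with a paired `*_defined` mask
column rather than NaN, so downstream matrices stay numeric. Sine/cosine
embeddings are emitted alongside.

**Secondary structure.** A native Kabsch–Sander-style assigner: an amide
hydrogen is placed geometrically when absent (1.01 Å from N along the
in-plane bisector away from CA and the preceding carbonyl carbon; prolines
get none), hydrogen-bond energies use
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a −0.5
bonding cutoff, and the usual patterns follow: two consecutive n-turns give
G/H/I helices for offsets 3/4/5 (α-helices take priority), bridge patterns
give B (isolated) or E (extended ladders), remaining turn spans give T, a
Cα pseudo-angle above 70° gives a bend S, and everything else is '-'.
The 3-state collapse is {H,G,I}→helix, {E,B}→sheet, else loop. Chains
shorter than three residues are all '-'. Full bridge-partner bookkeeping
(ladder and sheet labels) is not reproduced; the assigner is intended as a
faithful, compact equivalent for featurization, not a byte-for-byte clone
of any particular reference implementation.

**Sequence entropy.** Per-column Shannon entropy of an aligned FASTA MSA
over observed residue frequencies (gaps excluded), normalized by ln 20 so
the value lies in [0, 1] and the `is_conserved` threshold of 0.5 is
scale-free; all-gap columns score 1.0 (maximally uncertain). Columns map
onto the structure through the gapped first row, whose ungapped sequence
must match the domain. When no MSA is supplied, every position scores 1.0 —
no evolutionary information means maximal uncertainty — so the feature
matrix is always fully populated and `is_conserved` is everywhere false.

## Aggregation and discretization

Atom-level features aggregate to residues per the schema (charge and
potential by sum; concavity and radius by mean); residue-level features
(hydrophobicities, rASA, torsions, secondary structure, entropy, residue
identity) map down unchanged onto child atoms. The printed vdW row carries
a residue-level checkmark that is not computable as a map-down (the radius
is intrinsically atomic); it is treated as residue = mean of member-atom
radii. The seven Boolean features apply their relations exactly as printed,
with no epsilon: charge 0 is neither negative nor positive, rASA exactly
0.2 is not buried, cx exactly 2 is concave, entropy exactly 0.5 is not
conserved. Booleans are computed at whichever level their source feature
exists, then mapped down like any residue feature.

## Voxelization

Voxel centers sit on the integer lattice `origin + index × voxel_size`
(1.0 Å default; the envelope uses the bare vdW radius, no probe — both
choices were open and are fixed here). A voxel is occupied iff its center
lies within the van der Waals radius of at least one atom; each occupied
cell stores the list of contributing atoms and one feature vector,
aggregated per the schema's voxel rules (max for one-hots and flags, mean
for continuous features including charge and potential, min for entropy).
Atoms contribute whole feature vectors — there is no partial-volume or
Lennard–Jones weighting.

Two implementations share these semantics exactly: the sparse method
enumerates the few candidate cells inside each atom's bounding cube
(constant work per atom at fixed voxel size, so near-linear overall and
only occupied cells are ever materialized), while the dense oracle scans an
explicit bounding box and tests every voxel against every atom (O(n·m)).
The suite asserts cell-for-cell equality on dozens of random structures;
the dense method exists purely as the independent check.

Rotation augmentation draws unit quaternions by the three-uniform subgroup
(Shoemake) construction, which is exactly Haar-uniform over SO(3); the test
suite checks the rotation-angle marginal against its closed form
p(θ) = (1 − cos θ)/π by Kolmogorov–Smirnov at 20 000 samples.

## Residue graphs

Contact edges connect residues whose *minimum heavy-atom distance* (the
"contact" definition was open; hydrogens are excluded) is within the
cutoff, 5 Å by default to capture van der Waals and other noncovalent
interactions; fully-connected mode links all pairs. Each edge carries four
canonical features: Cα–Cα distance, minimum heavy-atom distance, sequence
separation |i−j|, and the Cαᵢ–Cβᵢ–Cβⱼ–Cαⱼ inter-residue dihedral (masked
for glycine, which has no Cβ). Edges are undirected, stored once with
i < j.

## Clustering and splits

Pairwise identity uses true global alignment (match +1, mismatch 0, linear
gap −1, end gaps penalized) with identity = matches / alignment length.
Clustering is greedy and incremental: sequences are processed longest-first
(ties broken by identifier, so the result is independent of input order)
and each joins the first cluster whose representative matches at ≥ the
threshold (0.35 by default, mirroring 35%-identity culling; 0.20 available
for the stricter guideline), else founds a new cluster. This is a simple
deterministic stand-in for heavier culling pipelines, not a reproduction of
any database's own procedure.

Splits operate on whole clusters only. Clusters are shuffled by a seeded
generator and assigned greedily to the bin (train/validation/test, targets
80/10/10) with the largest remaining deficit measured in domains; greedy
deficit-filling keeps realized fractions tight on small families, and the
deviation from target is bounded by (largest cluster)/(total domains). An
audit utility verifies that no cluster spans two splits; it is asserted
over a 100-seed sweep. The same seed always yields the same assignment.

## Hierarchical store

The HDF5 layout mirrors a 4-level domain-classification hierarchy:
`/C/A/T/H/domains/<id>/{atoms,residues,edges}` plus
`/C/A/T/H/data_splits/{train,validation,test}/<id>`, where every split
entry is an HDF5 hard link to the domain group — reading through a split
path yields the identical object, which the tests assert. Feature tables
are stored as compound-dtype datasets: one-hot and Boolean columns as
unsigned 8-bit integers, continuous columns as 32-bit floats. Domain ids
are sanitized to link-safe names (alphanumerics plus `._-`). The single
HDF5 file is the reference backend; the layout contract (groups, datasets,
attributes, hard links) is backend-agnostic, so a multi-reader service
endpoint could implement the same interface. A batch iterator yields every
linked domain exactly once per pass, deterministically under a fixed
shuffle seed.

## Synthetic fixtures

The fixtures module generates every input the toolkit consumes. Peptides
are built by the natural-extension reference frame (NeRF) algorithm from
ideal backbone internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°), with the
carbonyl O placed in-plane opposite the next amide N and Cβ by ideal
tetrahedral geometry; recomputing torsions recovers the prescribed φ/ψ to
machine precision, which is the package's parameter-recovery check. The
antiparallel sheet fixture builds one extended strand and generates its
partner by the two-fold rotation about the sheet normal, scanning the
interstrand separation and axial registry for the configuration with the
most backbone hydrogen bonds — a synthetic stand-in adequate for testing
hydrogen-bond pattern detection. Toy superfamilies draw cluster base
sequences from disjoint random sub-alphabets (re-drawn until all
representative identities fall below the clustering threshold) and populate
clusters with ≥90%-identity point mutants, so ground-truth clusters are
recoverable by construction; per-cluster torsion profiles alternate helical
and extended. Toy MSAs have exactly conserved columns and uniform random
columns.

These fixtures emulate the *geometric and statistical structure* the
calculators consume — ideal backbones, clean identity structure, exact
column statistics. They do not emulate real data's side chains, missing
atoms, non-ideal geometry, compositional bias or phylogenetic correlation
between MSA rows. Passing tests therefore demonstrate algorithmic
correctness under the stated conventions, not end-to-end accuracy on
experimental structures.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: peptides of 5–15 residues, toy superfamilies of ≤ 20 domains of
≤ 40 residues, 50 random voxelization fixtures of ≤ 8 atoms, 20 000
rotation samples, 100 split seeds. These sizes make every check exact or
statistically sharp while keeping the whole suite under a minute on one
core; all algorithms are independent of problem scale.

## Known limitations

* The charge and potential models are formal/screened approximations, not
  Poisson–Boltzmann solutions; provider hooks exist for external values.
* The secondary-structure assigner omits ladder/sheet bookkeeping beyond
  B/E and may differ from reference implementations at pattern edges.
* The entropy convention (ln-20 normalization, gaps excluded) is one
  documented choice among several used by conservation tools.
* Greedy identity clustering depends on the longest-first ordering; it is
  deterministic but not equivalent to exhaustive culling.
* Only single-chain domains are supported; mmCIF/MMTF, ligand chemistry and
  multi-chain assemblies are out of scope.
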