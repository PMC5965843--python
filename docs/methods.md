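# Methods

This note documents the models, conventions and numerical choices behind
`ploopflex`, and what the synthetic generators do and do not emulate.

## Coordinate model and input handling

Structures are read with gemmi and normalized into a plain hierarchy
(Structure → Model → Chain → Residue → Atom) holding heavy atoms only.
Hydrogens are dropped on input: the package is designed around X-ray models
that do not include them, and every geometric definition below is stated on
heavy atoms. Alternate conformations are resolved at parse time to the
highest-occupancy conformer (ties broken by the alphabetically first altloc
identifier), because single-conformer geometry is what conformational
comparisons report. Waters are discarded by default (retained under a flag
for descriptive output only); all other non-polymer residues are kept on a
separate hetero list, preserving the polymer/ligand partition. Residue
identity follows author numbering throughout, with ranges inclusive on both
ends. Modified residues (MSE, SEP, TPO, PTR, …) map to their parent amino
acid in sequence extraction; unknown residues map to `X`. For entries with
several copies in the asymmetric unit, the default analysis chain is the
first polymer chain, and any chain pair can be superposed explicitly for
the copy-agreement check.

## Superposition and structural alignment

`kabsch_superpose` is the closed-form SVD solution for the least-squares
optimal proper rotation, with the determinant sign correction, applied to
centroid-shifted paired point sets. Rank-deficient (collinear) sets emit a
warning but still solve. Optimality is verified in the test suite against a
1,000-random-rotation brute-force oracle.

Region RMSDs ("2.39 Å over the 8 loop Cα atoms") are evaluated with
`rmsd_in_frame` in the frame of the whole-chain superposition, with no
local re-fitting — this matches the convention of quoting a region's
deviation "when the structures are superimposed". A locally re-fitted RMSD
is available by superposing the region atoms directly.

`align_structures` produces the "N structurally aligned residues" style of
comparison: a global pairwise sequence alignment (BLOSUM62, affine gaps
−10/−0.5, biopython `PairwiseAligner`) proposes residue pairs; the Cα atoms
are superposed; pairs deviating more than max(2 × RMSD, 2.0 Å) are
discarded and the superposition repeated until stable (at most 10 cycles).
The trimming rule is a deliberate design choice — published aligned-residue
counts depend on the (usually unstated) protocol of the program that
produced them, so counts should be compared with a tolerance of a few
residues rather than exactly. For same-protein comparisons an
`identical-numbering` mode pairs residues by author number with no
trimming.

## Torsion angles and Ramachandran classes

Dihedrals use the standard atan2 construction, signed per the IUPAC
convention, range (−180°, 180°]. φ of residue i is C(i−1)–N(i)–CA(i)–C(i);
ψ is N(i)–CA(i)–C(i)–N(i+1); ω of residue i is the torsion of the peptide
bond preceding it, CA(i−1)–C(i−1)–N(i)–CA(i). Angles are reported absent at
termini and across chain breaks, detected as consecutive-Cα separation
greater than 4.5 Å.

Ramachandran classification is polygon membership, not probability
density: a versioned data file (`data/rama_polygons.json`) ships coarse
published-style regions — general favored (α and β basins), general
allowed (expanded basins plus the left-handed α region), and the φ > 0
mirror regions accessible only to glycine. Points on a polygon boundary
count as inside. The scientifically load-bearing contract is the
glycine-only call: a non-glycine residue at the same (φ, ψ) classifies as
an outlier, which is exactly the argument for why a given loop conformation
requires glycine at that position.

## Peptide flips and P-loop state

A peptide flip between two conformers is measured by superposing the Cα
atoms of residues i−1…i+2 (those present; at least 3) and taking the angle
between the residue-i C=O unit vectors in that local frame. The flip
threshold is 90°: a genuine flip is ≈180°, ordinary loop adjustment is far
below 90°, so the decision is insensitive to the exact value. The report is
symmetric in argument order.

Backbone amide directions are computed without hydrogens by the planar-
amide construction: the N–H unit vector is opposite the sum of the N→CA
and N→C(i−1) unit vectors. The P-loop state classifier scores the four
central residues of the 8-residue motif (positions 3–6): each contributes
the cosine between its N–H direction and the direction from N to the
pocket center. The pocket center defaults to the centroid of a bound
active-site ligand (vanadate, formate, a buffer molecule) when one lies
within 8 Å of the catalytic cysteine, falling back to the cysteine Sγ; the
tag used is recorded in the output. The call is `active` when the mean
cosine exceeds +0.2 with at least 3 of 4 residues individually above it,
`inactive` under the mirrored condition, `indeterminate` otherwise. The
±0.2 margin encodes "towards vs away" with a guard band against noise; the
classification of genuinely switched loops sits near ±0.6–0.9 and is far
from the margin.

Ensemble dihedral histograms use 36 right-inclusive 10° bins covering
(−180°, 180°], normalized to sum to 1 — the standard frequency-distribution
summary of a dihedral over simulation snapshots or multi-model entries.

## Hydrogen bonds and packing contacts

A hydrogen bond is a heavy-atom donor–acceptor pair at ≤ 3.5 Å whose angle
at the donor (measured to the donor's bonded antecedent atoms, minimum over
antecedents) is ≥ 90°. Donors are backbone N (except proline) and standard
side-chain N/O donors; acceptors are backbone O/OXT and side-chain O plus
histidine ring N. There is no acceptor-angle term and no energy model: the
criteria are deliberately permissive, as appropriate for hydrogen-free
X-ray models. Network differencing matches bonds across conformers by
donor/acceptor residue number + atom name, so a re-targeted bond appears as
one loss plus one gain.

Packing is counted as carbon–carbon atom pairs: side-chain carbons of the
query residue × any carbon of any other residue of the same polymer chain,
within 4.5 Å, each unordered pair counted once, sequence neighbours not
excluded, hetero and water excluded. Because published contact numbers do
not always state their convention, the result carries the same quantity
under alternate conventions (excluding ±1 neighbours; distinct partner
atoms; distinct partner residues) so a published count can be located among
them and the matching convention frozen in configuration. A per-residue
profile aggregates the counts, optionally excluding carbons belonging to
hydrophilic functional groups (His imidazole, Arg guanidinium, Asp/Glu
carboxylate, Asn/Gln amide) to separate hydrophobic packing from polar
burial. The neighbour search uses a k-d tree and is verified against a
brute-force O(N²) enumeration in the tests.

## Kinetics

Initial velocity is the least-squares slope of product signal versus time
over a window (default 2–10 min, inclusive), optionally converted by a
user-supplied linear fluorescence→concentration calibration; without one,
parameters carry signal units and are tagged uncalibrated. Substrate
depletion is ignored over the window (initial-rate assumption); a warning
is raised when product within the window exceeds 10% of S₀.

`fit_mm` fits v = Vmax·S/(KM+S) either by nonlinear least squares
(deterministic start values Vmax₀ = max v, KM₀ = S at half-max by
interpolation; tolerances 1e-10/1e-12; no random restarts) or from an
unweighted Lineweaver–Burk line, 1/v = (KM/Vmax)(1/S) + 1/Vmax. Fitting a
Hill equation with exponent fixed at 1 is mathematically identical to the
direct Michaelis–Menten fit; an optional diagnostic releases the exponent.
kcat = Vmax/[E] with explicit unit conversion (Vmax µM·min⁻¹, [E] nM,
kcat s⁻¹); the conversion round-trips exactly. On noiseless data the two
methods agree to 1e-6 relative. Under constant-magnitude (additive) read
noise the nonlinear fit has clearly lower KM error than the unweighted
double-reciprocal fit, because the reciprocal transform amplifies the
noisiest low-substrate points; under purely multiplicative (constant-CV)
noise the two are statistically comparable at these conditions — the
documented robustness advantage of the direct fit is therefore tested under
additive noise. The pH-activity profile is descriptive (per-pH velocity
with argmax); no titration model is fitted.

## Synthetic generators: what they emulate, and what not

`build_peptide` constructs backbone (N, CA, C, O) plus CB by internal-
coordinate (NeRF) chain extension on a versioned ideal-geometry table
(Engh–Huber-style averages), so prescribed φ/ψ/ω are recovered from the
built coordinates exactly; CB is placed L-configured (improper torsion
C–N–CA–CB = +122.6° in the placement convention, validated against the
chemical-component dictionary's ideal L-alanine). `perturb_rigid` applies a
known rigid motion and records it, providing the exact-recovery oracle for
superposition. `make_flip_pair` rotates the C(i), O(i), N(i+1) peptide unit
about the Cα(i)–Cα(i+1) axis (default 180°), which preserves the bonds to
both flanking Cα atoms so the chain stays closed; applying the same
rotation again restores the original. `make_ploop_fixture` builds the
HCMGGLGR motif, gives the catalytic cysteine its Sγ, and drops a
single-atom pseudo-ligand on the side the central amides face (or the
opposite side), creating ground-truth active/inactive loops.

The assay simulator produces product(t) = v(S₀)·t with v from the rate law
— the idealized initial-rate regime — with multiplicative (default 2% CV,
a typical plate-reader coefficient of variation) or additive Gaussian
noise, at the standard study layout: six substrate concentrations
(50–1500 µM), readings every 2 min for 10 min, 10 nM enzyme. Per-curve
random streams are derived from the master seed, so any single curve is
reproducible in isolation.

Limits of the emulation, and hence of what passing tests show about real
data: toy peptides carry no side chains beyond CB (and the fixture Sγ), no
rotamers and no force-field relaxation, so packing counts and side-chain
H-bonds on real structures exercise code paths the fixtures only cover at
the CB level; the assay simulator has no substrate depletion, no product
inhibition and no instrument drift, so parameter-recovery results bound
estimator error under the stated noise model only; and the flip generator
changes a single peptide unit, whereas real conformational switches also
shift flanking backbone. Analyses of the deposited crystal structures
(dihedral values, region RMSDs, contact counts published for specific
entries) require fetching those entries from the PDB archive and cannot be
reproduced from synthetic data.

## Problem sizes and determinism

Test and acceptance computations use deliberately small problems: peptides
of 4–20 residues, 100 assay replicates, 10,000-member ensembles for the
histogram checks, 1,000 alternative rotations for the superposition oracle.
All randomness flows through explicit seeds (numpy `default_rng`); report
generation is deterministic given inputs and configuration, and the
recorded provenance block reproduces a report bit for bit.

Statistical acceptance bounds account for multiplicity: the uniform-
histogram check uses a 4σ per-bin binomial bound so that the family-wise
false-failure probability across the 36 simultaneous bins stays below 1%.
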