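# Methods

This note records the model, the defaults, and the design decisions behind
`turnmap`, in the order the pipeline runs.

## Turn definition and classification

A turn is any window of four consecutive residues with complete backbones
(N, CA, C, O), no chain break (peptide C–N distance ≤ 2.5 Å), a
C&alpha;1–C&alpha;4 distance of at most 7.0 Å, and not all four residues
helical. Only the all-helical exclusion is applied (rather than excluding
any helical residue) so that turns capping helices are retained — helix
caps are among the most interesting turn contexts. Overlapping windows are
all reported; maps aggregate per turn, so no non-overlap culling is needed.

Classical types are assigned by the standard windowed rule: a turn matches
an ideal when three of its four central dihedrals (φ2, ψ2, φ3, ψ3) lie
within ±30° and the fourth within ±45°, with the cis/trans state of the
central peptide bond (ω of position 3) agreeing; among matching ideals the
angularly nearest wins, and a turn matching none is type IV. The cis types
VIa1/VIa2/VIb require |ω3| < 90°.

Secondary structure, needed only to separate strand turns (E2/E3/E2E3) from
beta turns, is assigned from dihedral runs: helix = runs of ≥ 4 residues
with φ ∈ (−100, −30), ψ ∈ (−67, −7); strand = runs of ≥ 3 with
φ ∈ (−170, −50), ψ ∈ (80, 180] ∪ (−180, −170]. A per-residue override
(e.g. DSSP output) can be supplied and takes precedence; the built-in rule
keeps the package self-contained. Terminal residues with one undefined
angle join a run when their defined angle fits, so a uniform fragment is
labeled uniformly.

Ramachandran region labels use a five-letter alphabet {A, B, L, E, G} of
half-open φ/ψ boxes tiling the torus (A: φ<0, ψ∈[−90,50); B: φ<0,
ψ∈[50,180)∪[−180,−170); L: φ≥0, ψ∈[−50,100); E: φ≥0 elsewhere; G: the
remaining left-half strip), lowercased when the peptide bond is cis. The
box table is configuration (`TurnmapConfig.rama_boxes`), so a published
partition with more regions can be dropped in without code changes; the
turn's two-character Ramachandran type uses positions 2 and 3.

## The turn-local frame

Every turn defines a rigid frame from its four C&alpha; atoms: their
centroid maps to the origin, the unit C&alpha;1→C&alpha;4 vector to +x, the
component of (midpoint of C&alpha;2/C&alpha;3 − centroid) orthogonal to x
to +y, and z = x × y. The frame is deterministic, invariant under rigid
motion of the input (verified to 1e-6 Å under random rotations), and
chirality-preserving (determinant +1), so a mirror-image turn is mapped to
the mirror of its parent's image and remains distinguishable. Expressing
all turns in their own frames superposes the entire dataset with no
pairwise fitting; all side-chain and tail distances are plain Euclidean
distances between these aligned coordinates. Note that the construction
does **not** force C&alpha;1 and C&alpha;4 to have opposite x coordinates —
only the difference vector is constrained — and the central midpoint is
placed in the +y half-plane.

## Clustering

*Backbone (stage 1).* Turns are clustered on (φ2, ψ2, φ3, ψ3) under the
wraparound metric d(u,v) = sqrt(Σ min(|Δ|, 360−|Δ|)²). A hybrid procedure
is used: DBSCAN (defaults eps = 30°, min_pts = min(25, max(5, n/50)) so
small synthetic sets remain clusterable) finds the number of dense groups
and a seed medoid for each; PAM SWAP refinement runs from those seeds on
the non-noise points; every noise point is then assigned to its nearest
medoid so that all turns carry a backbone label (maps must cover every
member). With zero core points the set falls back to a single cluster.
Alternatively, turns can be assigned to user-supplied labeled reference
medoids (nearest medoid, ties alphabetical), which is how an established
published backbone clustering would be used; `split_cluster` subdivides a
chosen cluster by PAM (the map-level scheme splits the dominant type-I
cluster into three, turning an 18-label scheme into 20).

*PAM.* BUILD seeds greedily (largest cost reduction, ties to the lowest
item index) and SWAP applies the first improving exchange in a fixed scan
order until none improves; the cost is non-increasing by construction and
is asserted. Assignment ties go to the medoid with the lower item index.
These deterministic tie-breaks make every clustering reproducible
bit-for-bit; on small planted instances PAM attains the exhaustive-optimum
cost (tested against a brute-force subset enumeration).

*Side chains (stage 2).* Within each backbone cluster, turns containing the
motif are clustered on the RMS distance between the motif residues'
side-chain heavy atoms (CB outward) in turn-local coordinates, name-matched,
with chemically equivalent pairs (Asp OD1/OD2, Glu OE1/OE2, Arg NH1/NH2,
Phe/Tyr ring CD/CE pairs, swapped as whole ring flips) resolved by taking
the smaller of the two pairings. The cluster count is chosen by mean
silhouette over k = 2..k_max (default 8), accepting the best k only when
its silhouette reaches 0.25; below that, or when all items are identical,
one cluster is returned. A glycine motif position has no side-chain heavy
atoms; the stage then degenerates to a single cluster with a warning.

*Tails (stage 3).* The N- and C-tails of each side-chain cluster are
clustered independently on the RMS over tail backbone atoms (N, CA, C, O)
in the same frame. Tails of unequal length cannot be atom-matched, so
members are partitioned by tail length (2, 1, 0 residues) and each
partition is clustered separately; the zero-length partition is the
designated "absent" group. Sizes are conserved at every level of the
hierarchy and are asserted in tests.

No re-superposition happens inside stages 2 and 3 — the shared frame is the
alignment; this is the central representational idea the package is built
around.

## Hydrogen bonds

Detection is heavy-atom only, because typical X-ray inputs carry no
hydrogens: a donor–acceptor pair is a bond when the heavy-atom distance is
≤ 3.5 Å and the angle antecedent–donor–acceptor is ≥ 90° (the antecedent
is the donor's covalent parent, e.g. CB for Ser OG; if it is missing the
distance criterion alone applies). Donors are backbone N (except proline)
and the standard side-chain N/O/S donors; acceptors are backbone O and
side-chain O/N/S acceptors. Intra-residue pairs are excluded and atoms are
restricted to the 8-residue window. Categories follow atom classes
(backbone = {N, CA, C, O}): SC/SC, SC/BB, BB/BB. Both cutoffs are
configuration. Before frequencies are tallied, chemically ambiguous atoms
are canonicalized (OD1/OD2 → OD*, etc., per amino acid), so a bond that
merely flips between equivalent labels counts once. A cluster's frequency
for a pair key is the fraction of members exhibiting at least one such
bond; pairs below the display threshold (default 20%) are omitted from
maps. Salt-bridge, aromatic and cation-π interactions are outside scope.

## Motif statistics

A motif is 1–3 (position, amino-acid) constraints over the window positions
{−2, −1, 1, 2, 3, 4, +1, +2}, written e.g. `D3S+1`. A turn matches when
every constrained position exists (tails may be absent) and carries the
residue. Significance within a cluster is the exact one-sided binomial
tail P(X ≥ k) with n = cluster members having all motif positions present
and p = the product of position-specific background frequencies taken over
the full turn set (positional, not global, composition — turn positions
differ strongly). The tail is summed directly on whichever side of the
count is smaller, anchored at a term computed exactly (integer binomial
coefficient, rational powers of the dyadic float p), which keeps the
relative error at a few ulp up to n ≈ 1e5; an arbitrary-precision oracle
verifies ≤ 1e-12 in tests. A hypergeometric variant and the alternative
overrepresentation convention are deliberately not implemented twice over:
fractional overrepresentation is (k − np)/k as a percentage, bounded above
by 100% and equal to 1 − 1/enrichment, which keeps the scale comparable
across motifs of very different abundance.

`rank_motifs` enumerates the motifs of a given arity actually observed at
least min_support times (default 10) in a scope (global, classical type, or
backbone cluster), scores each against the positional background, and sorts
by p, ties by count then name. Raw p-values are reported together with a
Bonferroni correction over the enumerated family; the ranking itself is
invariant to the correction. Under uniform random sequences the corrected
minimum p exceeds 0.05 in ≥ 95% of runs (calibration test). Map heat for a
motif is its significance score normalized by the best backbone cluster,
clipped to [0, 1].

## Synthetic data

The peptide builder converts internal coordinates to Cartesian by NeRF
placement. Backbone geometry is ideal (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°);
side-chain bond lengths, angles and ring torsions come from ideal residue
templates (the chemical component dictionary bundled with biotite), with
the requested χ angles substituted on the rotatable axes so that measured
φ/ψ/ω/χ reproduce the request to ~1e-3°. ω defaults to trans; cis bonds
(type VIa/VIb turns) are requested per residue. Proline's χ values default
to the ideal ring; forcing them distorts ring closure, which is acceptable
for fixtures. No energy model, clash relief or B-factors: ensembles emulate
*conformational* heterogeneity only, as wrapped-Gaussian noise applied in
dihedral space (never Cartesian) independently to every φ, ψ and χ.

Two named scenarios define the study conditions used throughout the tests:

- `classical_mixture_spec`: 600 turn/tail windows drawn equally from ideal
  types I, II and I′ with 10° dihedral noise — the backbone-recovery
  condition (hybrid clustering should find 3 clusters, ARI ≥ 0.95).
- `ser_rotamer_spec`: 300 type-I windows (sequence GAADDSKL) with the Ser
  at turn position 4 in three equal-weight χ1 rotamers (g+, g−, trans) and
  8° noise. The g+ component pairs χ1 = +60° with a helical Ser φ (−90°), a
  backbone-dependent rotamer preference, and forms the serine turn-capping
  bond OG(4)→O(1) at 2.1 Å; the other rotamers cannot. This plants a
  three-way side-chain truth and a rotamer-specific H-bond whose map
  frequency should track the realized component fraction.

Because the generator produces idealized, single-conformer fragments with
isotropic dihedral noise, passing tests demonstrate that the machinery
recovers planted structure under realistic noise magnitudes — not that real
crystallographic turns are this clean. Real data add missing atoms,
alternate conformations, correlated backbone motion and rotamer
populations far from equal weight; the detection and clustering paths
handle these (altloc resolution, backbone-completeness flags, noise
reassignment), but recovery rates on real structures will be lower.

## Dataset screening

Sequence-identity culling is not reimplemented: the package applies a
precomputed allow list (PISCES-style, `PDBID CHAIN` lines) and a resolution
cutoff (default ≤ 2.0 Å, configurable; structures without a recorded
resolution, i.e. synthetic ones, pass). Only PDB format is read, first
model only, HETATM excluded except MSE (kept as Met); other nonstandard
residues are dropped and break the chain for detection purposes.

## Numerical choices and degenerate inputs

- Angles live in (−180, 180]; box lookups normalize 180 → −180.
- Chain break threshold: peptide C–N > 2.5 Å; dihedrals across a break are
  absent, never extrapolated.
- Degenerate frames (C&alpha;1 = C&alpha;4, central midpoint on the x-axis)
  raise rather than guess.
- Altloc resolution keeps the highest occupancy, ties preferring altloc "A"
  then alphabetical; hydrogens are shelved, not deleted.
- All orderings that affect output (cluster labels, SC/tail ordering,
  H-bond sorting, JSON key order) are fully specified, so rebuilding a map
  from the same inputs reproduces the identical byte stream; exported JSON
  rounds floats to 6 decimals for this reason.
- Problem sizes in the test battery (600-turn backbone mixtures, 300-turn
  rotamer ensembles, 150-fragment end-to-end runs) were chosen as the
  smallest sets on which the planted effects are comfortably resolvable.

## Known limitations

- The dihedral-run secondary-structure rule is cruder than DSSP near
  irregular strand edges; the override path exists for exact reproduction
  of published strand assignments.
- The SC distance treats each symmetric group's flip independently per
  residue; a global assignment over multiple interacting symmetric groups
  is not attempted.
- Tails of different lengths are never co-clustered (by construction);
  maps of heavily truncated chains will show many small length-partition
  groups.
- H-bond detection does not place hydrogens, so donor-angle geometry is
  approximate; bifurcated bonds are counted independently and
  water-mediated bridges are invisible.
- Strand-turn backbone clustering uses the same hybrid procedure as beta
  turns rather than a fixed published reference; supply reference medoids
  to pin the labels.
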