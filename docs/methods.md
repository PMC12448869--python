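# Methods

This note records the models, conventions and numerical choices behind
`glycoforge`, in enough detail to reproduce or audit any verdict the
package emits.

## Glycan topology and residue numbering

A glycan is a rooted tree: nodes are monosaccharide residues (sugar name,
absolute configuration D/L, ring form pyranose/furanose/open-chain, anomer
α/β/none, plus position-tagged modifications), edges are glycosidic
linkages recorded as (donor, acceptor, acceptor position). The reducing-end
residue is the root; every other residue donates exactly one bond through
its anomeric carbon (C1 for aldoses, C2 for ketoses/sialic acids). One
linkage per acceptor position, no cycles, no donor reuse — violations are
reported by `validate_graph` rather than silently repaired.

Canonical numbering is breadth-first from the root, visiting branch
children in ascending acceptor-position order (O2 < O3 < O4 < O6). This
single rule reproduces the residue numbers used in the published template
set this library mirrors — the two terminal galactoses of biantennary G2
land on 8 and 9, and the 3-arm mannoses of M9 on 4, 6 and 9 — and it is the
order used for `ccdCodes` and `bondedAtomPairs` emission. Modifications
(sulfate, phosphate, acetyl, methyl) are appended as extra residues after
the sugars, ordered by (host residue, position), so the bond-count law
|pairs| = (residues − 1) + modifications (+ attachment) holds per glycan.

The text grammar is IUPAC-condensed with compact modification tokens
(`6S`, `2P`, `9Ac`, `3Me`). Defaults: configuration follows SNFG custom
(L for Fuc, Rha, Ara, IdoA; D otherwise), ring form is each sugar's usual
one, and a reducing-end token without an anomer letter is read as β.
The serializer writes the highest-position arm of a branch point in line
and the remaining arms bracketed in ascending position; `parse(write(g))`
is the identity for every representable graph (property-tested over random
trees), while non-canonical input strings may re-serialize with a
different but equivalent bracket arrangement.

## CCD registry and leaving-atom remediation

The registry maps (sugar, configuration, ring, anomer) to CCD codes —
the anomer is encoded purely by code choice, never by geometry. Aldoses
carry `leaving_atom = O1, auto_removed = True` (AlphaFold 3 honours the
`pdbx_leaving_atom_flag`); ketoses carry `O2, auto_removed = False`, which
is exactly why sialic-acid donors need an edited component. Edited
components are the original minus the named atoms and any hydrogens bonded
only to them; ring atoms are refused. New codes are base + `X`
(`X2`, `X3`, ... on collision), checked against the whole registry, and
recorded in the job manifest. Modification grafts retain the sugar's
bridging oxygen and strip one oxygen from the modification block, so every
bridging oxygen ends with exactly two heavy-atom neighbours; a phosphate
bridging two partners (GPI ethanolamine-phosphate) loses two.

Synthetic components are generated from the ideal reference builds with
hydroxyl hydrogens only (carbon-bound hydrogens are irrelevant to every
check here); coordinates are rounded to 3 decimals so CIF write/load
round-trips are exact. Real PDBeChem `chem_comp` files are drop-in
compatible. Codes for entries the common literature prints (NAG, BMA, SIA,
FUC, GLC/BGC, GCU/BDP, the lipid blocks) follow the official dictionary;
a few rarer entries (ribitol, Kdn/Kdo anomers, GDP-mannose) are registry
data-asset choices that only internal consistency depends on.

## Reference geometry and chirality checks

Every registry sugar has a reference build: a 6-ring at the ⁴C₁ chair pole
(Q = 0.57 Å) or a 5-ring envelope, ring radius 1.45 Å (1.25 Å furanose),
with each substituent placed in the axial or equatorial slot its
configuration dictates (Glc all-equatorial; Gal O4 axial; Man O2 axial;
IdoA as the D-ido pattern; 109.5° geometry throughout, C–O 1.43 Å,
C–N 1.47 Å, C–C 1.53 Å). L-sugars are built as the mirror image of their
D-configured pattern, which places them in their usual ¹C₄ chair. For
ketoses the anomeric C2 carries both the carboxylate C1 and the glycosidic
O2; α is built with O2 axial — a package convention applied identically to
reference and model sides, so verdicts are convention-independent.

A stereocenter verdict is the sign of det[v_prev, v_next, v_exo], the edge
vectors from the center to its previous ring atom, next ring atom and
defining exocyclic substituent (the glycosidic oxygen fills the anomeric
slot of a linked donor). The sign is compared against the same determinant
on the reference build. This deliberately avoids CIP priority rules: it is
total over the registry, exact, and directly tests the axial/equatorial
question that distinguishes epimers. Missing atoms make a center
indeterminate (reported, not fatal). Hydrogens are ignored throughout
validation.

Valence checks flag any oxygen with more than two heavy-atom neighbours
and any carbon bonded to three oxygens — the signature of a retained
leaving oxygen at a junction. Over-coordinated oxygens bonded to an
already-flagged carbon are folded into that carbon's flag: they are the
same junction defect, and merging them is what makes the corruption
detector's precision exact. Bonds are inferred geometrically
(d < r_cov(a) + r_cov(b) + 0.4 Å, heavy atoms only).

## Cremer–Pople puckering and conformer labels

Ring atoms are ordered ring-oxygen first, then the anomeric carbon, then
ascending carbons; with that phase convention the ⁴C₁ chair of a D-pyranose
sits at θ ≈ 0. Displacements come from the standard mean-plane
construction (Σz_j = 0 plus m = 1 orthogonality), amplitudes and phases
from the discrete Fourier sums, Q = √Σq_m², cos θ = q₃/Q for 6-rings;
5-rings have a single pseudorotation phase. The inverse transform
synthesizes z_j for any target (Q, θ, φ); the ring builder places atoms
clockwise on a circle with those displacements, so forward analysis
recovers the target to rounding error (≤ 1e-13 on the test grid, bound
1e-6 asserted).

The 38 canonical pyranose conformers (2 chairs, 6 boats, 6 twist-boats at
the equator, 12 envelopes and 12 half-chairs on the θ = 54.73°/125.27°
tropics) are not transcribed from a table: the labels are derived at import
time from the displacement pattern at each vertex — chairs name the
exocyclic para pair containing the anomeric carbon, boats the para pair
displaced together, twist-boats the meta pair (opposite sides) containing
the lowest-numbered carbon, envelopes/half-chairs the dominant atom or
adjacent opposite-sign pair. That generator reproduces the standard
assignment (³,ᴼB at φ=0 with C3 and O5 above the plane, ³S₁ at 30°, B₁,₄
at 60°, ..., ³H₄ on the southern tropic), and the tests cross-check the
labels against which atoms lie above/below the mean plane of an actually
built ring. Classification of a measured ring is nearest-vertex by
spherical angular distance; assignments with < 10° margin to the
runner-up are flagged borderline, and Q < 0.1 Å reports `planar`.

## Synthetic assemblies and corruption

Glycan models are assembled breadth-first: each donor's ideal build is
rigidly placed so its anomeric carbon sits 1.43 Å from the acceptor
oxygen at a 117° C–O–C angle, with glycosidic torsions φ = −60°,
ψ = 120° by default (chosen only to avoid clashes; no energetic claim).
If any non-bonded contact falls below 2.0 Å — which would read as a
spurious bond — a deterministic torsion scan (ψ then φ offsets) retries
before failing with a steric-collapse error. Donor leaving oxygens are
omitted, as in a remediated job.

`corrupt` injects exactly one named defect: an epimer flip moves the
substituent to the other tetrahedral slot (re-placing its chain atoms for
clearance); an anomer flip at a junction rotates the donor subtree 180°
about the exterior bisector at the anomeric carbon — which exactly swaps
the two exocyclic slots, inverting the anomeric chirality while leaving
the acceptor and the donor's internal stereocenters untouched — followed
by a chirality-preserving spin about the glycosidic bond for clearance;
retained-leaving-oxygen adds the leaving O back in the free tetrahedral
slot (or, at a fully substituted ketose junction, through the face
opposite the carboxylate, where the inevitable close contacts merge into
the same junction flag); ring-flatten zeroes the out-of-plane
displacements. The exhaustive detector audit (every registry form × every
stereocenter × three error classes, 201 injections) achieves
precision = recall = 1 with zero findings on clean builds.

What the synthetic fixtures do not emulate: realistic torsion populations,
solvent effects, thermal disorder, or AlphaFold 3's actual failure
geometry (which distorts many coordinates at once, not a single center).
Passing the synthetic suite demonstrates the *detectors* are correct and
complete on isolated defects; it does not certify real models, where
multiple simultaneous findings per residue are expected and the validator
reports all of them.

## Superposition

Kabsch superposition via SVD with the determinant correction (rotations
are always proper; mirror inputs cannot be "fit" by a reflection). Fewer
than 3 pairs or collinear point sets are rejected. `align_refine`
iterates: fit, compute residuals, discard pairs with residual greater
than `reject_sigma` × RMS residual (RMS, not standard deviation about the
mean — the latter over-trims tightly clustered residuals), refit; it
stops when nothing is rejected, when fewer than 3 pairs would remain, or
after `cycles` rounds. `cycles = 0` is bit-for-bit plain Kabsch. Both raw
and refined RMSD are always reported, because published comparisons do
not always state which was printed. Cross-structure comparison requires
an explicit residue mapping (crystal and model numbering differ); atoms
pair by name, heavy atoms by default.

The independent test oracle is a brute-force search over ~10⁵ sampled
rotations with progressive zoom around the best candidate; the closed
form never exceeds it and agrees to < 1e-3 Å on random 10-point clouds.

## AlphaFold 3 job emission

JSON uses the v2 dialect with a fixed key order (dialect, version, name,
modelSeeds, sequences, bondedAtomPairs, userCCD) and is byte-stable; a
golden-file test pins the G2 template. Bonded pairs are ordered acceptor
oxygen first, donor anomeric carbon second, matching the worked-example
convention (AlphaFold 3 itself is order-agnostic). Glycan entity ids are
a two-letter mnemonic plus counter (NG, NG2, ...). Default
`modelSeeds = [1]`; templates that in practice need more sampling to yield
credible conformers (GPI anchor, GAG linkers) default to five seeds. The
validator does not require the acceptor hydroxyl hydrogen to be stripped
(AlphaFold 3's behaviour there is undocumented) and ignores hydrogens
throughout. The GPI protein linkage is emitted as an explicit bonded pair
to the C-terminal serine by default, with a `ptmType`-based alternative
behind a flag; the GPI sidechain sialyl linkage is marked provisional
(α2,3) in the template notes.

Template protein sequences are synthetic stand-ins shipped as FASTA
fixtures with sequons/attachment sites at fixed positions; sequon
positions are fixture metadata, not computed. Swapping in real sequences
changes nothing structural about the emitted jobs except the sequences
themselves.

## Problem sizes and limitations

The test suite and the acceptance script run entirely on generated data:
420-point puckering grids, 201 corruption injections, 50 superposition
instances with ~10⁵-rotation oracles — a few seconds end to end. Known
limitations: the builder's geometry is idealized (no energy model), ring
perception assumes a single 5/6-ring with one oxygen per residue,
open-chain residues get epimer checks but no pucker, and benchmark
comparisons against deposited models require network access and are out
of the tested path (manifests ship in `data/benchmarks.json`).
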