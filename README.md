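# glycoforge

Glycan-topology compiler and stereochemistry validator for AlphaFold 3
glycoconjugate modeling.

AlphaFold 3 can model glycans, but only if the input describes them
unambiguously. SMILES input routinely scrambles anomeric configurations
(α/β) and epimeric orientations (axial vs equatorial hydroxyls); the robust
route is to spell each glycan out as Chemical Component Dictionary (CCD)
building blocks — one code per monosaccharide, with the anomer encoded
purely by code choice (e.g. `NAG` = β-GlcNAc, `BMA` = β-Man, `SIA` =
α-Neu5Ac) — joined by explicit covalent bonds in the `bondedAtomPairs`
field. That encoding has sharp edges: residue order in `ccdCodes` must
match the residue numbering used by the bond list, each glycosidic bond
pairs the acceptor hydroxyl oxygen O*x* with the donor anomeric carbon (C1
for aldoses, C2 for sialic acids), and leaving atoms must actually leave —
AlphaFold 3 strips a donor's O1 automatically but *not* the O2 of sialic
acids or the leaving oxygens of sulfate/phosphate/acetyl/methyl
decorations, which then produce chemically impossible junctions unless the
component is edited and supplied through `userCCD`.

`glycoforge` automates the whole pipeline and the quality control around it:

* **Topology model + notation.** Glycans are rooted trees of
  monosaccharides; an IUPAC-condensed grammar
  (`Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6[...]Manb1-4GlcNAcb1-4GlcNAc`)
  parses and serializes them losslessly. Canonical residue numbering is
  breadth-first from the reducing end, branch children in ascending
  acceptor-position order.
* **CCD registry + remediation.** 20 monosaccharides (both anomers where a
  code exists), lipid building blocks (SPH, STE, OTP, GOL, PL3, IPD, ETA,
  PO4) and modification blocks. Components can be loaded from real
  `chem_comp` mmCIF or generated from ideal reference-chair geometry;
  `strip_leaving_atoms` produces the edited `userCCD` entries (`SIA` →
  `SIAX`, minus O2 and its hydroxyl hydrogen) with collision-free codes.
* **Job compiler.** `build_job` / `template(...)` assemble complete
  AlphaFold 3 JSON (v2 dialect) jobs — proteins with attachment sites,
  N-/O-linked glycans, glycolipids with ceramide built from SPH+STE, a GPI
  anchor, GAG linkers with Xyl 2-O-phosphate, and a fully N-glycosylated
  Siglec-2 pair carrying 22 G2S2 glycans. `validate_job` catches dangling
  bonds, bad atom names and missing `userCCD` edits before you spend GPU
  time.
* **Stereochemistry validator.** Reads predicted mmCIF/PDB models and
  checks, per residue: anomeric configuration and every ring stereocenter
  (signed-volume comparison against ideal reference builds), valence sanity
  (retained leaving oxygens), and Cremer–Pople ring puckering
  (Q, θ, φ plus the nearest of the 38 canonical pyranose conformers —
  ⁴C₁, ³,ᴼB, ¹C₄, ...).
* **Superposer.** Closed-form Kabsch RMSD with PyMOL-align-style iterative
  outlier rejection for comparing models against reference structures.

The bundled protein sequences are synthetic stand-ins with attachment
sites at fixture-defined positions (real sequences are drop-in
replacements); all coordinate fixtures are generated by the synthetic
builder, so the test suite runs without downloads.

## Worked example

Compile the biantennary G2 N-glycan template and inspect the bond list:

```
$ glycoforge build --template g2 --out g2.json
g2: 1 entities, 8 bonded pairs
```

The emitted `ccdCodes` list begins `NAG, NAG, BMA` (chitobiose core plus
the β-mannose) and the first two bonded pairs are

```
[[["NG", 1, "O4"], ["NG", 2, "C1"]], [["NG", 2, "O4"], ["NG", 3, "C1"]]]
```

— the β1,4 linkages of the core, each pairing an acceptor O4 with a donor
C1. Residues 8 and 9 of this template are the two terminal galactoses.
Now generate a clean synthetic structure of LNnT and validate it:

```
$ glycoforge synth --glycan "Galb1-4GlcNAcb1-3Galb1-4Glc" --out lnnt.cif
$ glycoforge validate --model lnnt.cif --glycan "Galb1-4GlcNAcb1-3Galb1-4Glc"
 res code  anomer        epimers            pucker   Q
   1 BGC   ok            -                  4C1      0.57
   2 GAL   ok            -                  4C1      0.57
   3 NAG   ok            -                  4C1      0.57
   4 GAL   ok            -                  4C1      0.57
```

Exit code 0: every anomeric center and epimer matches the intended
topology, and all four pyranoses sit in the ⁴C₁ chair with puckering
amplitude Q = 0.57 Å. Corrupting the model (e.g. flipping the C4 hydroxyl
of residue 2 from axial to equatorial, which turns Gal into Glc) makes the
validator exit 1 and name exactly that center.

`glycoforge templates` lists the full curated catalog (M9, A1, G2, G2F,
G2S2, O-GalNAc cores 1–4, disialyl core 1, keratan-sulfate core 2, HS/CS
linkers, core M3 with ribitol phosphate, GP1c, Lewis-b lactoside, Globo H
with the Bc2L-C trimer, dolichol-PP-chitobiose with ALG1, GPI-anchored
glypican-1, and the Siglec-2 pair).

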