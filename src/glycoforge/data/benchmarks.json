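{
  "description": "Residue-mapping manifests for optional benchmark comparisons of deposited AlphaFold 3 glycoconjugate models (ModelArchive ma-af3glycan) against experimental structures. Running these requires downloading the listed entries; nothing in the package or test suite depends on them.",
  "atom_filters": ["heavy", "ring"],
  "refinement_settings": {"cycles": 5, "reject_sigma": 2.0},
  "comparisons": [
    {
      "name": "man1a1-m9-3arm",
      "reference_pdb": "5KKB",
      "model_archive": "ma-af3glycan",
      "glycan_residues_model": [3, 4, 6, 9],
      "note": "MAN1A1 Michaelis complex; 3-arm mannoses plus core"
    },
    {
      "name": "b3galt5-core3-disaccharide",
      "reference_pdb": "8ZX3",
      "model_archive": "ma-af3glycan",
      "glycan_residues_model": [2],
      "note": "terminal GlcNAc binding pose"
    },
    {
      "name": "pp2-chitotriose",
      "reference_pdb": "7W4B",
      "model_archive": "ma-af3glycan",
      "glycan_residues_model": [1, 2, 3],
      "note": "plant lectin with chitotriose"
    },
    {
      "name": "bc2lc-globoh",
      "reference_pdb": "6TIG",
      "model_archive": "ma-af3glycan",
      "glycan_residues_model": [4, 5, 6],
      "note": "lectin-bound terminal trisaccharide of Globo H"
    }
  ]
}
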