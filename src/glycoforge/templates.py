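"""Curated AlphaFold 3 input templates for common glycan classes.

The catalog spans the validated template library: high-mannose and complex
N-glycans (M9, A1, G2, G2F, G2S2), O-GalNAc cores 1-4 and their disialyl /
keratan-sulfate extensions on erythropoietin, the GAG linker on glypican-1
and bikunin (with Xyl 2-O-phosphate), the O-Man core M3 with ribitol
phosphate, glycosphingolipids (GP1c, Lewis-b lactoside, Globo H with the
Bc2L-C lectin trimer), the dolichol-PP-chitobiose analog with ALG1, a GPI
anchor assembled from CCD blocks, and a fully N-glycosylated Siglec-2 pair.

Protein sequences are synthetic stand-ins shipped as FASTA fixtures (the
attachment-site positions are fixture metadata, not computed from sequons).
Templates flagged "hard" (GPI, GAG linkers) default to a larger seed list,
reflecting that credible conformers for these assemblies tend to emerge only
with increased sampling.
"""

from __future__ import annotations

from importlib import resources

from .af3 import AF3Job, build_job
from .errors import JobError
from .graph import AttachmentSpec
from .notation import parse_iupac_condensed

HARD_SEEDS = (1, 2, 3, 4, 5)

#: IUPAC-condensed compositions used by the templates.
GLYCANS = {
    "lnnt": "Galb1-4GlcNAcb1-3Galb1-4Glc",
    "m9": ("Mana1-2Mana1-2Mana1-3[Mana1-2Mana1-3[Mana1-2Mana1-6]Mana1-6]"
           "Manb1-4GlcNAcb1-4GlcNAc"),
    "a1": "GlcNAcb1-2Mana1-3[Mana1-6]Manb1-4GlcNAcb1-4GlcNAc",
    "g2": ("Galb1-4GlcNAcb1-2Mana1-6[Galb1-4GlcNAcb1-2Mana1-3]"
           "Manb1-4GlcNAcb1-4GlcNAc"),
    "g2f": ("Galb1-4GlcNAcb1-2Mana1-6[Galb1-4GlcNAcb1-2Mana1-3]"
            "Manb1-4GlcNAcb1-4[Fuca1-6]GlcNAc"),
    "g2s2": ("Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6"
             "[Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3]Manb1-4GlcNAcb1-4GlcNAc"),
    "g2s2-6s": ("Neu5Aca2-6Galb1-4GlcNAc6Sb1-2Mana1-6"
                "[Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3]Manb1-4GlcNAcb1-4GlcNAc"),
    "o-core1": "Galb1-3GalNAca",
    "o-core2": "GlcNAcb1-6[Galb1-3]GalNAca",
    "o-core3": "GlcNAcb1-3GalNAca",
    "o-core4": "GlcNAcb1-6[GlcNAcb1-3]GalNAca",
    "disialyl-core1": "Neu5Aca2-6[Neu5Aca2-3Galb1-3]GalNAca",
    "ks-core2": ("Gal6Sb1-4GlcNAc6Sb1-3Gal6Sb1-4GlcNAc6Sb1-6[Galb1-3]GalNAca"),
    "hs-linker": ("GlcNAca1-4GlcAb1-4GlcNAca1-4GlcAb1-3Galb1-3Galb1-4Xyl2Pb"),
    "cs-linker": ("GalNAcb1-4GlcAb1-3GalNAcb1-4GlcAb1-3Galb1-3Galb1-4Xyl2Pb"),
    "core-m3": "Xyla1-2Rbo-ol5P1-3GalNAcb1-3GlcNAcb1-4Man6Pa",
    "gp1c": ("Neu5Aca2-8Neu5Aca2-3Galb1-3GalNAcb1-4"
             "[Neu5Aca2-8Neu5Aca2-8Neu5Aca2-3]Galb1-4Glc"),
    "leb-lactoside": "Fuca1-2Galb1-3[Fuca1-4]GlcNAcb1-3Galb1-4Glc",
    "globo-h": "Fuca1-2Galb1-3GalNAcb1-3Gala1-4Galb1-4Glc",
    "gpi-core": "Mana1-2Mana1-6Mana1-4GlcNa",  # root GlcN bonds to inositol O6
    "dolpp-chitobiose": "GlcNAcb1-4GlcNAca",
}

_PROTEIN_CACHE: dict = {}


def protein_sequence(key: str) -> str:
    """Synthetic stand-in sequence from the packaged FASTA fixture."""
    if not _PROTEIN_CACHE:
        text = (resources.files("glycoforge.data") / "synthetic_proteins.fasta"
                ).read_text()
        name, chunks = None, []
        for line in text.splitlines():
            if line.startswith(">"):
                if name:
                    _PROTEIN_CACHE[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip())
        if name:
            _PROTEIN_CACHE[name] = "".join(chunks)
    return _PROTEIN_CACHE[key]

#: Fixture attachment sites (1-based) on the synthetic stand-ins.
EPO_N_SITES = (24, 38, 83)
EPO_O_SER = 126
SIGLEC2_N_SITES = (17, 33, 49, 67, 91, 112, 135, 158, 179, 201, 223)
GPC1_HS_SER = 45
GPC1_CTERM_SER = 120
BIKUNIN_CS_SER = 10
ADG_CORE_M3_THR = 30

#: The GPC1 GPI sidechain sialyl linkage is provisional (alpha-2,3).
PROVISIONAL = {"gpi-gpc1": "sialyl linkage modeled provisionally as alpha-2,3"}


def _free_glycan(name, glycan_key, seeds=(1,)):
    return build_job(name, glycans=[("NG", parse_iupac_condensed(
        GLYCANS[glycan_key]), None)], seeds=seeds)


def _epo_o_glycan(name, glycan_key):
    att = AttachmentSpec("O-Ser", "A", EPO_O_SER)
    return build_job(name,
                     proteins=[("A", protein_sequence("EPO_SYNTHETIC"))],
                     glycans=[("OG1", parse_iupac_condensed(GLYCANS[glycan_key]),
                               att)])


def _t_m9_man1a1():
    return build_job("m9-man1a1",
                     proteins=[("A", protein_sequence("MAN1A1_SYNTHETIC"))],
                     glycans=[("NG", parse_iupac_condensed(GLYCANS["m9"]), None)],
                     ions=[("CA", "CA")])


def _t_hs_linker():
    att = AttachmentSpec("O-Ser", "A", GPC1_HS_SER)
    return build_job("hs-linker-gpc1",
                     proteins=[("A", protein_sequence("GPC1_SYNTHETIC"))],
                     glycans=[("OG1", parse_iupac_condensed(GLYCANS["hs-linker"]),
                               att)],
                     seeds=HARD_SEEDS)


def _t_cs_linker():
    att = AttachmentSpec("O-Ser", "A", BIKUNIN_CS_SER)
    return build_job("cs-linker-bikunin",
                     proteins=[("A", protein_sequence("BIKUNIN_SYNTHETIC"))],
                     glycans=[("OG1", parse_iupac_condensed(GLYCANS["cs-linker"]),
                               att)],
                     seeds=HARD_SEEDS)


def _t_core_m3():
    att = AttachmentSpec("O-Thr", "A", ADG_CORE_M3_THR)
    return build_job("core-m3-adg",
                     proteins=[("A", protein_sequence("ADG_SYNTHETIC"))],
                     glycans=[("OG1", parse_iupac_condensed(GLYCANS["core-m3"]),
                               att)])


def _t_gsl(name, glycan_key):
    # ceramide assembled from sphingosine + stearic acid with an amide bond
    att = AttachmentSpec("lipid", "CR", 1, "O1")
    return build_job(name,
                     ligand_blocks=[("CR", ["SPH", "STE"])],
                     glycans=[("NG", parse_iupac_condensed(GLYCANS[glycan_key]),
                               att)],
                     extra_bonds=[(("CR", 1, "N"), ("CR", 2, "C1"))])


def _t_globoh_bc2lc():
    proteins = [(pid, protein_sequence("BC2LC_SYNTHETIC"))
                for pid in ("A", "B", "C")]
    blocks, glycans, bonds = [], [], []
    for i, suffix in enumerate(("", "2", "3")):
        cid = f"CR{suffix}"
        gid = "NG" if not suffix else f"NG{suffix}"
        blocks.append((cid, ["SPH", "STE"]))
        bonds.append(((cid, 1, "N"), (cid, 2, "C1")))
        glycans.append((gid, parse_iupac_condensed(GLYCANS["globo-h"]),
                        AttachmentSpec("lipid", cid, 1, "O1")))
    return build_job("globoh-bc2lc", proteins=proteins, ligand_blocks=blocks,
                     glycans=glycans, extra_bonds=bonds)


def _t_dolpp_alg1():
    att = AttachmentSpec("lipid", "LL", 1, "O1")
    return build_job("dolpp-chitobiose-alg1",
                     proteins=[("A", protein_sequence("ALG1_SYNTHETIC"))],
                     ions=[("MN", "MN")],
                     ligand_blocks=[("LL", ["OTP"]), ("GD", ["GDM"])],
                     glycans=[("NG", parse_iupac_condensed(
                         GLYCANS["dolpp-chitobiose"]), att)])


def _t_gpi_gpc1(linkage_strategy: str = "bap"):
    """GPI-anchored glypican-1.

    The anchor is assembled from IPD + GOL + PL3 + STE; the
    phosphoethanolamine bridge from ETA + PO4 (the bridging phosphate loses
    two of its own oxygens).  ``linkage_strategy`` selects how the
    protein-EtN bond is expressed: ``"bap"`` (default) emits an explicit
    bonded pair to the C-terminal serine backbone carbonyl; ``"ptm"`` records
    a protein modification instead.
    """
    seq = protein_sequence("GPC1_SYNTHETIC")
    glycan = parse_iupac_condensed(GLYCANS["gpi-core"])
    att = AttachmentSpec("lipid", "AN", 1, "O6")
    strips = [("PO4", ["O1", "O2"])]
    extra = [
        (("AN", 1, "O2"), ("AN", 2, "C1")),   # inositol -> glycerol
        (("AN", 2, "O3"), ("AN", 3, "C1")),   # glycerol -> palmityl alcohol
        (("AN", 2, "O2"), ("AN", 4, "C1")),   # glycerol -> stearate ester
        (("EP", 1, "O"), ("EP", 2, "P")),     # ethanolamine -> phosphate
        (("NG", 4, "O6"), ("EP", 2, "P")),    # phosphate -> terminal Man O6
    ]
    protein_spec = ("A", seq)
    if linkage_strategy == "ptm":
        protein_spec = ("A", seq, [("PTM_GPI_ETA", GPC1_CTERM_SER)])
    else:
        extra.append((("A", GPC1_CTERM_SER, "C"), ("EP", 1, "N")))
    return build_job("gpi-gpc1",
                     proteins=[protein_spec],
                     ligand_blocks=[("AN", ["IPD", "GOL", "PL3", "STE"]),
                                    ("EP", ["ETA", "PO4"])],
                     glycans=[("NG", glycan, att)],
                     extra_bonds=extra,
                     seeds=HARD_SEEDS,
                     user_ccd_strips=strips)


def _t_siglec2_full_pair():
    """Two Siglec-2 molecules, each carrying one G2S2 per annotated sequon."""
    seq = protein_sequence("SIGLEC2_SYNTHETIC")
    glycans = []
    counter = 0
    for chain in ("A", "B"):
        for site in SIGLEC2_N_SITES:
            counter += 1
            gid = "NG" if counter == 1 else f"NG{counter}"
            glycans.append((gid, parse_iupac_condensed(GLYCANS["g2s2"]),
                            AttachmentSpec("N-linked", chain, site)))
    return build_job("siglec2-full-pair",
                     proteins=[("A", seq), ("B", seq)],
                     glycans=glycans)


_CATALOG = {
    "lnnt": lambda: _free_glycan("lnnt", "lnnt"),
    "m9": lambda: _free_glycan("m9", "m9"),
    "a1": lambda: _free_glycan("a1", "a1"),
    "g2": lambda: _free_glycan("g2", "g2"),
    "g2f": lambda: _free_glycan("g2f", "g2f"),
    "g2s2": lambda: _free_glycan("g2s2", "g2s2"),
    "g2s2-6s": lambda: _free_glycan("g2s2-6s", "g2s2-6s"),
    "m9-man1a1": _t_m9_man1a1,
    "o-core1": lambda: _epo_o_glycan("o-core1-epo", "o-core1"),
    "o-core2": lambda: _epo_o_glycan("o-core2-epo", "o-core2"),
    "o-core3": lambda: _epo_o_glycan("o-core3-epo", "o-core3"),
    "o-core4": lambda: _epo_o_glycan("o-core4-epo", "o-core4"),
    "disialyl-core1": lambda: _epo_o_glycan("disialyl-core1-epo", "disialyl-core1"),
    "ks-core2": lambda: _epo_o_glycan("ks-core2-epo", "ks-core2"),
    "hs-linker": _t_hs_linker,
    "cs-linker": _t_cs_linker,
    "core-m3": _t_core_m3,
    "gp1c": lambda: _t_gsl("gp1c", "gp1c"),
    "leb-lactoside": lambda: _t_gsl("leb-lactoside", "leb-lactoside"),
    "globoh-bc2lc": _t_globoh_bc2lc,
    "dolpp-chitobiose-alg1": _t_dolpp_alg1,
    "gpi-gpc1": _t_gpi_gpc1,
    "siglec2-full-pair": _t_siglec2_full_pair,
}


def template_names() -> list:
    return sorted(_CATALOG)


def template(name: str) -> AF3Job:
    """Fully built job for a catalog template; raises with the catalog
    listing on an unknown name."""
    builder = _CATALOG.get(name)
    if builder is None:
        raise JobError(f"unknown template {name!r}; catalog: "
                       + ", ".join(template_names()))
    return builder()
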