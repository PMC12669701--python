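"""Curated gene-panel data for the IRD cohort model.

The default panel abstracts a PanelApp-style IRD gene panel down to the
genes that actually carry diagnoses in a Singaporean multi-ethnic cohort:
per-phenotype causal-gene pools with observed proband counts, per-gene
inheritance modes, each gene's known clinical-disease spectrum (an
HPO/RetNet-style gene-to-phenotype mapping), and recurrent-variant pools
for the genes with strong founder effects in East / Southeast Asian
populations (EYS, USH2A, CYP4V2, PRPH2).

A gene can appear in the causal pool of a phenotype that is *not* in its
disease spectrum: that models the real situation where the presenting
clinical diagnosis is later refined by the molecular finding (e.g. a PEX6
Zellweger-spectrum variant in a patient initially diagnosed with Usher
syndrome).  Such cases are counted as genotype-phenotype discordant.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "Inheritance",
    "PHENOTYPE_COUNTS",
    "PHENOTYPE_POOLS",
    "INHERITANCE",
    "GENE_SPECTRUM",
    "VARIANT_POOLS",
    "PANEL_GENES",
    "default_gene_models",
]


class Inheritance(str, Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"
    MITOCHONDRIAL = "mitochondrial"


# Phenotype label -> (solved probands, total probands) in the reference
# cohort of 506 unrelated probands.  "other" aggregates rare diagnoses
# carried by a handful of probands each.
PHENOTYPE_COUNTS: dict[str, tuple[int, int]] = {
    "retinitis_pigmentosa": (124, 289),
    "cone_rod_dystrophy": (29, 57),
    "macular_dystrophy": (8, 20),
    "usher_syndrome": (14, 25),
    "bardet_biedl_syndrome": (5, 5),
    "leber_congenital_amaurosis": (6, 8),
    "stargardt_disease": (27, 43),
    "bietti_crystalline_dystrophy": (10, 11),
    "knobloch_syndrome": (1, 1),
    "achromatopsia": (1, 1),
    "alstrom_syndrome": (1, 1),
    "occult_macular_dystrophy": (1, 2),
    "pprca": (1, 3),
    "pattern_dystrophy": (3, 3),
    "pseudoxanthoma_elasticum": (1, 1),
    "vitelliform_dystrophy": (5, 8),
    "enhanced_s_cone_syndrome": (1, 1),
    "foveal_hypoplasia": (1, 1),
    "choroideremia": (3, 3),
    "retinoschisis": (4, 7),
    "other": (0, 16),
}

# Causal-gene pools per initial clinical diagnosis, weighted by the number
# of solved probands attributed to each gene.
PHENOTYPE_POOLS: dict[str, list[tuple[str, int]]] = {
    "retinitis_pigmentosa": [
        ("USH2A", 30), ("EYS", 28), ("RHO", 9), ("RPGR", 7), ("PRPH2", 6),
        ("RP1", 5), ("MFSD8", 3), ("CRX", 2), ("IFT140", 2), ("PDE6A", 2),
        ("PDE6B", 2), ("RP1L1", 2), ("ABCC6", 1), ("C21orf2", 1), ("CHM", 1),
        ("CLN3", 1), ("CNGA1", 1), ("CYP4V2", 1), ("FAM161A", 1), ("HK1", 1),
        ("IMPDH1", 1), ("KLHL7", 1), ("MT-ATP6", 1), ("MYO7A", 1), ("NRL", 1),
        ("PCDH15", 1), ("PRPF3", 1), ("PRPF31", 1), ("REEP6", 1),
        ("RLBP1", 1), ("RP2", 1), ("SLC24A1", 1), ("SNRNP200", 1),
        ("SPATA7", 1), ("TOPORS", 1), ("TULP1", 1), ("WDR19", 1),
        ("ZNF408", 1),
    ],
    "cone_rod_dystrophy": [
        ("GUCY2D", 6), ("ABCA4", 3), ("CRX", 3), ("PRPH2", 3), ("PROM1", 2),
        ("C21orf2", 1), ("CACNA2D4", 1), ("CNGA3", 1), ("CRB1", 1),
        ("EYS", 1), ("HK1", 1), ("MYO7A", 1), ("RCBTB1", 1), ("RP1", 1),
        ("RP2", 1), ("RPGR", 1), ("TTLL5", 1),
    ],
    "macular_dystrophy": [
        ("ABCA4", 1), ("CFH", 1), ("CNGB3", 1), ("CRX", 1), ("PROM1", 1),
        ("PRPH2", 1), ("RDH12", 1), ("RP1", 1),
    ],
    "usher_syndrome": [
        ("USH2A", 10), ("ADGRV1", 1), ("COL2A1", 1), ("EYS", 1), ("PEX6", 1),
    ],
    "bardet_biedl_syndrome": [
        ("BBS2", 2), ("ARL6", 1), ("BBS10", 1), ("MKKS", 1),
    ],
    "leber_congenital_amaurosis": [
        ("CRB1", 4), ("PROM1", 1), ("RPGRIP1", 1),
    ],
    "stargardt_disease": [
        ("ABCA4", 24), ("PRPH2", 2), ("RP1L1", 1),
    ],
    "bietti_crystalline_dystrophy": [
        ("CYP4V2", 9), ("PRPH2", 1),
    ],
    "knobloch_syndrome": [("COL18A1", 1)],
    "achromatopsia": [("CNGA3", 1)],
    "alstrom_syndrome": [("ALMS1", 1)],
    "occult_macular_dystrophy": [("RP1L1", 1)],
    "pprca": [("RDH12", 1)],
    "pattern_dystrophy": [("PRPH2", 3)],
    "pseudoxanthoma_elasticum": [("ABCC6", 1)],
    "vitelliform_dystrophy": [("BEST1", 5)],
    "enhanced_s_cone_syndrome": [("NR2E3", 1)],
    "foveal_hypoplasia": [("PAX6", 1)],
    "choroideremia": [("CHM", 3)],
    "retinoschisis": [("RS1", 4)],
    "other": [("PAX6", 1), ("BEST1", 1)],
}

INHERITANCE: dict[str, Inheritance] = {
    "ABCA4": Inheritance.AUTOSOMAL_RECESSIVE,
    "ABCC6": Inheritance.AUTOSOMAL_RECESSIVE,
    "ADGRV1": Inheritance.AUTOSOMAL_RECESSIVE,
    "ALMS1": Inheritance.AUTOSOMAL_RECESSIVE,
    "ARL6": Inheritance.AUTOSOMAL_RECESSIVE,
    "BBS10": Inheritance.AUTOSOMAL_RECESSIVE,
    "BBS2": Inheritance.AUTOSOMAL_RECESSIVE,
    "BEST1": Inheritance.AUTOSOMAL_DOMINANT,
    "C21orf2": Inheritance.AUTOSOMAL_RECESSIVE,
    "CACNA2D4": Inheritance.AUTOSOMAL_RECESSIVE,
    "CFH": Inheritance.AUTOSOMAL_DOMINANT,
    "CHM": Inheritance.X_LINKED,
    "CLN3": Inheritance.AUTOSOMAL_RECESSIVE,
    "CNGA1": Inheritance.AUTOSOMAL_RECESSIVE,
    "CNGA3": Inheritance.AUTOSOMAL_RECESSIVE,
    "CNGB3": Inheritance.AUTOSOMAL_RECESSIVE,
    "COL18A1": Inheritance.AUTOSOMAL_RECESSIVE,
    "COL2A1": Inheritance.AUTOSOMAL_DOMINANT,
    "CRB1": Inheritance.AUTOSOMAL_RECESSIVE,
    "CRX": Inheritance.AUTOSOMAL_DOMINANT,
    "CYP4V2": Inheritance.AUTOSOMAL_RECESSIVE,
    "EYS": Inheritance.AUTOSOMAL_RECESSIVE,
    "FAM161A": Inheritance.AUTOSOMAL_RECESSIVE,
    "GUCY2D": Inheritance.AUTOSOMAL_DOMINANT,
    "HK1": Inheritance.AUTOSOMAL_DOMINANT,
    "IFT140": Inheritance.AUTOSOMAL_RECESSIVE,
    "IMPDH1": Inheritance.AUTOSOMAL_DOMINANT,
    "KLHL7": Inheritance.AUTOSOMAL_DOMINANT,
    "MFSD8": Inheritance.AUTOSOMAL_RECESSIVE,
    "MKKS": Inheritance.AUTOSOMAL_RECESSIVE,
    "MT-ATP6": Inheritance.MITOCHONDRIAL,
    "MYO7A": Inheritance.AUTOSOMAL_RECESSIVE,
    "NR2E3": Inheritance.AUTOSOMAL_RECESSIVE,
    "NRL": Inheritance.AUTOSOMAL_DOMINANT,
    "PAX6": Inheritance.AUTOSOMAL_DOMINANT,
    "PCDH15": Inheritance.AUTOSOMAL_RECESSIVE,
    "PDE6A": Inheritance.AUTOSOMAL_RECESSIVE,
    "PDE6B": Inheritance.AUTOSOMAL_RECESSIVE,
    "PEX6": Inheritance.AUTOSOMAL_RECESSIVE,
    "PROM1": Inheritance.AUTOSOMAL_DOMINANT,
    "PRPF3": Inheritance.AUTOSOMAL_DOMINANT,
    "PRPF31": Inheritance.AUTOSOMAL_DOMINANT,
    "PRPH2": Inheritance.AUTOSOMAL_DOMINANT,
    "RCBTB1": Inheritance.AUTOSOMAL_RECESSIVE,
    "RDH12": Inheritance.AUTOSOMAL_RECESSIVE,
    "REEP6": Inheritance.AUTOSOMAL_RECESSIVE,
    "RHO": Inheritance.AUTOSOMAL_DOMINANT,
    "RLBP1": Inheritance.AUTOSOMAL_RECESSIVE,
    "RP1": Inheritance.AUTOSOMAL_DOMINANT,
    "RP1L1": Inheritance.AUTOSOMAL_DOMINANT,
    "RP2": Inheritance.X_LINKED,
    "RPGR": Inheritance.X_LINKED,
    "RPGRIP1": Inheritance.AUTOSOMAL_RECESSIVE,
    "RS1": Inheritance.X_LINKED,
    "SLC24A1": Inheritance.AUTOSOMAL_RECESSIVE,
    "SNRNP200": Inheritance.AUTOSOMAL_DOMINANT,
    "SPATA7": Inheritance.AUTOSOMAL_RECESSIVE,
    "TOPORS": Inheritance.AUTOSOMAL_DOMINANT,
    "TTLL5": Inheritance.AUTOSOMAL_RECESSIVE,
    "TULP1": Inheritance.AUTOSOMAL_RECESSIVE,
    "USH2A": Inheritance.AUTOSOMAL_RECESSIVE,
    "WDR19": Inheritance.AUTOSOMAL_RECESSIVE,
    "ZNF408": Inheritance.AUTOSOMAL_DOMINANT,
}

# Disease-spectrum overrides: genes whose known phenotype spectrum does NOT
# include one or more of the presenting diagnoses they appear under.  For
# every other gene the spectrum is the union of the pools it appears in.
_SPECTRUM_OVERRIDES: dict[str, set[str]] = {
    # Peroxisomal / connective-tissue genes masquerading as Usher syndrome.
    "PEX6": {"zellweger_spectrum_disorder"},
    "COL2A1": {"stickler_syndrome"},
    # Neuronal ceroid lipofuscinoses presenting as retinitis pigmentosa.
    "CLN3": {"neuronal_ceroid_lipofuscinosis"},
    "MFSD8": {"neuronal_ceroid_lipofuscinosis"},
    # ABCC6 retinopathy is secondary to pseudoxanthoma elasticum.
    "ABCC6": {"pseudoxanthoma_elasticum"},
    # Rod-dominant genes picked up under cone/cone-rod presentations.
    "EYS": {"retinitis_pigmentosa"},
    "MYO7A": {"usher_syndrome", "retinitis_pigmentosa"},
    "CRB1": {"leber_congenital_amaurosis", "retinitis_pigmentosa"},
    "HK1": {"retinitis_pigmentosa"},
    "C21orf2": {"retinitis_pigmentosa"},
    "RP2": {"retinitis_pigmentosa"},
    "RCBTB1": {"retinitis_pigmentosa"},
    # RDH12 causes LCA / early severe dystrophy, not adult macular disease.
    "RDH12": {"leber_congenital_amaurosis", "retinitis_pigmentosa"},
    "CFH": {"age_related_macular_degeneration"},
    # RP1L1: occult macular dystrophy and dominant RP, not Stargardt-like
    # or crystalline disease.
    "RP1L1": {"occult_macular_dystrophy", "retinitis_pigmentosa"},
    "PRPH2": {
        "retinitis_pigmentosa", "cone_rod_dystrophy", "macular_dystrophy",
        "pattern_dystrophy", "stargardt_disease",
    },
    "PAX6": {"foveal_hypoplasia", "other"},
    "BEST1": {"vitelliform_dystrophy", "other"},
}


def _build_spectrum() -> dict[str, set[str]]:
    spectrum: dict[str, set[str]] = {}
    for phenotype, pool in PHENOTYPE_POOLS.items():
        for gene, _ in pool:
            spectrum.setdefault(gene, set()).add(phenotype)
    spectrum.update({g: set(s) for g, s in _SPECTRUM_OVERRIDES.items()})
    return spectrum


#: Gene -> set of clinical diagnoses in its known disease spectrum.
GENE_SPECTRUM: dict[str, set[str]] = _build_spectrum()

#: All panel genes.
PANEL_GENES: frozenset[str] = frozenset(INHERITANCE)

# Recurrent-variant pools: gene -> list of (hgvs_c, hgvs_p, weight).  The
# weight is the share of gene-solved probands carrying the variant; the
# special entry hgvs_c=None is the residual mass of private variants, which
# the generator synthesises as unique alleles.
VARIANT_POOLS: dict[str, list[tuple[str | None, str, int]]] = {
    "EYS": [
        ("c.6416G>A", "p.Cys2139Tyr", 20),
        ("c.8107G>T", "p.Glu2703Ter", 8),
        (None, "", 2),
    ],
    "USH2A": [
        ("c.2802T>G", "p.Cys934Trp", 14),
        ("c.8559-2A>G", "", 4),
        ("c.15178T>C", "p.Ser5060Pro", 4),
        (None, "", 18),
    ],
    "CYP4V2": [
        ("c.802-8_810del17insGC", "", 8),
        (None, "", 2),
    ],
    "PRPH2": [
        ("c.514C>T", "p.Arg172Trp", 4),
        ("c.533A>G", "p.Gln178Arg", 3),
        (None, "", 8),
    ],
}

#: Preferred second allele for CYP4V2 founder-variant compound heterozygotes.
CYP4V2_PARTNER = ("c.992A>C", "p.His331Pro")


def default_gene_models():
    """Build the default gene -> GeneModel mapping for case resolution.

    Imported lazily to avoid a circular import with :mod:`.resolution`.
    """
    from .resolution import GeneModel

    return {
        gene: GeneModel(
            gene=gene,
            inheritance=INHERITANCE[gene],
            phenotypes=frozenset(GENE_SPECTRUM.get(gene, set())),
        )
        for gene in INHERITANCE
    }
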