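"""Built-in gene-set catalogue for the glyco-code analysis.

The fucosylation sets are the literal gene lists the analysis is built
around: GDP-fucose synthesis (GMDS, TSTA3), the fucosyltransferases
(FUT2, FUT3, FUT4, FUT6), their union, and the O-fucosylation machinery
(POFUT1/2, the Fringe family, B3GLCT, B4GALT1, ST6GAL1).  The remaining
glyco-pathway sets (O-glycan initiation/extension, sialylation, galectins,
N-glycosylation) and the epithelial/mesenchymal EMT sets are compact
curated stand-ins sized for synthetic data; on real data users supply
their own GMTs.
"""

from __future__ import annotations

from .io import GeneSet, GeneSetCollection

__all__ = [
    "O_FUCOSYLATION",
    "FUC_SYNTHESIS",
    "FUC_TRANSFERASES",
    "FUC_ALL",
    "EPITHELIAL",
    "MESENCHYMAL",
    "make_glyco_catalog",
]

O_FUCOSYLATION = ("LFNG", "MFNG", "RFNG", "B3GLCT", "B4GALT1", "ST6GAL1", "POFUT2", "POFUT1")
FUC_SYNTHESIS = ("GMDS", "TSTA3")
FUC_TRANSFERASES = ("FUT2", "FUT3", "FUT4", "FUT6")
FUC_ALL = FUC_SYNTHESIS + FUC_TRANSFERASES

O_GLYCAN_INITIATION = ("GALNT3", "GALNT4", "GALNT6", "GALNT7")
O_GLYCAN_EXTENSION = ("MUC1", "MUC13", "MUC17", "MUC20", "C1GALT1", "GCNT3")
SIALYLATION = ("ST3GAL1", "ST3GAL4", "ST6GALNAC1", "NEU1")
GALECTINS = ("LGALS1", "LGALS3", "LGALS4", "LGALS9")
N_GLYCOSYLATION = ("MGAT1", "MGAT3", "MGAT5", "ALG3")
BASAL_MARKERS = ("LGALS1", "MUC4", "MUC16")

EPITHELIAL = ("CDH1", "EPCAM", "LGALS4", "KRT8", "KRT18", "KRT19", "CLDN4", "TFF1")
MESENCHYMAL = ("VIM", "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "FN1", "CDH2")


def make_glyco_catalog() -> GeneSetCollection:
    """Return the glyco-code gene-set collection used throughout the pipeline.

    Guaranteed contents: ``O_FUCOSYLATION`` (8 genes), ``FUC_SYNTHESIS``
    (GMDS, TSTA3), ``FUC_TRANSFERASES`` (FUT2/3/4/6), ``FUC_ALL`` (their
    union, 6 genes), the glyco-pathway division sets, and the
    ``EPITHELIAL`` / ``MESENCHYMAL`` EMT sets.  Round-trips through GMT.
    """
    collection = GeneSetCollection()
    entries = [
        ("O_FUCOSYLATION", "O-fucosylation machinery", O_FUCOSYLATION),
        ("FUC_SYNTHESIS", "GDP-fucose synthesis", FUC_SYNTHESIS),
        ("FUC_TRANSFERASES", "Fucosyltransferases", FUC_TRANSFERASES),
        ("FUC_ALL", "GDP-fucose synthesis plus fucosyltransferases", FUC_ALL),
        ("O_GLYCAN_INITIATION", "O-glycan initiation (GalNAc transferases)", O_GLYCAN_INITIATION),
        ("O_GLYCAN_EXTENSION", "O-glycan extension and mucins", O_GLYCAN_EXTENSION),
        ("SIALYLATION", "Sialylation", SIALYLATION),
        ("GALECTINS", "Galectins", GALECTINS),
        ("N_GLYCOSYLATION", "N-glycosylation", N_GLYCOSYLATION),
        ("BASAL_MARKERS", "Basal-subtype markers", BASAL_MARKERS),
        ("EPITHELIAL", "Epithelial EMT pole", EPITHELIAL),
        ("MESENCHYMAL", "Mesenchymal EMT pole", MESENCHYMAL),
    ]
    for name, description, members in entries:
        collection.add(GeneSet(name, description, tuple(members)))
    return collection
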