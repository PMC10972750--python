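"""Cell-type catalogue: per-type mean diameters, lineages and stage order.

The diameters are the manually measured in-situ values (mean ± s.d., µm) for
each segmented haematopoietic stage; they drive every radius correction in
the distance analyses.  When a cell record carries no measured radius, the
catalogue mean radius for its type is substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SchemaError

__all__ = [
    "CellTypeInfo",
    "CELL_TYPE_CATALOG",
    "AUXILIARY_TYPES",
    "KNOWN_TYPES",
    "HSPC_TYPES",
    "CONFETTI_COLOURS",
    "mean_radius",
    "lineage_of",
]


@dataclass(frozen=True)
class CellTypeInfo:
    """Catalogue entry for one haematopoietic stage."""

    diameter_um: float       # mean measured diameter
    diameter_sd_um: float    # s.d. of the measured diameter
    lineage: str             # multipotent / erythroid / B / neutrophil / monoDC
    stage_order: int         # ordinal position within its lineage

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


# The 22 measured stages.  Diameters are in µm.
CELL_TYPE_CATALOG: dict[str, CellTypeInfo] = {
    "CD41- LT-HSC":      CellTypeInfo(8.67, 1.23, "multipotent", 0),
    "CD41+ LT-HSC":      CellTypeInfo(8.94, 0.91, "multipotent", 0),
    "ST-HSC":            CellTypeInfo(8.68, 1.10, "multipotent", 1),
    "MPP2":              CellTypeInfo(7.98, 1.05, "multipotent", 2),
    "MPP3":              CellTypeInfo(8.48, 1.32, "multipotent", 2),
    "MkP":               CellTypeInfo(14.45, 3.88, "multipotent", 3),
    "pre Meg-E":         CellTypeInfo(9.49, 1.34, "multipotent", 3),
    "pre CFU-E":         CellTypeInfo(13.92, 1.70, "erythroid", 0),
    "CFU-E":             CellTypeInfo(12.67, 1.88, "erythroid", 1),
    "early erythroblast": CellTypeInfo(8.86, 1.61, "erythroid", 2),
    "late erythroblast": CellTypeInfo(7.92, 1.36, "erythroid", 3),
    "reticulocyte":      CellTypeInfo(5.17, 0.76, "erythroid", 4),
    "RBC":               CellTypeInfo(4.38, 0.60, "erythroid", 5),
    "CLP":               CellTypeInfo(7.40, 0.97, "B", 0),
    "pre-pro B":         CellTypeInfo(8.90, 0.61, "B", 1),
    "pro B":             CellTypeInfo(7.71, 1.23, "B", 2),
    "pre B":             CellTypeInfo(6.10, 0.61, "B", 3),
    "MDP":               CellTypeInfo(12.13, 1.19, "monoDC", 0),
    "GP":                CellTypeInfo(11.70, 0.99, "neutrophil", 0),
    "PN":                CellTypeInfo(10.21, 1.08, "neutrophil", 1),
    "monocyte":          CellTypeInfo(9.30, 1.17, "monoDC", 1),
    "cDC":               CellTypeInfo(12.33, 2.69, "monoDC", 1),
}

# Working types that are not part of the measured 22: megakaryocytes are
# large niche cells segmented as surfaces, and "hematopoietic" is the
# type-agnostic background pool (all CD45+/Ter119+ positions) that the
# random-placement null resamples.
AUXILIARY_TYPES: dict[str, CellTypeInfo] = {
    "MK":            CellTypeInfo(30.0, 8.0, "niche", 0),
    "hematopoietic": CellTypeInfo(7.0, 2.0, "pool", 0),
}

KNOWN_TYPES: dict[str, CellTypeInfo] = {**CELL_TYPE_CATALOG, **AUXILIARY_TYPES}

# Multipotent / oligopotent progenitors analysed as dispersed single cells.
HSPC_TYPES: tuple[str, ...] = (
    "CD41- LT-HSC",
    "CD41+ LT-HSC",
    "ST-HSC",
    "MPP2",
    "MPP3",
    "MkP",
    "pre Meg-E",
)

CONFETTI_COLOURS: tuple[str, ...] = ("GFP", "YFP", "RFP", "CFP")


def mean_radius(cell_type: str) -> float:
    """Catalogue mean radius (µm) for *cell_type*; raises on unknown types."""
    try:
        return KNOWN_TYPES[cell_type].radius_um
    except KeyError:
        raise SchemaError(f"unknown cell type: {cell_type!r}") from None


def lineage_of(cell_type: str) -> str:
    try:
        return KNOWN_TYPES[cell_type].lineage
    except KeyError:
        raise SchemaError(f"unknown cell type: {cell_type!r}") from None
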