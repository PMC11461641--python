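"""Marker-gene signatures and the mitochondrial gene list.

Cell-type signatures combine canonical mammalian markers (CD68, TNNT2, ...)
with a handful of synthetic placeholder symbols so that the generator, the
bulk scoring stage and the nucleus annotation stage share one gene universe.
Users can supply their own ``SignatureSet`` (e.g. atlas-derived markers) via
two-column delimited files, see :mod:`fdgmismatch.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: The 13 protein-coding genes of the mitochondrial genome. Counts on these
#: genes define the per-nucleus mitochondrial fraction used in QC.
MITO_GENES: tuple[str, ...] = (
    "ND1", "ND2", "ND3", "ND4", "ND5", "ND6", "ND4L",
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
)


@dataclass(frozen=True)
class SignatureSet:
    """Mapping of cell type -> nonempty marker-gene list.

    Parameters
    ----------
    signatures
        Dict of cell-type name to list of marker gene symbols.
    provenance
        Free-text tag recording where the markers came from.
    """

    signatures: dict[str, list[str]]
    provenance: str = "builtin"

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValidationError("SignatureSet requires at least one cell type")
        for ct, genes in self.signatures.items():
            if not genes:
                raise ValidationError(f"signature for {ct!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"signature for {ct!r} has duplicate genes")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures)

    def genes(self) -> list[str]:
        """All marker genes, deduplicated, in first-seen order."""
        seen: dict[str, None] = {}
        for genes in self.signatures.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def __getitem__(self, cell_type: str) -> list[str]:
        return self.signatures[cell_type]


def _expand(cell_type: str, named: list[str], n_synthetic: int = 3) -> list[str]:
    tag = cell_type.upper().replace(" ", "")[:6]
    return named + [f"{tag}S{i}" for i in range(1, n_synthetic + 1)]


#: Immune signatures used for bulk abundance scoring.
IMMUNE_SIGNATURES = SignatureSet(
    {
        "Monocytes": _expand("Monocytes", ["CD14", "VCAN", "FCN1"]),
        "Macrophages": _expand("Macrophages", ["CD68", "MRC1", "CD163"]),
        "Neutrophils": _expand("Neutrophils", ["S100A8", "S100A9", "FCGR3B"]),
        "T cells": _expand("Tcells", ["CD3E", "CD3D", "CD2"]),
        "NK cells": _expand("NKcells", ["NKG7", "GNLY", "KLRD1"]),
        "B cells": _expand("Bcells", ["CD79A", "CD79B", "MS4A1"]),
    },
    provenance="builtin immune panel",
)

#: Full-tissue signatures used for nucleus annotation and counting.
CELL_TYPE_SIGNATURES = SignatureSet(
    {
        "Cardiomyocytes": _expand("Cardiomyocytes", ["TNNT2", "TNNI3", "MYH7", "RYR2"]),
        "Fibroblasts": _expand("Fibroblasts", ["COL1A1", "DCN", "PDGFRA"]),
        "Endothelial cells": _expand("Endothelial", ["PECAM1", "VWF", "CDH5"]),
        "Pericytes": _expand("Pericytes", ["RGS5", "KCNJ8", "ABCC9"]),
        "Smooth muscle cells": _expand("SMC", ["MYH11", "ACTA2", "TAGLN"]),
        "Monocytes": _expand("Monocytes", ["CD14", "VCAN", "FCN1"]),
        "Macrophages": _expand("Macrophages", ["CD68", "MRC1", "CD163"]),
        "Neutrophils": _expand("Neutrophils", ["S100A8", "S100A9", "FCGR3B"]),
        "T cells": _expand("Tcells", ["CD3E", "CD3D", "CD2"]),
        "NK cells": _expand("NKcells", ["NKG7", "GNLY", "KLRD1"]),
        "B cells": _expand("Bcells", ["CD79A", "CD79B", "MS4A1"]),
    },
    provenance="builtin tissue panel",
)
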