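"""The 39-marker multiplexed-immunofluorescence panel and its sub-panels.

Markers fall into two tiers: *phenotypic* markers identify cell lineages
(T/B/NK cells, dendritic-cell subsets, macrophages, melanoma cells, ...),
*functional* markers read out activation, exhaustion and proliferation
state.  Cytotoxic T cells (Tcy, CD3+CD8+) get a personalised functional
sub-panel centred on the four activation/exhaustion markers.
"""

from __future__ import annotations

#: Markers used for lineage (phenotype) identification.
PHENOTYPIC_MARKERS: tuple[str, ...] = (
    "CD3", "CD20", "CD4", "HLA-DR", "Bcl6", "CD16", "CD68", "CD56",
    "CD141", "CD1a", "CD1c", "Blimp1", "Langerin", "Lysozyme",
    "Podoplanin", "FOXP3", "S100AB", "IRF4", "IRF8", "CXCL13",
    "CD8", "CD138", "CD123", "PD-1", "MelanA",
)

#: Markers used for functional sub-clustering within a lineage.
FUNCTIONAL_MARKERS: tuple[str, ...] = (
    "CD69", "Ki-67", "TAP2", "GBP1", "MYC", "p16", "MX1", "OX40",
    "c-Maf", "PD-L1", "LAG3", "TIM3", "Phospho-Stat1",
)

#: Personalised functional panel for cytotoxic T cells.
TCY_FUNCTIONAL_MARKERS: tuple[str, ...] = (
    "CD8", "CD69", "OX40", "LAG3", "TIM3", "PD-1", "Ki-67",
)

#: The two activation and two exhaustion markers scored on CD8+ cells,
#: in the canonical order expected by the activation model.
ACTIVATION_MARKERS: tuple[str, str, str, str] = ("CD69", "OX40", "LAG3", "TIM3")

#: Full panel (phenotypic + functional + CD163 used for macrophage calls).
PANEL: tuple[str, ...] = PHENOTYPIC_MARKERS + FUNCTIONAL_MARKERS + ("CD163",)

#: Prefix for z-score columns in a cell table.
Z_PREFIX = "z_"


def z_cols(markers) -> list[str]:
    """Z-score column names for a list of markers."""
    return [Z_PREFIX + m for m in markers]
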