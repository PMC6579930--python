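"""Staining panel definition for the 18-color whole-blood DC panel.

The panel identifies five dendritic-cell subsets (pDC, cDC1, cDC2, slanDC,
moDC) in whole blood and reads out three costimulatory molecules (CD40,
CD80, CD86) and three immune checkpoints (PD-L1, ILT2, TIM-3) per subset.
21 antibody stains resolve to 18 fluorescence detectors because the four
lineage-dump antibodies (CD3/CD19/CD20/CD56) share the FITC detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: roles a marker can play in the analysis
ROLES = (
    "pan_leukocyte",      # CD45: pre-filter for the embedding, not gated in the tree
    "lineage",            # FITC dump (CD3/CD19/CD20/CD56): excluded in both branches
    "lineage_conditional",  # CD14/CD16: excluded for DC-lineage DCs only
    "subset",             # identity markers of the gating tree
    "costim",             # activation read-outs
    "checkpoint",         # inhibitory read-outs
    "viability",          # dead-cell exclusion stain
)

#: markers whose FMO controls define net-MFI backgrounds
READOUT_MARKERS = ("CD40", "CD80", "CD86", "PD-L1", "ILT2", "TIM-3")

#: marker set entering the t-SNE embedding (identity + read-outs; no scatter,
#: no viability, no CD45/lineage which are pre-filters)
EMBED_MARKERS = (
    "CD14", "CD16", "HLA-DR", "CD11c", "CD123", "CD141", "CD1c", "M-DC8",
    "CD1a", "CD40", "CD80", "CD86", "PD-L1", "ILT2", "TIM-3",
)

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

#: (marker, detector, role) — mirrors the antibody/conjugate table of the
#: panel; the pooled FITC dump is carried as a single "Lineage" parameter.
_DEFAULT_MARKERS = [
    ("CD45", "AF700-A", "pan_leukocyte"),
    ("Lineage", "FITC-A", "lineage"),
    ("CD14", "BV570-A", "lineage_conditional"),
    ("CD16", "BUV496-A", "lineage_conditional"),
    ("HLA-DR", "BUV661-A", "subset"),
    ("CD123", "PE-Cy7-A", "subset"),
    ("CD11c", "PE-Cy5-A", "subset"),
    ("CD141", "BV605-A", "subset"),
    ("CD1c", "BV421-A", "subset"),
    ("M-DC8", "APC-A", "subset"),
    ("CD1a", "BUV395-A", "subset"),
    ("CD40", "BV650-A", "costim"),
    ("CD80", "BV510-A", "costim"),
    ("CD86", "BUV737-A", "costim"),
    ("PD-L1", "PE-CF594-A", "checkpoint"),
    ("ILT2", "PE-A", "checkpoint"),
    ("TIM-3", "BV711-A", "checkpoint"),
    ("Viability", "APC-Cy7-A", "viability"),
]

#: antibodies pooled into the "Lineage" FITC dump channel
LINEAGE_COMPONENTS = ("CD3", "CD19", "CD20", "CD56")


@dataclass(frozen=True)
class PanelDefinition:
    """Mapping marker <-> detector channel <-> analysis role.

    ``markers`` is a list of ``(marker_name, detector_channel, role)``
    triples covering the fluorescence parameters; scatter channels are
    carried separately.
    """

    markers: tuple = tuple(_DEFAULT_MARKERS)
    scatter_channels: tuple = SCATTER_CHANNELS
    lineage_components: tuple = LINEAGE_COMPONENTS

    def __post_init__(self):
        names = [m for m, _, _ in self.markers]
        dets = [d for _, d, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        if len(set(dets)) != len(dets):
            raise ValueError("each detector channel may appear at most once")
        for m, d, r in self.markers:
            if r not in ROLES:
                raise ValueError(f"unknown role {r!r} for marker {m}")

    # -- lookups ---------------------------------------------------------
    @property
    def marker_names(self) -> list:
        return [m for m, _, _ in self.markers]

    @property
    def detectors(self) -> list:
        return [d for _, d, _ in self.markers]

    @property
    def n_fluorescence(self) -> int:
        return len(self.markers)

    @property
    def stains(self) -> list:
        """All antibody stains, un-pooling the lineage dump (21 for the
        default panel)."""
        out = []
        for m, _, r in self.markers:
            if r == "lineage":
                out.extend(self.lineage_components)
            else:
                out.append(m)
        return out

    def role_of(self, marker: str) -> str:
        for m, _, r in self.markers:
            if m == marker:
                return r
        raise KeyError(marker)

    def detector_of(self, marker: str) -> str:
        for m, d, _ in self.markers:
            if m == marker:
                return d
        raise KeyError(marker)

    def markers_with_role(self, role: str) -> list:
        return [m for m, _, r in self.markers if r == role]


def default_panel() -> PanelDefinition:
    """The 18-fluorescence-parameter whole-blood DC panel."""
    return PanelDefinition()
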