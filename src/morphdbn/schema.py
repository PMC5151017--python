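"""Canonical feature schema for region-wise brain morphometry tables.

The pipeline's universal data currency is a subjects x 113 feature matrix:
68 mean cortical thickness values (34 Desikan-Killiany regions per
hemisphere, prefixed ``lh_``/``rh_``) followed by 45 subcortical and
whole-structure volumes as emitted by FreeSurfer's ``aseg.stats``
(v5-era structure list).  The order is fixed and versioned here rather
than inferred from input files, so that model weights, reports and
tables written by different runs stay column-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Desikan-Killiany cortical parcellation, one hemisphere, in the row
#: order FreeSurfer writes ``?h.aparc.stats``.
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Anatomical structures in ``aseg.stats`` row order (FreeSurfer v5 list,
#: 45 entries).  Later FreeSurfer versions add or drop rows, hence the pin.
ASEG_STRUCTURES: tuple[str, ...] = (
    "Left-Lateral-Ventricle",
    "Left-Inf-Lat-Vent",
    "Left-Cerebellum-White-Matter",
    "Left-Cerebellum-Cortex",
    "Left-Thalamus-Proper",
    "Left-Caudate",
    "Left-Putamen",
    "Left-Pallidum",
    "3rd-Ventricle",
    "4th-Ventricle",
    "Brain-Stem",
    "Left-Hippocampus",
    "Left-Amygdala",
    "CSF",
    "Left-Accumbens-area",
    "Left-VentralDC",
    "Left-vessel",
    "Left-choroid-plexus",
    "Right-Lateral-Ventricle",
    "Right-Inf-Lat-Vent",
    "Right-Cerebellum-White-Matter",
    "Right-Cerebellum-Cortex",
    "Right-Thalamus-Proper",
    "Right-Caudate",
    "Right-Putamen",
    "Right-Pallidum",
    "Right-Hippocampus",
    "Right-Amygdala",
    "Right-Accumbens-area",
    "Right-VentralDC",
    "Right-vessel",
    "Right-choroid-plexus",
    "5th-Ventricle",
    "WM-hypointensities",
    "Left-WM-hypointensities",
    "Right-WM-hypointensities",
    "non-WM-hypointensities",
    "Left-non-WM-hypointensities",
    "Right-non-WM-hypointensities",
    "Optic-Chiasm",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
)

#: Accepted diagnosis labels: healthy control, chronic schizophrenia,
#: first-episode psychosis.
LABELS: tuple[str, ...] = ("HC", "SCZ", "FEP")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed, versioned ordering of the 113 morphometric features.

    Canonical order is the thickness block (left hemisphere then right,
    atlas order) followed by the volume block (``aseg.stats`` row order).
    """

    thickness_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            f"{hemi}_{region}"
            for hemi in ("lh", "rh")
            for region in DESIKAN_KILLIANY_REGIONS
        )
    )
    volume_names: tuple[str, ...] = field(default_factory=lambda: ASEG_STRUCTURES)

    def __post_init__(self) -> None:
        if len(self.thickness_names) != 68:
            raise ValueError(
                f"expected 68 thickness names, got {len(self.thickness_names)}"
            )
        if len(self.volume_names) != 45:
            raise ValueError(
                f"expected 45 volume names, got {len(self.volume_names)}"
            )
        names = self.canonical_order
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def canonical_order(self) -> tuple[str, ...]:
        """All 113 feature names: thickness block then volume block."""
        return self.thickness_names + self.volume_names

    @property
    def n_features(self) -> int:
        return len(self.canonical_order)

    def index_of(self, name: str) -> int:
        try:
            return self.canonical_order.index(name)
        except ValueError:
            raise KeyError(f"unknown feature name: {name!r}") from None


DEFAULT_SCHEMA = FeatureSchema()
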