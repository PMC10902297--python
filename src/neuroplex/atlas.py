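"""Desikan-Killiany cortical parcellation labels.

The 68-region cortical atlas (34 regions per hemisphere) used as the node
set of the connectome.  Labels follow the FreeSurfer ``aparc`` naming with
an ``lh-``/``rh-`` hemisphere prefix.
"""

from __future__ import annotations

_DK_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
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
    "temporalpole",
    "transversetemporal",
)

#: The 68 Desikan-Killiany cortical labels, left hemisphere first.
DK_LABELS: tuple[str, ...] = tuple(
    f"{hemi}-{region}" for hemi in ("lh", "rh") for region in _DK_REGIONS
)

#: Occipital + parietal regions used by default for alpha-peak detection.
OCCIPITOPARIETAL = tuple(
    f"{hemi}-{region}"
    for hemi in ("lh", "rh")
    for region in (
        "cuneus",
        "pericalcarine",
        "lateraloccipital",
        "lingual",
        "precuneus",
        "superiorparietal",
        "inferiorparietal",
    )
)


def generic_labels(n_rois: int) -> tuple[str, ...]:
    """Return ROI labels for an ``n_rois``-node parcellation.

    The full Desikan-Killiany label set is used when ``n_rois`` is 68;
    otherwise synthetic ``roi-XX`` labels are generated.
    """
    if n_rois == len(DK_LABELS):
        return DK_LABELS
    return tuple(f"roi-{i:02d}" for i in range(n_rois))
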