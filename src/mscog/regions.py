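"""Names of the 76 regional brain volumes carried through the pipeline.

31 cortical labels per hemisphere (Desikan-Killiany-Tourville protocol) plus
7 subcortical structures per hemisphere, i.e. (31 + 7) x 2 = 76 features.
Column names are prefixed ``vol_lh_`` / ``vol_rh_``.
"""

from __future__ import annotations

DKT_CORTICAL = (
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
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
    "transversetemporal",
)

SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

REGION_VOLUME_COLUMNS: tuple[str, ...] = tuple(
    f"vol_{hemi}_{name}"
    for hemi in ("lh", "rh")
    for name in DKT_CORTICAL + SUBCORTICAL
)

assert len(REGION_VOLUME_COLUMNS) == 76
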