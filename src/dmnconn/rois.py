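"""Default-mode-network regions of interest.

The default ROI table lists the 8 core DMN regions, bilaterally
(16 regional sources): medial frontal gyrus (MFG), superior frontal
gyrus (SFG), anterior cingulate cortex (ACC), posterior cingulate
cortex/precuneus (PCC), superior temporal gyrus (STG), angular gyrus
(AG), inferior parietal lobule (IPL) and middle temporal gyrus (MTG),
with Talairach peak coordinates (mm), peak Z value and voxel extent.
"""

from __future__ import annotations

import pandas as pd

#: Canonical ROI ordering used for all 8-node outputs.
ROI_ORDER = ["MFG", "SFG", "ACC", "PCC", "STG", "AG", "IPL", "MTG"]

# name, hemisphere, x, y, z (Talairach mm), peak Z, voxel extent
_ROI_ROWS = [
    ("MFG", "L", -2, 57, 21, 5.54, 422),
    ("MFG", "R", 2, 57, 8, 4.94, 341),
    ("SFG", "L", -2, 57, 23, 5.57, 495),
    ("SFG", "R", 4, 58, 25, 3.19, 742),
    ("ACC", "L", -2, 54, -1, 3.71, 77),
    ("ACC", "R", 4, 47, 9, 2.75, 57),
    ("PCC", "L", -2, -49, 25, 3.14, 65),
    ("PCC", "R", 2, -50, 19, 3.36, 82),
    ("STG", "L", -38, 17, -19, 2.21, 56),
    ("STG", "R", 38, 17, -19, 2.27, 33),
    ("AG", "L", -49, -63, 31, 2.43, 19),
    ("AG", "R", 51, -63, 31, 2.00, 16),
    ("IPL", "L", -46, -50, 52, 2.40, 206),
    ("IPL", "R", 50, -42, 56, 1.52, 15),
    ("MTG", "L", -49, -63, 29, 2.41, 39),
    ("MTG", "R", 53, -59, 25, 2.10, 22),
]


def default_roi_table() -> pd.DataFrame:
    """Return the default 16-row bilateral DMN ROI table."""
    return pd.DataFrame(
        _ROI_ROWS,
        columns=["name", "hemisphere", "x", "y", "z", "peak_z", "n_voxels"],
    )


def default_region_labels() -> list[str]:
    """16 region labels in canonical order, e.g. ``MFG_L, MFG_R, SFG_L, ...``."""
    return [f"{name}_{hem}" for name, hem in
            ((r[0], r[1]) for r in _ROI_ROWS)]


def bilateral_pairing(labels: list[str]) -> dict[str, list[int]]:
    """Group region labels of the form ``ROI_L`` / ``ROI_R`` by ROI.

    Returns a mapping ROI name -> indices of its hemispheric nodes, in
    label order. Raises if any label lacks a ``_<hemisphere>`` suffix or
    an ROI does not have exactly two nodes.
    """
    pairing: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if "_" not in lab:
            raise ValueError(f"region label {lab!r} has no hemisphere suffix")
        roi = lab.rsplit("_", 1)[0]
        pairing.setdefault(roi, []).append(i)
    for roi, idx in pairing.items():
        if len(idx) != 2:
            raise ValueError(
                f"ROI {roi!r} has {len(idx)} nodes; bilateral pairing "
                "requires exactly two"
            )
    return pairing


def roi_of_label(label: str) -> str:
    """ROI name of a hemispheric region label (``PCC_L`` -> ``PCC``)."""
    if "_" not in label:
        raise ValueError(f"region label {label!r} has no hemisphere suffix")
    return label.rsplit("_", 1)[0]
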