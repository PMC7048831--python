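"""Volumetric ratio features and per-viewpoint shape properties.

Twelve volumetric features describe the whole tumor (WT) and its
sub-regions (edema ED, enhancing tumor ET, necrosis NCR) as absolute volume
and mutual/brain-relative ratios; at 1 mm isotropic spacing a voxel count is
a volume in mm³.  Shape properties are measured on the three orthogonal
any-voxel projections (collapse along x, y or z) of each region:
area, bounding box, centroid, perimeter, major/minor axis length,
eccentricity, orientation, solidity and extent — 14 scalars per
(region, axis), 168 in total.

Arrays are indexed (x, y, z) with z inferior→superior, so the "z"
projection is the axial viewpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .io import SegmentationMask, derive_region_masks

REGIONS = ("WT", "ED", "ET", "NCR")
AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

VOLUMETRIC_FEATURES = (
    "V_WT",
    "V_WT_over_V_brain",
    "V_ED_over_V_WT",
    "V_ET_over_V_WT",
    "V_NCR_over_V_WT",
    "V_ED_over_V_brain",
    "V_ET_over_V_brain",
    "V_NCR_over_V_brain",
    "V_ET_over_V_ED",
    "V_NCR_over_V_ED",
    "V_ED_over_V_ET_plus_NCR",
    "V_NCR_over_V_ED_plus_ET",
)

SHAPE_PROPERTIES = (
    "area",
    "bbox_corner_x",
    "bbox_corner_y",
    "bbox_width",
    "bbox_height",
    "centroid_x",
    "centroid_y",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "orientation",
    "solidity",
    "extent",
)


@dataclass
class RegionVolumes:
    """Voxel counts of the tumor regions and the brain (1 mm³ voxels)."""

    V_WT: int
    V_ED: int
    V_ET: int
    V_NCR: int
    V_brain: int

    @classmethod
    def from_masks(cls, mask: SegmentationMask, brain_mask: np.ndarray) -> "RegionVolumes":
        regions = derive_region_masks(mask)
        return cls(
            V_WT=int(regions["WT"].sum()),
            V_ED=int(regions["ED"].sum()),
            V_ET=int(regions["ET"].sum()),
            V_NCR=int(regions["NCR"].sum()),
            V_brain=int(np.asarray(brain_mask).astype(bool).sum()),
        )


def _ratio(num: float, den: float, flags: set, name: str) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def volumetric_features(v: RegionVolumes) -> tuple[dict[str, float], set]:
    """The 12 volumetric features; zero-denominator ratios are 0 and flagged."""
    if v.V_brain <= 0:
        raise ValueError("brain volume must be positive")
    flags: set = set()
    feats = {
        "V_WT": float(v.V_WT),
        "V_WT_over_V_brain": v.V_WT / v.V_brain,
        "V_ED_over_V_WT": _ratio(v.V_ED, v.V_WT, flags, "V_ED_over_V_WT"),
        "V_ET_over_V_WT": _ratio(v.V_ET, v.V_WT, flags, "V_ET_over_V_WT"),
        "V_NCR_over_V_WT": _ratio(v.V_NCR, v.V_WT, flags, "V_NCR_over_V_WT"),
        "V_ED_over_V_brain": v.V_ED / v.V_brain,
        "V_ET_over_V_brain": v.V_ET / v.V_brain,
        "V_NCR_over_V_brain": v.V_NCR / v.V_brain,
        "V_ET_over_V_ED": _ratio(v.V_ET, v.V_ED, flags, "V_ET_over_V_ED"),
        "V_NCR_over_V_ED": _ratio(v.V_NCR, v.V_ED, flags, "V_NCR_over_V_ED"),
        "V_ED_over_V_ET_plus_NCR": _ratio(v.V_ED, v.V_ET + v.V_NCR, flags, "V_ED_over_V_ET_plus_NCR"),
        "V_NCR_over_V_ED_plus_ET": _ratio(v.V_NCR, v.V_ED + v.V_ET, flags, "V_NCR_over_V_ED_plus_ET"),
    }
    assert len(feats) == 12
    return feats, flags


def projection_region_properties(region: np.ndarray, axis: str) -> tuple[dict[str, float], bool]:
    """Shape properties of the any-voxel projection of a 3D region.

    The projection collapses the named axis; properties are measured on the
    single region formed by all projected pixels (connectivity is irrelevant
    because the pixel set is treated as one region).  Orientation is in
    degrees in (-90, 90], measured from the first in-plane axis.  An empty
    region returns zeros with the degenerate flag.
    """
    region = np.asarray(region).astype(bool)
    proj = region.any(axis=_AXIS_INDEX[axis])
    if not proj.any():
        return {k: 0.0 for k in SHAPE_PROPERTIES}, True
    props = measure.regionprops(proj.astype(np.uint8))[0]
    minr, minc, maxr, maxc = props.bbox
    try:
        solidity = float(props.solidity)
    except Exception:  # degenerate hull (e.g. collinear pixels)
        solidity = 1.0
    orientation_deg = float(np.degrees(props.orientation))
    # skimage measures orientation from the 0th (row) axis in (-pi/2, pi/2]
    if orientation_deg <= -90.0:
        orientation_deg += 180.0
    feats = {
        "area": float(props.area),
        "bbox_corner_x": float(minr),
        "bbox_corner_y": float(minc),
        "bbox_width": float(maxr - minr),
        "bbox_height": float(maxc - minc),
        "centroid_x": float(props.centroid[0]),
        "centroid_y": float(props.centroid[1]),
        "perimeter": float(props.perimeter),
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
        "eccentricity": float(props.eccentricity),
        "orientation": orientation_deg,
        "solidity": solidity,
        "extent": float(props.extent),
    }
    return feats, False


def shape_feature_block(mask: SegmentationMask) -> tuple[dict[str, float], set]:
    """All shape properties: 4 regions × 3 viewpoints × 14 scalars = 168.

    Keys follow ``<region>.shape_<axis>.<property>``; degenerate (empty)
    regions contribute zeros and are flagged.
    """
    regions = derive_region_masks(mask)
    feats: dict[str, float] = {}
    flags: set = set()
    for region_name in REGIONS:
        for axis in AXES:
            props, degenerate = projection_region_properties(regions[region_name], axis)
            prefix = f"{region_name}.shape_{axis}"
            if degenerate:
                flags.add(prefix)
            for k, v in props.items():
                feats[f"{prefix}.{k}"] = v
    assert len(feats) == 168
    return feats, flags
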