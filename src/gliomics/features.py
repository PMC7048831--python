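"""Assembly of per-case feature vectors and cohort feature tables.

Feature names follow ``<source>.<region>.<family>.<feature>``:

* 41 texture features on the whole tumor for each of T1Gd, T2, FLAIR and
  for each fractal characterization map (PTPSA, MBM, HE) — 246;
* 6 histogram statistics per sub-region (ED, ET, NCR) on each raw sequence
  (T1, T1Gd, T2, FLAIR) — 72 — plus 6 per characterization map on the
  whole tumor — 18;
* 12 volumetric features (``mask.volumetric.<name>``);
* 168 projection shape properties (``mask.<region>.shape_<axis>.<prop>``).

Default catalogue: 516 features, with the characterization maps computed
once per case from FLAIR.  The ``per_sequence_maps`` variant computes the
maps from each of T1Gd, T2 and FLAIR (sources like ``MBM_T1Gd``), growing
the texture block to 492 and the catalogue to 744.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fractal import FractalMapConfig, characterization_map
from .io import CaseRecord, Cohort, derive_region_masks
from .morphometry import RegionVolumes, shape_feature_block, volumetric_features
from .texture import (
    HISTOGRAM_FEATURES,
    TEXTURE_CATALOGUE,
    compute_texture_matrices,
    histogram_stats,
    quantize_roi,
    texture_feature_vector,
)

TEXTURE_SEQUENCES = ("T1Gd", "T2", "FLAIR")
HISTOGRAM_SEQUENCES = ("T1", "T1Gd", "T2", "FLAIR")
MAP_KINDS = ("PTPSA", "MBM", "HE")
SUBREGIONS = ("ED", "ET", "NCR")


class AssemblyError(ValueError):
    """A feature could not be resolved to a finite value."""


@dataclass
class FeatureConfig:
    """Catalogue options for feature assembly."""

    ng: int = 32
    map_config: FractalMapConfig = field(default_factory=FractalMapConfig)
    map_source: str = "FLAIR"
    per_sequence_maps: bool = False
    wt_only: bool = False  # zero-fill sub-region blocks

    def map_sources(self) -> list[tuple[str, str]]:
        """(source name, sequence) pairs for the characterization maps."""
        if self.per_sequence_maps:
            return [(f"{kind}_{seq}", seq) for kind in MAP_KINDS for seq in TEXTURE_SEQUENCES]
        return [(kind, self.map_source) for kind in MAP_KINDS]


def catalogue_names(config: FeatureConfig | None = None) -> list[str]:
    """The ordered feature-name catalogue for a configuration."""
    config = config or FeatureConfig()
    names: list[str] = []
    texture_sources = list(TEXTURE_SEQUENCES) + [s for s, _ in config.map_sources()]
    for src in texture_sources:
        names += [f"{src}.WT.{fam}.{feat}" for fam, feat in TEXTURE_CATALOGUE]
    for seq in HISTOGRAM_SEQUENCES:
        for region in SUBREGIONS:
            names += [f"{seq}.{region}.histogram.{h}" for h in HISTOGRAM_FEATURES]
    # Map histogram statistics accompany the single-source variant; in the
    # per-sequence variant the maps already contribute three texture blocks
    # each and the catalogue stays within its documented size.
    if not config.per_sequence_maps:
        for src, _ in config.map_sources():
            names += [f"{src}.WT.histogram.{h}" for h in HISTOGRAM_FEATURES]
    from .morphometry import AXES, REGIONS, SHAPE_PROPERTIES, VOLUMETRIC_FEATURES

    names += [f"mask.volumetric.{v}" for v in VOLUMETRIC_FEATURES]
    for region in REGIONS:
        for axis in AXES:
            names += [f"mask.{region}.shape_{axis}.{p}" for p in SHAPE_PROPERTIES]
    return names


def fractal_feature_subset(names: list[str]) -> list[str]:
    """Features derived from the PTPSA / MBM / HE characterization maps."""
    out = []
    for name in names:
        source = name.split(".", 1)[0]
        if source.split("_", 1)[0] in MAP_KINDS:
            out.append(name)
    return out


def assemble_case_features(case: CaseRecord, config: FeatureConfig | None = None) -> tuple[dict[str, float], set]:
    """One named feature vector for a case; returns (features, degenerate flags).

    Raises :class:`AssemblyError` if any feature resolves to a non-finite
    value after the degenerate conventions are applied.
    """
    config = config or FeatureConfig()
    regions = derive_region_masks(case.mask)
    wt = regions["WT"]
    feats: dict[str, float] = {}
    flags: set = set()

    maps = {}
    for src, seq in config.map_sources():
        kind = src.split("_", 1)[0]
        maps[src] = characterization_map(case.images[seq], wt, kind, config.map_config)

    # texture block on WT: raw sequences then characterization maps
    for src in list(TEXTURE_SEQUENCES) + list(maps):
        data = maps[src].data if src in maps else case.images[src].data
        q = quantize_roi(data, wt, config.ng, source=src)
        if q.degenerate:
            flags.add(f"{src}.WT.texture")
        vec = compute_texture_matrices(q)
        for key, val in texture_feature_vector(vec).items():
            feats[f"{src}.WT.{key}"] = val

    # histogram statistics per sub-region on raw sequences
    for seq in HISTOGRAM_SEQUENCES:
        for region in SUBREGIONS:
            prefix = f"{seq}.{region}.histogram"
            msk = regions[region]
            if config.wt_only or not msk.any():
                for h in HISTOGRAM_FEATURES:
                    feats[f"{prefix}.{h}"] = 0.0
                flags.add(prefix)
                continue
            for h, v in histogram_stats(case.images[seq].data, msk).items():
                feats[f"{prefix}.{h}"] = v

    # histogram statistics of each characterization map on WT
    if not config.per_sequence_maps:
        for src in maps:
            for h, v in histogram_stats(maps[src].data, wt).items():
                feats[f"{src}.WT.histogram.{h}"] = v

    # volumetric and shape blocks
    vols = RegionVolumes.from_masks(case.mask, case.brain_mask)
    vfeats, vflags = volumetric_features(vols)
    flags |= vflags
    for k, v in vfeats.items():
        feats[f"mask.volumetric.{k}"] = v
    if config.wt_only:
        from .morphometry import AXES, REGIONS, SHAPE_PROPERTIES, projection_region_properties

        for region in REGIONS:
            for axis in AXES:
                prefix = f"{region}.shape_{axis}"
                if region == "WT":
                    props, deg = projection_region_properties(regions["WT"], axis)
                else:
                    props, deg = {k: 0.0 for k in SHAPE_PROPERTIES}, True
                if deg:
                    flags.add(prefix)
                for k, v in props.items():
                    feats[f"mask.{prefix}.{k}"] = v
    else:
        sfeats, sflags = shape_feature_block(case.mask)
        flags |= sflags
        for k, v in sfeats.items():
            feats[f"mask.{k}"] = v

    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise AssemblyError(f"non-finite feature value(s) for {bad[:5]}")
    return feats, flags


def assemble_cohort_features(cohort: Cohort, config: FeatureConfig | None = None) -> pd.DataFrame:
    """Cohort feature table: one row per case, identical columns throughout."""
    config = config or FeatureConfig()
    names = catalogue_names(config)
    rows = []
    for case in cohort.cases:
        feats, _ = assemble_case_features(case, config)
        rows.append([feats[n] for n in names])
    return pd.DataFrame(rows, index=[c.case_id for c in cohort.cases], columns=names)


def feature_catalogue_table(config: FeatureConfig | None = None) -> pd.DataFrame:
    """Machine-readable catalogue: name, source, region, family, feature."""
    rows = []
    for name in catalogue_names(config):
        parts = name.split(".")
        if parts[1] == "volumetric":
            rows.append((name, parts[0], "WT", "volumetric", parts[2]))
        else:
            rows.append((name, parts[0], parts[1], parts[2], parts[3]))
    return pd.DataFrame(rows, columns=["name", "source", "region", "family", "feature"])
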