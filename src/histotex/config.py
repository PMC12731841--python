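"""Pipeline configuration.

All tunable knobs of the texture pipeline live in one dataclass so a run is
fully described by (inputs, config, seed). Values can be loaded from a YAML
mapping with the same field names.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("histotex")

#: Second-pass feature set used for texture-derivative analysis: the GLCM and
#: GLDM features reported for second-pass use, 13 in total.
SECOND_PASS_DEFAULT: tuple[str, ...] = (
    "GLCM Contrast",
    "GLCM Cluster Prominence",
    "GLCM Sum Entropy",
    "GLCM Informational Measure of Correlation 2",
    "GLCM Difference Variance",
    "GLCM Inverse Difference Normalized",
    "GLCM Inverse Difference Moment Normalized",
    "GLDM High Gray-Level Emphasis",
    "GLDM Low Gray-Level Emphasis",
    "GLDM Dependence Variance",
    "GLDM Dependence Entropy",
    "GLDM Small Dependence Low Gray-Level Emphasis",
    "GLDM Small Dependence High Gray-Level Emphasis",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the histology texture pipeline.

    Attributes
    ----------
    ng : int
        Number of gray levels for first-pass quantization (equal-width bins
        over the in-ROI intensity range).
    ng2 : int
        Gray levels for re-quantizing texture maps before the second pass;
        coarser than ``ng`` because maps have few samples.
    downsample_factor : int
        Block-mean downsampling factor applied to raw high-magnification
        images before analysis.
    pixel_spacing_um : float
        Isotropic pixel spacing in micrometres *after* downsampling.
    block_mm : float
        Side length of the square texture-map window blocks, millimetres.
    min_coverage : float
        Minimum in-ROI area fraction for a window block to enter a texture
        map.
    glcm_distance, gldm_distance, ngtdm_distance : int
        Pixel offsets used by the respective matrices.
    gldm_alpha : int
        Gray-level tolerance for the dependence criterion.
    second_pass_features : tuple of str
        Feature names evaluated on each re-quantized texture map.
    alpha : float
        Significance level for group comparisons.
    """

    ng: int = 32
    ng2: int = 16
    downsample_factor: int = 10
    pixel_spacing_um: float = 5.0
    block_mm: float = 0.5
    min_coverage: float = 0.5
    glcm_distance: int = 1
    gldm_distance: int = 1
    gldm_alpha: int = 0
    ngtdm_distance: int = 1
    second_pass_features: tuple[str, ...] = SECOND_PASS_DEFAULT
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "second_pass_features" in raw:
            raw["second_pass_features"] = tuple(raw["second_pass_features"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["second_pass_features"] = list(data["second_pass_features"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
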