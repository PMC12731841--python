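"""Second-pass (texture-derivative) analysis.

Treats each first-pass texture map as an image in its own right — one
block = one pixel, unit spacing — re-quantizes it, and runs texture
extraction again. The resulting features are named by joining the
first-pass map and second-pass feature, e.g.
"Cluster Prominence–Sum Entropy".

Maps with fewer than 2x2 valid blocks cannot support the second-pass
matrices; their entries are emitted as missing (NaN) and logged rather
than aborting the run, so the derivative vector always has exactly
|maps| x |second-pass features| entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import SECOND_PASS_DEFAULT
from .io_preprocess import QuantizedImage, ROIMask
from .texture_features import ALL_FEATURE_NAMES, FAMILIES, extract_all
from .texture_map import TextureMap

logger = logging.getLogger("histotex")

#: En dash joining first-pass and second-pass feature names.
JOIN = "–"


@dataclass
class DerivativeFeatureVector:
    """Ordered (map feature, second-pass feature) -> value."""

    values: dict[tuple[str, str], float]
    n_valid_blocks: dict[str, int]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def __len__(self) -> int:
        return len(self.values)

    @staticmethod
    def joined_name(map_feature: str, second_feature: str) -> str:
        """Display name: family prefixes stripped, en-dash joined."""
        return f"{_strip(map_feature)}{JOIN}{_strip(second_feature)}"

    def by_name(self) -> dict[str, float]:
        """Unique names: the first-pass family prefixes the joined name
        (e.g. "GLCM Cluster Prominence–Sum Entropy"), since different
        families share some first-pass feature names."""
        return {f"{_family(a)} {self.joined_name(a, b)}": v
                for (a, b), v in self.values.items()}


def _strip(name: str) -> str:
    for fam in FAMILIES:
        if name.startswith(fam + " "):
            return name[len(fam) + 1:]
    return name


def _family(name: str) -> str:
    for fam in FAMILIES:
        if name.startswith(fam + " "):
            return fam
    return ""


def requantize_map(m: TextureMap, ng2: int = 16) -> tuple[QuantizedImage, ROIMask]:
    """Quantize a real-valued texture map into ng2 equal-width levels.

    Valid blocks span the bins; invalid blocks are excluded from the ROI of
    the derived image. A constant map maps to level 1 everywhere.
    """
    if ng2 < 2:
        raise ValueError("ng2 must be >= 2")
    ok = m.valid & np.isfinite(m.values)
    if not ok.any():
        raise ValueError(f"texture map '{m.feature_name}' has no valid block")
    vals = m.values[ok]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(m.values.shape, dtype=np.int32)
    if hi > lo:
        width = (hi - lo) / ng2
        with np.errstate(invalid="ignore"):
            lv = np.floor((np.nan_to_num(m.values, nan=lo) - lo) / width)
        lv = np.clip(lv.astype(np.int32) + 1, 1, ng2)
        levels[ok] = lv[ok]
        edges = np.linspace(lo, hi, ng2 + 1)
    else:
        levels[ok] = 1
        edges = np.linspace(lo, lo + 1.0, ng2 + 1)
    q = QuantizedImage(levels=levels, ng=ng2, bin_edges=edges,
                       pixel_spacing=1.0)  # block = pixel, unit spacing
    return q, ROIMask(mask=ok, label=f"map:{m.feature_name}")


def derivative_features(maps: list[TextureMap],
                        second_pass: tuple[str, ...] = SECOND_PASS_DEFAULT,
                        ng2: int = 16) -> DerivativeFeatureVector:
    """Second-pass features for every (map, second-pass feature) pair."""
    second_pass = tuple(second_pass)
    unknown = set(second_pass) - set(ALL_FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown second-pass features: {sorted(unknown)}")
    needed = tuple(f for f in FAMILIES
                   if any(name.startswith(f + " ") for name in second_pass))
    values: dict[tuple[str, str], float] = {}
    n_valid: dict[str, int] = {}
    for m in maps:
        ok = m.valid & np.isfinite(m.values)
        n_valid[m.feature_name] = int(ok.sum())
        rows = np.nonzero(ok.any(axis=1))[0]
        cols = np.nonzero(ok.any(axis=0))[0]
        if ok.sum() < 4 or rows.size < 2 or cols.size < 2:
            logger.warning("map '%s' has fewer than 2x2 valid blocks; "
                           "derivative entries set to NaN", m.feature_name)
            for name in second_pass:
                values[(m.feature_name, name)] = float("nan")
            continue
        q, roi = requantize_map(m, ng2)
        fv = extract_all(q, roi, families=needed)
        for name in second_pass:
            values[(m.feature_name, name)] = fv[name]
    return DerivativeFeatureVector(values=values, n_valid_blocks=n_valid)
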