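"""Windowed texture maps.

Tiles an ROI into non-overlapping square blocks of physical size (default
0.5 mm x 0.5 mm), computes texture features per block, and assembles one
2D map per feature over the block grid. Maps are summarized by their
median over valid blocks; they are also the input of the second-pass
(texture-derivative) analysis.

Blocks inherit the whole-ROI gray-level quantization so values are
comparable across the map. A block enters a map when its in-ROI coverage
is at least ``min_coverage`` (area fraction of the full block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_preprocess import QuantizedImage, ROIMask
from .texture_features import (ALL_FEATURE_NAMES, FAMILIES, extract_all)

logger = logging.getLogger("histotex")


@dataclass
class Block:
    row: int
    col: int
    window: tuple[slice, slice]
    n_roi_pixels: int


@dataclass
class BlockGrid:
    block_mm: float
    block_px: int
    origin: tuple[int, int]          # pixel offset of block (0, 0)
    shape: tuple[int, int]           # (n_rows, n_cols) of the block lattice
    blocks: list[Block]              # valid blocks only
    valid: np.ndarray                # (n_rows, n_cols) bool

    @property
    def n_valid(self) -> int:
        return len(self.blocks)


@dataclass
class TextureMap:
    feature_name: str
    values: np.ndarray               # (n_rows, n_cols)
    valid: np.ndarray                # (n_rows, n_cols) bool
    block_mm: float


def tile_roi(q: QuantizedImage, roi: ROIMask, block_mm: float = 0.5,
             min_coverage: float = 0.5) -> BlockGrid:
    """Tile the ROI bounding box into block_mm-sized square windows.

    The grid is anchored at the bounding-box top-left. A block is valid
    when its in-ROI coverage is >= ``min_coverage`` (and intersects the ROI
    at all when ``min_coverage`` is 0).
    """
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    block_px = int(round(block_mm * 1000.0 / q.pixel_spacing))
    if block_px < 2:
        raise ValueError(
            f"block of {block_mm} mm is {block_px} px at "
            f"{q.pixel_spacing} um/px; need >= 2 px")
    rows, cols = np.nonzero(roi.mask)
    r0, c0 = int(rows.min()), int(cols.min())
    r1, c1 = int(rows.max()) + 1, int(cols.max()) + 1
    h, w = roi.mask.shape
    n_rows = max(1, int(np.ceil((r1 - r0) / block_px)))
    n_cols = max(1, int(np.ceil((c1 - c0) / block_px)))
    area = float(block_px * block_px)
    blocks: list[Block] = []
    valid = np.zeros((n_rows, n_cols), dtype=bool)
    for br in range(n_rows):
        for bc in range(n_cols):
            rs = slice(r0 + br * block_px, min(r0 + (br + 1) * block_px, h))
            cs = slice(c0 + bc * block_px, min(c0 + (bc + 1) * block_px, w))
            n_in = int(roi.mask[rs, cs].sum())
            coverage = n_in / area
            if n_in > 0 and coverage >= min_coverage:
                valid[br, bc] = True
                blocks.append(Block(br, bc, (rs, cs), n_in))
    if not blocks:
        logger.warning("no block reaches %.2f in-ROI coverage "
                       "(block %d px, ROI bbox %dx%d)",
                       min_coverage, block_px, r1 - r0, c1 - c0)
    return BlockGrid(block_mm=block_mm, block_px=block_px, origin=(r0, c0),
                     shape=(n_rows, n_cols), blocks=blocks, valid=valid)


def compute_texture_map(q: QuantizedImage, roi: ROIMask, grid: BlockGrid,
                        features: tuple[str, ...] | list[str] = ALL_FEATURE_NAMES,
                        **extract_kwargs) -> list[TextureMap]:
    """One texture map per requested feature.

    Per valid block, features are extracted on the block window with the
    block's portion of the ROI, inheriting the global quantization (no
    per-block re-quantization). Only the families needed for the requested
    features are computed.
    """
    features = tuple(features)
    unknown = set(features) - set(ALL_FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    needed = tuple(f for f in FAMILIES
                   if any(name.startswith(f + " ") for name in features))
    n_rows, n_cols = grid.shape
    stacks = {name: np.full((n_rows, n_cols), np.nan) for name in features}
    for blk in grid.blocks:
        rs, cs = blk.window
        sub_q = QuantizedImage(levels=q.levels[rs, cs], ng=q.ng,
                               bin_edges=q.bin_edges,
                               pixel_spacing=q.pixel_spacing)
        sub_roi = ROIMask(mask=roi.mask[rs, cs], label=roi.label)
        fv = extract_all(sub_q, sub_roi, families=needed, **extract_kwargs)
        for name in features:
            stacks[name][blk.row, blk.col] = fv[name]
    return [TextureMap(feature_name=name, values=stacks[name],
                       valid=grid.valid.copy(), block_mm=grid.block_mm)
            for name in features]


def map_median(m: TextureMap) -> float:
    """Median of a texture map over its valid blocks only."""
    vals = m.values[m.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"texture map '{m.feature_name}' has no valid block")
    return float(np.median(vals))
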