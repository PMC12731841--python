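"""End-to-end cohort pipeline over synthetic or loaded phantoms.

For every subject: preprocess the grayscale image, extract the 59-feature
vector from the whole tumor and from the damaged region, build windowed
texture maps and their medians, derive second-pass features, and collect
the damaged-area fraction. Each tier then goes through ANOVA + Bonferroni
group comparisons, and the whole run is written as deterministic CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io_preprocess import normalize_intensity, quantize
from .stats_report import (compare_all_features, damaged_fraction,
                           make_group_table, report)
from .synthetic_data import PhantomOutput, gen_cohort
from .texture_derivative import DerivativeFeatureVector, derivative_features
from .texture_features import extract_all
from .texture_map import compute_texture_map, map_median, tile_roi

logger = logging.getLogger("histotex")

TIERS = ("whole_tumor", "segmented", "map_medians", "derivatives")


def analyze_phantom(ph: PhantomOutput,
                    config: AnalysisConfig = DEFAULT_CONFIG
                    ) -> dict[str, dict[str, float]]:
    """All four analysis tiers for one subject, as feature -> value maps."""
    img = normalize_intensity(ph.image)
    q = quantize(img, ph.tumor_mask, config.ng)
    kwargs = dict(glcm_distance=config.glcm_distance,
                  gldm_alpha=config.gldm_alpha,
                  gldm_distance=config.gldm_distance,
                  ngtdm_distance=config.ngtdm_distance)

    whole = extract_all(q, ph.tumor_mask, region_label="whole_tumor", **kwargs)

    tiers: dict[str, dict[str, float]] = {"whole_tumor": dict(whole.values)}

    if ph.damaged_mask.n_pixels > 0:
        q_seg = quantize(img, ph.damaged_mask, config.ng)
        seg = extract_all(q_seg, ph.damaged_mask, region_label="damaged",
                          **kwargs)
        tiers["segmented"] = dict(seg.values)
    else:
        logger.warning("subject %s has an empty damaged mask; segmented "
                       "tier skipped", ph.subject_id)
        tiers["segmented"] = {}

    grid = tile_roi(q, ph.tumor_mask, block_mm=config.block_mm,
                    min_coverage=config.min_coverage)
    maps = compute_texture_map(q, ph.tumor_mask, grid, **kwargs)
    tiers["map_medians"] = {m.feature_name: map_median(m) for m in maps}

    deriv = derivative_features(maps, second_pass=config.second_pass_features,
                                ng2=config.ng2)
    tiers["derivatives"] = deriv.by_name()

    tiers["damaged_area"] = {
        "Damaged Area Fraction": damaged_fraction(ph.damaged_mask,
                                                  ph.tumor_mask)}
    return tiers


def run_cohort_pipeline(outdir: str | Path, base_seed: int = 0,
                        n_per_group: dict[str, int] | None = None,
                        image_size: int = 1000,
                        config: AnalysisConfig = DEFAULT_CONFIG,
                        cohort: list[PhantomOutput] | None = None
                        ) -> dict[str, Path]:
    """Generate (or take) a cohort, run every tier, write the CSV report.

    Returns the written file paths keyed by tier. Identical inputs and
    seed produce byte-identical outputs.
    """
    if cohort is None:
        cohort = gen_cohort(n_per_group=n_per_group, base_seed=base_seed,
                            image_size=image_size)
    rows: dict[str, list] = {tier: [] for tier in
                             (*TIERS, "damaged_area")}
    for ph in cohort:
        tiers = analyze_phantom(ph, config)
        for tier, values in tiers.items():
            for feature, value in values.items():
                rows[tier].append((ph.subject_id, ph.spec.group,
                                   feature, value))
    tables = {tier: make_group_table(r) for tier, r in rows.items() if r}
    results = {tier: compare_all_features(tab, alpha=config.alpha)
               for tier, tab in tables.items()}
    paths = report(tables, results, outdir)
    return {p.stem: p for p in paths}
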