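"""Synthetic phantoms: histology-like textures and DCE-MRI series.

Histology phantoms emulate the three tissue regimes seen in H&E sections
of treated tumors at analysis resolution:

* viable tumor — fine, high-contrast nuclear speckle (dark nuclei on
  light cytoplasm, grain at the nuclear scale);
* early-apoptotic damage — a smoothed field salted with small dark
  condensed/fragmented foci;
* necrosis — large connected low-variance zones with dissolved structure.

Damage is laid down as connected blobs inside an elliptical tumor mask
until a target damaged-area fraction is met; the realized fraction is
recorded as ground truth. Per-group default fractions follow the reported
treatment-arm means (11.2% control ... 36.9% combined treatment targeted
to low perfusion), with draws around the group mean/SD when generating a
cohort.

The DCE phantom produces a ramp-plateau enhancement scaled by a smooth
spatial perfusion field, with the analytic area under the curve recorded
so recovery can be checked exactly.

Textures are stylized (binarized smoothed noise and blob fields), not
stain-realistic; they carry the statistical contrasts the analysis is
sensitive to, which is what phantom-based validation needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_preprocess import RasterImage, ROIMask
from .perfusion_targeting import DCESeries

logger = logging.getLogger("histotex")

GROUPS: tuple[str, ...] = ("control", "XRT", "USMB", "USMB_XRT",
                           "USMB_XRT_LOW", "USMB_XRT_HIGH")

#: Reported per-group damaged-area fraction (mean, SD) of tumor area.
GROUP_DAMAGED_FRACTION: dict[str, tuple[float, float]] = {
    "control": (0.112, 0.051),
    "XRT": (0.118, 0.006),
    "USMB": (0.294, 0.035),
    "USMB_XRT": (0.291, 0.022),
    "USMB_XRT_LOW": (0.369, 0.048),
    "USMB_XRT_HIGH": (0.351, 0.039),
}

#: Reported per-group animal counts.
GROUP_N: dict[str, int] = {
    "control": 5, "XRT": 4, "USMB": 5, "USMB_XRT": 5,
    "USMB_XRT_LOW": 5, "USMB_XRT_HIGH": 5,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one histology phantom."""

    group: str = "control"
    image_size: int = 1000
    pixel_spacing: float = 5.0          # µm/pixel at analysis resolution
    damaged_fraction_target: float = 0.112
    speckle_grain_px: float = 1.5       # nuclear-scale speckle grain
    speckle_contrast: float = 130.0     # light-dark separation, intensity units
    necrotic_zone_radius_px: int = 60   # typical damage blob radius
    focus_density: float = 0.03         # condensed-foci area fraction in damage
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.damaged_fraction_target <= 1.0:
            raise ValueError("damaged_fraction_target must be in [0, 1]")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class PhantomOutput:
    image: RasterImage
    tumor_mask: ROIMask
    damaged_mask: ROIMask
    spec: PhantomSpec
    realized_damaged_fraction: float
    subject_id: str = ""


def _speckle(shape: tuple[int, int], rng: np.random.Generator,
             grain: float, dark: float, light: float,
             dark_fraction: float = 0.4) -> np.ndarray:
    """Binarized smoothed noise: dark blobs (nuclei) on a light background."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), grain)
    thr = np.quantile(noise, dark_fraction)
    tex = np.where(noise < thr, dark, light).astype(float)
    tex += rng.normal(0.0, 6.0, shape)
    return tex


def _damage_field(shape: tuple[int, int], rng: np.random.Generator,
                  focus_density: float) -> np.ndarray:
    """Smooth low-variance necrotic field, salted with condensed dark foci."""
    # necrosis loses hematoxylin-stained nuclei, so the field sits near
    # cytoplasm brightness with low variance
    base = ndimage.gaussian_filter(rng.standard_normal(shape), 12.0)
    sd = float(base.std()) or 1.0
    base = 190.0 + base * (4.0 / sd)
    if focus_density > 0:
        fine = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
        thr = np.quantile(fine, focus_density)
        base = np.where(fine < thr, 60.0, base)
    return base


def _place_damage(tumor: np.ndarray, target: float, base_radius: int,
                  rng: np.random.Generator, tol: float = 0.02) -> np.ndarray:
    """Union of random discs inside the tumor until the damaged-area
    fraction reaches the target (within +-tol)."""
    n_tumor = int(tumor.sum())
    damaged = np.zeros_like(tumor)
    if target <= 0:
        return damaged
    coords = np.argwhere(tumor)
    h, w = tumor.shape
    yy, xx = np.mgrid[0:h, 0:w]
    frac = 0.0
    for _ in range(5000):
        if frac >= target - tol / 2:
            break
        remaining = (target - frac) * n_tumor
        r = int(min(base_radius, max(3, np.sqrt(remaining / np.pi))))
        cy, cx = coords[rng.integers(len(coords))]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        damaged |= disc & tumor
        frac = damaged.sum() / n_tumor
    else:
        raise ValueError(
            f"could not reach damaged fraction {target:.3f} (got {frac:.3f})")
    if abs(frac - target) > tol:
        raise ValueError(
            f"damaged fraction {frac:.3f} outside +-{tol} of {target:.3f}")
    return damaged


def gen_histology_phantom(spec: PhantomSpec) -> PhantomOutput:
    """One labeled phantom: image, tumor mask, damaged mask, ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    shape = (n, n)

    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    a, b = 0.46 * n, 0.42 * n
    tumor = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    light = 200.0
    dark = light - spec.speckle_contrast
    viable = _speckle(shape, rng, spec.speckle_grain_px, dark, light)
    damage_tex = _damage_field(shape, rng, spec.focus_density)
    damaged = _place_damage(tumor, spec.damaged_fraction_target,
                            spec.necrotic_zone_radius_px, rng)

    image = np.full(shape, 235.0)
    image[tumor] = viable[tumor]
    image[damaged] = damage_tex[damaged]

    realized = float(damaged.sum() / tumor.sum())
    return PhantomOutput(
        image=RasterImage(image, spec.pixel_spacing,
                          provenance=f"phantom:{spec.group}:seed{spec.seed}"),
        tumor_mask=ROIMask(tumor, label="whole_tumor"),
        damaged_mask=ROIMask(damaged, label="damaged"),
        spec=spec, realized_damaged_fraction=realized)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = 0.0, hi: float = 1.0) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def gen_cohort(n_per_group: dict[str, int] | None = None,
               base_seed: int = 0, image_size: int = 1000,
               **spec_overrides) -> list[PhantomOutput]:
    """Deterministic cohort of phantoms with group-wise damaged fractions.

    Per-subject seeds and damage draws derive from ``base_seed``; each
    group's fractions are drawn from a truncated normal at the group's
    reported mean/SD.
    """
    n_per_group = dict(GROUP_N) if n_per_group is None else n_per_group
    out: list[PhantomOutput] = []
    k = 0
    for group in GROUPS:
        n = n_per_group.get(group, 0)
        if n < 1 and group in n_per_group:
            raise ValueError(f"need n >= 1 for group {group}")
        mean, sd = GROUP_DAMAGED_FRACTION[group]
        for j in range(n):
            ss = np.random.SeedSequence([base_seed, k])
            draw_rng = np.random.default_rng(ss)
            frac = _truncated_normal(draw_rng, mean, sd)
            seed = int(ss.generate_state(1)[0] % (2 ** 31))
            spec = PhantomSpec(group=group, image_size=image_size,
                               damaged_fraction_target=frac, seed=seed,
                               **spec_overrides)
            ph = gen_histology_phantom(spec)
            ph.subject_id = f"{group}_{j + 1}"
            out.append(ph)
            k += 1
    return out


def gen_dce_phantom(shape: tuple[int, int, int, int] = (24, 24, 4, 32),
                    perfusion_field: np.ndarray | None = None,
                    seed: int = 0, dt: float = 5.0, s0: float = 100.0,
                    k_enh: float = 1.0, injection_frame: int = 4,
                    ramp_s: float = 30.0, noise_sd: float = 0.0,
                    ) -> tuple[DCESeries, np.ndarray, dict]:
    """4D DCE phantom with ramp-plateau enhancement.

    Per voxel, S(t) = S0 (1 + k * perfusion * g(t)) + noise, where g ramps
    linearly from 0 to 1 over ``ramp_s`` seconds after injection and then
    plateaus. Returns the series, the analytic ground-truth initial AUC
    over the first 120 s post injection, and the generator parameters.
    """
    nx, ny, nz, nt = shape
    if nt < 4:
        raise ValueError("need at least 4 time frames")
    rng = np.random.default_rng(seed)
    if perfusion_field is None:
        perfusion_field = ndimage.gaussian_filter(
            rng.random((nx, ny, nz)), sigma=(3, 3, 1))
        lo, hi = perfusion_field.min(), perfusion_field.max()
        if hi > lo:
            perfusion_field = 0.2 + 0.8 * (perfusion_field - lo) / (hi - lo)
        else:
            perfusion_field = np.full((nx, ny, nz), 0.6)
    times = np.arange(nt) * dt
    t_inj = times[injection_frame]
    g = np.clip((times - t_inj) / ramp_s, 0.0, 1.0)
    signal = s0 * (1.0 + k_enh * perfusion_field[..., None] * g[None, None, None, :])
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    series = DCESeries(signal=signal, times=times,
                       baseline_frames=tuple(range(injection_frame)))
    # analytic integral of S0 k perf g(t) over [t_inj, t_inj + 120]
    window = min(120.0, times[-1] - t_inj)
    ramp_part = min(ramp_s, window)
    integral = ramp_part ** 2 / (2.0 * ramp_s) + max(0.0, window - ramp_s)
    auc_gt = s0 * k_enh * perfusion_field * integral
    params = {"dt": dt, "s0": s0, "k_enh": k_enh, "ramp_s": ramp_s,
              "injection_time": float(t_inj), "window_used": window,
              "noise_sd": noise_sd}
    return series, auc_gt, params
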