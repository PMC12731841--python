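"""Four-family radiomics texture features.

Builds the gray-level co-occurrence (GLCM), size-zone (GLSZM), dependence
(GLDM) and neighborhood gray-tone difference (NGTDM) matrices from a
quantized image plus ROI, and evaluates the canonical feature set of each
family: 24 GLCM + 16 GLSZM + 14 GLDM + 5 NGTDM = 59 features per region.

Feature definitions follow the standard published formula sets for these
families (the ones with exactly these cardinalities). Gray levels are
1-based; level 0 marks pixels outside the ROI.

Conventions, chosen once and applied everywhere:

* GLCM: distance 1, the four 2D directions (0, 45, 90, 135 degrees),
  symmetric accumulation; features are computed per direction on the
  direction's normalized matrix and then averaged over directions.
* GLSZM: zones are 8-connected.
* GLDM: a neighbor within Chebyshev distance ``distance`` is *dependent*
  when its gray level differs from the center by at most ``alpha``. The
  matrix stores neighbor-only dependence counts d (a lone pixel has d=0);
  feature formulas use the dependence size k = d + 1 (center included) so
  small-dependence emphases remain finite.
* NGTDM: the 8-neighborhood mean uses only in-ROI neighbors; border pixels
  therefore have smaller neighborhoods. A constant region gives contrast
  and busyness 0 and the coarseness cap value.
* Regions quantized to a single level (flat necrotic blocks) take their
  constant-image limits instead of erroring, so windowed texture maps stay
  defined everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_preprocess import QuantizedImage, ROIMask

logger = logging.getLogger("histotex")

_EPS = np.spacing(1.0)

#: Coarseness returned when the NGTDM coarseness denominator is zero.
COARSENESS_CAP = 1e6

#: The four 2D GLCM directions as (row, col) offsets: 0, 45, 90, 135 degrees.
GLCM_ANGLES: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation", "Joint Average", "Cluster Prominence", "Cluster Shade",
    "Cluster Tendency", "Contrast", "Correlation", "Difference Average",
    "Difference Entropy", "Difference Variance", "Joint Energy",
    "Joint Entropy", "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2", "Inverse Difference Moment",
    "Maximal Correlation Coefficient",
    "Inverse Difference Moment Normalized", "Inverse Difference",
    "Inverse Difference Normalized", "Inverse Variance",
    "Maximum Probability", "Sum Average", "Sum Entropy", "Sum of Squares",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "Small Area Emphasis", "Large Area Emphasis", "Gray-Level Non-Uniformity",
    "Gray-Level Non-Uniformity Normalized", "Size Zone Non-Uniformity",
    "Size Zone Non-Uniformity Normalized", "Zone Percentage",
    "Gray-Level Variance", "Zone Variance", "Zone Entropy",
    "Low Gray-Level Zone Emphasis", "High Gray-Level Zone Emphasis",
    "Small Area Low Gray-Level Emphasis", "Small Area High Gray-Level Emphasis",
    "Large Area Low Gray-Level Emphasis", "Large Area High Gray-Level Emphasis",
)

GLDM_FEATURES: tuple[str, ...] = (
    "Small Dependence Emphasis", "Large Dependence Emphasis",
    "Gray-Level Non-Uniformity", "Dependence Non-Uniformity",
    "Dependence Non-Uniformity Normalized", "Gray-Level Variance",
    "Dependence Variance", "Dependence Entropy", "Low Gray-Level Emphasis",
    "High Gray-Level Emphasis", "Small Dependence Low Gray-Level Emphasis",
    "Small Dependence High Gray-Level Emphasis",
    "Large Dependence Low Gray-Level Emphasis",
    "Large Dependence High Gray-Level Emphasis",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
)

FAMILIES: tuple[str, ...] = ("GLCM", "GLSZM", "GLDM", "NGTDM")
FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "GLCM": GLCM_FEATURES, "GLSZM": GLSZM_FEATURES,
    "GLDM": GLDM_FEATURES, "NGTDM": NGTDM_FEATURES,
}

#: All 59 prefixed feature names, in deterministic extraction order.
ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{fam} {name}" for fam in FAMILIES for name in FAMILY_FEATURES[fam]
)


@dataclass
class FeatureVector:
    """Ordered feature_name -> value map with a family tag per feature."""

    values: dict[str, float]
    families: dict[str, str]
    region_label: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families.values():
            counts[fam] = counts.get(fam, 0) + 1
        return counts


def _named(family: str, names: tuple[str, ...], vals: np.ndarray,
           region_label: str = "") -> FeatureVector:
    values = {f"{family} {n}": float(v) for n, v in zip(names, vals)}
    fams = {k: family for k in values}
    return FeatureVector(values=values, families=fams, region_label=region_label)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class GLCMatrix:
    counts: np.ndarray            # (n_angles, Ng, Ng)
    probabilities: np.ndarray     # (n_angles, Ng, Ng), per-angle normalized
    distance: int
    angles: tuple[tuple[int, int], ...]
    symmetric: bool
    ng: int


def _check_roi(q: QuantizedImage, roi: ROIMask) -> np.ndarray:
    if q.levels.shape != roi.mask.shape:
        raise ValueError("ROI shape does not match quantized image")
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    return roi.mask


def _shift_pairs(levels: np.ndarray, mask: np.ndarray,
                 dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Gray levels of all in-ROI pixel pairs at offset (dr, dc)."""
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a[ok], b[ok]


def compute_glcm(q: QuantizedImage, roi: ROIMask, distance: int = 1,
                 angles: tuple[tuple[int, int], ...] = GLCM_ANGLES,
                 symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence counts of in-ROI gray-level pairs at each direction.

    Both pixels of a pair must lie inside the ROI. Symmetric mode adds the
    transposed counts, making each matrix equal to its transpose.
    """
    if len(angles) == 0:
        raise ValueError("empty angle set")
    mask = _check_roi(q, roi)
    ng = q.ng
    counts = np.zeros((len(angles), ng, ng), dtype=float)
    for k, (dr, dc) in enumerate(angles):
        a, b = _shift_pairs(q.levels, mask, dr * distance, dc * distance)
        if a.size:
            np.add.at(counts[k], (a - 1, b - 1), 1.0)
    if symmetric:
        counts = counts + counts.transpose(0, 2, 1)
    totals = counts.sum(axis=(1, 2), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
    return GLCMatrix(counts=counts, probabilities=probs, distance=distance,
                     angles=tuple(angles), symmetric=symmetric, ng=ng)


def _glcm_features_single(p: np.ndarray, ng: int) -> np.ndarray:
    """The 24 GLCM features of one normalized co-occurrence matrix."""
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None]
    jj = i[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    ksum = (ii + jj).astype(int)          # 2..2Ng
    kdiff = np.abs(ii - jj).astype(int)   # 0..Ng-1
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    autocorr = float((p * ii * jj).sum())
    joint_avg = mu_x
    clus = ii + jj - mu_x - mu_y
    cluster_prom = float((p * clus ** 4).sum())
    cluster_shade = float((p * clus ** 3).sum())
    cluster_tend = float((p * clus ** 2).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    if sig_x * sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0
    diff_avg = float((p_diff * k_diff).sum())
    diff_ent = float(-(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum())
    diff_var = float((p_diff * (k_diff - diff_avg) ** 2).sum())
    joint_energy = float((p ** 2).sum())
    hxy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())

    # Informational measures of correlation
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pxy = px[:, None] * py[None, :]
    m = p > 0
    hxy1 = float(-(p[m] * np.log2(pxy[m])).sum())
    m2 = pxy > 0
    hxy2 = float(-(pxy[m2] * np.log2(pxy[m2])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = 0.0 if hxy2 < hxy else float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy))))

    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    mcc = _glcm_mcc(p, px, py)
    idmn = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    idf = float((p / (1.0 + np.abs(ii - jj))).sum())
    idn = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off = np.abs(ii - jj) > 0
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum())
    max_prob = float(p.max())
    sum_avg = float((p_sum * k_sum).sum())
    sum_ent = float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum())
    sum_squares = float((p * (ii - mu_x) ** 2).sum())

    return np.array([
        autocorr, joint_avg, cluster_prom, cluster_shade, cluster_tend,
        contrast, correlation, diff_avg, diff_ent, diff_var, joint_energy,
        hxy, imc1, imc2, idm, mcc, idmn, idf, idn, inv_var, max_prob,
        sum_avg, sum_ent, sum_squares,
    ])


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))."""
    present_i = px > 0
    present_k = py > 0
    if present_i.sum() < 2 or present_k.sum() < 2:
        return 1.0
    psub = p[np.ix_(present_i, present_k)]
    pxs = px[present_i]
    pys = py[present_k]
    # Q[a,b] = sum_k psub[a,k] psub[b,k] / (pxs[a] pys[k])
    w = psub / pys[None, :]
    q_mat = (psub @ w.T) / pxs[:, None]
    eig = np.linalg.eigvals(q_mat)
    eig = np.sort(np.real(eig))
    second = eig[-2]
    return float(np.sqrt(max(second, 0.0)))


def glcm_features(m: GLCMatrix, region_label: str = "") -> FeatureVector:
    """Direction-averaged 24-feature GLCM vector.

    Directions with no valid pixel pair are skipped; if no direction has a
    pair (single-pixel ROI) the constant-image limits are returned.
    """
    totals = m.counts.sum(axis=(1, 2))
    if not np.allclose(m.probabilities.sum(axis=(1, 2))[totals > 0], 1.0,
                       atol=1e-9):
        raise RuntimeError("GLCM probabilities are not normalized")
    per_angle = [
        _glcm_features_single(m.probabilities[k], m.ng)
        for k in range(len(m.angles)) if totals[k] > 0
    ]
    if not per_angle:
        point = np.zeros((m.ng, m.ng))
        point[0, 0] = 1.0
        per_angle = [_glcm_features_single(point, m.ng)]
    vals = np.mean(per_angle, axis=0)
    return _named("GLCM", GLCM_FEATURES, vals, region_label)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

@dataclass
class GLSZMatrix:
    counts: np.ndarray   # (Ng, Smax): number of zones of level i and size s
    nz: int              # total number of zones
    n_pixels: int        # in-ROI pixel count
    ng: int
    connectivity: int = 8


_STRUCT8 = np.ones((3, 3), dtype=bool)


def compute_glszm(q: QuantizedImage, roi: ROIMask) -> GLSZMatrix:
    """Count 8-connected same-level zones, indexed by (level, zone size)."""
    mask = _check_roi(q, roi)
    ng = q.ng
    n_pixels = int(mask.sum())
    zone_sizes: dict[int, list[int]] = {}
    smax = 1
    for lvl in np.unique(q.levels[mask]):
        lab, n_zones = ndimage.label((q.levels == lvl) & mask,
                                     structure=_STRUCT8)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes[int(lvl)] = sizes.tolist()
        smax = max(smax, int(sizes.max()))
    counts = np.zeros((ng, smax), dtype=float)
    for lvl, sizes in zone_sizes.items():
        for s in sizes:
            counts[lvl - 1, s - 1] += 1
    nz = int(counts.sum())
    return GLSZMatrix(counts=counts, nz=nz, n_pixels=n_pixels, ng=ng)


def glszm_features(m: GLSZMatrix, region_label: str = "") -> FeatureVector:
    if m.nz < 1:
        raise ValueError("GLSZM has no zones")
    P = m.counts
    nz = float(m.nz)
    ng, smax = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    p = P / nz
    pg = P.sum(axis=1)   # per gray level
    ps = P.sum(axis=0)   # per zone size

    sae = float((P / s ** 2).sum() / nz)
    lae = float((P * s ** 2).sum() / nz)
    gln = float((pg ** 2).sum() / nz)
    glnn = float((pg ** 2).sum() / nz ** 2)
    szn = float((ps ** 2).sum() / nz)
    sznn = float((ps ** 2).sum() / nz ** 2)
    zone_pct = nz / float(m.n_pixels)
    mu_i = float((p * i).sum())
    glv = float((p * (i - mu_i) ** 2).sum())
    mu_s = float((p * s).sum())
    zv = float((p * (s - mu_s) ** 2).sum())
    ze = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    lglze = float((P / i ** 2).sum() / nz)
    hglze = float((P * i ** 2).sum() / nz)
    salgle = float((P / (i ** 2 * s ** 2)).sum() / nz)
    sahgle = float((P * i ** 2 / s ** 2).sum() / nz)
    lalgle = float((P * s ** 2 / i ** 2).sum() / nz)
    lahgle = float((P * i ** 2 * s ** 2).sum() / nz)

    vals = np.array([sae, lae, gln, glnn, szn, sznn, zone_pct, glv, zv, ze,
                     lglze, hglze, salgle, sahgle, lalgle, lahgle])
    return _named("GLSZM", GLSZM_FEATURES, vals, region_label)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

@dataclass
class GLDMatrix:
    counts: np.ndarray   # (Ng, Dmax+1): pixels with level i and d dependent neighbors
    alpha: int
    distance: int
    n_pixels: int
    ng: int


def _chebyshev_offsets(distance: int) -> list[tuple[int, int]]:
    return [(dr, dc)
            for dr in range(-distance, distance + 1)
            for dc in range(-distance, distance + 1)
            if (dr, dc) != (0, 0)]


def compute_gldm(q: QuantizedImage, roi: ROIMask, alpha: int = 0,
                 distance: int = 1) -> GLDMatrix:
    """Dependence counts: for each in-ROI pixel, the number of in-ROI
    neighbors within the Chebyshev distance whose gray level differs by at
    most ``alpha``. The center pixel itself is not counted."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    mask = _check_roi(q, roi)
    h, w = q.levels.shape
    dep = np.zeros((h, w), dtype=np.int32)
    for dr, dc in _chebyshev_offsets(distance):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q.levels[r0:r1, c0:c1]
        b = q.levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (mask[r0:r1, c0:c1]
              & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
              & (np.abs(a - b) <= alpha))
        dep[r0:r1, c0:c1][ok] += 1
    dmax = int(dep[mask].max()) if mask.any() else 0
    counts = np.zeros((q.ng, dmax + 1), dtype=float)
    np.add.at(counts, (q.levels[mask] - 1, dep[mask]), 1.0)
    return GLDMatrix(counts=counts, alpha=alpha, distance=distance,
                     n_pixels=int(mask.sum()), ng=q.ng)


def gldm_features(m: GLDMatrix, region_label: str = "") -> FeatureVector:
    total = m.counts.sum()
    if total < 1:
        raise ValueError("GLDM is empty")
    P = m.counts
    ng, ndep = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    # dependence size including the center pixel; keeps 1/k^2 finite at d=0
    k = np.arange(1, ndep + 1, dtype=float)[None, :]
    nz = float(total)
    p = P / nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)

    sde = float((P / k ** 2).sum() / nz)
    lde = float((P * k ** 2).sum() / nz)
    gln = float((pg ** 2).sum() / nz)
    dn = float((pd ** 2).sum() / nz)
    dnn = float((pd ** 2).sum() / nz ** 2)
    mu_i = float((p * i).sum())
    glv = float((p * (i - mu_i) ** 2).sum())
    mu_k = float((p * k).sum())
    dv = float((p * (k - mu_k) ** 2).sum())
    de = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
    lgle = float((P / i ** 2).sum() / nz)
    hgle = float((P * i ** 2).sum() / nz)
    sdlgle = float((P / (i ** 2 * k ** 2)).sum() / nz)
    sdhgle = float((P * i ** 2 / k ** 2).sum() / nz)
    ldlgle = float((P * k ** 2 / i ** 2).sum() / nz)
    ldhgle = float((P * i ** 2 * k ** 2).sum() / nz)

    vals = np.array([sde, lde, gln, dn, dnn, glv, dv, de, lgle, hgle,
                     sdlgle, sdhgle, ldlgle, ldhgle])
    return _named("GLDM", GLDM_FEATURES, vals, region_label)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

@dataclass
class NGTDMatrix:
    s: np.ndarray        # per-level summed |level - neighborhood mean|
    n: np.ndarray        # per-level pixel counts
    p: np.ndarray        # per-level probabilities n_i / sum(n)
    ng: int


def compute_ngtdm(q: QuantizedImage, roi: ROIMask,
                  distance: int = 1) -> NGTDMatrix:
    """Accumulate |level - mean of in-ROI neighborhood| per gray level.

    Pixels with no in-ROI neighbor are skipped; an ROI in which no pixel
    has a neighbor is an error.
    """
    mask = _check_roi(q, roi)
    h, w = q.levels.shape
    nb_sum = np.zeros((h, w), dtype=float)
    nb_cnt = np.zeros((h, w), dtype=np.int32)
    for dr, dc in _chebyshev_offsets(distance):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        nb_mask = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        nb_sum[r0:r1, c0:c1] += np.where(
            nb_mask, q.levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc], 0)
        nb_cnt[r0:r1, c0:c1] += nb_mask
    valid = mask & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no ROI pixel has an in-ROI neighbor")
    lv = q.levels[valid]
    diffs = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(q.ng, dtype=float)
    n = np.zeros(q.ng, dtype=float)
    np.add.at(s, lv - 1, diffs)
    np.add.at(n, lv - 1, 1.0)
    p = n / n.sum()
    return NGTDMatrix(s=s, n=n, p=p, ng=q.ng)


def ngtdm_features(m: NGTDMatrix, region_label: str = "") -> FeatureVector:
    if m.n.sum() < 1:
        raise ValueError("NGTDM is empty")
    i = np.arange(1, m.ng + 1, dtype=float)
    p, s = m.p, m.s
    n_total = float(m.n.sum())
    present = p > 0
    n_levels = int(present.sum())

    denom = float((p * s).sum())
    coarseness = 1.0 / denom if denom > 0 else COARSENESS_CAP

    if n_levels > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        ii = i[present][:, None]
        jj = i[present][None, :]
        contrast = (float((pi * pj * (ii - jj) ** 2).sum())
                    / (n_levels * (n_levels - 1)) * float(s.sum()) / n_total)
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = denom / busy_den if busy_den > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        complexity = float((np.abs(ii - jj)
                            * (pi * si + pj * sj) / (pi + pj)).sum()) / n_total
        strength_num = float(((pi + pj) * (ii - jj) ** 2).sum())
        strength = strength_num / float(s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    vals = np.array([coarseness, contrast, busyness, complexity, strength])
    return _named("NGTDM", NGTDM_FEATURES, vals, region_label)


# ---------------------------------------------------------------------------
# Combined extraction
# ---------------------------------------------------------------------------

def extract_all(q: QuantizedImage, roi: ROIMask,
                glcm_distance: int = 1, gldm_alpha: int = 0,
                gldm_distance: int = 1, ngtdm_distance: int = 1,
                families: tuple[str, ...] = FAMILIES,
                region_label: str = "") -> FeatureVector:
    """All texture features of a region: 24 GLCM + 16 GLSZM + 14 GLDM +
    5 NGTDM = 59 named entries in deterministic order (or the requested
    family subset)."""
    mask = _check_roi(q, roi)
    parts: list[FeatureVector] = []
    for fam in families:
        if fam == "GLCM":
            parts.append(glcm_features(
                compute_glcm(q, roi, distance=glcm_distance), region_label))
        elif fam == "GLSZM":
            parts.append(glszm_features(compute_glszm(q, roi), region_label))
        elif fam == "GLDM":
            parts.append(gldm_features(
                compute_gldm(q, roi, alpha=gldm_alpha, distance=gldm_distance),
                region_label))
        elif fam == "NGTDM":
            try:
                parts.append(ngtdm_features(
                    compute_ngtdm(q, roi, distance=ngtdm_distance),
                    region_label))
            except ValueError:
                # isolated-pixel ROI: constant-image limits
                vals = np.array([COARSENESS_CAP, 0.0, 0.0, 0.0, 0.0])
                parts.append(_named("NGTDM", NGTDM_FEATURES, vals,
                                    region_label))
        else:
            raise ValueError(f"unknown texture family: {fam}")
    values: dict[str, float] = {}
    fams: dict[str, str] = {}
    for part in parts:
        values.update(part.values)
        fams.update(part.families)
    return FeatureVector(values=values, families=fams,
                         region_label=region_label)
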