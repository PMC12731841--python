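"""Independent brute-force constructions of the four texture matrices.

Deliberately naive (per-pixel Python loops, BFS flood fill) so they share
no code path with the vectorized implementations they check.
"""

from collections import deque

import numpy as np


def glcm_oracle(levels, mask, ng, distance, angles, symmetric):
    """Exhaustive pixel-pair enumeration at each offset."""
    h, w = levels.shape
    counts = np.zeros((len(angles), ng, ng))
    for k, (dr, dc) in enumerate(angles):
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[k, levels[r, c] - 1, levels[r2, c2] - 1] += 1
    if symmetric:
        counts = counts + counts.transpose(0, 2, 1)
    return counts


def glszm_oracle(levels, mask, ng):
    """8-connected flood fill per gray level; counts[(i, s)] zones."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            lvl = levels[r, c]
            queue = deque([(r, c)])
            seen[r, c] = True
            size = 0
            while queue:
                y, x = queue.popleft()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < h and 0 <= xx < w and mask[yy, xx]
                                and not seen[yy, xx] and levels[yy, xx] == lvl):
                            seen[yy, xx] = True
                            queue.append((yy, xx))
            zones.append((lvl, size))
    smax = max(s for _, s in zones)
    counts = np.zeros((ng, smax))
    for lvl, size in zones:
        counts[lvl - 1, size - 1] += 1
    return counts


def gldm_oracle(levels, mask, ng, alpha, distance):
    """Per-pixel neighbor scan within the Chebyshev distance."""
    h, w = levels.shape
    deps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            d = 0
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                            and abs(int(levels[rr, cc]) - int(levels[r, c])) <= alpha):
                        d += 1
            deps.append((levels[r, c], d))
    dmax = max(d for _, d in deps)
    counts = np.zeros((ng, dmax + 1))
    for lvl, d in deps:
        counts[lvl - 1, d] += 1
    return counts


def ngtdm_oracle(levels, mask, ng, distance):
    """Per-pixel neighborhood-mean absolute differences."""
    h, w = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = []
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        nb.append(levels[rr, cc])
            if nb:
                lvl = levels[r, c]
                s[lvl - 1] += abs(lvl - sum(nb) / len(nb))
                n[lvl - 1] += 1
    p = n / n.sum()
    return s, n, p


def anova_oracle(groups):
    """Hand sum-of-squares decomposition: F, p, R^2."""
    from scipy.stats import f as fdist

    allv = np.concatenate(groups)
    grand = allv.mean()
    k = len(groups)
    n = allv.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sst = ((allv - grand) ** 2).sum()
    f_stat = (ssb / (k - 1)) / (ssw / (n - k))
    p = fdist.sf(f_stat, k - 1, n - k)
    return f_stat, p, ssb / sst
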