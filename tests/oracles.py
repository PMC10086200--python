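"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration with plain
Python loops — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _in_bounds(p, shape) -> bool:
    return all(0 <= p[i] < shape[i] for i in range(3))


def brute_glcm(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    """Symmetrized co-occurrence counts by exhaustive pair enumeration."""
    out = np.zeros((len(directions), ng, ng))
    for k, d in enumerate(directions):
        for p in itertools.product(*(range(s) for s in levels.shape)):
            q = tuple(p[i] + d[i] for i in range(3))
            if not _in_bounds(q, levels.shape):
                continue
            a, b = levels[p], levels[q]
            if a > 0 and b > 0:
                out[k, a - 1, b - 1] += 1
                out[k, b - 1, a - 1] += 1
    return out


def brute_glrlm(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    """Maximal-run counts by walking every run start."""
    max_run = max(levels.shape)
    out = np.zeros((len(directions), ng, max_run))
    for k, d in enumerate(directions):
        for p in itertools.product(*(range(s) for s in levels.shape)):
            lev = levels[p]
            if lev == 0:
                continue
            prev = tuple(p[i] - d[i] for i in range(3))
            if _in_bounds(prev, levels.shape) and levels[prev] == lev:
                continue  # not a run start
            length = 1
            q = tuple(p[i] + d[i] for i in range(3))
            while _in_bounds(q, levels.shape) and levels[q] == lev:
                length += 1
                q = tuple(q[i] + d[i] for i in range(3))
            out[k, lev - 1, length - 1] += 1
    return out


def _flood(levels: np.ndarray, start, neighbors) -> set:
    lev = levels[start]
    zone = {start}
    stack = [start]
    while stack:
        p = stack.pop()
        for d in neighbors:
            q = tuple(p[i] + d[i] for i in range(3))
            if _in_bounds(q, levels.shape) and q not in zone and levels[q] == lev:
                zone.add(q)
                stack.append(q)
    return zone


def brute_glszm(levels: np.ndarray, ng: int) -> list[tuple[int, int]]:
    """(gray level, zone size) pairs via 26-connected flood fill."""
    seen: set = set()
    zones = []
    for p in itertools.product(*(range(s) for s in levels.shape)):
        if levels[p] == 0 or p in seen:
            continue
        z = _flood(levels, p, NEIGHBORS_26)
        seen |= z
        zones.append((int(levels[p]), len(z)))
    return sorted(zones)


def brute_gldm(levels: np.ndarray, ng: int) -> list[tuple[int, int]]:
    """(gray level, dependence) per ROI voxel; dependence = 1 + number of
    26-neighbors with the identical level (center counts)."""
    out = []
    for p in itertools.product(*(range(s) for s in levels.shape)):
        lev = levels[p]
        if lev == 0:
            continue
        dep = 1
        for d in NEIGHBORS_26:
            q = tuple(p[i] + d[i] for i in range(3))
            if _in_bounds(q, levels.shape) and levels[q] == lev:
                dep += 1
        out.append((int(lev), dep))
    return sorted(out)


def brute_ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    """(n_i, p_i, s_i) table; voxels with no in-ROI neighbor excluded."""
    table = np.zeros((ng, 3))
    total = 0
    for p in itertools.product(*(range(s) for s in levels.shape)):
        lev = levels[p]
        if lev == 0:
            continue
        nb = [
            levels[tuple(p[i] + d[i] for i in range(3))]
            for d in NEIGHBORS_26
            if _in_bounds(tuple(p[i] + d[i] for i in range(3)), levels.shape)
        ]
        nb = [v for v in nb if v > 0]
        if not nb:
            continue
        table[lev - 1, 0] += 1
        table[lev - 1, 2] += abs(lev - sum(nb) / len(nb))
        total += 1
    if total:
        table[:, 1] = table[:, 0] / total
    return table


def brute_connected_components(bright: np.ndarray, neighbors) -> int:
    """Number of connected components of a boolean lattice."""
    levels = bright.astype(int)
    seen: set = set()
    n = 0
    for p in itertools.product(*(range(s) for s in bright.shape)):
        if levels[p] and p not in seen:
            seen |= _flood(levels, p, neighbors)
            n += 1
    return n


def brute_auroc(scores, labels) -> float:
    """Concordant-pair fraction, ties counting one half."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels) -> tuple[float, float]:
    """Best (cutoff, J) over observed scores, pos iff score > t, ties to
    the higher threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best = None
    for t in sorted(set(scores.tolist())):
        pred = scores > t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if best is None or j > best[1] or (j == best[1] and t > best[0]):
            best = (t, j)
    return best


def brute_patient_criteria(depots) -> tuple[bool, bool]:
    """(criterion1, criterion2) from a list of
    (region, laterality, positive) triples — a literal reading of the
    diagnosis rules."""
    crit1 = any(pos for _, _, pos in depots)
    crit2 = False
    for region in ("cervical", "supraclavicular", "axillary"):
        left = any(r == region and l == "left" and pos for r, l, pos in depots)
        right = any(r == region and l == "right" and pos for r, l, pos in depots)
        if left and right:
            crit2 = True
    if any(r == "mediastinal" and pos for r, _, pos in depots):
        crit2 = True
    return crit1, crit2


def brute_agatston(slice_hu: np.ndarray, pixel_area: float) -> float:
    """Hand application of the per-slice weight table on a 2D HU grid:
    8-connected components of pixels > 130 HU, >= 3 pixels, score =
    area x weight(max HU)."""
    bright = slice_hu > 130.0
    levels = bright.astype(int)[None]  # reuse 3D flood fill on a 1-slice grid
    neighbors = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen: set = set()
    score = 0.0
    for p in itertools.product(range(1), *(range(s) for s in slice_hu.shape)):
        if levels[p] and p not in seen:
            comp = _flood(levels, p, neighbors)
            seen |= comp
            if len(comp) < 3:
                continue
            max_hu = max(slice_hu[c[1], c[2]] for c in comp)
            w = 4 if max_hu >= 400 else 3 if max_hu >= 300 else 2 if max_hu >= 200 else 1
            score += len(comp) * pixel_area * w
    return score
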