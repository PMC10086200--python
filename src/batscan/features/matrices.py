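"""Gray-level matrix builders: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders take an integer level lattice (level 0 marks voxels outside
the ROI, levels 1..Ng inside) and return raw count matrices.  Conventions:

* 13 unique 3D directions at Chebyshev distance 1 for GLCM and GLRLM
  (each direction also counts its opposite via symmetrization / maximal
  runs);
* 26-connectivity for GLSZM zones;
* the distance-1 26-neighborhood for GLDM and NGTDM;
* GLDM dependence of a voxel = 1 + number of neighbors with identical
  level (the center counts, so the dependence index starts at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: The 13 lexicographically-positive offsets of the 26-neighborhood.
DIRECTIONS_13 = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_NEIGHBORS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


@dataclass
class GrayLevelMatrix:
    """A raw texture count matrix plus its parameters."""

    kind: str
    matrix: np.ndarray  # (Ndir, Ng, ...) for GLCM/GLRLM, (Ng, ...) otherwise
    n_levels: int
    params: dict


def _shifted_views(arr: np.ndarray, offset):
    """Two views of arr such that view_a[i] and view_b[i] are offset-apart."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, arr.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm(levels: np.ndarray, n_levels: int, directions=DIRECTIONS_13) -> GrayLevelMatrix:
    """Symmetrized co-occurrence counts per direction at distance 1."""
    ng = n_levels
    mats = np.zeros((len(directions), ng, ng))
    for k, off in enumerate(directions):
        a, b = _shifted_views(levels, off)
        valid = (a > 0) & (b > 0)
        counts = np.bincount(
            (a[valid].astype(np.int64) - 1) * ng + (b[valid].astype(np.int64) - 1),
            minlength=ng * ng,
        ).reshape(ng, ng)
        mats[k] = counts + counts.T
    return GrayLevelMatrix("GLCM", mats, ng, {"distance": 1, "directions": directions})


def glrlm(levels: np.ndarray, n_levels: int, directions=DIRECTIONS_13) -> GrayLevelMatrix:
    """Maximal same-level run counts per direction."""
    ng = n_levels
    max_run = int(max(levels.shape))
    mats = np.zeros((len(directions), ng, max_run))
    shape = np.array(levels.shape)
    for k, off in enumerate(directions):
        off_a = np.array(off)
        # run starts: in-ROI voxels whose predecessor along -off is absent/different
        a, b = _shifted_views(levels, off)  # a at p, b at p + off
        same_as_prev = np.zeros(levels.shape, dtype=bool)
        sl_b = tuple(
            slice(o, n) if o > 0 else slice(0, n + o) if o < 0 else slice(None)
            for o, n in zip(off, levels.shape)
        )
        same_as_prev[sl_b] = (a == b) & (a > 0) & (b > 0)
        starts = np.argwhere((levels > 0) & ~same_as_prev)
        if len(starts) == 0:
            continue
        lev = levels[tuple(starts.T)]
        pos = starts.copy()
        alive = np.arange(len(starts))
        run_len = np.ones(len(starts), dtype=np.int64)
        while len(alive):
            nxt = pos + off_a
            inside = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(alive), dtype=bool)
            cont[inside] = levels[tuple(nxt[inside].T)] == lev[alive][inside]
            run_len[alive[cont]] += 1
            alive = alive[cont]
            pos = nxt[cont]
        np.add.at(mats[k], (lev - 1, run_len - 1), 1.0)
    return GrayLevelMatrix("GLRLM", mats, ng, {"directions": directions})


def glszm(levels: np.ndarray, n_levels: int) -> GrayLevelMatrix:
    """Zone-size counts: 26-connected same-level components."""
    ng = n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    for lev in range(1, ng + 1):
        lab, n = ndimage.label(levels == lev, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lev, int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, max_size))
    for lev, s in zones:
        mat[lev - 1, s - 1] += 1
    return GrayLevelMatrix("GLSZM", mat, ng, {"connectivity": 26})


def gldm(levels: np.ndarray, n_levels: int) -> GrayLevelMatrix:
    """Dependence counts: P[i, j] = number of ROI voxels with level i+1
    and dependence j+1, dependence = 1 + equal-level 26-neighbors."""
    ng = n_levels
    inroi = levels > 0
    dep = np.ones(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        a, b = _shifted_views(levels, off)
        sl_a = tuple(
            slice(0, n - o) if o > 0 else slice(-o, n) if o < 0 else slice(None)
            for o, n in zip(off, levels.shape)
        )
        eq = np.zeros(levels.shape, dtype=np.int64)
        eq[sl_a] = ((a == b) & (a > 0) & (b > 0)).astype(np.int64)
        dep += eq
    max_dep = int(dep[inroi].max())
    mat = np.zeros((ng, max_dep))
    np.add.at(mat, (levels[inroi] - 1, dep[inroi] - 1), 1.0)
    return GrayLevelMatrix("GLDM", mat, ng, {"alpha": 0, "distance": 1})


def ngtdm(levels: np.ndarray, n_levels: int) -> GrayLevelMatrix:
    """Neighborhood gray-tone difference table.

    Returns a (Ng, 3) array with columns n_i (voxel count), p_i
    (probability) and s_i (summed absolute difference from the mean level
    of each voxel's in-ROI 26-neighborhood).  Voxels with no in-ROI
    neighbor are excluded.
    """
    ng = n_levels
    inroi = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS_26:
        a, b = _shifted_views(levels, off)
        sl_a = tuple(
            slice(0, n - o) if o > 0 else slice(-o, n) if o < 0 else slice(None)
            for o, n in zip(off, levels.shape)
        )
        contrib = np.zeros(levels.shape)
        cnt = np.zeros(levels.shape, dtype=np.int64)
        contrib[sl_a] = np.where(b > 0, b, 0)
        cnt[sl_a] = (b > 0).astype(np.int64)
        nb_sum += contrib
        nb_cnt += cnt
    valid = inroi & (nb_cnt > 0)
    table = np.zeros((ng, 3))
    if valid.any():
        lev = levels[valid]
        diff = np.abs(lev - nb_sum[valid] / nb_cnt[valid])
        np.add.at(table[:, 0], lev - 1, 1.0)
        np.add.at(table[:, 2], lev - 1, diff)
        table[:, 1] = table[:, 0] / table[:, 0].sum()
    return GrayLevelMatrix("NGTDM", table, ng, {"distance": 1})
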