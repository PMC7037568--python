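"""Envelope similarity: overlap correlation, optimal alignment, clustering.

The volume-overlap correlation coefficient cc = |A n B| / sqrt(|A| |B|)
measures the shared occupied volume of two grids against the geometric
mean of their volumes.  Because the grids are size-normalized by
construction (bounding sphere = 15 voxel units regardless of physical
radius), comparing occupancies directly is comparing shapes scaled to the
same size.  ``align_cc`` maximizes cc over a quasi-uniform rotation grid
(the 24 cube rotations are always included), the mirror image — solution
scattering cannot distinguish enantiomers — and integer translations near
centroid superposition, refining the best orientation basins by local
descent at shrinking angular steps.  Repeated
reconstructions are grouped by average-linkage hierarchical clustering of
the correlation distance 1 - cc.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.fft import irfftn, rfftn
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .voxel_shapes import CENTER_INDEX, GRID_SIZE, VoxelGrid

#: default rotation-grid size (24 exact cube rotations + quasi-uniform fill)
N_ROTATIONS = 576
#: translation search window around centroid superposition, voxels
SHIFT_WINDOW = 5
#: FFT box for the translation cross-correlation (>= grid + window)
_FFT_N = 40


class EmptyGridError(ValueError):
    """Overlap correlation is undefined for an empty grid."""


@dataclass
class Alignment:
    """Best rigid (possibly improper) superposition of one grid on another."""

    rotation: np.ndarray
    translation: np.ndarray
    mirrored: bool
    cc: float


@dataclass
class ClusterResult:
    """Pairwise correlation distances, linkage tree and flat labels."""

    distance_matrix: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray
    cutoff: float


def overlap_cc(a: VoxelGrid, b: VoxelGrid) -> float:
    """cc = |A n B| / sqrt(|A| |B|) over occupied voxels, no alignment."""
    na, nb = a.n_occupied, b.n_occupied
    if na == 0 or nb == 0:
        raise EmptyGridError("overlap cc undefined for empty grids")
    inter = int(np.logical_and(a.occupancy, b.occupancy).sum())
    return inter / np.sqrt(na * nb)


def _super_fibonacci(n: int) -> np.ndarray:
    """Deterministic quasi-uniform rotation sample (super-Fibonacci spiral)."""
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041  # positive root of x^4 = x + 4
    i = np.arange(n)
    s = i + 0.5
    t = s / n
    d = 2 * np.pi * s
    r = np.sqrt(t)
    R = np.sqrt(1.0 - t)
    alpha = d / phi
    beta = d / psi
    quat = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                     R * np.sin(beta), R * np.cos(beta)], axis=1)
    return Rotation.from_quat(quat).as_matrix()


@lru_cache(maxsize=4)
def _rotation_set(n: int) -> np.ndarray:
    cube = Rotation.create_group("O").as_matrix()
    extra = _super_fibonacci(max(n - len(cube), 0))
    return np.concatenate([cube, extra]) if len(extra) else cube


def _rasterize(points: np.ndarray) -> np.ndarray:
    """Centered float coords (N, 3) -> binary grid (points outside dropped)."""
    idx = np.rint(points + CENTER_INDEX).astype(np.int64)
    ok = ((idx >= 0) & (idx < GRID_SIZE)).all(axis=1)
    occ = np.zeros((GRID_SIZE,) * 3, dtype=np.uint8)
    occ[tuple(idx[ok].T)] = 1
    return occ


def _pull_rotate(occ: np.ndarray, center: np.ndarray, R: np.ndarray,
                 mirror: bool) -> np.ndarray:
    """Resample ``occ`` under (mirror then) rotation about its centroid.

    Pull scheme with trilinear interpolation re-thresholded at 0.5: every
    output voxel looks up its source neighborhood, so no occupancy is lost
    to rounding collisions and surface jitter stays below the overlap
    tolerance.  The result is centered at the grid center; ``center`` is
    the occupied centroid of the source in voxel indices.
    """
    from scipy import ndimage

    mat = R.T if not mirror else np.diag([-1.0, 1.0, 1.0]) @ R.T
    c0 = np.full(3, float(CENTER_INDEX))
    # integer offset keeps exact lattice rotations exact; the subvoxel
    # remainder is absorbed by the integer translation search downstream
    offset = np.rint(center - mat @ c0)
    out = ndimage.affine_transform(occ.astype(np.float32), mat,
                                   offset=offset, order=1)
    return (out > 0.5).astype(np.uint8)


def transform_grid(grid: VoxelGrid, rotation: np.ndarray,
                   translation: np.ndarray | tuple = (0.0, 0.0, 0.0),
                   mirror: bool = False) -> VoxelGrid:
    """Rigidly transform an envelope about its occupied centroid.

    Volume-preserving nearest-neighbor resampling; the result is centered
    at the grid center plus ``translation`` (voxels).  Useful for building
    test cases and for applying a found Alignment.
    """
    centroid = grid.occupied_coords().mean(axis=0) + CENTER_INDEX
    rolled = _pull_rotate(grid.occupancy, centroid, rotation, mirror)
    shift = np.rint(np.asarray(translation)).astype(int)
    if shift.any():
        rolled = np.roll(rolled, shift, axis=(0, 1, 2))
    return VoxelGrid(rolled, radius=grid.radius)


def _overlap_counts_fft(fb_conj: np.ndarray, a_occ: np.ndarray) -> np.ndarray:
    """Cross-correlation counts |A shifted by s n B| for all shifts."""
    fa = rfftn(a_occ.astype(np.float32), s=(_FFT_N,) * 3)
    corr = irfftn(fa * fb_conj, s=(_FFT_N,) * 3)
    return corr


def _best_shifted_overlap(corr: np.ndarray, window: int = SHIFT_WINDOW
                          ) -> float:
    """Max correlation over shifts within +/- window voxels (wrapped FFT)."""
    sl = np.r_[0:window + 1, _FFT_N - window:_FFT_N]
    sub = corr[np.ix_(sl, sl, sl)]
    return float(sub.max())


def align_cc(a: VoxelGrid, b: VoxelGrid, n_rotations: int = N_ROTATIONS,
             refine: bool = True, mirror: bool = True) -> Alignment:
    """Maximize the overlap cc of ``a`` onto ``b`` over rigid superpositions.

    Searches ``n_rotations`` quasi-uniform rotations (always containing the
    24 cube rotations), optionally the mirror image of ``a``, and integer
    translations within +/-5 voxels of centroid superposition; the best
    few orientation basins are then refined by local descent at 10, 5, 2
    and 1 degree steps.  The identity is always a candidate, so the result
    is never worse than the unaligned cc.
    """
    na, nb = a.n_occupied, b.n_occupied
    if na == 0 or nb == 0:
        raise EmptyGridError("alignment undefined for empty grids")
    a_centroid = a.occupied_coords().mean(axis=0) + CENTER_INDEX
    # b is shifted so its centroid sits at the grid center: translation
    # search then reduces to small shifts around zero
    pb = b.occupied_coords()
    b_cen = _rasterize(pb - pb.mean(axis=0))
    fb_conj = np.conj(rfftn(b_cen.astype(np.float32), s=(_FFT_N,) * 3))

    def score(R: np.ndarray, mirrored: bool) -> float:
        occ = _pull_rotate(a.occupancy, a_centroid, R, mirrored)
        n_rot = occ.sum()
        if n_rot == 0:
            return 0.0
        corr = _overlap_counts_fft(fb_conj, occ)
        return _best_shifted_overlap(corr) / np.sqrt(n_rot * nb)

    rotations = _rotation_set(n_rotations)
    candidates = [(R, False) for R in rotations]
    if mirror:
        candidates += [(R, True) for R in rotations]
    scored = [(score(R, m), i) for i, (R, m) in enumerate(candidates)]
    scored.sort(reverse=True, key=lambda t: t[0])
    best_cc, best_i = scored[0]
    best_R, best_m = candidates[best_i]

    if refine:
        # the coarse grid has a covering radius of ~15-20 degrees, so
        # refine the few best basins by local descent at shrinking steps
        for cc0, i in scored[:6]:
            R, m = candidates[i]
            cc_loc = cc0
            for step_deg in (10.0, 5.0, 2.0, 1.0):
                step = np.deg2rad(step_deg)
                for _ in range(4):
                    improved = False
                    for ax in range(3):
                        for sign in (1.0, -1.0):
                            delta = np.zeros(3)
                            delta[ax] = sign * step
                            Rtry = Rotation.from_rotvec(delta).as_matrix() @ R
                            cc = score(Rtry, m)
                            if cc > cc_loc:
                                cc_loc, R = cc, Rtry
                                improved = True
                    if not improved:
                        break
            if cc_loc > best_cc:
                best_cc, best_R, best_m = cc_loc, R, m

    # recover the best integer translation for reporting
    occ = _pull_rotate(a.occupancy, a_centroid, best_R, best_m)
    corr = _overlap_counts_fft(fb_conj, occ)
    sl = np.r_[0:SHIFT_WINDOW + 1, _FFT_N - SHIFT_WINDOW:_FFT_N]
    sub = corr[np.ix_(sl, sl, sl)]
    k = np.unravel_index(np.argmax(sub), sub.shape)
    shift = np.array([sl[i] if sl[i] <= SHIFT_WINDOW else sl[i] - _FFT_N
                      for i in k])
    return Alignment(rotation=best_R, translation=shift, mirrored=best_m,
                     cc=min(best_cc, 1.0))


def random_pair_baseline(models: list[VoxelGrid], n_pairs: int, seed: int = 0,
                         n_rotations: int = 96, refine: bool = False
                         ) -> tuple[float, float]:
    """Mean and std of aligned cc over randomly sampled model pairs.

    The null distribution of cc between unrelated size-normalized shapes;
    a coarser rotation grid keeps large samples affordable.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    rng = np.random.default_rng(seed)
    ccs = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(models), size=2, replace=False)
        ccs.append(align_cc(models[i], models[j], n_rotations=n_rotations,
                            refine=refine).cc)
    return float(np.mean(ccs)), float(np.std(ccs))


def cluster_models(models: list[VoxelGrid], cutoff: float = 0.3,
                   n_rotations: int = N_ROTATIONS) -> ClusterResult:
    """Average-linkage clustering on the correlation distance 1 - align_cc.

    Flat labels are produced by cutting the tree at ``cutoff`` (default
    0.3, i.e. members of a cluster overlap with cc >~ 0.7 on average).
    """
    n = len(models)
    if n < 2:
        raise ValueError("need at least 2 models")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cc = align_cc(models[i], models[j], n_rotations=n_rotations).cc
            D[i, j] = D[j, i] = 1.0 - cc
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    return ClusterResult(distance_matrix=D, linkage=Z, labels=labels,
                         cutoff=cutoff)
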