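"""Size-normalized binary voxel envelopes and a synthetic shape corpus.

Every model handled by the pipeline lives on a fixed 31x31x31 binary grid.
Before voxelization a structure is translated so the center of its minimal
bounding sphere sits at the grid center (voxel (15,15,15)) and uniformly
scaled so the bounding-sphere radius spans 15 voxel units; the physical size
is carried separately as the grid's ``radius`` attribute (reference 50 A,
voxel edge = radius/15 A).  This normalization decouples shape from size: the
same grid can be interpreted at any model radius, which is what allows the
reconstruction engine to treat the radius as one extra free parameter.

The synthetic shape generator replaces a database-derived training corpus
with six parametric families (ellipsoids, cylinders, dumbbells, tori,
prisms, blob unions) rasterized at random orientations.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import AtomicModel

GRID_SIZE = 31
#: voxel index of the grid center along each axis
CENTER_INDEX = GRID_SIZE // 2
#: bounding-sphere radius expressed in voxel units (voxel edge = radius/15)
SCALE_VOX = 15.0
#: largest center-to-voxel-center distance the cubic grid can represent;
#: occupancy is clipped to this ball so grids embed in a sphere
BALL_RADIUS_VOX = 15.5
REFERENCE_RADIUS = 50.0
#: occupancy rule: a voxel is occupied iff its center lies within this many
#: voxel edges of a model point
VICINITY_VOX = 1.0

FAMILIES = ("ellipsoid", "cylinder", "dumbbell", "torus", "prism",
            "blob_union")


class DegenerateModelError(ValueError):
    """All model points coincide; no shape can be voxelized."""


@dataclass
class VoxelGrid:
    """A 31^3 binary occupancy grid plus the physical radius it represents.

    Parameters
    ----------
    occupancy:
        ``(31, 31, 31)`` array with values in {0, 1} (stored as uint8).
    radius:
        Radius in Angstrom of the minimal bounding sphere of the model the
        grid encodes.  The grid geometry itself is size-normalized; this
        field restores physical units (voxel edge = ``radius / 15``).
    """

    occupancy: np.ndarray
    radius: float = REFERENCE_RADIUS

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != (GRID_SIZE,) * 3:
            raise ValueError(f"occupancy must be {(GRID_SIZE,)*3}, "
                             f"got {occ.shape}")
        vals = np.unique(occ)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("occupancy must be binary")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("radius must be a positive finite number")
        self.occupancy = occ.astype(np.uint8)

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def voxel_edge(self) -> float:
        """Edge length of one voxel in Angstrom."""
        return self.radius / SCALE_VOX

    def occupied_coords(self, physical: bool = False) -> np.ndarray:
        """Coordinates of occupied voxel centers relative to the grid center.

        In voxel units by default; in Angstrom when ``physical`` is set.
        """
        idx = np.argwhere(self.occupancy > 0).astype(np.float64)
        idx -= CENTER_INDEX
        if physical:
            idx *= self.voxel_edge
        return idx

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.occupancy.copy(), self.radius)


def _close(occ: np.ndarray) -> np.ndarray:
    """Morphological closing (3^3 element) with padding so the image
    border is not artificially eroded."""
    padded = np.pad(occ, 2)
    closed = ndimage.binary_closing(padded, structure=np.ones((3, 3, 3)))
    return closed[2:-2, 2:-2, 2:-2]


def _voxel_center_coords() -> np.ndarray:
    """(31,31,31,3) array of voxel-center coordinates, grid center at 0."""
    ax = np.arange(GRID_SIZE, dtype=np.float64) - CENTER_INDEX
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
    return g


_COORDS = _voxel_center_coords()
_R_VOX = np.sqrt((_COORDS ** 2).sum(axis=-1))
#: boolean mask of voxel centers inside the representable ball
BALL_MASK = _R_VOX <= BALL_RADIUS_VOX


# ---------------------------------------------------------------------------
# minimal bounding sphere (Welzl's algorithm)

def _sphere_from(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact circumsphere of 0..4 points (smallest sphere through them)."""
    n = len(points)
    if n == 0:
        return np.zeros(3), 0.0
    if n == 1:
        return points[0].copy(), 0.0
    if n == 2:
        c = points.mean(axis=0)
        return c, float(np.linalg.norm(points[0] - c))
    # 3 or 4 points: solve |p_i - c|^2 equal for all i -> linear system
    p0 = points[0]
    A = 2.0 * (points[1:] - p0)
    b = (points[1:] ** 2).sum(axis=1) - (p0 ** 2).sum()
    c, *_ = np.linalg.lstsq(A, b, rcond=None)
    return c, float(np.linalg.norm(p0 - c))


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    pts = points[rng.permutation(len(points))]
    eps = 1e-9

    def mb(n: int, boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
        if n == 0 or len(boundary) == 4:
            return _sphere_from(np.array(boundary) if boundary
                                else np.empty((0, 3)))
        c, r = mb(n - 1, boundary)
        p = pts[n - 1]
        if np.linalg.norm(p - c) <= r * (1 + eps) + eps:
            return c, r
        return mb(n - 1, boundary + [p])

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(pts) + 100))
    try:
        return mb(len(pts), [])
    finally:
        sys.setrecursionlimit(old)


def minimal_bounding_sphere(model: AtomicModel) -> tuple[np.ndarray, float]:
    """Center and radius (A) of the smallest sphere enclosing all points.

    Uses Welzl's randomized algorithm on the convex-hull vertices (exact up
    to floating-point tolerance); falls back to all points for degenerate
    (flat or tiny) inputs where hull construction fails.
    """
    pts = np.asarray(model.coordinates, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("model must contain at least one 3D point")
    if len(pts) <= 4:
        cand = pts
    else:
        try:
            from scipy.spatial import ConvexHull
            cand = pts[ConvexHull(pts).vertices]
        except Exception:
            cand = pts
    rng = np.random.default_rng(0)
    c, r = _welzl(cand, rng)
    # guard: enforce enclosure against round-off
    d = np.linalg.norm(pts - c, axis=1).max()
    return c, float(max(r, d))


# ---------------------------------------------------------------------------
# voxelization

def voxelize(model: AtomicModel, target_radius: float = REFERENCE_RADIUS,
             grid: int = GRID_SIZE) -> VoxelGrid:
    """Map an atomic/bead model onto the size-normalized 31^3 binary grid.

    The model is translated so its bounding-sphere center sits at the grid
    center and scaled so the bounding-sphere radius spans 15 voxel units
    (i.e. equals ``target_radius`` at ``target_radius/15`` A per voxel).  A
    voxel is occupied iff its center lies within one voxel edge of any
    scaled model point; occupancy is restricted to the largest ball the
    cubic grid represents (15.5 voxel units) and single-voxel holes are
    removed by one pass of morphological closing.  The returned grid stores
    the model's *original* bounding-sphere radius so physical size survives
    normalization.
    """
    if grid != GRID_SIZE:
        raise ValueError("only the 31-voxel grid is supported")
    pts = np.asarray(model.coordinates, dtype=np.float64)
    center, radius = minimal_bounding_sphere(model)
    if radius <= 0:
        raise DegenerateModelError("all model points coincide")
    scaled = (pts - center) * (SCALE_VOX / radius)

    tree = cKDTree(scaled)
    centers = _COORDS[BALL_MASK]
    dist, _ = tree.query(centers, k=1)
    occ = np.zeros((GRID_SIZE,) * 3, dtype=bool)
    occ[BALL_MASK] = dist <= VICINITY_VOX
    occ = _close(occ)
    occ &= BALL_MASK
    return VoxelGrid(occ.astype(np.uint8), radius=float(radius))


# ---------------------------------------------------------------------------
# synthetic shape corpus

#: per-family parameter bounds (dimensionless, shapes normalized to unit
#: bounding radius); chosen so every shape fills 2--55% of the grid and
#: stays 6-connected
PARAM_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "ellipsoid": {"b": (0.25, 1.0), "c": (0.25, 1.0)},
    "cylinder": {"half_length": (0.3, 0.95)},
    "dumbbell": {"ball_radius": (0.35, 0.6), "separation": (0.0, 0.9)},
    "torus": {"minor_radius": (0.12, 0.35)},
    "prism": {"b": (0.25, 1.0), "c": (0.25, 1.0)},
    "blob_union": {"n_balls": (2, 6)},
}


@dataclass
class ShapeSpec:
    """Recipe for one synthetic shape: family, geometry parameters, seed.

    Parameters omitted from ``params`` are drawn reproducibly from ``seed``
    within the documented bounds; the random orientation is always drawn
    from ``seed``.  The same (family, params, seed) triple always produces
    the same grid.
    """

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {FAMILIES}")
        bounds = PARAM_BOUNDS[self.family]
        for key, val in self.params.items():
            if key not in bounds:
                raise ValueError(f"unknown parameter {key!r} for family "
                                 f"{self.family!r}")
            lo, hi = bounds[key]
            if not lo <= val <= hi:
                raise ValueError(f"{self.family}.{key}={val} outside "
                                 f"bounds [{lo}, {hi}]")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    from scipy.spatial.transform import Rotation
    return Rotation.from_quat(q).as_matrix()


def _resolve_params(spec: ShapeSpec, rng: np.random.Generator) -> dict:
    out = {}
    for key, (lo, hi) in PARAM_BOUNDS[spec.family].items():
        if key in spec.params:
            out[key] = spec.params[key]
        elif key == "n_balls":
            out[key] = int(rng.integers(lo, hi + 1))
        else:
            out[key] = float(rng.uniform(lo, hi))
    return out


def _inside(family: str, p: dict, u: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Indicator of the solid (unit bounding radius) at points u (N,3)."""
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    if family == "ellipsoid":
        b, c = p["b"], p["c"]
        return x ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0 + 1e-9
    if family == "cylinder":
        h = p["half_length"]
        rho = np.sqrt(max(1.0 - h * h, 1e-9))
        return (np.abs(x) <= h + 1e-9) & (y ** 2 + z ** 2 <= rho ** 2 + 1e-9)
    if family == "dumbbell":
        r = p["ball_radius"]
        s = p["separation"] * r          # center offset, <= 0.9 r: overlap
        scale = 1.0 / (s + r)            # normalize bounding radius to 1
        rs, ss = r * scale, s * scale
        d1 = (x - ss) ** 2 + y ** 2 + z ** 2
        d2 = (x + ss) ** 2 + y ** 2 + z ** 2
        return (d1 <= rs ** 2 + 1e-9) | (d2 <= rs ** 2 + 1e-9)
    if family == "torus":
        a = p["minor_radius"]
        R = 1.0 - a
        return (np.sqrt(x ** 2 + y ** 2) - R) ** 2 + z ** 2 <= a ** 2 + 1e-9
    if family == "prism":
        b, c = p["b"], p["c"]
        d = np.sqrt(1.0 + b * b + c * c)
        return ((np.abs(x) <= 1.0 / d + 1e-9) & (np.abs(y) <= b / d + 1e-9)
                & (np.abs(z) <= c / d + 1e-9))
    if family == "blob_union":
        n = int(p["n_balls"])
        radii = rng.uniform(0.25, 0.5, size=n)
        centers = np.zeros((n, 3))
        for i in range(1, n):
            # chain the balls so the union stays connected
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            step = 0.8 * (radii[i - 1] + radii[i])
            centers[i] = centers[i - 1] + step * direction
        centers -= centers.mean(axis=0)
        bound = (np.linalg.norm(centers, axis=1) + radii).max()
        centers /= bound
        radii = radii / bound
        hit = np.zeros(len(u), dtype=bool)
        for ctr, rad in zip(centers, radii):
            hit |= ((u - ctr) ** 2).sum(axis=1) <= rad ** 2 + 1e-9
        return hit
    raise ValueError(family)


def generate_shape(spec: ShapeSpec) -> VoxelGrid:
    """Rasterize one synthetic shape at a random orientation.

    Deterministic in ``spec``; the result is a valid grid whose occupied
    set is 6-connected after the closing pass.  ``blob_union`` draws are
    re-sampled (still deterministically) until the occupancy fraction lands
    in the guard band [0.025, 0.5] that keeps training examples
    non-degenerate.
    """
    rng = np.random.default_rng([spec.seed, _family_code(spec.family)])
    params = _resolve_params(spec, rng)
    rot = _random_rotation(rng)

    u_all = _COORDS[BALL_MASK] / SCALE_VOX     # unit-bounding-radius coords
    for _ in range(20):
        hit = _inside(spec.family, params, u_all @ rot, rng)
        frac = hit.sum() / BALL_MASK.size
        if 0.02 <= frac <= 0.55 or spec.family != "blob_union":
            break
        # re-draw internal randomness (blob centers/radii) from the stream
    occ = np.zeros((GRID_SIZE,) * 3, dtype=bool)
    occ[BALL_MASK] = hit
    occ = _close(occ)
    occ &= BALL_MASK
    if not occ.any():
        raise ValueError(f"degenerate shape from spec {spec}")
    return VoxelGrid(occ.astype(np.uint8), radius=REFERENCE_RADIUS)


def _family_code(family: str) -> int:
    return FAMILIES.index(family) + 1


@dataclass
class ShapeDataset:
    """A reproducible corpus of synthetic envelopes with a train/val split."""

    grids: list
    specs: list
    train_indices: np.ndarray
    val_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.grids)


def make_dataset(n: int, families: list[str] | tuple[str, ...] = FAMILIES,
                 seed: int = 0, val_fraction: float = 0.1) -> ShapeDataset:
    """Draw ``n`` shapes uniformly over ``families`` with random orientations.

    Reproducible from ``seed``; emits a shuffled train/validation index
    split alongside the grids.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    families = tuple(families)
    if not families:
        raise ValueError("families must be non-empty")
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}")
    rng = np.random.default_rng([seed, 9173])
    specs = []
    for i in range(n):
        fam = families[int(rng.integers(len(families)))]
        specs.append(ShapeSpec(fam, seed=int(rng.integers(2 ** 31))))
    grids = [generate_shape(s) for s in specs]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return ShapeDataset(grids=grids, specs=specs,
                        train_indices=np.sort(perm[n_val:]),
                        val_indices=np.sort(perm[:n_val]))


def save_grids(path, grids: list[VoxelGrid]) -> None:
    """Cache a list of grids (occupancy + radius) in one compressed archive."""
    occ = np.stack([g.occupancy for g in grids]).astype(np.uint8)
    radii = np.array([g.radius for g in grids])
    np.savez_compressed(path, occupancy=occ, radii=radii)


def load_grids(path) -> list[VoxelGrid]:
    with np.load(path) as f:
        occ, radii = f["occupancy"], f["radii"]
    return [VoxelGrid(o, radius=float(r)) for o, r in zip(occ, radii)]
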