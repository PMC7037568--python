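"""Readers and writers for the file formats the pipeline touches.

SAXS profiles are plain whitespace-separated text (q [1/A], I, optional
sigma) in the dialect used by the small-angle scattering databases; atomic
and bead models are PDB v3.3 (parsed with gemmi); reconstructed envelopes
are written as DAMMIN-style dummy-atom PDB files or CCP4 density maps so
standard molecular viewers render them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .saxs_compute import SAXSProfile
    from .voxel_shapes import VoxelGrid


class FormatError(ValueError):
    """The file exists but contains no parseable records."""


class InsufficientDataError(ValueError):
    """Too few usable rows/points for the requested operation."""


@dataclass
class AtomicModel:
    """A bare point model: coordinates in Angstrom plus free-text labels."""

    coordinates: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        pts = np.asarray(self.coordinates, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("coordinates must be a non-empty (N, 3) array")
        if not np.isfinite(pts).all():
            raise ValueError("coordinates must be finite")
        self.coordinates = pts

    def __len__(self) -> int:
        return len(self.coordinates)


def read_saxs_dat(path, q_unit: str = "A^-1") -> "SAXSProfile":
    """Read a 2-3 column SAXS profile text file.

    Header/footer lines that do not parse into at least two numbers are
    skipped (including '#'-prefixed comments).  Rows with q <= 0 are
    dropped, rows are sorted by q and exact duplicates in q averaged.  A
    third column becomes sigma only when present on every row and strictly
    positive throughout.  ``q_unit='nm^-1'`` divides q by 10 to convert the
    common nm^-1 dialect to 1/A.
    """
    from .saxs_compute import SAXSProfile

    rows = []
    with_sigma = []
    for line in Path(path).read_text().splitlines():
        parts = line.replace(",", " ").split()
        vals = []
        for tok in parts[:3]:
            try:
                vals.append(float(tok))
            except ValueError:
                break
        if len(vals) < 2 or not all(np.isfinite(vals)):
            continue
        rows.append(vals[:2])
        with_sigma.append(vals[2] if len(vals) >= 3 else None)
    if not rows:
        raise FormatError(f"no numeric q/I rows found in {path}")

    arr = np.array(rows, dtype=np.float64)
    sig = np.array([np.nan if s is None else s for s in with_sigma])
    if q_unit == "nm^-1":
        arr[:, 0] /= 10.0
    elif q_unit != "A^-1":
        raise ValueError(f"unknown q unit {q_unit!r}")

    keep = arr[:, 0] > 0
    arr, sig = arr[keep], sig[keep]
    if len(arr) < 2:
        raise InsufficientDataError(f"fewer than 2 usable rows in {path}")
    order = np.argsort(arr[:, 0], kind="stable")
    arr, sig = arr[order], sig[order]

    # average exact duplicates in q
    q, inverse, counts = np.unique(arr[:, 0], return_inverse=True,
                                   return_counts=True)
    I = np.bincount(inverse, weights=arr[:, 1]) / counts
    sigma = None
    if not np.isnan(sig).any() and (sig > 0).all():
        sigma = np.bincount(inverse, weights=sig) / counts
    return SAXSProfile(q=q, I=I, sigma=sigma)


def write_saxs_dat(profile: "SAXSProfile", path, header: str = "") -> None:
    """Write a profile as 2-3 column text round-trippable by read_saxs_dat."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("#      q(1/A)             I(q)" +
                 ("              sigma" if profile.sigma is not None else ""))
    for i in range(len(profile.q)):
        row = f"{profile.q[i]:.8e}  {profile.I[i]:.8e}"
        if profile.sigma is not None:
            row += f"  {profile.sigma[i]:.8e}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_fit(data: "SAXSProfile", model_I: np.ndarray, scale: float,
              path) -> None:
    """4-column fit file: q, I_exp, sigma, scaled model intensity."""
    sigma = data.sigma if data.sigma is not None else np.zeros_like(data.q)
    lines = ["#      q(1/A)             I_exp              sigma"
             "              c*I_model"]
    for i in range(len(data.q)):
        lines.append(f"{data.q[i]:.8e}  {data.I[i]:.8e}  "
                     f"{sigma[i]:.8e}  {scale * model_I[i]:.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> AtomicModel:
    """Read ATOM/HETATM coordinates (A) from a PDB file.

    First model only; alternate locations collapsed to the first occurring
    conformer of each atom.
    """
    import gemmi

    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"no models in {path}")
    model = structure[0]
    coords, labels = [], []
    for chain in model:
        for residue in chain:
            seen = set()
            for atom in residue:
                if atom.name in seen:      # keep first altloc only
                    continue
                seen.add(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                labels.append(f"{chain.name}/{residue.name}"
                              f"{residue.seqid.num}/{atom.name}")
    if not coords:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    return AtomicModel(np.array(coords), labels)


def write_bead_pdb(grid: "VoxelGrid", path) -> None:
    """Write one dummy atom per occupied voxel, DAMMIN-style.

    Beads are placed at voxel centers in Angstrom with the grid center at
    the origin (voxel edge = radius/15 A); residue DUM, atom CA, occupancy
    1.00, so dummy-atom-aware viewers render the envelope.
    """
    if grid.n_occupied == 0:
        raise ValueError("cannot write an empty grid")
    coords = grid.occupied_coords(physical=True)
    lines = [
        "REMARK   dummy-atom envelope written by saxshape",
        f"REMARK   model radius {grid.radius:.2f} A, "
        f"voxel edge {grid.voxel_edge:.3f} A",
    ]
    for i, (x, y, z) in enumerate(coords, start=1):
        serial = i % 100000
        resseq = i % 10000
        lines.append(
            f"ATOM  {serial:5d}  CA  DUM A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ccp4(grid: "VoxelGrid", path) -> None:
    """Export the envelope as a CCP4/MRC density map (0/1 occupancy)."""
    import gemmi

    data = np.ascontiguousarray(grid.occupancy.astype(np.float32))
    cell_edge = grid.voxel_edge * data.shape[0]
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(data)
    ccp4.grid.unit_cell = gemmi.UnitCell(cell_edge, cell_edge, cell_edge,
                                         90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
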