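"""File formats: MRC volumes, pose tables (CSV / STAR), observation stacks
and external quadrature tables.

Volumes use the MRC2014 map format (mode 2, float32) through gemmi, with
the voxel size carried in the unit-cell header.  Pose tables store unit
quaternions (w, x, y, z with w >= 0) plus intrinsic ZYZ Euler angles in
degrees, the common cryo-EM metadata convention; STAR export writes the
same columns in a single data block.  Observation stacks are flat float32
binaries with a JSON sidecar recording shape, sigma, model tag and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .forward_model import Volume3D
from .reconstruction import ObservationSet
from .so3 import (
    RotationGrid,
    euler_zyz_deg_from_matrix,
    matrix_from_quaternion,
    quaternion_from_matrix,
)

__all__ = [
    "read_mrc",
    "write_mrc",
    "pose_table",
    "write_pose_csv",
    "read_pose_csv",
    "write_pose_star",
    "save_observations",
    "load_observations",
    "read_quadrature_table",
]


def write_mrc(path, V: Volume3D) -> None:
    """Write a volume as an MRC2014 mode-2 (float32) map."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(V.grid, dtype=np.float32))
    n = V.n
    a = n * V.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> Volume3D:
    """Read an MRC/CCP4 map; axis order is taken from the header mapc/mapr/maps
    fields (gemmi reorders to a canonical XYZ grid)."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"malformed or truncated MRC file {path}: {exc}") from exc
    m.setup(float("nan"))  # honor header axis order
    data = np.array(m.grid, copy=True).astype(float)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError("expected a cubic map")
    voxel = m.grid.unit_cell.a / data.shape[0]
    return Volume3D(data, voxel_size=voxel)


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

_POSE_COLUMNS = ["id", "qw", "qx", "qy", "qz", "euler_rot", "euler_tilt", "euler_psi"]


def pose_table(rotations: np.ndarray, ids=None) -> pd.DataFrame:
    """Tidy table of rotations: unit quaternion (canonical, w >= 0) and ZYZ
    intrinsic Euler angles in degrees."""
    rotations = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
    ids = list(range(len(rotations))) if ids is None else list(ids)
    rows = []
    for i, g in zip(ids, rotations):
        q = quaternion_from_matrix(g)
        e = euler_zyz_deg_from_matrix(g)
        rows.append(dict(zip(_POSE_COLUMNS, [i, *q, *e])))
    return pd.DataFrame(rows, columns=_POSE_COLUMNS)


def write_pose_csv(path, rotations: np.ndarray, ids=None, extra: pd.DataFrame | None = None) -> None:
    df = pose_table(rotations, ids)
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def read_pose_csv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Load rotations from a pose CSV (quaternion columns are authoritative)."""
    df = pd.read_csv(path)
    missing = {"qw", "qx", "qy", "qz"} - set(df.columns)
    if missing:
        raise ValueError(f"pose table missing columns {sorted(missing)}")
    rots = np.stack(
        [matrix_from_quaternion(q) for q in df[["qw", "qx", "qy", "qz"]].to_numpy()]
    )
    return rots, df


def write_pose_star(path, rotations: np.ndarray, ids=None, block_name: str = "poses") -> None:
    """STAR export: one data block, loop over the pose-table fields."""
    df = pose_table(rotations, ids)
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_pose.", _POSE_COLUMNS)
    for _, row in df.iterrows():
        loop.add_row([str(row["id"])] + [f"{row[c]:.9g}" for c in _POSE_COLUMNS[1:]])
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# observation stacks
# ---------------------------------------------------------------------------


def save_observations(prefix, obs: ObservationSet, seed: int | None = None) -> None:
    """Flat float32 binary + JSON sidecar (shape, sigma, model, seed)."""
    prefix = Path(prefix)
    obs.data.astype(np.float32).tofile(prefix.with_suffix(".bin"))
    meta = {
        "shape": list(obs.data.shape),
        "dtype": "float32",
        "sigma": obs.sigma,
        "model": obs.model,
        "seed": seed,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_observations(prefix) -> ObservationSet:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype=meta["dtype"])
    data = data.reshape(meta["shape"]).astype(float)
    return ObservationSet(data, meta["sigma"], meta["model"])


# ---------------------------------------------------------------------------
# external quadrature tables
# ---------------------------------------------------------------------------


def read_quadrature_table(path) -> RotationGrid:
    """Plain-text quadrature: 10 numbers per line (row-major 3x3 matrix +
    weight).  Weights are renormalized to sum to 1."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] != 10:
        raise ValueError("expected 10 columns: 9 matrix entries + weight")
    nodes = raw[:, :9].reshape(-1, 3, 3)
    w = raw[:, 9]
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return RotationGrid(nodes, w / w.sum(), flavor="product-quadrature")
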