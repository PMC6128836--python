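"""File formats: MRC2014 volumes/stacks and STAR particle metadata.

Volumes and image stacks are written as MRC2014 mode 2 (32-bit float,
little-endian) through gemmi's CCP4/MRC machinery; per-particle metadata
round-trips through STAR tables with Relion-style column names.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import gemmi

from .geometry import Orientation
from .optics import CTFParams
from .phantom import Volume

__all__ = [
    "FormatError",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
    "particle_table",
    "table_to_metadata",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def write_mrc(path, data, pixel_size: float) -> None:
    """Write a volume, image or stack as MRC2014 mode 2 (little-endian float32).

    ``data`` may be a Volume or a 2D/3D array; the voxel size (A) is
    recorded in the header via the unit cell.
    """
    if isinstance(data, Volume):
        pixel_size = data.pixel_size
        data = data.grid
    arr = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nz, ny, nx = arr.shape  # gemmi grid nu,nv,nw follow the numpy axes
    m.grid.unit_cell = gemmi.UnitCell(
        nz * pixel_size, ny * pixel_size, nx * pixel_size, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> Volume | tuple[np.ndarray, float]:
    """Read an MRC2014 mode-2 file.

    Returns a Volume for cubic data, else (array, pixel_size).  Voxel size
    round-trips at the header's float32 precision; array data round-trips
    exactly.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise FormatError(f"unsupported MRC mode {mode} (only mode 2 is supported)")
    arr = np.array(m.grid, copy=True).astype(np.float64)
    pixel = m.grid.unit_cell.a / m.grid.shape[0]
    if arr.ndim == 3 and len(set(arr.shape)) == 1 and arr.shape[0] % 2 == 0:
        return Volume(arr, pixel)
    return arr, pixel


# STAR column dialect (Relion-style); degrees and Angstrom preserved as-is.
_COLUMNS = {
    "phi": "rlnAngleRot",
    "theta": "rlnAngleTilt",
    "psi": "rlnAnglePsi",
    "defocus_u": "rlnDefocusU",
    "defocus_v": "rlnDefocusV",
    "astigmatism_angle": "rlnDefocusAngle",
    "phase_shift": "rlnPhaseShift",
    "score": "rlnParticleScore",
    "weight": "rlnParticleWeight",
}
_REQUIRED = ("phi", "theta", "psi", "defocus_u", "defocus_v")


def particle_table(ps) -> pd.DataFrame:
    """Per-particle metadata of a ParticleSet as a DataFrame (STAR columns)."""
    rows = {
        "rlnAngleRot": [o.phi for o in ps.orientations],
        "rlnAngleTilt": [o.theta for o in ps.orientations],
        "rlnAnglePsi": [o.psi for o in ps.orientations],
        "rlnDefocusU": [c.defocus_u for c in ps.ctf_params],
        "rlnDefocusV": [c.defocus_v for c in ps.ctf_params],
        "rlnDefocusAngle": [c.astigmatism_angle_deg for c in ps.ctf_params],
        "rlnPhaseShift": [c.phase_shift_rad for c in ps.ctf_params],
        "rlnParticleScore": list(ps.scores) if ps.scores is not None else [0.0] * len(ps),
        "rlnParticleWeight": list(ps.weights),
    }
    return pd.DataFrame(rows)


def table_to_metadata(df: pd.DataFrame):
    """DataFrame -> (orientations, ctf_params, scores, weights)."""
    for key in _REQUIRED:
        col = _COLUMNS[key]
        if col not in df.columns:
            raise FormatError(f"missing required column {key!r} ({col})")
    orientations = [
        Orientation(phi=r, theta=t, psi=p)
        for r, t, p in zip(df["rlnAngleRot"], df["rlnAngleTilt"], df["rlnAnglePsi"])
    ]
    ast = df.get("rlnDefocusAngle", pd.Series(np.zeros(len(df))))
    phase = df.get("rlnPhaseShift", pd.Series(np.zeros(len(df))))
    ctfs = [
        CTFParams(u, v, a, s)
        for u, v, a, s in zip(df["rlnDefocusU"], df["rlnDefocusV"], ast, phase)
    ]
    scores = df["rlnParticleScore"].to_numpy(float) if "rlnParticleScore" in df else None
    weights = (
        df["rlnParticleWeight"].to_numpy(float) if "rlnParticleWeight" in df else None
    )
    return orientations, ctfs, scores, weights


def write_star(path, df: pd.DataFrame, block_name: str = "particles") -> None:
    """Write a DataFrame as a single-block STAR loop, full float precision."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    loop = block.init_loop("_", [str(c) for c in df.columns])
    for _, row in df.iterrows():
        loop.add_row([repr(v) if isinstance(v, float) else str(v) for v in row])
    doc.write_file(str(path))


def read_star(path) -> pd.DataFrame:
    """Read the first loop of a STAR file into a DataFrame.

    Numeric columns are parsed as floats; unknown columns are preserved.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read STAR file {path}: {exc}") from exc
    block = doc.sole_block()
    data = {}
    for item in block:
        loop = item.loop
        if loop is None:
            continue
        width = loop.width()
        for j, tag in enumerate(loop.tags):
            name = tag.lstrip("_")
            col = loop.values[j::width]
            try:
                data[name] = [float(v) for v in col]
            except ValueError:
                data[name] = col
        break
    if not data:
        raise FormatError(f"no loop found in STAR file {path}")
    return pd.DataFrame(data)
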