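"""MRC/CCP4 map input and output (mode 2, float32), plus PNG slice export.

Maps are written with an orthogonal P1 cell whose dimensions equal grid
shape times voxel size and with the world origin in the MRC2014 ORIGIN
header words, so the files round-trip through this module and load in
standard visualization tools.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .volume import DensityVolume

__all__ = ["read_mrc", "write_mrc", "write_slice_png"]

# MRC2014 ORIGIN x/y/z header words
_ORIGIN_WORDS = (50, 51, 52)


def write_mrc(volume: DensityVolume, path) -> None:
    """Write a density volume as an MRC mode-2 (float32) map."""
    nz, ny, nx = volume.grid.shape
    m = gemmi.Ccp4Map()
    # gemmi's FloatGrid is X-fastest; our arrays are Z,Y,X-major already
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.grid, dtype=np.float32))
    h = volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * h, ny * h, nz * h, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip(_ORIGIN_WORDS, volume.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityVolume:
    """Read an MRC/CCP4 map written by :func:`write_mrc`."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed MRC file {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True).astype(float)
    nz, ny, nx = grid.shape
    cell = m.grid.unit_cell
    voxel = cell.a / nx if nx else 1.0
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS], dtype=float)
    return DensityVolume(grid, voxel_size=voxel, origin=origin)


def write_slice_png(volume: DensityVolume, path, axis: int = 0,
                    index: int | None = None) -> None:
    """Save one central (or chosen) slice as a grayscale PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if index is None:
        index = volume.grid.shape[axis] // 2
    sl = np.take(volume.grid, index, axis=axis)
    plt.imsave(str(path), sl, cmap="gray")
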