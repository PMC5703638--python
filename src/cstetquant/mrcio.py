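"""MRC/CCP4 volume I/O.

Volumes travel as MRC maps (the field's standard) through gemmi. The
in-memory convention is (z, y, x) with an isotropic voxel size in nm; on
disk the cell is recorded in angstroms. Label volumes are written as float
maps and cast back to integers on read (component counts can exceed the
range of the small integer MRC modes).
"""

from __future__ import annotations

import numpy as np
import gemmi

from cstetquant.morphometry import LabelVolume, VolumeGrid

_NM_TO_A = 10.0


def write_mrc(volume: VolumeGrid, path) -> None:
    """Write a VolumeGrid as an MRC (mode 2, float32) map."""
    data = np.ascontiguousarray(volume.data, dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    nz, ny, nx = data.shape
    cell_nm = volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(
        nz * cell_nm * _NM_TO_A, ny * cell_nm * _NM_TO_A, nx * cell_nm * _NM_TO_A,
        90, 90, 90,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path, voxel_size: float | None = None) -> VolumeGrid:
    """Read an MRC map into a VolumeGrid.

    The voxel size comes from the map header (cell / grid size, converted
    to nm); pass ``voxel_size`` to override absent or zero headers.
    """
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    if voxel_size is None:
        spacing = np.asarray(m.grid.spacing) / _NM_TO_A
        if np.any(spacing <= 0):
            raise ValueError(
                f"{path}: map header has no usable voxel size; "
                "pass voxel_size explicitly"
            )
        if not np.allclose(spacing, spacing[0], rtol=1e-3):
            raise ValueError(f"{path}: anisotropic voxel size {spacing} nm")
        voxel_size = float(spacing[0])
    return VolumeGrid(data, voxel_size)


def write_labels_mrc(labels: LabelVolume, path) -> None:
    vol = VolumeGrid(labels.labels.astype(np.float32), labels.voxel_size)
    write_mrc(vol, path)


def read_labels_mrc(path, voxel_size: float | None = None,
                    connectivity: int = 26) -> LabelVolume:
    vol = read_mrc(path, voxel_size)
    labels = np.rint(vol.data).astype(np.int32)
    return LabelVolume(labels, int(labels.max()), connectivity, vol.voxel_size)
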