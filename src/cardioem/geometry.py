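"""Voxel-grid geometry and the physical coordinate convention.

Arrays are indexed ``[i, j, k]`` where ``i`` is the image row, ``j`` the image
column and ``k`` the slice (section) number.  Physical coordinates follow the
cardiac-wall convention used throughout the package:

* ``x = j * sx`` — in-plane direction approximately parallel to the ventricular
  wall (circumferential),
* ``y = i * sy`` — in-plane radial direction (towards the lumen),
* ``z = k * sz`` — the stack / sectioning direction (longitudinal).

Spacings are anisotropic by default: serial block-face SEM acquires 10 nm
lateral pixels and 40 nm sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default SBF-SEM voxel spacing in nm: 10 nm lateral, 40 nm per section
DEFAULT_SPACING_NM = (10.0, 10.0, 40.0)


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical interpretation of a voxel grid.

    Parameters
    ----------
    spacing : tuple of float
        Physical length per voxel along (x, y, z).  Units are whatever the
        caller uses consistently (nm for EM volumes, µm for micro-CT volumes);
        the ``unit`` field records them for provenance.
    origin : tuple of float
        Physical coordinate of voxel index (0, 0, 0).
    unit : str
        Length unit label.
    """

    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "nm"

    def __post_init__(self) -> None:
        if len(self.spacing) != 3:
            raise ValueError("spacing must have three components (x, y, z)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (N, 3) as (i, j, k) to physical (x, y, z).

        ``x`` comes from the column index ``j``, ``y`` from the row index
        ``i`` and ``z`` from the slice index ``k``.
        """
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(idx)
        out[:, 0] = idx[:, 1] * sx + ox
        out[:, 1] = idx[:, 0] * sy + oy
        out[:, 2] = idx[:, 2] * sz + oz
        return out

    def voxel_indices(self, coords: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`physical_coords` (rounded to nearest voxel)."""
        xyz = np.atleast_2d(np.asarray(coords, dtype=float))
        sx, sy, sz = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(xyz)
        out[:, 0] = (xyz[:, 1] - oy) / sy
        out[:, 1] = (xyz[:, 0] - ox) / sx
        out[:, 2] = (xyz[:, 2] - oz) / sz
        return np.rint(out).astype(np.int64)
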