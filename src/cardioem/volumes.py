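"""In-memory containers: grayscale voxel volumes and integer label volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VolumeGeometry

# Canonical tissue classes for EM label volumes.
CLASS_EXTRACELLULAR = 0
CLASS_NUCLEUS = 1
CLASS_MITOCHONDRION = 2
CLASS_MYOFIBRIL = 3
CLASS_OTHER_CYTOPLASM = 4
CLASS_IGNORE = 255

EM_CLASS_MAP: dict[int, str] = {
    CLASS_EXTRACELLULAR: "extracellular",
    CLASS_NUCLEUS: "nucleus",
    CLASS_MITOCHONDRION: "mitochondrion",
    CLASS_MYOFIBRIL: "myofibril",
    CLASS_OTHER_CYTOPLASM: "other_cytoplasm",
    CLASS_IGNORE: "ignore",
}

# Whole-heart (micro-CT scale) label classes.
HEART_BACKGROUND = 0
HEART_TISSUE = 1
HEART_LV_LUMEN = 2
HEART_RV_LUMEN = 3

HEART_CLASS_MAP: dict[int, str] = {
    HEART_BACKGROUND: "background",
    HEART_TISSUE: "tissue",
    HEART_LV_LUMEN: "lv_lumen",
    HEART_RV_LUMEN: "rv_lumen",
}


@dataclass
class VoxelVolume:
    """A 3D grayscale image with attached geometry.

    ``data`` is indexed ``[row, column, slice]``; see
    :mod:`cardioem.geometry` for the physical-axis convention.
    """

    data: np.ndarray
    geometry: VolumeGeometry = field(default_factory=VolumeGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice(self, k: int) -> np.ndarray:
        return self.data[:, :, k]

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.geometry)


@dataclass
class LabelVolume:
    """An integer class mask with a closed class map.

    Every voxel carries exactly one class; integer values not declared in
    ``class_map`` are rejected at construction.
    """

    data: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(EM_CLASS_MAP))
    geometry: VolumeGeometry = field(default_factory=VolumeGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must be integer-typed, got {self.data.dtype}")
        present = set(np.unique(self.data).tolist())
        undeclared = sorted(present - set(self.class_map))
        if undeclared:
            raise ValueError(
                f"label volume contains values not declared in the class map: {undeclared}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[int, int]:
        """Voxel count per declared class (zero for absent classes)."""
        values, counts = np.unique(self.data, return_counts=True)
        found = dict(zip(values.tolist(), counts.tolist()))
        return {c: int(found.get(c, 0)) for c in self.class_map}

    def mask(self, class_id: int) -> np.ndarray:
        if class_id not in self.class_map:
            raise KeyError(f"class {class_id} not in class map")
        return self.data == class_id

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), dict(self.class_map), self.geometry)
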