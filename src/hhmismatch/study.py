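"""Core imaging containers: a co-registered multimodal CT study and its lesion masks.

An :class:`ImagingStudy` bundles one non-contrast CT volume (Hounsfield units)
with five perfusion parameter maps — cerebral blood volume (CBV, mL/100 mL),
cerebral blood flow (CBF, mL/100 mL/min), mean transit time (MTT, s), time to
drain (TTD, s) and time-to-maximum of the residue function (Tmax, s) — all on
one voxel grid with known spacing.  The grid is assumed pre-aligned so that the
midsagittal plane is the central plane of ``midline_axis``; left/right
homologous voxels are index-reflections of each other along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAP_NAMES = ("ncct", "cbv", "cbf", "mtt", "ttd", "tmax")


@dataclass
class ImagingStudy:
    """One patient's co-registered NCCT + perfusion maps.

    Parameters
    ----------
    ncct, cbv, cbf, mtt, ttd, tmax : ndarray
        Voxel grids sharing one shape. NCCT in Hounsfield units, CBV in
        mL/100 mL, CBF in mL/100 mL/min, the time maps in seconds.
    voxel_spacing_mm : tuple of float
        Per-axis voxel spacing in millimetres.
    brain_mask : ndarray of bool
        Voxels belonging to brain tissue; analysis is restricted to it.
    midline_axis : int
        Axis index of the left-right direction; the midsagittal plane is the
        central plane of this axis.
    """

    ncct: np.ndarray
    cbv: np.ndarray
    cbf: np.ndarray
    mtt: np.ndarray
    ttd: np.ndarray
    tmax: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    brain_mask: np.ndarray
    midline_axis: int = 0

    def __post_init__(self) -> None:
        shape = self.ncct.shape
        for name in MAP_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"grid mismatch: map '{name}' has shape {arr.shape}, "
                    f"expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"map '{name}' contains non-finite voxels")
            setattr(self, name, arr)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != shape:
            raise ValueError(
                f"grid mismatch: brain_mask has shape {self.brain_mask.shape}, "
                f"expected {shape}"
            )
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != self.ncct.ndim:
            raise ValueError("voxel_spacing_mm must give one spacing per axis")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if not 0 <= self.midline_axis < self.ncct.ndim:
            raise ValueError(f"midline_axis {self.midline_axis} out of range")
        for name in ("cbv", "cbf", "mtt", "ttd", "tmax"):
            if np.any(getattr(self, name)[self.brain_mask] < 0):
                raise ValueError(f"map '{name}' is negative inside the brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ncct.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0

    def maps(self) -> dict[str, np.ndarray]:
        """All six grids keyed by their canonical short names."""
        return {name: getattr(self, name) for name in MAP_NAMES}


@dataclass
class LesionMasks:
    """Binary lesion masks derived from one study, with volumes in mL.

    ``core_source`` records which perfusion map defined the core: ``"CBV"``
    (primary rule), ``"CBF"`` (fallback when no CBV lesion was present) or
    ``"none"`` when the core is empty.
    """

    ischemic_area: np.ndarray
    core: np.ndarray
    hypoperfusion_tmax: np.ndarray
    core_source: str
    voxel_spacing_mm: tuple[float, float, float]
    volumes_ml: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .segmentation import mask_volume_ml  # local import: avoid cycle

        for name in ("ischemic_area", "core", "hypoperfusion_tmax"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if self.core.shape != self.ischemic_area.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.core & ~self.ischemic_area):
            raise ValueError("core mask extends outside the ischemic area")
        if self.core_source not in ("CBV", "CBF", "none"):
            raise ValueError(f"unknown core_source {self.core_source!r}")
        if (self.core_source == "none") != (not self.core.any()):
            raise ValueError("core_source must be 'none' iff the core is empty")
        if not self.volumes_ml:
            self.volumes_ml = {
                name: mask_volume_ml(getattr(self, name), self.voxel_spacing_mm)
                for name in ("ischemic_area", "core", "hypoperfusion_tmax")
            }
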