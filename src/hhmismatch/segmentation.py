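"""Threshold-based segmentation of perfusion maps into lesion masks.

The rater procedure being emulated works in two steps: the total ischemic
area is found on the bolus-delay maps (MTT/TTD, here operationalised as
relative MTT elevation or Tmax above a cut-off), and within that area the
ischemic core is identified on CBV — values below an absolute cut or below a
fraction of the contralateral ("normal side") value — falling back to an
analogous CBF rule when no CBV lesion is present.  Contralateral reference
values come from mirroring each map across the midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .study import ImagingStudy, LesionMasks


@dataclass
class SegmentationThresholds:
    """Perfusion thresholds for ischemic-area and core delineation.

    Defaults follow the standard reading criteria: core on CBV below
    2 mL/100 mL absolute or 30% of the contralateral side; CBF fallback below
    30 mL/100 mL/min absolute or 60% relative; hypoperfusion at Tmax > 6 s.
    ``ischemic_area_rel_mtt`` (145% of the mirror value) operationalises the
    visual reading of the sensitive MTT/TTD maps; it is a conventional
    penumbra threshold, not a universal constant, hence configurable.

    ``core_rule_logic`` selects whether the absolute and relative core
    criteria fire alternatively ("OR", default) or jointly ("AND").
    ``largest_component_only`` emulates a human rater ignoring speckle by
    keeping only the largest 26-connected component of the ischemic area.
    """

    cbv_abs: float = 2.0          # mL/100 mL
    cbv_rel: float = 0.30         # fraction of contralateral
    cbf_abs: float = 30.0         # mL/100 mL/min
    cbf_rel: float = 0.60
    tmax_cut_s: float = 6.0
    ischemic_area_rel_mtt: float = 1.45
    min_core_voxels: int = 1
    core_rule_logic: str = "OR"   # "OR" | "AND"
    largest_component_only: bool = True

    def __post_init__(self) -> None:
        for name in ("cbv_abs", "cbf_abs", "tmax_cut_s", "ischemic_area_rel_mtt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cbv_rel", "cbf_rel"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_core_voxels < 0:
            raise ValueError("min_core_voxels must be non-negative")
        if self.core_rule_logic not in ("OR", "AND"):
            raise ValueError("core_rule_logic must be 'OR' or 'AND'")


def mirror_reference(map_grid: np.ndarray, midline_axis: int = 0) -> np.ndarray:
    """Contralateral reference: each voxel's value at its mirror position.

    The midsagittal plane is the central plane of ``midline_axis``; index i
    reflects to N-1-i, so applying the reflection twice is the identity and
    every reflected index stays inside the grid.
    """
    map_grid = np.asarray(map_grid)
    if not 0 <= midline_axis < map_grid.ndim:
        raise ValueError(f"midline_axis {midline_axis} out of range for ndim {map_grid.ndim}")
    return np.flip(map_grid, axis=midline_axis)


def _relative_below(map_grid, mirror, fraction, within):
    """Voxels (within `within`) whose value is below fraction x mirror.

    Where the mirrored value is 0 the relative comparison is undefined and
    never fires (the absolute criterion alone applies there).
    """
    with np.errstate(invalid="ignore"):
        rel = within & (mirror > 0) & (map_grid < fraction * mirror)
    return rel


def ischemic_area_mask(study: ImagingStudy, thr: SegmentationThresholds) -> np.ndarray:
    """Total ischemic area: relative MTT elevation OR prolonged Tmax, in brain.

    Optionally keeps only the largest 26-connected component (speckle
    cleanup); an empty mask is a legal result.
    """
    mirror_mtt = mirror_reference(study.mtt, study.midline_axis)
    with np.errstate(invalid="ignore"):
        mtt_hit = (mirror_mtt > 0) & (study.mtt > thr.ischemic_area_rel_mtt * mirror_mtt)
    mask = study.brain_mask & (mtt_hit | (study.tmax > thr.tmax_cut_s))
    if thr.largest_component_only and mask.any():
        labels = cc_label(mask, connectivity=mask.ndim)  # 26-connectivity in 3D
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return mask


def _core_rule(map_grid, mirror, abs_cut, rel_frac, area, logic):
    absolute = area & (map_grid < abs_cut)
    relative = _relative_below(map_grid, mirror, rel_frac, area)
    if logic == "AND":
        # where the relative criterion is undefined (mirror 0) only the
        # absolute criterion applies
        undefined = area & ~(mirror > 0)
        return (absolute & relative) | (absolute & undefined)
    return absolute | relative


def core_mask(
    study: ImagingStudy, thr: SegmentationThresholds, area: np.ndarray
) -> tuple[np.ndarray, str]:
    """Ischemic core within the ischemic area.

    CBV rule first (< ``cbv_abs`` or < ``cbv_rel`` x contralateral); if the
    CBV lesion has fewer than ``min_core_voxels`` voxels — "no CBV lesion was
    present" — the CBF fallback rule is used instead.  Returns the mask and
    which map defined it (``"CBV"``, ``"CBF"`` or ``"none"``).
    """
    area = np.asarray(area, dtype=bool)
    mirror_cbv = mirror_reference(study.cbv, study.midline_axis)
    core = _core_rule(study.cbv, mirror_cbv, thr.cbv_abs, thr.cbv_rel, area,
                      thr.core_rule_logic)
    if core.sum() >= max(thr.min_core_voxels, 1):
        return core, "CBV"
    mirror_cbf = mirror_reference(study.cbf, study.midline_axis)
    core = _core_rule(study.cbf, mirror_cbf, thr.cbf_abs, thr.cbf_rel, area,
                      thr.core_rule_logic)
    if core.any():
        return core, "CBF"
    return np.zeros_like(area), "none"


def hypoperfusion_mask(study: ImagingStudy, thr: SegmentationThresholds) -> np.ndarray:
    """Hypoperfused tissue: Tmax above the cut-off, within brain."""
    return study.brain_mask & (study.tmax > thr.tmax_cut_s)


def mask_volume_ml(mask: np.ndarray, voxel_spacing_mm) -> float:
    """Volume of a binary mask in mL: voxel count x voxel volume (mm^3) / 1000."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    voxel_mm3 = float(np.prod([float(s) for s in voxel_spacing_mm]))
    return float(np.count_nonzero(mask)) * voxel_mm3 / 1000.0


def segment_study(
    study: ImagingStudy, thr: SegmentationThresholds | None = None
) -> LesionMasks:
    """Full segmentation: ischemic area, core (CBV-first), Tmax hypoperfusion."""
    thr = thr or SegmentationThresholds()
    area = ischemic_area_mask(study, thr)
    core, source = core_mask(study, thr, area)
    tmax_mask = hypoperfusion_mask(study, thr)
    return LesionMasks(
        ischemic_area=area,
        core=core,
        hypoperfusion_tmax=tmax_mask,
        core_source=source,
        voxel_spacing_mm=study.voxel_spacing_mm,
    )
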