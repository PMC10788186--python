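"""Hypoperfusion-hypodensity mismatch (HHM): the CT tissue clock.

A core lesion visible on the perfusion maps without a corresponding
hypodensity on the non-contrast CT indicates an early stroke: water uptake
into ischemic tissue lowers its CT density only gradually, so a hypoperfused
core that is still isodense to its mirror-image healthy counterpart was most
likely occluded recently (within the thrombolysis window).

The human judgement "clear hypodensity present" is operationalised as the
net water uptake (NWU) of the core region,

    NWU = (1 - mean HU(core) / mean HU(mirrored core)) x 100  [percent],

exceeding a threshold ``delta_pct``.  Equality — doubt — rates as *absence*
of hypodensity, the conservative rule of the reading protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import mirror_reference
from .study import ImagingStudy, LesionMasks

GLOBAL = "GLOBAL"
ALL_SLICES = "ALL_SLICES"


@dataclass
class HypodensityReading:
    """Quantities behind one hypodensity judgement.

    ``per_slice_nwu`` holds the NWU of each axial slice intersecting the
    core (the maps are read slice by slice); ``per_slice_present`` the
    corresponding per-slice hypodensity calls once judged.
    """

    mean_hu_core: float
    mean_hu_mirror: float
    nwu_pct: float
    per_slice_nwu: list[float] = field(default_factory=list)
    per_slice_present: list[bool] = field(default_factory=list)
    hypodense: bool | None = None


@dataclass
class HHMDecision:
    """Outcome of the HHM classification for one study."""

    core_present: bool
    hypodense: bool
    mismatch: bool
    reading: HypodensityReading | None = None

    def __post_init__(self) -> None:
        if self.mismatch != (self.core_present and not self.hypodense):
            raise ValueError("mismatch must equal core_present AND NOT hypodense")
        if (self.reading is None) != (not self.core_present):
            raise ValueError("reading must be absent iff the core is absent")


def compute_nwu(
    ncct: np.ndarray,
    core_mask: np.ndarray,
    midline_axis: int = 0,
    axial_axis: int = -1,
) -> HypodensityReading:
    """Net water uptake of the core region relative to its mirror image.

    Negative NWU (core denser than mirror) is legal and simply means "no
    hypodensity".  Raises on an empty core (callers must check
    ``core_present`` first) and on a non-positive mirror mean.
    """
    core_mask = np.asarray(core_mask, dtype=bool)
    if not core_mask.any():
        raise ValueError("core mask is empty; nothing to read")
    mirrored_ncct = mirror_reference(np.asarray(ncct, dtype=float), midline_axis)

    def one_region(mask):
        mean_core = float(np.mean(ncct[mask]))
        mean_mirror = float(np.mean(mirrored_ncct[mask]))
        if mean_mirror <= 0:
            raise ValueError(
                f"mean mirrored HU is {mean_mirror:.3f} <= 0; NWU undefined"
            )
        return mean_core, mean_mirror, (1.0 - mean_core / mean_mirror) * 100.0

    mean_core, mean_mirror, nwu = one_region(core_mask)

    axial = axial_axis % core_mask.ndim
    per_slice = []
    for z in range(core_mask.shape[axial]):
        sl = np.take(core_mask, z, axis=axial)
        if sl.any():
            full = np.zeros_like(core_mask)
            index = [slice(None)] * core_mask.ndim
            index[axial] = z
            full[tuple(index)] = sl
            per_slice.append(one_region(full)[2])

    return HypodensityReading(
        mean_hu_core=mean_core,
        mean_hu_mirror=mean_mirror,
        nwu_pct=nwu,
        per_slice_nwu=per_slice,
    )


def judge_hypodensity(
    reading: HypodensityReading, delta_pct: float = 5.0, slice_rule: str = GLOBAL
) -> bool:
    """Is a clear hypodensity present?

    GLOBAL (default): the pooled core NWU must *strictly* exceed
    ``delta_pct`` — at equality the images are "in doubt" and rate as
    absence.  ALL_SLICES: every core-bearing axial slice must individually
    exceed ``delta_pct`` (a hypoperfusion-hypodensity match should encompass
    all slices).  Fills ``reading.per_slice_present`` and
    ``reading.hypodense`` as a side effect.
    """
    if delta_pct < 0:
        raise ValueError("delta_pct must be >= 0")
    if slice_rule not in (GLOBAL, ALL_SLICES):
        raise ValueError(f"unknown slice_rule {slice_rule!r}")
    reading.per_slice_present = [v > delta_pct for v in reading.per_slice_nwu]
    if slice_rule == GLOBAL:
        hypodense = reading.nwu_pct > delta_pct
    else:
        hypodense = bool(reading.per_slice_present) and all(reading.per_slice_present)
    reading.hypodense = hypodense
    return hypodense


def classify_hhm(
    study: ImagingStudy,
    masks: LesionMasks,
    delta_pct: float = 5.0,
    slice_rule: str = GLOBAL,
) -> HHMDecision:
    """HHM call for one study: core present, hypodensity absent."""
    if masks.core.shape != study.shape:
        raise ValueError(
            f"mask grid {masks.core.shape} does not match study grid {study.shape}"
        )
    if not masks.core.any():
        return HHMDecision(core_present=False, hypodense=False, mismatch=False)
    reading = compute_nwu(study.ncct, masks.core, study.midline_axis)
    hypodense = judge_hypodensity(reading, delta_pct, slice_rule)
    return HHMDecision(
        core_present=True,
        hypodense=hypodense,
        mismatch=not hypodense,
        reading=reading,
    )
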