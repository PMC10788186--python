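"""Automated perfusion-mismatch eligibility (EXTEND criteria).

The automated rule validated by the EXTEND thrombolysis trial selects
patients with salvageable tissue: an ischemic core (relative CBF below 30%
of the contralateral side) that is small (< 70 mL) and surrounded by a
substantially larger hypoperfused region (Tmax > 6 s), quantified by the
mismatch ratio (penumbra/core > 1.2) and the absolute mismatch volume
(> 10 mL).  Thrombolysis eligibility in a known-onset cohort is then:
within the 4.5 h window, or beyond it with a positive automated mismatch.

The published phrasing chains the three clauses with an ambiguous "or";
both readings are provided.  CONJUNCTIVE (default, the trial's own rule)
requires ratio AND absolute mismatch AND core cap; DISJUNCTIVE requires the
core cap and either of the two mismatch clauses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import (SegmentationThresholds, _relative_below,
                           mask_volume_ml, mirror_reference)
from .study import ImagingStudy

CONJUNCTIVE = "CONJUNCTIVE"
DISJUNCTIVE = "DISJUNCTIVE"

THROMBOLYSIS_WINDOW_H = 4.5


@dataclass
class PerfusionVolumes:
    """Core / penumbra volumes and their mismatch, as an automated tool reports them.

    ``mismatch_ratio`` is ``inf`` when the core is empty but penumbra
    present, and NaN (undefined) when both are empty.  A negative
    ``mismatch_ml`` (core extending beyond the Tmax lesion) is legal and
    flagged via :attr:`negative_mismatch`.
    """

    core_ml: float
    penumbra_ml: float

    def __post_init__(self) -> None:
        if self.core_ml < 0 or self.penumbra_ml < 0:
            raise ValueError("volumes must be >= 0")

    @property
    def mismatch_ml(self) -> float:
        return self.penumbra_ml - self.core_ml

    @property
    def mismatch_ratio(self) -> float:
        if self.core_ml == 0:
            return math.inf if self.penumbra_ml > 0 else math.nan
        return self.penumbra_ml / self.core_ml

    @property
    def negative_mismatch(self) -> bool:
        return self.mismatch_ml < 0


@dataclass
class ExtendCriteria:
    """Cut-offs of the automated perfusion-mismatch rule."""

    ratio_cut: float = 1.2
    abs_cut_ml: float = 10.0
    core_cap_ml: float = 70.0
    logic: str = CONJUNCTIVE

    def __post_init__(self) -> None:
        if min(self.ratio_cut, self.abs_cut_ml, self.core_cap_ml) <= 0:
            raise ValueError("all cut-offs must be positive")
        if self.logic not in (CONJUNCTIVE, DISJUNCTIVE):
            raise ValueError(f"unknown logic {self.logic!r}")


@dataclass
class EligibilityLabel:
    """Thrombolysis eligibility of one patient."""

    onset_to_ct_h: float
    within_window: bool
    extend_positive: bool

    @property
    def eligible(self) -> bool:
        return self.within_window or self.extend_positive


def perfusion_volumes(
    study: ImagingStudy,
    thr: SegmentationThresholds | None = None,
    core_cbf_rel: float = 0.30,
) -> PerfusionVolumes:
    """Core (CBF < 30% of contralateral) and penumbra (Tmax > 6 s) volumes.

    This is the automated-software counterpart of the rater segmentation:
    whole-brain relative-CBF thresholding for the core (``core_cbf_rel`` of
    the mirrored value — note this 30% is a different number from the rater
    protocol's 60% CBF fallback fraction), Tmax thresholding for the
    hypoperfused tissue.  Voxels whose mirrored CBF is zero have an
    undefined relative value and never enter the core.
    """
    thr = thr or SegmentationThresholds()
    mirror_cbf = mirror_reference(study.cbf, study.midline_axis)
    core = _relative_below(study.cbf, mirror_cbf, core_cbf_rel, study.brain_mask)
    penumbra = study.brain_mask & (study.tmax > thr.tmax_cut_s)
    return PerfusionVolumes(
        core_ml=mask_volume_ml(core, study.voxel_spacing_mm),
        penumbra_ml=mask_volume_ml(penumbra, study.voxel_spacing_mm),
    )


def extend_decision(v: PerfusionVolumes, c: ExtendCriteria | None = None) -> bool:
    """Does the volume profile satisfy the automated mismatch criteria?

    An empty core with penumbra above the absolute cut counts as positive
    (the ratio is treated as infinite); no lesion at all is negative —
    nothing to salvage — not an error.
    """
    c = c or ExtendCriteria()
    if v.core_ml >= c.core_cap_ml:
        return False
    if v.penumbra_ml == 0 and v.core_ml == 0:
        return False
    ratio_ok = v.mismatch_ratio > c.ratio_cut  # inf > cut; nan never
    abs_ok = v.mismatch_ml > c.abs_cut_ml
    if c.logic == CONJUNCTIVE:
        return bool(ratio_ok and abs_ok)
    return bool(ratio_ok or abs_ok)


def label_eligibility(onset_to_ct_h: float, extend_positive: bool) -> EligibilityLabel:
    """Eligibility: within the 4.5 h window, or late with a positive mismatch.

    The window boundary is strict: onset-to-imaging of exactly 4.5 h does
    not count as "within 4.5 h".
    """
    if onset_to_ct_h < 0:
        raise ValueError("onset_to_ct_h must be >= 0")
    return EligibilityLabel(
        onset_to_ct_h=float(onset_to_ct_h),
        within_window=onset_to_ct_h < THROMBOLYSIS_WINDOW_H,
        extend_positive=bool(extend_positive),
    )


def classify_extend(
    study: ImagingStudy,
    thr: SegmentationThresholds | None = None,
    criteria: ExtendCriteria | None = None,
) -> tuple[bool, PerfusionVolumes]:
    """Convenience: volumes + decision in one call."""
    v = perfusion_volumes(study, thr)
    return extend_decision(v, criteria), v
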