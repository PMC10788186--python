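"""Digital head phantoms for multimodal stroke CT.

Generates single-patient studies — an NCCT volume plus co-registered CBV /
CBF / MTT / TTD / Tmax maps with known ground truth — and whole synthetic
cohorts.  The phantom is deliberately simple: an ellipsoidal brain with a
mirror-symmetric healthy hemisphere, an ellipsoidal hypoperfused lesion
(penumbra) confined to one hemisphere, and a core ellipsoid inside it whose
perfusion values satisfy the standard core thresholds.  The NCCT density in
the true core decreases with time since onset through net water uptake
(NWU), the "tissue clock": ischemic tissue takes up water after arterial
occlusion, which reads as a slowly growing hypodensity relative to the
mirror-image healthy tissue.

No attempt is made to model skull, CSF, beam hardening, partial-volume
effects or patient motion; the phantom exists to exercise the segmentation
and classification rules against a known truth, not to look like a scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .study import ImagingStudy

#: Conventional healthy gray-matter baselines used throughout the defaults.
DEFAULT_BASELINES = {"hu": 33.0, "cbf": 50.0, "cbv": 4.0, "tmax_s": 0.5,
                     "mtt_s": 4.0, "ttd_s": 6.0}


def nwu_time_course(t_h: float, rate: float = 1.3, cap: float = 12.0) -> float:
    """Net water uptake (percent) as a function of time since onset.

    Water uptake into ischemic tissue accrues roughly steadily in the first
    hours after occlusion and then saturates; this implementation is the
    simplest such curve, linear with a hard cap::

        NWU(t) = min(rate * t, cap)

    Parameters
    ----------
    t_h : float
        Hours since symptom onset, >= 0.
    rate : float
        Accrual rate in percent per hour, >= 0.
    cap : float
        Saturation value in percent, 0 <= cap < 100.

    Returns
    -------
    float
        NWU in percent; non-decreasing and continuous in ``t_h``.
    """
    if t_h < 0:
        raise ValueError(f"time since onset must be >= 0, got {t_h}")
    if rate < 0:
        raise ValueError(f"NWU rate must be >= 0, got {rate}")
    if not 0 <= cap < 100:
        raise ValueError(f"NWU cap must lie in [0, 100), got {cap}")
    return min(rate * t_h, cap)


@dataclass
class PhantomSpec:
    """Geometry, physiology and acquisition parameters of one phantom.

    The lesion is an ellipsoid (``lesion_radii_mm``, the penumbra) with a
    core ellipsoid (``core_radii_mm``) sharing its centre; the core must fit
    inside the penumbra and the whole lesion inside one hemisphere.  Core
    CBF is ``core_cbf_fraction`` of the contralateral value (below the 30%
    core threshold by default) and every penumbra voxel carries
    ``penumbra_tmax_s`` (above the 6 s hypoperfusion cut by default).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)
    brain_baseline_hu: float = DEFAULT_BASELINES["hu"]
    hu_noise_sd: float = 1.0
    baseline_cbf: float = DEFAULT_BASELINES["cbf"]
    baseline_cbv: float = DEFAULT_BASELINES["cbv"]
    baseline_tmax_s: float = DEFAULT_BASELINES["tmax_s"]
    baseline_mtt_s: float = DEFAULT_BASELINES["mtt_s"]
    baseline_ttd_s: float = DEFAULT_BASELINES["ttd_s"]
    lesion_center_voxel: tuple[float, float, float] = (16.0, 32.0, 8.0)
    lesion_radii_mm: tuple[float, float, float] = (20.0, 24.0, 20.0)
    core_radii_mm: tuple[float, float, float] = (10.0, 12.0, 10.0)
    core_cbf_fraction: float = 0.20      # of contralateral; < 0.30
    core_cbv_ml_per_100ml: float = 1.0   # below 2 absolute and 30% relative
    penumbra_cbf_fraction: float = 0.50  # hypoperfused but above core cut
    penumbra_tmax_s: float = 8.0         # > 6 s
    penumbra_delay_factor: float = 2.0   # MTT/TTD elevation inside penumbra
    perfusion_noise_frac: float = 0.01   # multiplicative noise SD on maps
    nwu_rate_pct_per_h: float = 1.3
    nwu_cap_pct: float = 12.0
    onset_to_ct_h: float = 2.0
    lesion_present: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if any(r <= 0 for r in self.lesion_radii_mm):
            raise ValueError("lesion radii must be positive")
        if any(c > p for c, p in zip(self.core_radii_mm, self.lesion_radii_mm)):
            raise ValueError("core ellipsoid must fit inside the penumbra ellipsoid")
        if not 0 <= self.nwu_cap_pct < 100:
            raise ValueError("nwu_cap_pct must lie in [0, 100)")
        if self.nwu_rate_pct_per_h < 0:
            raise ValueError("nwu_rate_pct_per_h must be >= 0")
        if self.onset_to_ct_h < 0:
            raise ValueError("onset_to_ct_h must be >= 0")
        if self.hu_noise_sd < 0 or self.perfusion_noise_frac < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def nwu_applied_pct(self) -> float:
        """NWU that the generator applies to the true core at acquisition."""
        return nwu_time_course(self.onset_to_ct_h, self.nwu_rate_pct_per_h,
                               self.nwu_cap_pct)


@dataclass
class GroundTruth:
    """Simulation truth accompanying a generated study."""

    core_mask_true: np.ndarray
    penumbra_mask_true: np.ndarray
    onset_to_ct_h: float
    nwu_applied_pct: float

    def __post_init__(self) -> None:
        self.core_mask_true = np.asarray(self.core_mask_true, dtype=bool)
        self.penumbra_mask_true = np.asarray(self.penumbra_mask_true, dtype=bool)
        if self.core_mask_true.shape != self.penumbra_mask_true.shape:
            raise ValueError("truth masks must share one grid")
        if np.any(self.core_mask_true & ~self.penumbra_mask_true):
            raise ValueError("true core must be contained in the true penumbra")


def _ellipsoid_mask(shape, spacing, center_voxel, radii_mm):
    """Voxels whose centre lies inside the given ellipsoid (physical mm)."""
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    center_mm = [c * s for c, s in zip(center_voxel, spacing)]
    d2 = sum(((x - c) / r) ** 2 for x, c, r in zip(coords, center_mm, radii_mm))
    return d2 <= 1.0


def _brain_mask(shape, spacing):
    """Mirror-symmetric ellipsoidal brain filling ~90% of the grid extent."""
    center = [(n - 1) / 2.0 for n in shape]
    radii = [0.45 * n * s for n, s in zip(shape, spacing)]
    return _ellipsoid_mask(shape, spacing, center, radii)


def generate_phantom(
    spec: PhantomSpec, seed: int | np.random.SeedSequence | None = None
) -> tuple[ImagingStudy, GroundTruth]:
    """Generate one phantom study plus its ground truth.

    The same ``(spec, seed)`` pair always yields bit-identical output.
    A seed is mandatory: silent irreproducibility is worse than an error.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    shape, spacing = tuple(spec.grid_shape), tuple(spec.voxel_spacing_mm)

    brain = _brain_mask(shape, spacing)
    if spec.lesion_present:
        penumbra = _ellipsoid_mask(shape, spacing, spec.lesion_center_voxel,
                                   spec.lesion_radii_mm)
        core = _ellipsoid_mask(shape, spacing, spec.lesion_center_voxel,
                               spec.core_radii_mm)
        core &= penumbra  # guard against voxelisation edge cases
    else:
        penumbra = np.zeros(shape, dtype=bool)
        core = np.zeros(shape, dtype=bool)

    if np.any(penumbra & ~brain):
        raise ValueError("lesion extends outside the brain mask")
    # hemisphere confinement: no lesion voxel may touch the mirror image of
    # the lesion (which would mean it crosses the midsagittal plane)
    idx = np.nonzero(penumbra)[0]
    if idx.size:
        n0 = shape[0]
        left = idx <= (n0 - 1) / 2.0 - 0.5
        right = idx >= (n0 - 1) / 2.0 + 0.5
        if not (left.all() or right.all()):
            raise ValueError("lesion crosses the midsagittal plane")

    nwu = spec.nwu_applied_pct

    def noisy(base_grid, sd):
        if sd == 0:
            return base_grid.astype(float)
        return base_grid + rng.normal(0.0, sd, size=shape)

    ncct = np.full(shape, spec.brain_baseline_hu)
    ncct[core] = spec.brain_baseline_hu * (1.0 - nwu / 100.0)
    ncct = noisy(ncct, spec.hu_noise_sd)

    pnoise = spec.perfusion_noise_frac
    cbf = np.full(shape, spec.baseline_cbf)
    cbf[penumbra] = spec.penumbra_cbf_fraction * spec.baseline_cbf
    cbf[core] = spec.core_cbf_fraction * spec.baseline_cbf
    cbf = np.clip(noisy(cbf, pnoise * spec.baseline_cbf), 0, None)

    cbv = np.full(shape, spec.baseline_cbv)
    cbv[core] = spec.core_cbv_ml_per_100ml
    cbv = np.clip(noisy(cbv, pnoise * spec.baseline_cbv), 0, None)

    mtt = np.full(shape, spec.baseline_mtt_s)
    mtt[penumbra] = spec.penumbra_delay_factor * spec.baseline_mtt_s
    mtt = np.clip(noisy(mtt, pnoise * spec.baseline_mtt_s), 0, None)

    ttd = np.full(shape, spec.baseline_ttd_s)
    ttd[penumbra] = spec.penumbra_delay_factor * spec.baseline_ttd_s
    ttd = np.clip(noisy(ttd, pnoise * spec.baseline_ttd_s), 0, None)

    tmax = np.full(shape, spec.baseline_tmax_s)
    tmax[penumbra] = spec.penumbra_tmax_s
    tmax = np.clip(noisy(tmax, pnoise * spec.baseline_tmax_s), 0, None)

    study = ImagingStudy(
        ncct=ncct, cbv=cbv, cbf=cbf, mtt=mtt, ttd=ttd, tmax=tmax,
        voxel_spacing_mm=spacing, brain_mask=brain, midline_axis=0,
    )
    truth = GroundTruth(
        core_mask_true=core, penumbra_mask_true=penumbra,
        onset_to_ct_h=spec.onset_to_ct_h, nwu_applied_pct=nwu,
    )
    return study, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Composition and onset-time distributions of a synthetic cohort.

    Three strata: patients imaged within the 4.5 h thrombolysis window
    (``n_within_window``), late patients with a favourable automated
    perfusion-mismatch profile (``n_late_mismatch``, eligible) and late
    patients without one (``n_late_no_mismatch``, not eligible).  Onset
    times are drawn from normals truncated at zero — resampling on
    non-positives — with the eligible / non-eligible group means and SDs of
    the reference cohort (2.70 h SD 2.30 h; 8.27 h SD 6.10 h).
    """

    n_within_window: int = 197
    n_late_mismatch: int = 22
    n_late_no_mismatch: int = 28
    onset_mean_eligible_h: float = 2.70      # 2:42
    onset_sd_eligible_h: float = 2.30        # 2:18
    onset_mean_noneligible_h: float = 8.27   # 8:16
    onset_sd_noneligible_h: float = 6.10     # 6:06
    #: fraction of within-window patients given a favourable (mismatch)
    #: perfusion profile, matching the observed 88/197
    p_mismatch_within_window: float = 88 / 197
    phantom_template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_within_window", "n_late_mismatch", "n_late_no_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("onset_sd_eligible_h", "onset_sd_noneligible_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_within_window + self.n_late_mismatch + self.n_late_no_mismatch


def _sample_onset(rng, mean, sd, low, high=math.inf):
    """One draw from N(mean, sd) truncated (by resampling) to (low, high)."""
    for _ in range(100_000):
        x = rng.normal(mean, sd)
        if low < x < high and x > 0:
            return float(x)
    raise RuntimeError("onset-time resampling failed to hit the stratum window")


def _jitter_radii(rng, radii, frac=0.10):
    return tuple(float(r * (1.0 + rng.uniform(-frac, frac))) for r in radii)


#: Baseline-characteristic generators per eligibility group, emulating the
#: reference cohort's marginals (age ~74 y, half women, hypertension more
#: prevalent among eligible patients, NIHSS ~8-10).  Values are rounded the
#: way a registry would record them; a small fraction is left missing.
_COVARIATE_PARAMS = {
    True: dict(age_mean=73.9, age_sd=13.3, p_women=0.502, p_htn=0.778,
               nihss_mean=8.6, nihss_sd=5.9),
    False: dict(age_mean=77.3, age_sd=15.6, p_women=0.500, p_htn=0.462,
                nihss_mean=10.0, nihss_sd=6.8),
}


def _sample_covariates(rng, eligible: bool, p_missing: float = 0.08) -> dict:
    p = _COVARIATE_PARAMS[eligible]
    cov = {
        "age_y": float(np.clip(round(rng.normal(p["age_mean"], p["age_sd"])), 18, 105)),
        "sex_female": bool(rng.random() < p["p_women"]),
        "hypertension": bool(rng.random() < p["p_htn"]),
        "nihss": float(np.clip(round(rng.normal(p["nihss_mean"], p["nihss_sd"])), 0, 42)),
    }
    for key in ("hypertension", "nihss"):
        if rng.random() < p_missing:
            cov[key] = None
    return cov


def generate_cohort(cs: CohortSpec) -> Iterator[tuple[ImagingStudy, "CohortRecord"]]:
    """Lazily generate a synthetic cohort of (study, record) pairs.

    Stratum geometry is drawn so that the within-window and late-mismatch
    strata carry a favourable perfusion profile (small core inside a large
    penumbra) where required, while the late no-mismatch stratum carries a
    matched lesion (core filling the penumbra) that fails the automated
    mismatch criteria by construction.  Records carry the true stratum
    label; wrap in ``list()`` for an in-memory cohort.
    """
    from .cohort import CohortRecord  # local import: avoid cycle

    if cs.n_total == 0:
        raise ValueError("cohort must contain at least one patient")
    rng = np.random.default_rng(cs.seed)
    tpl = cs.phantom_template

    strata = (
        ["within_window"] * cs.n_within_window
        + ["late_mismatch"] * cs.n_late_mismatch
        + ["late_no_mismatch"] * cs.n_late_no_mismatch
    )
    for i, stratum in enumerate(strata):
        if stratum == "within_window":
            onset = _sample_onset(rng, cs.onset_mean_eligible_h,
                                  cs.onset_sd_eligible_h, 0.0, 4.5)
            favourable = rng.random() < cs.p_mismatch_within_window
        elif stratum == "late_mismatch":
            onset = _sample_onset(rng, cs.onset_mean_eligible_h,
                                  cs.onset_sd_eligible_h, 4.5)
            favourable = True
        else:
            onset = _sample_onset(rng, cs.onset_mean_noneligible_h,
                                  cs.onset_sd_noneligible_h, 4.5)
            favourable = False

        lesion_radii = _jitter_radii(rng, tpl.lesion_radii_mm)
        if favourable:
            core_radii = _jitter_radii(rng, tpl.core_radii_mm)
            core_radii = tuple(min(c, l) for c, l in zip(core_radii, lesion_radii))
        else:
            # matched lesion: core fills the hypoperfused region, so the
            # mismatch volume and ratio collapse and the automated rule fails
            core_radii = lesion_radii

        spec = replace(
            tpl,
            onset_to_ct_h=onset,
            lesion_radii_mm=lesion_radii,
            core_radii_mm=core_radii,
        )
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        covariates = _sample_covariates(rng, eligible=stratum != "late_no_mismatch")
        study, truth = generate_phantom(spec, seed=phantom_seed)
        record = CohortRecord(
            patient_id=f"P{i:04d}",
            onset_to_ct_h=onset,
            stratum=stratum,
            nwu_true_pct=truth.nwu_applied_pct,
            phantom_seed=phantom_seed,
            covariates=covariates,
        )
        yield study, record


def cohort_records(cs: CohortSpec) -> list["CohortRecord"]:
    """The cohort's records only (studies generated and discarded)."""
    return [record for _, record in generate_cohort(cs)]
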