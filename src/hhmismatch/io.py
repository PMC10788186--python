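"""Readers/writers, pipeline configuration and the end-to-end cohort run.

Imaging interchange is NIfTI-1 (one file per map, suffixes ``_ncct``,
``_cbv``, ``_cbf``, ``_mtt``, ``_ttd``, ``_tmax``, plus ``_brainmask``),
with voxel spacing carried in the header; cohorts are CSV with one row per
patient; decisions and reports are JSON.  Identical configuration + seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .cohort import CohortRecord, frame_to_records, records_to_frame
from .diagnostics import accuracy_metrics, confusion_from_cohort
from .extend import ExtendCriteria, classify_extend, label_eligibility
from .hhm import GLOBAL, classify_hhm
from .phantom import CohortSpec, PhantomSpec, generate_cohort
from .segmentation import SegmentationThresholds, segment_study
from .study import MAP_NAMES, ImagingStudy

log = logging.getLogger("hhmismatch")

_STUDY_FILES = MAP_NAMES + ("brainmask",)


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_study(study: ImagingStudy, out_dir, prefix: str = "study",
                sidecar: dict | None = None) -> Path:
    """Write a study as NIfTI volumes plus a JSON sidecar; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_spacing_mm)
    for name in MAP_NAMES:
        img = nib.Nifti1Image(getattr(study, name).astype(np.float64), aff)
        nib.save(img, out_dir / f"{prefix}_{name}.nii")
    nib.save(nib.Nifti1Image(study.brain_mask.astype(np.uint8), aff),
             out_dir / f"{prefix}_brainmask.nii")
    meta = {"midline_axis": study.midline_axis,
            "voxel_spacing_mm": list(study.voxel_spacing_mm)}
    if sidecar:
        meta.update(sidecar)
    (out_dir / f"{prefix}.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out_dir


def read_study(study_dir, prefix: str = "study") -> ImagingStudy:
    """Read a study directory written by :func:`write_study`.

    Validates presence of all maps, shape/affine agreement and finiteness;
    voxel spacing is taken from the NIfTI header.
    """
    study_dir = Path(study_dir)
    grids, affines = {}, {}
    for name in _STUDY_FILES:
        path = study_dir / f"{prefix}_{name}.nii"
        if not path.exists() and path.with_suffix(".nii.gz").exists():
            path = path.with_suffix(".nii.gz")
        if not path.exists():
            raise FileNotFoundError(f"missing map '{name}': {path}")
        img = nib.load(path)
        grids[name] = np.asarray(img.dataobj, dtype=float)
        affines[name] = img.affine
    shapes = {name: g.shape for name, g in grids.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"grid mismatch between maps: {shapes}")
    ref = affines["ncct"]
    for name, aff in affines.items():
        if not np.allclose(aff, ref):
            raise ValueError(f"affine of '{name}' differs from NCCT affine")
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(ref))
    midline_axis = 0
    meta_path = study_dir / f"{prefix}.json"
    if meta_path.exists():
        midline_axis = int(json.loads(meta_path.read_text()).get("midline_axis", 0))
    return ImagingStudy(
        **{name: grids[name] for name in MAP_NAMES},
        voxel_spacing_mm=spacing,
        brain_mask=grids["brainmask"] > 0,
        midline_axis=midline_axis,
    )


def write_masks(masks, out_dir, prefix: str = "masks") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(masks.voxel_spacing_mm)
    for name in ("ischemic_area", "core", "hypoperfusion_tmax"):
        nib.save(nib.Nifti1Image(getattr(masks, name).astype(np.uint8), aff),
                 out_dir / f"{prefix}_{name}.nii")
    (out_dir / f"{prefix}.json").write_text(json.dumps(
        {"core_source": masks.core_source, "volumes_ml": masks.volumes_ml},
        indent=2, sort_keys=True))
    return out_dir


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything one reproducible cohort run depends on.

    Round-trips losslessly through YAML; every threshold default equals the
    published reading-protocol value where one exists.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    hhm_delta_pct: float = 5.0
    hhm_slice_rule: str = GLOBAL
    extend_criteria: ExtendCriteria = field(default_factory=ExtendCriteria)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the cohort's phantoms follow the pipeline's phantom template
        self.cohort.phantom_template = self.phantom
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [listify(v) for v in obj]
            return obj

        d = dataclasses.asdict(self)
        del d["cohort"]["phantom_template"]  # aliased to d["phantom"]
        return listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        phantom = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in d.pop("phantom", {}).items()})
        cohort_d = d.pop("cohort", {})
        cohort_d.pop("phantom_template", None)
        cohort = CohortSpec(phantom_template=phantom, **cohort_d)
        thresholds = SegmentationThresholds(**d.pop("thresholds", {}))
        criteria = ExtendCriteria(**d.pop("extend_criteria", {}))
        return cls(phantom=phantom, cohort=cohort, thresholds=thresholds,
                   extend_criteria=criteria, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the end-to-end run


def classify_patient(study: ImagingStudy, config: PipelineConfig,
                     record: CohortRecord) -> CohortRecord:
    """Run segmentation + both classifiers + eligibility on one patient."""
    masks = segment_study(study, config.thresholds)
    hhm_dec = classify_hhm(study, masks, config.hhm_delta_pct,
                           config.hhm_slice_rule)
    extend_pos, volumes = classify_extend(study, config.thresholds,
                                          config.extend_criteria)
    if volumes.negative_mismatch:
        log.warning("%s: negative mismatch volume (%.1f mL)",
                    record.patient_id, volumes.mismatch_ml)
    label = label_eligibility(record.onset_to_ct_h, extend_pos)
    record.hhm_positive = hhm_dec.mismatch
    record.extend_positive = extend_pos
    record.eligible = label.eligible
    record.covariates.update({
        "core_ml": volumes.core_ml,
        "penumbra_ml": volumes.penumbra_ml,
        "nwu_measured_pct": (hhm_dec.reading.nwu_pct
                             if hhm_dec.reading is not None else None),
    })
    return record


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Simulate a cohort, classify every patient, evaluate both rules.

    Returns a report dict (and, when ``out_dir`` is given, writes the
    labelled cohort CSV, the per-classifier accuracy reports and a
    provenance record).  Identical config + seed give identical reports.
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    if config.cohort.n_total == 0:
        raise ValueError("cohort must contain at least one patient")

    records = []
    for study, record in generate_cohort(config.cohort):
        try:
            records.append(classify_patient(study, config, record))
        except Exception as exc:  # noqa: BLE001 - reraise with context
            raise RuntimeError(
                f"pipeline failed at patient {record.patient_id} "
                f"(classification stage): {exc}"
            ) from exc
    log.info("classified %d patients in %.1f s", len(records),
             time.perf_counter() - t0)

    df = records_to_frame(records)
    report = {
        "n_patients": len(records),
        "n_eligible": int(df["eligible"].sum()),
        "thresholds": config.to_dict()["thresholds"],
        "hhm_delta_pct": config.hhm_delta_pct,
        "extend_criteria": config.to_dict()["extend_criteria"],
        "provenance": {"config_sha256": config.digest(), "seed": config.seed,
                       "version": __version__},
        "classifiers": {},
    }
    for clf in ("hhm_positive", "extend_positive"):
        table = confusion_from_cohort(records, clf)
        acc = accuracy_metrics(table)
        report["classifiers"][clf] = {
            "confusion": {"tp": table.tp, "fp": table.fp,
                          "fn": table.fn, "tn": table.tn},
            "metrics_pct": {
                name: (None if acc.metric(name) is None
                       else dict(zip(("value", "ci_low", "ci_high"),
                                     acc.metric(name).rounded())))
                for name in ("sensitivity", "specificity", "ppv", "npv", "auc")
            },
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "cohort_labeled.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def label_cohort_csv(in_csv, out_csv) -> None:
    """Fill the ``eligible`` column of a cohort CSV from onset + EXTEND call."""
    import pandas as pd

    df = pd.read_csv(in_csv)
    records = frame_to_records(df)
    for r in records:
        if r.extend_positive is None:
            raise ValueError(f"record {r.patient_id} lacks extend_positive")
        r.eligible = label_eligibility(r.onset_to_ct_h, r.extend_positive).eligible
    records_to_frame(records).to_csv(out_csv, index=False)
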