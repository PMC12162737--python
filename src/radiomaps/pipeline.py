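"""End-to-end orchestration of the two study designs.

experimental: n subjects, each rendered at every FOV in the acquisition list
(default: the 256x329 / 279x359 / 302x390 mm triplet at matrix 224x157);
per-subject COVs across FOVs.

clinical: n subjects, each rendered at a single subject-specific FOV drawn
deterministically from the configured FOV range (emulating per-patient FOV
adjustment); COVs across subjects.

Both designs run: phantom -> threshold segmentation -> conventional
extraction -> parametric maps + ROI readout -> COV reports -> method
comparison, and are bitwise reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ImageSlice, SegmentationMask
from .features import ALL_FEATURES, ExtractionSettings, extract_all
from .maps import DEFAULT_TILE_MM, build_tile_grid, compute_all_maps, map_roi_mean
from .phantom import (
    DEFAULT_ACQUISITIONS,
    AcquisitionSpec,
    CohortRecord,
    PhantomSpec,
    SubjectJitter,
    generate_cohort,
    generate_subject_truth,
    render_fov,
)
from .reproducibility import (
    STABILITY_THRESHOLD,
    clinical_design_covs,
    compare_methods,
    experimental_design_covs,
    make_feature_table,
)
from .segmentation import DEFAULT_THRESHOLD, circle_region, threshold_segment

__all__ = ["RunConfig", "RunResult", "run_experimental", "run_clinical"]

log = logging.getLogger("radiomaps")

#: Margin added to the (jittered) outer myocardial radius for the coarse ROI.
ROI_MARGIN_MM = 1.0


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; YAML round-trippable."""

    design: str = "experimental"
    n_subjects: int = 12
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisitions: tuple[AcquisitionSpec, ...] = DEFAULT_ACQUISITIONS
    #: Clinical design: FOV interpolated between these two (row, col) pairs.
    clinical_fov_range: tuple[tuple[float, float], tuple[float, float]] = (
        (329.0, 256.0),
        (390.0, 302.0),
    )
    clinical_matrix: tuple[int, int] = (224, 157)
    tile_size_mm: tuple[float, float, float] = DEFAULT_TILE_MM
    settings: ExtractionSettings = field(default_factory=ExtractionSettings)
    threshold: tuple[float, float] = DEFAULT_THRESHOLD
    cov_threshold: float = STABILITY_THRESHOLD
    out_dir: str | None = None

    def validate(self) -> None:
        if self.design not in ("experimental", "clinical"):
            raise ValueError("design must be 'experimental' or 'clinical'")
        if self.design == "experimental" and len(self.acquisitions) < 2:
            raise ValueError("experimental design requires >= 2 acquisitions")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists, plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            if isinstance(ph.get("subject_jitter"), dict):
                ph["subject_jitter"] = SubjectJitter(**ph["subject_jitter"])
            if "center_mm" in ph:
                ph["center_mm"] = tuple(ph["center_mm"])
            d["phantom"] = PhantomSpec(**ph)
        if "acquisitions" in d:
            d["acquisitions"] = tuple(
                AcquisitionSpec(
                    fov_mm=tuple(a["fov_mm"]),
                    matrix=tuple(a.get("matrix", (224, 157))),
                    slice_thickness_mm=a.get("slice_thickness_mm", 8.0),
                )
                for a in d["acquisitions"]
            )
        if "settings" in d and isinstance(d["settings"], dict):
            s = dict(d["settings"])
            if "angles_2d" in s:
                s["angles_2d"] = tuple(tuple(a) for a in s["angles_2d"])
            d["settings"] = ExtractionSettings(**s)
        for key in ("clinical_fov_range",):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        for key in ("clinical_matrix", "tile_size_mm", "threshold"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class RunResult:
    """In-memory artifact bundle of one pipeline run."""

    config: RunConfig
    feature_table: pd.DataFrame
    report_conventional: object
    report_map: object
    summary: object
    n_images: int
    manifest: pd.DataFrame


def _segment_record(rec: CohortRecord, config: RunConfig) -> SegmentationMask:
    roi = circle_region(
        rec.image, rec.truth.center_mm, rec.truth.r_outer_mm + ROI_MARGIN_MM
    )
    lo, hi = config.threshold
    return threshold_segment(rec.image, roi, lo, hi)


def _extract_record(rec: CohortRecord, config: RunConfig):
    """Both extraction methods for one image; returns (conv_row, map_row)."""
    t0 = time.perf_counter()
    mask = _segment_record(rec, config)
    fv = extract_all(rec.image, mask, config.settings)
    conv_row = {
        "subject_id": rec.subject_id,
        "fov_label": rec.fov_label,
        "method": "conventional",
    }
    conv_row.update(
        {k: (v if fv.valid[k] else np.nan) for k, v in fv.values.items()}
    )

    grid = build_tile_grid(rec.image, config.tile_size_mm)
    maps = compute_all_maps(rec.image, grid, config.settings)
    map_row = {
        "subject_id": rec.subject_id,
        "fov_label": rec.fov_label,
        "method": "map",
    }
    for name in ALL_FEATURES:
        ro = map_roi_mean(maps[name], mask)
        map_row[name] = ro.value if ro.valid else np.nan
    log.info(
        "subject %d fov %s: extracted both methods in %.2f s",
        rec.subject_id,
        rec.fov_label,
        time.perf_counter() - t0,
    )
    return conv_row, map_row


def _write_outputs(result: RunResult) -> None:
    out = result.config.out_dir
    os.makedirs(out, exist_ok=True)
    result.feature_table.to_csv(os.path.join(out, "features.csv"), index=False)
    result.report_conventional.cov_table.to_csv(
        os.path.join(out, "covs_conventional.csv"), index=False
    )
    result.report_map.cov_table.to_csv(os.path.join(out, "covs_map.csv"), index=False)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2, sort_keys=True)
    result.config.to_yaml(os.path.join(out, "config.yaml"))
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(
            {
                "config_hash": result.config.content_hash(),
                "seed": result.config.seed,
                "version": __version__,
                "n_images": result.n_images,
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def _finalize(config, records, rows, design_cov_fn) -> RunResult:
    table = make_feature_table(rows)
    rep_conv = design_cov_fn(table, "conventional", config.cov_threshold)
    rep_map = design_cov_fn(table, "map", config.cov_threshold)
    summary = compare_methods(rep_conv, rep_map)
    manifest = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "fov_label": [r.fov_label for r in records],
            "spacing_row_mm": [r.image.spacing_mm[0] for r in records],
            "spacing_col_mm": [r.image.spacing_mm[1] for r in records],
        }
    )
    result = RunResult(
        config=config,
        feature_table=table,
        report_conventional=rep_conv,
        report_map=rep_map,
        summary=summary,
        n_images=len(records),
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(result)
    return result


def run_experimental(config: RunConfig | None = None) -> RunResult:
    """Multi-FOV design: every subject imaged at every acquisition."""
    config = config or RunConfig()
    config = replace(config, design="experimental")
    config.validate()
    spec = replace(config.phantom, seed=config.seed)
    images_dir = (
        os.path.join(config.out_dir, "images") if config.out_dir is not None else None
    )
    cohort = generate_cohort(spec, config.acquisitions, config.n_subjects, images_dir)
    rows = []
    for rec in cohort:
        conv_row, map_row = _extract_record(rec, config)
        rows.append(conv_row)
        rows.append(map_row)
    return _finalize(config, cohort.records, rows, experimental_design_covs)


def run_clinical(config: RunConfig | None = None) -> RunResult:
    """Single-FOV-per-subject design with per-subject FOV adjustment."""
    config = config or RunConfig(design="clinical", n_subjects=61)
    config = replace(config, design="clinical")
    config.validate()
    if config.n_subjects < 2:
        raise ValueError("clinical design COVs require at least 2 subjects")
    spec = replace(config.phantom, seed=config.seed)
    (fov_lo, fov_hi) = config.clinical_fov_range
    rng = np.random.default_rng([config.seed, 3])
    t = rng.uniform(0.0, 1.0, size=config.n_subjects)

    records = []
    rows = []
    for sid in range(config.n_subjects):
        fov = (
            fov_lo[0] + t[sid] * (fov_hi[0] - fov_lo[0]),
            fov_lo[1] + t[sid] * (fov_hi[1] - fov_lo[1]),
        )
        acq = AcquisitionSpec(fov_mm=fov, matrix=config.clinical_matrix)
        truth = generate_subject_truth(spec, sid)
        image = render_fov(truth, acq)
        rec = CohortRecord(
            subject_id=sid,
            fov_label=acq.label,
            image=image,
            truth=truth,
            acquisition=acq,
        )
        records.append(rec)
        conv_row, map_row = _extract_record(rec, config)
        rows.append(conv_row)
        rows.append(map_row)
    return _finalize(config, records, rows, clinical_design_covs)
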