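"""File formats: multi-page TIFF volumes, CSV tables, YAML configs.

Volumes are written as one TIFF page per B-scan plus a JSON sidecar
(`<stem>.json`) holding the pixel scales, identifiers and, when
available, the ground-truth boundary rows.  Traces, morphometry, cohort
and result tables are plain CSV.  Every writer here has a matching
reader and the pair round-trips losslessly (float rows to 4 decimals in
the truth sidecar).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import MorphometryRecord
from .segmentation import SegmentationParams, VolumeTraces
from .synthetic import CohortParams, OCTVolume, SceneTruth, VolumeParams


# ---------------------------------------------------------------------------
# volumes and masks
# ---------------------------------------------------------------------------

def write_volume(path, volume: OCTVolume, truth: SceneTruth | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.frames, photometric="minisblack")
    meta = {
        "lateral_scale_mm": volume.lateral_scale_mm,
        "axial_scale_um": volume.axial_scale_um,
        "eye_id": volume.eye_id,
        "person_id": volume.person_id,
        "laterality": volume.laterality,
    }
    if truth is not None:
        meta["truth"] = {
            "ilm_truth": np.round(truth.ilm_truth, 4).tolist(),
            "rpe_truth": np.round(truth.rpe_truth, 4).tolist(),
            "a_fovea_true": truth.a_fovea_true,
            "a_macula_true": truth.a_macula_true,
            "pit_center": list(truth.pit_center),
            "cprt_true_px": truth.cprt_true_px,
            "noise_sigma": truth.noise_sigma,
            "seed": truth.seed,
        }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_volume(path) -> tuple[OCTVolume, SceneTruth | None]:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    volume = OCTVolume(
        frames=np.asarray(frames, np.float32),
        lateral_scale_mm=meta["lateral_scale_mm"],
        axial_scale_um=meta["axial_scale_um"],
        eye_id=meta["eye_id"], person_id=meta["person_id"],
        laterality=meta["laterality"])
    truth = None
    if "truth" in meta:
        t = meta["truth"]
        truth = SceneTruth(
            ilm_truth=np.asarray(t["ilm_truth"], float),
            rpe_truth=np.asarray(t["rpe_truth"], float),
            a_fovea_true=t["a_fovea_true"], a_macula_true=t["a_macula_true"],
            pit_center=tuple(t["pit_center"]), cprt_true_px=t["cprt_true_px"],
            noise_sigma=t["noise_sigma"], seed=t["seed"])
    return volume, truth


def write_masks(path, masks: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(masks, np.uint8) * 255,
                     photometric="minisblack")


def read_masks(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


# ---------------------------------------------------------------------------
# traces and morphometry
# ---------------------------------------------------------------------------

def write_traces(path, traces: VolumeTraces) -> None:
    S, W = traces.ilm.shape
    s, c = np.meshgrid(np.arange(S), np.arange(W), indexing="ij")
    pd.DataFrame({
        "slice": s.ravel(), "column": c.ravel(),
        "ilm_row": traces.ilm.ravel(), "rpe_row": traces.rpe.ravel(),
        "valid": traces.valid.ravel().astype(int),
        "scan_qc": np.repeat(traces.qc, W),
    }).to_csv(path, index=False)


def read_traces(path) -> VolumeTraces:
    df = pd.read_csv(path)
    S = int(df["slice"].max()) + 1
    W = int(df["column"].max()) + 1
    df = df.sort_values(["slice", "column"])
    ilm = df["ilm_row"].to_numpy().reshape(S, W)
    rpe = df["rpe_row"].to_numpy().reshape(S, W)
    valid = df["valid"].to_numpy().reshape(S, W).astype(bool)
    qc = list(df.groupby("slice")["scan_qc"].first())
    return VolumeTraces(ilm=ilm, rpe=rpe, valid=valid, qc=qc)


MORPHOMETRY_COLUMNS = ["person_id", "eye", "fc", "fc_x100", "mc", "mc_x100",
                       "cprt_px", "cprt_um", "center_slice", "center_column", "qc"]


def morphometry_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "person_id": r.person_id, "eye": r.laterality,
            "fc": r.fc, "fc_x100": r.fc_x100, "mc": r.mc, "mc_x100": r.mc_x100,
            "cprt_px": r.cprt_px, "cprt_um": r.cprt_um,
            "center_slice": None if r.center is None else r.center.slice,
            "center_column": None if r.center is None else r.center.column,
            "qc": r.qc,
        })
    return pd.DataFrame(rows, columns=MORPHOMETRY_COLUMNS)


def write_morphometry(path, records: list[MorphometryRecord]) -> None:
    morphometry_frame(records).to_csv(path, index=False)


def read_morphometry(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, YAML round-trippable.

    Defaults marked (assumption) are not fixed by the imaging protocol:
    frame height and axial scale are typical for the emulated device.
    """

    volume: VolumeParams = dataclasses.field(default_factory=VolumeParams)
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    cohort: CohortParams = dataclasses.field(default_factory=CohortParams)
    n_volumes: int = 2
    n_persons: int = 200
    effects: dict = dataclasses.field(default_factory=dict)
    variance_components: tuple = (0.85, 0.5)
    fit_halfwidth: int = 12  # FC window: 12 columns either side of centre
    n_central_slices: int = 32
    seed: int = 0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def read_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key == "volume":
            val = VolumeParams(**{**val, "pit_center": tuple(val["pit_center"])})
        elif key == "segmentation":
            val = SegmentationParams(**val)
        elif key == "cohort":
            val = CohortParams(**val)
        elif key == "variance_components":
            val = tuple(val)
        elif not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    return cfg
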