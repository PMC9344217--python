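"""Held-out validation studies of the quantification pipeline.

Two study designs mirror the validation of the original phenotyping
method at desk scale:

* segmentation validation: fresh synthetic B-scans at default speckle,
  segmented blind, scored by mask intersection-over-union against the
  rendered truth and averaged;
* tertile-ordering validation: a pool of synthetic volumes whose true
  foveal curvature spans the population spread is split into FC
  tertiles; sets of three scans (one per tertile) must be ranked
  flattest-to-steepest by the pipeline's FC.

Both draw their scene parameters from the generator's population
defaults and derive all randomness from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .morphometry import TertileValidation, quantify_volume, tertile_ordering_validation
from .segmentation import SegmentationParams, astar_segment, miou


@dataclass
class SegmentationValidation:
    mean_iou: float
    per_scan_iou: np.ndarray
    n_scans: int


def run_segmentation_validation(n_scans: int = 200, seed: int = 0,
                                base_params: synthetic.VolumeParams | None = None,
                                seg_params: SegmentationParams | None = None
                                ) -> SegmentationValidation:
    """Mean IoU of predicted vs truth retina masks on fresh B-scans.

    Each scan gets its own foveal curvature, pit centre and thickness
    drawn from the population spread, plus default speckle noise.
    """
    rng = np.random.default_rng(seed)
    ious = np.empty(n_scans)
    for i in range(n_scans):
        params = synthetic.sample_fovea_params(rng, base_params)
        frame, ilm, rpe = synthetic.generate_bscan(
            params, seed=int(rng.integers(2**31)))
        pred = astar_segment(frame, seg_params)
        truth = synthetic.truth_mask(ilm, rpe, params.height)
        ious[i] = miou(pred, truth)
    return SegmentationValidation(mean_iou=float(ious.mean()),
                                  per_scan_iou=ious, n_scans=n_scans)


def run_tertile_validation(pool_size: int = 30, n_sets: int = 10, seed: int = 0,
                           base_params: synthetic.VolumeParams | None = None,
                           seg_params: SegmentationParams | None = None
                           ) -> TertileValidation:
    """End-to-end tertile ordering check on a fresh volume pool.

    Generates pool_size full volumes with population-spread FC, runs the
    complete segmentation + morphometry pipeline on each, and counts the
    sets (one scan per truth tertile) whose pipeline FC ordering matches
    the truth tertile ranks.
    """
    rng = np.random.default_rng(seed)
    truth_fc = np.empty(pool_size)
    pipe_fc = np.empty(pool_size)
    for i in range(pool_size):
        params = synthetic.sample_fovea_params(rng, base_params)
        vol, truth = synthetic.generate_volume(
            params, seed=int(rng.integers(2**31)), eye_id=f"pool-{i:03d}")
        rec = quantify_volume(vol, seg_params)
        if rec.fc is None:
            raise RuntimeError(f"pipeline QC failure on pool volume {i}: {rec.qc}")
        truth_fc[i] = truth.a_fovea_true
        pipe_fc[i] = rec.fc
    return tertile_ordering_validation(truth_fc, pipe_fc, n_sets=n_sets)
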