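"""Quantitative foveal morphometry from boundary traces.

Three per-eye measures are derived from the ILM and RPE traces of a
128-slice volume, mirroring the automated OCT phenotyping pipeline:

* fovea centre / centre-point retinal thickness (CPRT): the (slice,
  column) centre of the thinnest-retina region of the smoothed thickness
  map, and the ILM-to-RPE distance there;
* foveal curvature (FC): the leading coefficient of an ordinary
  least-squares quadratic fitted to the ILM trace of the centre slice
  over 12 columns left and right of the centre (25 points);
* macular curvature (MC): the median over the 32 central B-scans of the
  quadratic leading coefficient fitted to each RPE trace.

Fits are performed on pixel coordinates.  Rows increase downward, so a
pit makes the ILM a row-maximum at its centre and the raw leading
coefficient negative; reported FC (and MC, same bowl orientation) is the
negated coefficient, positive for a normal pit.  The x100 reporting
scales are exactly 100x the raw coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label, uniform_filter

from .segmentation import SegmentationParams, VolumeTraces, segment_volume
from .synthetic import OCTVolume

FIT_HALFWIDTH = 12  # columns either side of the centre -> 25-point fit
CENTRAL_SLICES = range(48, 80)  # middle 32 of 128 B-scans


class QCError(ValueError):
    """A morphometry stage failed its quality-control contract."""


@dataclass
class FoveaCenter:
    slice: int
    column: int


@dataclass
class MorphometryRecord:
    """Per-eye quantitative output of the pipeline."""

    fc: float | None = None
    mc: float | None = None
    cprt_px: float | None = None
    cprt_um: float | None = None
    center: FoveaCenter | None = None
    qc: str = "ok"  # "ok" or failure reason
    eye_id: str = ""
    person_id: str = ""
    laterality: str = ""

    @property
    def fc_x100(self):
        return None if self.fc is None else 100.0 * self.fc

    @property
    def mc_x100(self):
        return None if self.mc is None else 100.0 * self.mc


def locate_fovea_center(ilm: np.ndarray, rpe: np.ndarray,
                        smooth_slices: int = 3, smooth_columns: int = 11,
                        fit_halfwidth: int = FIT_HALFWIDTH) -> FoveaCenter:
    """Centre of the thinnest-retina area of the volume.

    Builds the (slices x columns) thickness map, smooths it with an
    anisotropic moving average (slice spacing is ~12x the column spacing,
    so the window is 3 slices x 11 columns), and returns the centroid of
    the connected region of minimal smoothed thickness, rounded to the
    nearest (slice, column).  Ties across disjoint minimal regions break
    to the lowest slice, then lowest column.
    """
    ilm = np.asarray(ilm, float)
    rpe = np.asarray(rpe, float)
    if ilm.shape != rpe.shape or ilm.ndim != 2:
        raise ValueError("ilm and rpe trace arrays must share a 2-D shape")
    S, W = ilm.shape
    thick = rpe - ilm
    sm = uniform_filter(thick, size=(smooth_slices, smooth_columns), mode="nearest")
    mn = sm.min()
    minimal = sm <= mn + 1e-9
    labels, nlab = label(minimal)
    best = None
    for lab in range(1, nlab + 1):
        ss, cc = np.nonzero(labels == lab)
        cand = (float(ss.mean()), float(cc.mean()))
        if best is None or cand < best:
            best = cand
    sl = int(round(best[0]))
    co = int(round(best[1]))
    if sl in (0, S - 1):
        raise QCError(f"thickness minimum on volume border (slice {sl}); pit not captured")
    if co < fit_halfwidth or co >= W - fit_halfwidth:
        raise QCError(f"fovea centre column {co} within {fit_halfwidth} of the lateral edge")
    return FoveaCenter(slice=sl, column=co)


def compute_cprt(ilm_rows: np.ndarray, rpe_rows: np.ndarray, center: FoveaCenter,
                 axial_scale_um: float) -> tuple[float, float]:
    """Centre-point retinal thickness: RPE minus ILM row at the centre column."""
    c = center.column
    cprt_px = float(rpe_rows[c] - ilm_rows[c])
    if cprt_px <= 0:
        raise QCError(f"non-positive thickness {cprt_px} at the fovea centre")
    return cprt_px, cprt_px * axial_scale_um


def fit_foveal_curvature(ilm_rows: np.ndarray, center_column: int,
                         valid: np.ndarray | None = None,
                         halfwidth: int = FIT_HALFWIDTH) -> float:
    """Leading coefficient of the 25-point OLS quadratic around the centre.

    Sign-adjusted: rows grow downward, so the raw coefficient of a pit is
    negative; the returned FC is its negation (positive = steeper pit).
    """
    ilm_rows = np.asarray(ilm_rows, float)
    W = len(ilm_rows)
    lo, hi = center_column - halfwidth, center_column + halfwidth
    if lo < 0 or hi >= W:
        raise QCError(f"fit window [{lo}, {hi}] clipped by the image edge")
    if valid is not None and not np.all(valid[lo:hi + 1]):
        raise QCError("fit window contains invalid trace columns")
    x = np.arange(lo, hi + 1, dtype=float)
    coef = np.polyfit(x - center_column, ilm_rows[lo:hi + 1], 2)
    return -float(coef[0])


def fit_macular_curvature(rpe: np.ndarray, valid: np.ndarray | None = None,
                          central_slices=CENTRAL_SLICES,
                          min_valid_fraction: float = 0.9,
                          max_bad_slices: int = 3) -> float:
    """Median RPE quadratic leading coefficient over the central B-scans.

    Each central slice gets its own OLS quadratic over its valid columns;
    the median of the sign-adjusted coefficients is robust to a minority
    of corrupted slices.
    """
    rpe = np.asarray(rpe, float)
    S, W = rpe.shape
    coeffs = []
    bad = 0
    for s in central_slices:
        v = np.ones(W, bool) if valid is None else np.asarray(valid[s], bool)
        if v.mean() < min_valid_fraction:
            bad += 1
            continue
        x = np.flatnonzero(v).astype(float)
        coef = np.polyfit(x - x.mean(), rpe[s, v], 2)
        coeffs.append(-float(coef[0]))
    if bad > max_bad_slices:
        raise QCError(f"{bad} central slices unusable (> {max_bad_slices})")
    return float(np.median(coeffs))


def quantify_traces(traces: VolumeTraces, axial_scale_um: float,
                    eye_id: str = "", person_id: str = "",
                    laterality: str = "") -> MorphometryRecord:
    """Morphometry from already-computed volume traces."""
    rec = MorphometryRecord(eye_id=eye_id, person_id=person_id, laterality=laterality)
    try:
        center = locate_fovea_center(traces.ilm, traces.rpe)
        rec.center = center
        rec.cprt_px, rec.cprt_um = compute_cprt(
            traces.ilm[center.slice], traces.rpe[center.slice], center, axial_scale_um)
        rec.fc = fit_foveal_curvature(
            traces.ilm[center.slice], center.column, traces.valid[center.slice])
        rec.mc = fit_macular_curvature(traces.rpe, traces.valid)
    except QCError as exc:
        rec.qc = str(exc)
        return rec
    low_conf = sum(1 for q in traces.qc if q != "ok")
    if low_conf:
        rec.qc = f"ok ({low_conf} low-confidence scans)"
    return rec


def quantify_volume(volume: OCTVolume,
                    seg_params: SegmentationParams | None = None) -> MorphometryRecord:
    """Full per-eye pipeline: segment every scan, then measure FC/MC/CPRT."""
    volume.validate()
    traces = segment_volume(volume.frames, seg_params)
    return quantify_traces(traces, volume.axial_scale_um,
                           eye_id=volume.eye_id, person_id=volume.person_id,
                           laterality=volume.laterality)


# ---------------------------------------------------------------------------
# tertile-ordering validation
# ---------------------------------------------------------------------------

@dataclass
class TertileValidation:
    sets_correct: int
    n_sets: int
    tie_flagged: list = field(default_factory=list)  # set indices with tied FC


def tertile_ordering_validation(truth_fc: np.ndarray, pipeline_fc: np.ndarray,
                                n_sets: int = 10) -> TertileValidation:
    """Count image sets whose pipeline FC ordering matches the truth tertiles.

    The pool is sorted by true FC and split into three contiguous
    tertiles; set i contains the rank-matched (evenly spaced) member of
    each tertile.  A set is correct when the three pipeline FC values are
    strictly increasing with tertile rank; ties count as incorrect and
    are flagged.
    """
    truth_fc = np.asarray(truth_fc, float)
    pipeline_fc = np.asarray(pipeline_fc, float)
    if truth_fc.shape != pipeline_fc.shape:
        raise ValueError("truth and pipeline FC arrays must align")
    n = len(truth_fc)
    if n < 3 * n_sets:
        raise ValueError(f"need at least {3 * n_sets} eyes, got {n}")
    order = np.argsort(truth_fc, kind="stable")
    third = n // 3
    tert = [order[:third], order[third:2 * third], order[2 * third:3 * third]]
    if truth_fc[tert[0]].max() >= truth_fc[tert[1]].min() and \
       truth_fc[tert[0]].max() == truth_fc[tert[2]].min():
        raise ValueError("truth FC values do not separate into distinct tertiles")
    correct = 0
    ties = []
    for i in range(n_sets):
        picks = []
        for t in tert:
            k = int(round(i * (len(t) - 1) / max(n_sets - 1, 1)))
            picks.append(t[k])
        vals = pipeline_fc[picks]
        if len(np.unique(vals)) < 3:
            ties.append(i)
            continue
        if vals[0] < vals[1] < vals[2]:
            correct += 1
    return TertileValidation(sets_correct=correct, n_sets=n_sets, tie_flagged=ties)
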