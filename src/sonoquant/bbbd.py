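"""Per-session BBB-opening efficacy metrics and the detection criterion.

For each sonication session the concentration map is summarized over the
beam cylinder and its mirrored contralateral control:

* **Gd quantity** ``Q = sum_voxels C * V_voxel * M`` converted to
  micrograms, summing signed concentrations (negative noise included, so
  ``Q_roi - Q_ctrl`` stays unbiased under symmetric noise) over
  non-missing voxels.  The mass basis defaults to the gadoterate complex
  (558.6 g/mol) and is configurable.
* **Enhanced volume**: voxels above an adaptive concentration threshold,
  chosen as the smallest observed control value such that strictly fewer
  than 5% of control voxels exceed it.
* **Detection**: a session counts as a successful opening when
  ``Q_roi > Q_ctrl + 2 * SD`` where SD is the sample standard deviation
  (n-1) of the control-ROI quantities pooled across all sessions of the
  cohort — a single cohort-wide criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, ParameterError, SampleSizeError
from .gd import GD_DOTA_MOLAR_MASS, ConcentrationMap
from .volumes import RoiMask, check_mask_congruent

#: Strict-exceedance control fraction for the enhancement threshold.
TARGET_FRACTION = 0.05


@dataclass
class RoiQuantification:
    """Per-session Gd quantity and enhanced volume for beam and control."""

    session: str
    q_roi_ug: float
    q_ctrl_ug: float
    v_roi_ml: float
    v_ctrl_ml: float
    threshold_mm: float
    molar_mass: float = GD_DOTA_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.v_roi_ml < 0 or self.v_ctrl_ml < 0 or self.threshold_mm < 0:
            raise ParameterError("volumes and threshold must be non-negative")


@dataclass
class DetectionResult:
    """Outcome of the cohort-level detection criterion for one session."""

    session: str
    detected: bool
    criterion_ug: float
    sd_all_ctrl_ug: float


def gd_quantity(
    cmap: ConcentrationMap, roi: RoiMask, molar_mass: float = GD_DOTA_MOLAR_MASS
) -> float:
    """Total Gd quantity in a ROI, micrograms.

    ``Q = sum(C [mM] * 1e-3 mol/L) * V_voxel [L] * M [g/mol] * 1e6 ug/g``
    over non-missing ROI voxels, keeping the sign of each concentration.
    """
    if molar_mass <= 0:
        raise ParameterError("molar mass must be positive")
    check_mask_congruent(cmap.volume, roi)
    if roi.n_voxels == 0:
        raise EmptyRegionError(f"ROI {roi.name!r} has no voxels")
    values = cmap.data[roi.mask]
    total_mm = float(np.nansum(values))
    voxel_l = cmap.volume.voxel_volume_mm3 * 1e-6  # mm^3 -> L
    return total_mm * 1e-3 * voxel_l * molar_mass * 1e6


def adaptive_threshold(
    ctrl_values: np.ndarray, target_fraction: float = TARGET_FRACTION
) -> float:
    """Smallest observed value with strict-exceedance fraction below target.

    Returns the smallest control value ``t`` such that
    ``|{v : v > t}| / n < target_fraction`` — the nearest-rank
    upper-quantile convention, guaranteeing by construction that fewer
    than the target fraction of control voxels are classified enhanced.
    """
    values = np.asarray(ctrl_values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n < 20:
        raise SampleSizeError(f"need >= 20 control values, got {n}")
    if not (0 < target_fraction <= 1):
        raise ParameterError("target fraction must be in (0, 1]")
    values = np.sort(values)
    # strict-exceedance count of t = values[i] is n minus the right-insertion
    # index of that value; the max always has exceedance 0, so a solution exists
    exceed = n - np.searchsorted(values, values, side="right")
    ok = np.nonzero(exceed / n < target_fraction)[0]
    return float(values[ok[0]])


def enhancement_volumes(
    cmap: ConcentrationMap,
    roi: RoiMask,
    ctrl: RoiMask,
    target_fraction: float = TARGET_FRACTION,
) -> tuple[float, float, float]:
    """Enhanced volume in mL for beam and control ROIs plus the threshold.

    The threshold is adapted on the control-ROI concentrations and the
    same threshold is applied to both masks; a voxel is enhanced when its
    concentration strictly exceeds it.
    """
    check_mask_congruent(cmap.volume, roi)
    check_mask_congruent(cmap.volume, ctrl)
    ctrl_values = cmap.data[ctrl.mask]
    threshold = adaptive_threshold(ctrl_values, target_fraction)
    voxel_ml = cmap.volume.voxel_volume_mm3 * 1e-3  # mm^3 -> mL
    v_roi = float(np.nansum(cmap.data[roi.mask] > threshold)) * voxel_ml
    v_ctrl = float(np.nansum(ctrl_values > threshold)) * voxel_ml
    return v_roi, v_ctrl, float(threshold)


def quantify_session(
    cmap: ConcentrationMap,
    roi: RoiMask,
    ctrl: RoiMask,
    session: str = "",
    molar_mass: float = GD_DOTA_MOLAR_MASS,
    target_fraction: float = TARGET_FRACTION,
) -> RoiQuantification:
    """All per-session efficacy metrics in one record."""
    v_roi, v_ctrl, threshold = enhancement_volumes(cmap, roi, ctrl, target_fraction)
    return RoiQuantification(
        session=session,
        q_roi_ug=gd_quantity(cmap, roi, molar_mass),
        q_ctrl_ug=gd_quantity(cmap, ctrl, molar_mass),
        v_roi_ml=v_roi,
        v_ctrl_ml=v_ctrl,
        threshold_mm=max(threshold, 0.0),
        molar_mass=molar_mass,
    )


def detect_bbbd(
    q: RoiQuantification, all_ctrl_quantities_ug: np.ndarray
) -> DetectionResult:
    """Cohort-level detection: ``Q_roi > Q_ctrl + 2 * SD(all controls)``.

    SD is the sample standard deviation (n-1 denominator) of the control
    quantities pooled across every session supplied, so one criterion
    spread applies to the whole cohort.
    """
    ctrl = np.asarray(all_ctrl_quantities_ug, dtype=float)
    if ctrl.size < 2:
        raise SampleSizeError("need >= 2 control quantities to define the SD")
    sd = float(np.std(ctrl, ddof=1))
    criterion = q.q_ctrl_ug + 2.0 * sd
    return DetectionResult(
        session=q.session,
        detected=bool(q.q_roi_ug > criterion),
        criterion_ug=criterion,
        sd_all_ctrl_ug=sd,
    )
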