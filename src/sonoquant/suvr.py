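"""SUVR computation, longitudinal change, positivity calls and QC.

A standardized uptake value ratio is the mean PET uptake in a target
region divided by the mean in a reference region assumed unaffected by
the intervention.  Several reference schemes are supported, mirroring
common amyloid-PET practice: the mirrored opposite-hemisphere box, a
same-hemisphere distal box, the bilateral parietal cortex, the whole
cerebellum, and eroded subcortical white matter (WM label eroded by two
voxels on a 1-mm grid to avoid partial-volume contamination).

Longitudinal change between time points (months 0, 4, 8) is reported
three ways: absolute SUVR difference, percent change
``100 * (SUVR_t - SUVR_0) / SUVR_0``, and annualized percent change
(simple percent change divided by the elapsed years; a compounded
variant is available).  Amyloid positivity uses the conventional
cerebellar-reference cut-off of 1.1, applied strictly: a value exactly
at threshold is negative.

Scan-level QC flags a subject when any region distant from the implant
shows a longitudinal change beyond a plausibility bound (default 5% per
interval) — large apparent change far from the sonicated tissue signals
embedded head motion or other technical artifact rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import ndimage

from .errors import ParameterError
from .volumes import LabelVolume, RoiMask, VolumeGrid, mask_mean

#: Conventional amyloid-positivity SUVR cut-off (whole-cerebellum reference).
AMYLOID_POSITIVITY_THRESHOLD = 1.1
#: Default distal-region plausibility bound for QC, percent per interval.
QC_BOUND_PCT = 5.0
#: Months elapsed at each time point.
TIME_POINT_MONTHS = {"M0": 0.0, "M4": 4.0, "M8": 8.0}


@dataclass
class SuvrRecord:
    subject: str
    tracer: str
    time_point: str
    target: str
    reference: str
    suvr: float


@dataclass
class ChangeRecord:
    subject: str
    target: str
    reference: str
    delta: float
    pct_change: float
    apc: float  # percent per year
    interval_months: float


@dataclass
class QcVerdict:
    subject: str
    flagged: bool
    offenders: list
    bound_pct: float


def compute_suvr(
    pet: VolumeGrid,
    target: RoiMask,
    reference: RoiMask,
    subject: str = "",
    tracer: str = "amyloid",
    time_point: str = "M0",
) -> SuvrRecord:
    """SUVR = mean(target) / mean(reference)."""
    num = mask_mean(pet, target)
    den = mask_mean(pet, reference)
    if den <= 0:
        raise ParameterError(
            f"reference region {reference.name!r} has nonpositive mean ({den:g})"
        )
    return SuvrRecord(
        subject=subject,
        tracer=tracer,
        time_point=time_point,
        target=target.name,
        reference=reference.name,
        suvr=num / den,
    )


def longitudinal_change(
    s0: SuvrRecord, st: SuvrRecord, compounded: bool = False
) -> ChangeRecord:
    """Absolute, percent and annualized change between two SUVR records."""
    if (s0.subject, s0.target, s0.reference, s0.tracer) != (
        st.subject, st.target, st.reference, st.tracer
    ):
        raise ParameterError("records do not form a matched pair")
    if s0.suvr <= 0:
        raise ParameterError("baseline SUVR must be positive")
    months = TIME_POINT_MONTHS[st.time_point] - TIME_POINT_MONTHS[s0.time_point]
    if months <= 0:
        raise ParameterError("second record must be later than the first")
    years = months / 12.0
    delta = st.suvr - s0.suvr
    pct = 100.0 * delta / s0.suvr
    if compounded:
        apc = 100.0 * ((st.suvr / s0.suvr) ** (1.0 / years) - 1.0)
    else:
        apc = pct / years
    return ChangeRecord(
        subject=s0.subject,
        target=s0.target,
        reference=s0.reference,
        delta=delta,
        pct_change=pct,
        apc=apc,
        interval_months=months,
    )


def amyloid_positive(
    suvr_cerebellum_ref: float, threshold: float = AMYLOID_POSITIVITY_THRESHOLD
) -> bool:
    """Positive iff SUVR strictly exceeds the cut-off (1.1 itself is negative)."""
    if suvr_cerebellum_ref <= 0:
        raise ParameterError("SUVR must be positive")
    return suvr_cerebellum_ref > threshold


def qc_longitudinal(
    distal_changes_pct: dict[str, float], bound_pct: float = QC_BOUND_PCT
) -> QcVerdict:
    """Flag a subject when any distal region changes more than the bound.

    ``distal_changes_pct`` maps region names to observed percent changes
    in regions the sonication cannot plausibly have affected; the verdict
    lists the offending regions and their |%change|.
    """
    if not distal_changes_pct:
        raise ParameterError("at least one distal region is required")
    offenders = [
        (region, abs(pct))
        for region, pct in distal_changes_pct.items()
        if abs(pct) > bound_pct
    ]
    subject = ""
    return QcVerdict(
        subject=subject, flagged=bool(offenders), offenders=offenders, bound_pct=bound_pct
    )


def eroded_wm_mask(labels: LabelVolume, erosion_voxels: int = 2) -> RoiMask:
    """Subcortical WM reference: the WM label eroded by ``erosion_voxels``."""
    wm = labels.tissue_mask("WM")
    if erosion_voxels > 0:
        wm = ndimage.binary_erosion(wm, iterations=erosion_voxels)
    if not wm.any():
        raise ParameterError("erosion removed all WM voxels")
    return RoiMask(wm, name="eroded-WM", side="bilateral")


def reference_mask(labels: LabelVolume, scheme: str) -> RoiMask:
    """Standard reference regions by name on a label volume."""
    if scheme == "whole-cerebellum":
        return labels.mask_for(region="cerebellum", name="whole-cerebellum")
    if scheme == "bilateral-parietal":
        return labels.mask_for(region="parietal", name="bilateral-parietal")
    if scheme == "eroded-WM":
        return eroded_wm_mask(labels)
    raise ParameterError(f"unknown reference scheme {scheme!r}")
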