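"""Implant-anchored measurement geometry and in-brain pressure derating.

The ultrasound transducer sits in a skull burr hole and fires inward along
an axis approximately perpendicular to the skull.  All efficacy ROIs are
anchored to that geometry:

* a cylinder (default 15 mm diameter x 55 mm length) covering the beam,
  used for Gd-DOTA quantification, with a mirrored contralateral control;
* a rectangular implant box (default 10 x 10 x 40 mm^3) aligned to the
  axis, used for PET SUVR measurement, optionally restricted to exclude
  CSF or to gray matter only;
* comparator boxes: the mirrored opposite-hemisphere box and an
  equal-dimension distal box shifted within the same coronal slices of the
  same hemisphere.

The module also provides the simplified 1-D acoustic derating
``p(d) = p0 * 10^(-alpha * f * d / 20)`` with soft-tissue attenuation
``alpha`` in dB/cm/MHz.

The "15 x 55 mm" cylinder is read as *diameter* 15 mm x length 55 mm (the
transducer itself is 10 mm across, so 15 mm covers the spread of the
near-field beam); both dimensions are overridable.  Voxel inclusion is by
voxel-center test, without partial-volume weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyRegionError, GeometryError, ParameterError
from .volumes import LabelVolume, RoiMask, VolumeGrid, check_congruent, mirror_mask

#: Default beam-covering cylinder, mm.
BEAM_DIAMETER_MM = 15.0
BEAM_LENGTH_MM = 55.0
#: Default implant-centered PET box, mm (width, height, depth along axis).
IMPLANT_BOX_MM = (10.0, 10.0, 40.0)
#: Default in-plane shift of the same-hemisphere distal comparator, mm.
DISTAL_OFFSET_MM = 20.0
#: Soft-tissue acoustic attenuation, dB/cm/MHz.
ATTENUATION_DB_CM_MHZ = 0.6


@dataclass
class ImplantGeometry:
    """Skull entry point and inward beam axis of the implanted transducer.

    ``entry_mm`` is the world-mm position of the transducer face at the
    skull; ``axis`` the inward unit vector.  ``pressure_mpa`` is the
    nominal acoustic pressure calibrated in water (1.03 MPa after the
    first-session escalation from 0.9 MPa) and ``freq_mhz`` the operating
    frequency.
    """

    entry_mm: np.ndarray
    axis: np.ndarray
    pressure_mpa: float = 1.03
    freq_mhz: float = 1.0

    def __post_init__(self) -> None:
        self.entry_mm = np.asarray(self.entry_mm, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.entry_mm.shape != (3,) or self.axis.shape != (3,):
            raise ParameterError("entry point and axis must be 3-vectors")
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-6:
            raise ParameterError(f"axis must be a unit vector (|axis| = {norm:.8f})")
        self.axis = self.axis / norm
        if self.pressure_mpa <= 0 or self.freq_mhz <= 0:
            raise ParameterError("pressure and frequency must be positive")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors orthogonal to the axis (deterministic choice)."""
        helper = np.array([0.0, 0.0, 1.0])
        if abs(self.axis @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(self.axis, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(self.axis, e1)
        return e1, e2

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "entry_mm": self.entry_mm.tolist(),
                    "axis": self.axis.tolist(),
                    "pressure_mpa": self.pressure_mpa,
                    "freq_mhz": self.freq_mhz,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ImplantGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["entry_mm"], float),
            np.asarray(d["axis"], float),
            float(d.get("pressure_mpa", 1.03)),
            float(d.get("freq_mhz", 1.0)),
        )


@dataclass
class BeamRoiSet:
    """The full implant-anchored ROI family for one geometry."""

    beam: RoiMask
    control: RoiMask
    implant_box: RoiMask
    same_hemisphere: RoiMask
    opposite_hemisphere: RoiMask
    restriction: str = "none"
    meta: dict = field(default_factory=dict)


def _axis_coordinates(geom: ImplantGeometry, grid: VolumeGrid):
    """(s, t1, t2): along-axis and transverse world-mm coordinates of all voxels."""
    world = grid.world_coordinates().reshape(-1, 3) - geom.entry_mm
    e1, e2 = geom.basis()
    s = world @ geom.axis
    t1 = world @ e1
    t2 = world @ e2
    return s.reshape(grid.shape), t1.reshape(grid.shape), t2.reshape(grid.shape)


def cylinder_mask(
    geom: ImplantGeometry,
    grid: VolumeGrid,
    diameter_mm: float = BEAM_DIAMETER_MM,
    length_mm: float = BEAM_LENGTH_MM,
    name: str = "beam",
) -> RoiMask:
    """Cylindrical beam ROI: voxels whose center lies within ``diameter/2``
    of the axis segment ``[entry, entry + length * axis]``."""
    if diameter_mm <= 0 or length_mm <= 0:
        raise GeometryError("cylinder diameter and length must be positive")
    s, t1, t2 = _axis_coordinates(geom, grid)
    mask = (s >= 0) & (s <= length_mm) & (t1**2 + t2**2 <= (diameter_mm / 2.0) ** 2)
    if not mask.any():
        raise GeometryError("beam cylinder lies entirely outside the grid")
    side = _dominant_side(mask, grid)
    return RoiMask(mask, name=name, side=side)


def box_mask(
    geom: ImplantGeometry,
    grid: VolumeGrid,
    dims_mm: tuple[float, float, float] = IMPLANT_BOX_MM,
    offset_mm: np.ndarray | None = None,
    name: str = "implant_box",
) -> RoiMask:
    """Axis-aligned rectangular prism starting at the entry point.

    ``dims_mm = (w, h, depth)``: transverse half-widths w/2 and h/2 along
    the two axis-orthogonal basis vectors, depth along the beam axis.
    ``offset_mm`` translates the box in world space (used for the distal
    comparator).
    """
    w, h, depth = dims_mm
    if min(dims_mm) <= 0:
        raise GeometryError("box dimensions must be positive")
    g = geom
    if offset_mm is not None:
        g = ImplantGeometry(geom.entry_mm + np.asarray(offset_mm, float), geom.axis,
                            geom.pressure_mpa, geom.freq_mhz)
    s, t1, t2 = _axis_coordinates(g, grid)
    mask = (s >= 0) & (s <= depth) & (np.abs(t1) <= w / 2.0) & (np.abs(t2) <= h / 2.0)
    if not mask.any():
        raise GeometryError("implant box lies entirely outside the grid")
    return RoiMask(mask, name=name, side=_dominant_side(mask, grid))


def restrict_mask(
    mask: RoiMask, labels: LabelVolume, restrict: str, name: str | None = None
) -> RoiMask:
    """Apply a tissue restriction: ``none``, ``exclude-CSF`` or ``GM-only``."""
    if restrict == "none":
        out = mask.mask.copy()
    elif restrict == "exclude-CSF":
        out = mask.mask & ~labels.tissue_mask("CSF")
    elif restrict == "GM-only":
        out = mask.mask & labels.tissue_mask("GM")
    else:
        raise ParameterError(f"unknown restriction {restrict!r}")
    if not out.any():
        raise EmptyRegionError(
            f"restriction {restrict!r} empties ROI {mask.name!r}"
        )
    return RoiMask(out, name=name or f"{mask.name}[{restrict}]", side=mask.side)


def implant_box_mask(
    geom: ImplantGeometry,
    grid: VolumeGrid,
    labels: LabelVolume | None = None,
    dims_mm: tuple[float, float, float] = IMPLANT_BOX_MM,
    restrict: str = "none",
) -> RoiMask:
    """Implant-centered PET measurement box with optional tissue restriction."""
    if labels is not None:
        check_congruent(grid, labels.labels)
    box = box_mask(geom, grid, dims_mm=dims_mm)
    if restrict == "none":
        return box
    if labels is None:
        raise ParameterError("a label volume is required for tissue restriction")
    return RoiMask(
        restrict_mask(box, labels, restrict).mask, name=box.name, side=box.side
    )


def comparator_masks(
    geom: ImplantGeometry,
    grid: VolumeGrid,
    labels: LabelVolume,
    dims_mm: tuple[float, float, float] = IMPLANT_BOX_MM,
    restrict: str = "none",
    distal_offset_mm: float = DISTAL_OFFSET_MM,
    distal_direction: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    cylinder_diameter_mm: float = BEAM_DIAMETER_MM,
    cylinder_length_mm: float = BEAM_LENGTH_MM,
    plane_x: float | None = None,
) -> BeamRoiSet:
    """Build the full implant-anchored ROI family.

    The opposite-hemisphere ROI is the mid-sagittal mirror of the
    geometric implant box with the identical tissue restriction applied on
    its own side.  The same-hemisphere distal ROI is an equal-dimension
    box translated ``distal_offset_mm`` within the coronal plane (constant
    anterior-posterior coordinate, default direction inferior) so it
    samples the same coronal slices of the same hemisphere.  The mirrored
    control cylinder carries the same tissue restriction as the beam
    cylinder (none by default).
    """
    check_congruent(grid, labels.labels)
    beam = cylinder_mask(geom, grid, cylinder_diameter_mm, cylinder_length_mm)
    control = mirror_mask(beam, grid, plane_x=plane_x)
    control.name = "control"

    box_geo = box_mask(geom, grid, dims_mm=dims_mm)  # geometric, unrestricted
    box = restrict_mask(box_geo, labels, restrict, name="implant_box")

    opp_geo = mirror_mask(box_geo, grid, plane_x=plane_x)
    opposite = restrict_mask(opp_geo, labels, restrict, name="opposite_hemisphere")

    if distal_direction is None:
        # stay within the same coronal slices: shift has no y (A-P) component
        distal_direction = np.array([0.0, 0.0, -1.0])
    distal_direction = np.asarray(distal_direction, float)
    if abs(distal_direction[1]) > 1e-9:
        raise ParameterError("distal shift must lie within the coronal plane (y = const)")
    distal_direction = distal_direction / np.linalg.norm(distal_direction)
    if distal_offset_mm < max(dims_mm[0], dims_mm[1]):
        raise ParameterError(
            "distal offset smaller than the box cross-section would overlap the implant box"
        )
    distal_geo = box_mask(
        geom, grid, dims_mm=dims_mm,
        offset_mm=distal_offset_mm * distal_direction, name="same_hemisphere",
    )
    if brain_mask is not None and not bool(brain_mask[distal_geo.mask].all()):
        n_out = int((~brain_mask[distal_geo.mask]).sum())
        raise GeometryError(
            f"distal comparator box leaves the brain mask ({n_out} voxel(s) outside)"
        )
    distal = restrict_mask(distal_geo, labels, restrict, name="same_hemisphere")

    if (box.mask & opposite.mask).any() or (box.mask & distal.mask).any() or (
        opposite.mask & distal.mask
    ).any():
        raise GeometryError("comparator ROIs overlap; adjust offsets or geometry")
    if (beam.mask & control.mask).any():
        raise GeometryError("beam and mirrored control cylinders overlap the midline")

    return BeamRoiSet(
        beam=beam,
        control=control,
        implant_box=box,
        same_hemisphere=distal,
        opposite_hemisphere=opposite,
        restriction=restrict,
        meta={
            "dims_mm": tuple(dims_mm),
            "distal_offset_mm": distal_offset_mm,
            "cylinder_mm": (cylinder_diameter_mm, cylinder_length_mm),
        },
    )


def derate_pressure(
    geom: ImplantGeometry,
    depth_cm: float | np.ndarray,
    attenuation_db_cm_mhz: float = ATTENUATION_DB_CM_MHZ,
) -> float | np.ndarray:
    """In-brain acoustic pressure at tissue depth ``depth_cm``.

    ``p(d) = p0 * 10^(-alpha * f * d / 20)`` with ``alpha`` in dB/cm/MHz
    and ``f`` in MHz; amplitude attenuation, hence the factor 20.
    """
    d = np.asarray(depth_cm, dtype=float)
    if np.any(d < 0):
        raise ParameterError("depth must be non-negative")
    if attenuation_db_cm_mhz < 0:
        raise ParameterError("attenuation must be non-negative")
    p = geom.pressure_mpa * 10.0 ** (-attenuation_db_cm_mhz * geom.freq_mhz * d / 20.0)
    return float(p) if np.isscalar(depth_cm) else p


def _dominant_side(mask: np.ndarray, grid: VolumeGrid) -> str:
    """left/right/bilateral by the world-x sign of the mask centroid."""
    from .volumes import mid_sagittal_x

    idx = np.argwhere(mask)
    world_x = (idx @ grid.affine[:3, :3].T + grid.affine[:3, 3])[:, 0]
    mid = mid_sagittal_x(grid)
    frac_left = float((world_x < mid).mean())
    if frac_left > 0.95:
        return "left"
    if frac_left < 0.05:
        return "right"
    return "bilateral"


def write_roi_set(rois: BeamRoiSet, grid: VolumeGrid,
                  nifti_path: str | Path, legend_path: str | Path) -> None:
    """Write the ROI family as one integer-coded NIfTI + JSON legend."""
    from .volumes import write_volume

    coded = np.zeros(grid.shape, np.int16)
    legend: dict[str, str] = {}
    for code, roi in enumerate(
        [rois.beam, rois.control, rois.implant_box, rois.same_hemisphere,
         rois.opposite_hemisphere], start=1
    ):
        coded[roi.mask & (coded == 0)] = code
        legend[str(code)] = roi.name
    write_volume(grid.like(coded), nifti_path)
    with open(legend_path, "w") as fh:
        json.dump(legend, fh, indent=1)
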