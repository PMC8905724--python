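"""Voxel-grid data model, NIfTI I/O, masks, mirroring and ROI arithmetic.

Everything downstream (concentration maps, beam ROIs, SUVRs, pattern
analysis) operates on co-registered 3-D volumes.  This module provides the
shared carrier type :class:`VolumeGrid`, boolean regions of interest
(:class:`RoiMask`), integer-coded anatomical label volumes
(:class:`LabelVolume`) and the small set of grid operations — congruence
checking, ROI means, mid-sagittal mirroring — that the measurement modules
build on.

Conventions
-----------
Voxel indices are 0-based; world coordinates are millimetres under the
NIfTI RAS+ affine (``+x`` right, ``+y`` anterior, ``+z`` superior).  Two
volumes are *congruent* when their shapes are identical and their affines
agree to 1e-4 mm; every multi-volume computation checks this rather than
assuming it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import CongruenceError, EmptyRegionError, FormatError, GeometryError

#: Affines closer than this (element-wise, mm) are treated as identical.
AFFINE_ATOL = 1e-4

_FLIP_SIDE = {"left": "right", "right": "left", "bilateral": "bilateral"}


@dataclass
class VolumeGrid:
    """A 3-D scalar field on a regular voxel grid.

    Parameters
    ----------
    data:
        3-D array.  Value semantics depend on use: seconds for T1 maps,
        mM for concentration maps, activity-normalized units for PET,
        integer codes for label volumes.
    affine:
        4x4 voxel-index -> world-mm map (RAS+).
    frame:
        Free-form identifier tying co-registered volumes together.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise FormatError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.indices(self.shape).reshape(3, -1)
        world = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
        return world.T.reshape(*self.shape, 3)

    def like(self, data: np.ndarray, frame: str | None = None) -> "VolumeGrid":
        """A new volume on this grid carrying different data."""
        return VolumeGrid(data, self.affine.copy(), self.frame if frame is None else frame)


@dataclass
class RoiMask:
    """A boolean region of interest congruent with some :class:`VolumeGrid`."""

    mask: np.ndarray
    name: str = ""
    side: str = "bilateral"  # left | right | bilateral

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise FormatError("ROI mask must be 3-D")
        if self.side not in _FLIP_SIDE:
            raise FormatError(f"unknown side {self.side!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabelVolume:
    """Integer-coded anatomical labels with a code legend.

    ``legend`` maps each nonzero code to ``{"tissue": GM|WM|CSF|background,
    "region": name, "hemisphere": left|right|bilateral}``.
    """

    labels: VolumeGrid
    legend: dict[int, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = set(np.unique(self.labels.data).tolist()) - {0}
        missing = codes - set(self.legend)
        if missing:
            raise FormatError(f"label codes without legend entry: {sorted(missing)}")

    def mask_for(
        self,
        *,
        tissue: str | None = None,
        region: str | None = None,
        hemisphere: str | None = None,
        name: str = "",
    ) -> RoiMask:
        """Boolean mask of all voxels whose legend entry matches the filters."""
        codes = [
            c
            for c, entry in self.legend.items()
            if (tissue is None or entry["tissue"] == tissue)
            and (region is None or entry["region"] == region)
            and (hemisphere is None or entry["hemisphere"] == hemisphere)
        ]
        mask = np.isin(self.labels.data, codes)
        sides = {self.legend[c]["hemisphere"] for c in codes}
        side = sides.pop() if len(sides) == 1 else "bilateral"
        return RoiMask(mask, name=name or (region or tissue or "selection"), side=side)

    def tissue_mask(self, tissue: str) -> np.ndarray:
        codes = [c for c, e in self.legend.items() if e["tissue"] == tissue]
        return np.isin(self.labels.data, codes)


def check_congruent(*grids: VolumeGrid, atol: float = AFFINE_ATOL) -> None:
    """Raise :class:`CongruenceError` unless all grids share shape and affine."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise CongruenceError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if not np.allclose(g.affine, ref.affine, atol=atol, rtol=0):
            raise CongruenceError("affine mismatch beyond %.0e mm" % atol)


def check_mask_congruent(vol: VolumeGrid, roi: RoiMask) -> None:
    if roi.mask.shape != vol.shape:
        raise CongruenceError(
            f"mask shape {roi.mask.shape} does not match volume shape {vol.shape}"
        )


def read_volume(path: str | Path, frame: str = "") -> VolumeGrid:
    """Load a NIfTI-1 volume.

    4-D files with a single frame are squeezed to 3-D; genuinely 4-D input
    is rejected because all pipeline volumes are static 3-D maps.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] == 1:
            data = data[..., 0]
        else:
            raise FormatError(
                f"{path} is 4-D with {data.shape[3]} frames along axis 3; expected a 3-D volume"
            )
    elif data.ndim != 3:
        raise FormatError(f"{path} has ndim={data.ndim}; expected 3")
    return VolumeGrid(data, img.affine, frame=frame or path.name)


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1, preserving dtype (bit-exact for float32)."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))


def read_labels(nifti_path: str | Path, legend_path: str | Path) -> LabelVolume:
    """Load an integer label volume plus its JSON legend sidecar."""
    vol = read_volume(nifti_path)
    with open(legend_path) as fh:
        raw = json.load(fh)
    legend = {int(code): entry for code, entry in raw.items()}
    return LabelVolume(vol.like(np.rint(vol.data).astype(np.int32)), legend)


def write_labels(labels: LabelVolume, nifti_path: str | Path, legend_path: str | Path) -> None:
    write_volume(labels.labels.like(labels.labels.data.astype(np.int16)), nifti_path)
    with open(legend_path, "w") as fh:
        json.dump({str(c): e for c, e in labels.legend.items()}, fh, indent=1)


def mask_mean(vol: VolumeGrid, roi: RoiMask) -> float:
    """Arithmetic mean of ``vol`` over the true voxels of ``roi``.

    Missing voxels (NaN) inside the region are excluded from the mean; a
    region that is empty (or all-missing) raises :class:`EmptyRegionError`.
    """
    check_mask_congruent(vol, roi)
    if roi.n_voxels == 0:
        raise EmptyRegionError(f"ROI {roi.name!r} has no voxels")
    values = vol.data[roi.mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyRegionError(f"ROI {roi.name!r} contains only missing voxels")
    return float(values.mean())


def mid_sagittal_x(grid: VolumeGrid) -> float:
    """World x of the grid center, the default mid-sagittal mirror plane."""
    center_idx = (np.asarray(grid.shape, dtype=float) - 1.0) / 2.0
    return float((grid.affine[:3, :3] @ center_idx + grid.affine[:3, 3])[0])


def mirror_mask(roi: RoiMask, grid: VolumeGrid, plane_x: float | None = None) -> RoiMask:
    """Reflect a mask across the mid-sagittal world plane ``x = plane_x``.

    Each true voxel center is reflected exactly in world space and then
    rasterized to the nearest grid voxel (no interpolation of booleans).
    Reflections landing outside the grid raise :class:`GeometryError`
    reporting how many voxels would be clipped.
    """
    check_mask_congruent(grid, roi)
    if plane_x is None:
        plane_x = mid_sagittal_x(grid)
    idx = np.argwhere(roi.mask)
    if idx.size == 0:
        return RoiMask(np.zeros(grid.shape, bool), name=roi.name + "_mirror",
                       side=_FLIP_SIDE[roi.side])
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    world[:, 0] = 2.0 * plane_x - world[:, 0]
    inv = np.linalg.inv(grid.affine)
    back = world @ inv[:3, :3].T + inv[:3, 3]
    back = np.rint(back).astype(int)
    inside = np.all((back >= 0) & (back < np.asarray(grid.shape)), axis=1)
    n_clipped = int((~inside).sum())
    if n_clipped:
        raise GeometryError(
            f"mirroring {roi.name!r} across x={plane_x:g} clips {n_clipped} voxel(s) "
            "outside the grid"
        )
    out = np.zeros(grid.shape, bool)
    out[tuple(back.T)] = True
    return RoiMask(out, name=roi.name + "_mirror", side=_FLIP_SIDE[roi.side])
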