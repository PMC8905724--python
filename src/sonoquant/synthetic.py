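"""Synthetic head phantoms, PET series, cohorts and pattern datasets.

Every input the analysis chain consumes can be generated here with known
ground truth, so the whole pipeline — concentration mapping, beam-ROI
quantification, SUVR change, matching, pattern analysis — is exercised by
parameter-recovery tests rather than by eyeballing real scans.

The head phantom is deliberately minimal: an ellipsoidal brain with a
2-mm outer CSF shell, a 4-mm cortical gray-matter shell, white matter in
the interior, a cerebellar compartment in the inferior-posterior brain,
and a parietal subdivision of the cortex — the simplest geometry that
exercises CSF exclusion, gray-matter restriction, hemispheric mirroring
and the standard SUVR reference regions.  Tissue T1 values default to
3-T literature values (GM 1.4 s, WM 0.9 s, CSF 4.0 s).  Contrast
enhancement is planted by inverting the relaxometry model: inside the
enhancement region ``1/T1_post = 1/T1_pre + r1 * C_true`` before noise,
so the concentration-mapping module must recover ``C_true`` exactly at
zero noise.  Measurement noise is additive Gaussian on T1 (the measured
quantity), truncated at 0.05 s to keep relaxation rates physical.

All randomness flows from one integer seed through a named
:class:`numpy.random.Generator` per artifact, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .cva import ScanMatrix
from .errors import GeometryError, ParameterError
from .gd import GD_DOTA_RELAXIVITY
from .geometry import ImplantGeometry
from .volumes import LabelVolume, RoiMask, VolumeGrid

#: Default tissue T1 means at 3 T, seconds.
T1_MEANS_S = {"GM": 1.4, "WM": 0.9, "CSF": 4.0}

#: Label codes of the phantom legend.
PHANTOM_LEGEND = {
    1: {"tissue": "CSF", "region": "csf", "hemisphere": "left"},
    2: {"tissue": "CSF", "region": "csf", "hemisphere": "right"},
    3: {"tissue": "GM", "region": "parietal", "hemisphere": "left"},
    4: {"tissue": "GM", "region": "parietal", "hemisphere": "right"},
    5: {"tissue": "GM", "region": "cortex", "hemisphere": "left"},
    6: {"tissue": "GM", "region": "cortex", "hemisphere": "right"},
    7: {"tissue": "WM", "region": "white-matter", "hemisphere": "left"},
    8: {"tissue": "WM", "region": "white-matter", "hemisphere": "right"},
    9: {"tissue": "GM", "region": "cerebellum", "hemisphere": "bilateral"},
}


def _rng(seed: int, name: str) -> np.random.Generator:
    """A named child generator: one root seed, one stream per artifact."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class EnhancementSpec:
    """The planted Gd enhancement: a sub-region of the beam.

    ``shape`` is ``cylinder`` (diameter x length along the beam axis;
    default 10 x 10.3 mm, a 0.81-mL volume matching a typical successful
    opening) or ``box`` (w x h x length in the axis frame, convenient
    when an exact voxel count is wanted).  ``offset_mm`` positions the
    region's start along the axis from the skull entry point.
    """

    c_true_mm: float = 0.2
    shape: str = "cylinder"
    diameter_mm: float = 10.0
    length_mm: float = 10.3
    width_mm: float = 10.0
    height_mm: float = 10.0
    offset_mm: float = 18.0


@dataclass
class PhantomSpec:
    """Parameters of one head phantom.

    The grid is sized to hold an adult-scale brain (semi-axes 65 x 80 x
    55 mm): the full 55-mm beam cylinder must stay within one hemisphere
    so that the mirrored contralateral control is disjoint from it, which
    a smaller head cannot accommodate.
    """

    shape: tuple[int, int, int] = (144, 176, 128)
    spacing_mm: float = 1.0
    semi_axes_mm: tuple[float, float, float] = (65.0, 80.0, 55.0)
    t1_means_s: dict = field(default_factory=lambda: dict(T1_MEANS_S))
    t1_noise_sd_s: float = 0.02
    r1: float = GD_DOTA_RELAXIVITY
    geometry: ImplantGeometry | None = None
    enhancement: EnhancementSpec = field(default_factory=EnhancementSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.t1_means_s.values()):
            raise ParameterError("tissue T1 means must be positive")
        if self.t1_noise_sd_s < 0:
            raise ParameterError("T1 noise sd must be non-negative")
        if self.enhancement.c_true_mm < 0:
            raise ParameterError("planted concentration must be non-negative")


@dataclass
class Phantom:
    """One generated phantom with its ground truth."""

    pre: VolumeGrid
    post: VolumeGrid
    labels: LabelVolume
    geometry: ImplantGeometry
    enhancement_mask: RoiMask
    brain_mask: np.ndarray
    truth: dict


def default_geometry(spec: PhantomSpec) -> ImplantGeometry:
    """Implant at the left parietotemporal surface, axis inward.

    The entry point is where the ray from the brain center along a fixed
    left-lateral, slightly posterior-superior direction pierces the
    ellipsoid surface; the beam axis points back toward the center, i.e.
    approximately perpendicular to the skull.
    """
    u = np.array([-1.0, -0.25, 0.35])
    u /= np.linalg.norm(u)
    a = np.asarray(spec.semi_axes_mm, float)
    t = 1.0 / np.sqrt(np.sum((u / a) ** 2))
    entry = t * u
    return ImplantGeometry(entry_mm=entry, axis=-u)


def _phantom_grid(spec: PhantomSpec) -> VolumeGrid:
    shape = np.asarray(spec.shape, int)
    affine = np.eye(4)
    affine[:3, :3] *= spec.spacing_mm
    affine[:3, 3] = -spec.spacing_mm * (shape - 1) / 2.0  # world origin at center
    return VolumeGrid(np.zeros(tuple(shape)), affine, frame="phantom")


def make_labels(spec: PhantomSpec) -> tuple[LabelVolume, np.ndarray]:
    """Ellipsoid brain with CSF/GM/WM shells, cerebellum and parietal regions."""
    grid = _phantom_grid(spec)
    world = grid.world_coordinates()
    a = np.asarray(spec.semi_axes_mm, float)
    brain = np.sum((world / a) ** 2, axis=-1) <= 1.0
    depth = ndimage.distance_transform_edt(brain, sampling=[spec.spacing_mm] * 3)
    csf = brain & (depth <= 2.0)
    gm = brain & (depth > 2.0) & (depth <= 6.0)
    wm = brain & (depth > 6.0)

    x, y, z = world[..., 0], world[..., 1], world[..., 2]
    left = x < 0
    codes = np.zeros(grid.shape, np.int16)
    codes[csf & left] = 1
    codes[csf & ~left] = 2
    parietal = gm & (z > 0.45 * a[2])
    codes[parietal & left] = 3
    codes[parietal & ~left] = 4
    codes[gm & ~parietal & left] = 5
    codes[gm & ~parietal & ~left] = 6
    codes[wm & left] = 7
    codes[wm & ~left] = 8
    cerebellum = brain & ~csf & (z < -0.55 * a[2]) & (y < -0.3 * a[1])
    codes[cerebellum] = 9
    labels = LabelVolume(grid.like(codes, frame="labels"), dict(PHANTOM_LEGEND))
    return labels, brain


def enhancement_mask(
    spec: PhantomSpec, geometry: ImplantGeometry, grid: VolumeGrid, brain: np.ndarray
) -> RoiMask:
    """Rasterize the planted enhancement region; must lie inside the brain."""
    enh = spec.enhancement
    world = grid.world_coordinates().reshape(-1, 3) - geometry.entry_mm
    e1, e2 = geometry.basis()
    s = (world @ geometry.axis).reshape(grid.shape) - enh.offset_mm
    t1 = (world @ e1).reshape(grid.shape)
    t2 = (world @ e2).reshape(grid.shape)
    if enh.shape == "cylinder":
        mask = (s >= 0) & (s < enh.length_mm) & (
            t1**2 + t2**2 <= (enh.diameter_mm / 2.0) ** 2
        )
    elif enh.shape == "box":
        mask = (
            (s >= 0)
            & (s < enh.length_mm)
            & (np.abs(t1) < enh.width_mm / 2.0)
            & (np.abs(t2) < enh.height_mm / 2.0)
        )
    else:
        raise ParameterError(f"unknown enhancement shape {enh.shape!r}")
    if not mask.any():
        raise GeometryError("enhancement region contains no voxels")
    if not brain[mask].all():
        n_out = int((~brain[mask]).sum())
        raise GeometryError(
            f"enhancement region leaves the brain mask ({n_out} voxel(s) outside)"
        )
    return RoiMask(mask, name="enhancement", side="left")


class PhantomFactory:
    """Builds the deterministic anatomy of a phantom once, samples noise per seed.

    The labels, geometry, enhancement mask and noise-free T1 maps depend
    only on the spec, not on the seed, so simulations that sweep seeds
    (detection operating characteristics, quantity-recovery replicates)
    construct the factory once and call :meth:`sample` per seed.
    ``PhantomFactory(spec).sample(spec.seed)`` is exactly
    ``make_phantom(spec)``.
    """

    def __init__(self, spec: PhantomSpec | None = None) -> None:
        self.spec = spec or PhantomSpec()
        self.labels, self.brain = make_labels(self.spec)
        grid = self.labels.labels
        self.geometry = self.spec.geometry or default_geometry(self.spec)
        self.enh_mask = enhancement_mask(self.spec, self.geometry, grid, self.brain)

        t1 = np.full(grid.shape, self.spec.t1_means_s["CSF"])
        t1[~self.brain] = np.nan
        for tissue in ("CSF", "GM", "WM"):
            t1[self.labels.tissue_mask(tissue)] = self.spec.t1_means_s[tissue]
        t1_post = t1.copy()
        c = self.spec.enhancement.c_true_mm
        if c > 0:
            m = self.enh_mask.mask
            t1_post[m] = 1.0 / (1.0 / t1[m] + self.spec.r1 * c)
        self._t1_pre_clean = t1
        self._t1_post_clean = t1_post

    def sample(self, seed: int) -> Phantom:
        spec = self.spec
        grid = self.labels.labels
        t1, t1_post = self._t1_pre_clean, self._t1_post_clean
        if spec.t1_noise_sd_s > 0:
            rng_pre = _rng(seed, "phantom-pre")
            rng_post = _rng(seed, "phantom-post")
            t1 = t1 + rng_pre.normal(0.0, spec.t1_noise_sd_s, grid.shape)
            t1_post = t1_post + rng_post.normal(0.0, spec.t1_noise_sd_s, grid.shape)
            t1 = np.clip(t1, 0.05, None)
            t1_post = np.clip(t1_post, 0.05, None)
        truth = {
            "c_true_mm": spec.enhancement.c_true_mm,
            "enhancement_voxels": self.enh_mask.n_voxels,
            "enhancement_volume_mm3": self.enh_mask.n_voxels * grid.voxel_volume_mm3,
            "r1": spec.r1,
            "t1_noise_sd_s": spec.t1_noise_sd_s,
            "seed": seed,
        }
        return Phantom(
            pre=grid.like(np.array(t1), frame="t1_pre"),
            post=grid.like(np.array(t1_post), frame="t1_post"),
            labels=self.labels,
            geometry=self.geometry,
            enhancement_mask=self.enh_mask,
            brain_mask=self.brain,
            truth=truth,
        )


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate pre/post-contrast T1 maps with a planted enhancement.

    Inside the enhancement region, before noise,
    ``1/T1_post = 1/T1_pre + r1 * C_true``; outside, post equals pre.
    Gaussian T1 noise (sd ``t1_noise_sd_s``) is then added independently
    to both maps and truncated at 0.05 s.  Identical seeds give
    bit-identical volumes.
    """
    spec = spec or PhantomSpec()
    return PhantomFactory(spec).sample(spec.seed)


@dataclass
class PetSeriesSpec:
    """Planted longitudinal PET series on a label volume.

    ``baseline_means`` maps region names (legend ``region`` values, or
    ``region:hemisphere``) to baseline uptake; ``change_factors`` maps
    region names to per-time-point multiplicative factors, e.g.
    ``{"parietal:left": {"M4": 0.934}}``; factors default to 1.  Focal
    regions (arbitrary masks, e.g. the implant box) multiply whatever
    value the label regions assigned.
    """

    baseline_means: dict
    change_factors: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    tracer: str = "amyloid"
    seed: int = 0
    focal_factors: list = field(default_factory=list)  # (RoiMask, {tp: factor})

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.baseline_means.values()):
            raise ParameterError("baseline means must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be non-negative")
        if self.tracer not in ("amyloid", "FDG"):
            raise ParameterError(f"unknown tracer {self.tracer!r}")


TIME_POINTS = ("M0", "M4", "M8")


def _region_mask(labels: LabelVolume, key: str) -> np.ndarray:
    if ":" in key:
        region, hemi = key.split(":", 1)
        m = labels.mask_for(region=region, hemisphere=hemi).mask
    else:
        m = labels.mask_for(region=key).mask
    return m


def make_pet_series(
    spec: PetSeriesSpec, labels: LabelVolume
) -> tuple[dict[str, VolumeGrid], dict]:
    """Generate M0/M4/M8 PET volumes with planted regional changes.

    Voxel values are regional mean x change factor plus Gaussian noise;
    all factors are 1 at M0.  Unknown region names raise ``KeyError``.
    """
    grid = labels.labels
    known = {e["region"] for e in labels.legend.values()}
    for key in list(spec.baseline_means) + list(spec.change_factors):
        region = key.split(":", 1)[0]
        if region not in known:
            raise KeyError(f"region {region!r} not present in the label legend")

    volumes: dict[str, VolumeGrid] = {}
    for tp in TIME_POINTS:
        data = np.zeros(grid.shape)
        for key, mean in spec.baseline_means.items():
            data[_region_mask(labels, key)] = mean
        if tp != "M0":
            # change keys may be finer-grained than baseline keys
            # (e.g. baseline "parietal", change "parietal:left")
            for key, factors in spec.change_factors.items():
                data[_region_mask(labels, key)] *= factors.get(tp, 1.0)
        for mask, factors in spec.focal_factors:
            factor = 1.0 if tp == "M0" else factors.get(tp, 1.0)
            data[mask.mask] *= factor
        if spec.noise_sd > 0:
            rng = _rng(spec.seed, f"pet-{spec.tracer}-{tp}")
            data = data + rng.normal(0.0, spec.noise_sd, grid.shape)
        volumes[tp] = grid.like(data, frame=f"{spec.tracer}-{tp}")
    truth = {
        "tracer": spec.tracer,
        "baseline_means": dict(spec.baseline_means),
        "change_factors": {k: dict(v) for k, v in spec.change_factors.items()},
        "focal_factors": [
            (mask.name, dict(factors)) for mask, factors in spec.focal_factors
        ],
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return volumes, truth


def make_cohort_table(n: int, seed: int = 0) -> pd.DataFrame:
    """A synthetic candidate-pool demographics table.

    Ages ~ Uniform[55, 85] rounded to 0.1 year, MMSE uniform on 18..30,
    genders balanced, diagnosis MCI/AD at random — the strata the
    matching procedure needs, nothing more.
    """
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    rng = _rng(seed, "cohort")
    ages = np.round(rng.uniform(55.0, 85.0, n), 1)
    mmse = rng.integers(18, 31, n)
    gender = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    rng.shuffle(gender)
    diagnosis = rng.choice(["MCI", "AD"], n)
    return pd.DataFrame(
        {
            "id": [f"C{i:04d}" for i in range(1, n + 1)],
            "age": ages,
            "gender": gender,
            "mmse": mmse,
            "diagnosis": diagnosis,
        }
    )


def make_pattern_dataset(
    n_per_class: int,
    n_voxels: int,
    effect_size: float,
    n_classes: int = 3,
    seed: int = 0,
    baseline: float = 100.0,
) -> tuple[ScanMatrix, dict]:
    """Longitudinal scan set with a planted discriminative spatial pattern.

    ``n_per_class`` subjects each contribute one scan per class; class k's
    mean sits at ``(k - (K-1)/2) * effect_size`` along a random unit-norm
    voxel pattern, on top of a positive baseline, with isotropic unit
    Gaussian noise.  ``effect_size`` is therefore the between-adjacent-
    class separation in noise-SD units along the pattern.
    """
    if n_classes < 2:
        raise ParameterError("need at least 2 classes")
    if n_per_class < 4:
        raise ParameterError("need at least 4 subjects per class")
    if effect_size < 0:
        raise ParameterError("effect size must be non-negative")
    rng = _rng(seed, "pattern")
    pattern = rng.normal(size=n_voxels)
    pattern /= np.linalg.norm(pattern)
    offsets = (np.arange(n_classes) - (n_classes - 1) / 2.0) * effect_size
    rows, subjects, classes = [], [], []
    for s in range(n_per_class):
        for k in range(n_classes):
            rows.append(baseline + offsets[k] * pattern + rng.normal(size=n_voxels))
            subjects.append(f"S{s:03d}")
            classes.append(f"M{4 * k}")
    scans = ScanMatrix(np.stack(rows), np.array(subjects), np.array(classes))
    truth = {
        "pattern": pattern,
        "offsets": offsets,
        "effect_size": effect_size,
        "baseline": baseline,
        "seed": seed,
    }
    return scans, truth


def null_phantom_spec(seed: int, noise_sd: float = 0.02) -> PhantomSpec:
    """A phantom with no planted enhancement (detection null condition)."""
    return PhantomSpec(
        enhancement=EnhancementSpec(c_true_mm=0.0), t1_noise_sd_s=noise_sd, seed=seed
    )


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return replace(spec, seed=seed)
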