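"""Synthetic multi-parametric MRI cohort generator with planted imaging subtypes.

Real glioblastoma mpMRI cohorts are rarely shareable, so the generator builds
co-registered multi-channel volumes in a common (synthetic) atlas space with
three planted archetypes — *rim-enhancing*, *irregular* and *solid* — whose
imaging contrasts, survival, spatial preference and molecular composition
mirror the qualitative structure the downstream pipeline is designed to
recover:

* edema size ordered irregular > rim-enhancing > solid;
* boundary irregularity ordered irregular > solid > rim-enhancing;
* diffusion trace (TR, inverse proxy of cellularity) in the tumor core ordered
  rim-enhancing > irregular > solid;
* perfusion (rCBV) ordered solid > irregular > rim-enhancing;
* median overall survival 19 / 12 / 6 months;
* EGFRvIII prevalence 12.5% / 39.02% / 30.61%.

Each subject is an :class:`ImagingStudy`: 11 channel volumes (T1, T1CE, T2,
FLAIR, AX, FA, RAD, TR, rCBV, PH, PSR), a segmentation of enhancing tumor
(TU), non-enhancing core (NC) and edema (ED), and a clinical record.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

CHANNELS: tuple[str, ...] = (
    "T1", "T1CE", "T2", "FLAIR", "AX", "FA", "RAD", "TR", "rCBV", "PH", "PSR",
)
REGIONS: tuple[str, ...] = ("TU", "NC", "ED")

#: segmentation label convention (BraTS-style, configurable at IO level)
SEG_LABELS: dict[str, int] = {"NC": 1, "ED": 2, "TU": 4}

ATLAS_REGIONS: tuple[str, ...] = (
    "frontal", "temporal", "parietal", "basal_ganglia", "insula",
    "cc_fornix", "occipital", "cerebellum", "brain_stem",
)

MOLECULAR_SUBTYPES: tuple[str, ...] = ("classical", "mesenchymal", "proneural", "neural")


@dataclass
class SubtypeArchetype:
    """Generator parameters for one planted imaging subtype."""

    name: str
    #: per (region, channel): (mean, sd) of the Gaussian intensity law (arbitrary units)
    region_intensity_params: dict[tuple[str, str], tuple[float, float]]
    edema_scale: float          # ED volume / core volume, > 0
    irregularity: float         # boundary perturbation amplitude, voxels, >= 0
    survival_median: float      # months
    censoring_fraction: float   # probability of administrative censoring
    egfrviii_prevalence: float
    molecular_mixture: dict[str, float]
    spatial_center: str         # atlas region the tumors are preferentially seeded in
    idh1_mutant_prob: float
    #: placement is a predilection, not a rule: probability over seed regions
    #: (defaults to 60% spatial_center, 20/20% the other two lobar regions)
    spatial_mixture: dict[str, float] | None = None
    mgmt_methylated_prob: float = 0.45
    core_radius: float = 5.0    # mean core semi-axis, voxels
    #: SD of per-subject residual offsets of the region/channel means
    #: (inter-patient variability on top of the shared latent factors)
    between_subject_sd: float = 4.0
    #: scale of the shared latent patient factors (intensity, vascularity,
    #: cellularity, edema water) that shift many channels coherently and give
    #: the feature clouds the correlated, elongated shape of real radiomics
    factor_scale: float = 1.0
    #: lognormal sigma of per-subject edema-scale jitter
    edema_jitter: float = 0.18
    growth_params: tuple[tuple[float, float], ...] = (
        (100.0, 15.0), (0.5, 0.1), (1.2, 0.4))  # (mean, sd) for dt, dw, foci

    def __post_init__(self) -> None:
        if self.edema_scale <= 0:
            raise ValueError("edema_scale must be > 0")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")
        if self.survival_median <= 0:
            raise ValueError("survival_median must be > 0")
        for p in (self.censoring_fraction, self.egfrviii_prevalence, self.idh1_mutant_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.molecular_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"molecular_mixture sums to {total}, expected 1")
        if any(p < 0 for p in self.molecular_mixture.values()):
            raise ValueError("molecular_mixture probabilities must be >= 0")


@dataclass
class CohortSpec:
    """Cohort-level generation settings."""

    n_subjects: int = 30
    archetype_proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_noise_sd: float = 2.0
    random_seed: int = 0
    egfr_unknown_fraction: float = 0.0  # fraction of subjects with unknown EGFRvIII status

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if abs(sum(self.archetype_proportions) - 1.0) > 1e-9:
            raise ValueError("archetype_proportions must sum to 1")
        if any(s < 16 for s in self.volume_shape):
            raise ValueError("every volume_shape component must be >= 16")
        if self.voxel_noise_sd < 0:
            raise ValueError("voxel_noise_sd must be >= 0")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            payload = json.load(fh)
        payload["archetype_proportions"] = tuple(payload.get(
            "archetype_proportions", (1 / 3, 1 / 3, 1 / 3)))
        payload["volume_shape"] = tuple(payload.get("volume_shape", (40, 40, 40)))
        return cls(**payload)


@dataclass
class SurvivalRecord:
    subject_id: str
    time: float                 # months, > 0
    event: int                  # 1 = death observed, 0 = censored
    age: float
    egfrviii: str               # present / absent / unknown
    idh1: str                   # mutant / wildtype / unknown
    mgmt: str                   # methylated / unmethylated / unknown
    molecular_subtype: str
    growth_dt: float
    growth_dw: float
    growth_foci: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass
class ImagingStudy:
    """One subject's co-registered channel volumes plus segmentation and clinical data."""

    subject_id: str
    channels: dict[str, np.ndarray]
    segmentation: np.ndarray
    clinical: SurvivalRecord
    truth_archetype: str | None = None

    def region_mask(self, region: str) -> np.ndarray:
        return self.segmentation == SEG_LABELS[region]

    def core_mask(self) -> np.ndarray:
        """Tumor core = enhancing + non-enhancing components."""
        return (self.segmentation == SEG_LABELS["TU"]) | (self.segmentation == SEG_LABELS["NC"])

    def validate(self) -> None:
        shape = self.segmentation.shape
        for name, vol in self.channels.items():
            if vol.shape != shape:
                raise ValueError(f"channel {name} shape {vol.shape} != segmentation {shape}")
        for region in REGIONS:
            if not self.region_mask(region).any():
                raise ValueError(f"subregion {region} is empty")


# ---------------------------------------------------------------------------
# default archetypes
# ---------------------------------------------------------------------------

# baseline per-channel (TU, NC, ED) means; brain background is 80 for every channel
_BASE_MEANS: dict[str, tuple[float, float, float]] = {
    "T1":    (90.0,  70.0,  75.0),
    "T1CE":  (200.0, 90.0,  85.0),
    "T2":    (110.0, 130.0, 150.0),
    "FLAIR": (110.0, 120.0, 150.0),
    "AX":    (120.0, 110.0, 140.0),
    "FA":    (60.0,  80.0,  50.0),
    "RAD":   (110.0, 100.0, 135.0),
    "TR":    (120.0, 110.0, 140.0),
    "rCBV":  (140.0, 100.0, 90.0),
    "PH":    (130.0, 100.0, 90.0),
    "PSR":   (70.0,  90.0,  85.0),
}

# normal-appearing brain: wide spread emulating CSF/GM/WM heterogeneity, so
# per-subject percentile normalization anchors on brain tissue rather than on
# the (size-varying) tumor intensity tail
BACKGROUND_MEAN = 100.0
BACKGROUND_SD = 25.0

# archetype-specific (region, channel) mean overrides encoding the Table-1-style
# contrasts: TR core rim > irregular > solid, rCBV solid > irregular > rim,
# FLAIR edema highest in irregular (water density), FA core lowest in rim.
_OVERRIDES: dict[str, dict[tuple[str, str], float]] = {
    "rim_enhancing": {
        ("TU", "T1CE"): 235.0,
        ("TU", "TR"): 160.0, ("NC", "TR"): 150.0, ("ED", "TR"): 150.0,
        ("NC", "FA"): 55.0, ("TU", "FA"): 50.0,
        ("TU", "rCBV"): 100.0, ("NC", "rCBV"): 80.0, ("ED", "rCBV"): 80.0,
        ("TU", "PH"): 95.0, ("ED", "FLAIR"): 150.0,
    },
    "irregular": {
        ("TU", "T1CE"): 185.0,
        ("TU", "TR"): 140.0, ("NC", "TR"): 130.0, ("ED", "TR"): 150.0,
        ("NC", "FA"): 80.0,
        ("TU", "rCBV"): 125.0, ("NC", "rCBV"): 95.0, ("ED", "rCBV"): 90.0,
        ("ED", "FLAIR"): 195.0, ("ED", "T2"): 185.0,
        ("ED", "AX"): 160.0, ("ED", "RAD"): 155.0, ("TU", "PSR"): 85.0,
    },
    "solid": {
        ("TU", "T1CE"): 210.0,
        ("TU", "TR"): 100.0, ("NC", "TR"): 95.0, ("ED", "TR"): 110.0,
        ("NC", "FA"): 100.0, ("TU", "FA"): 85.0,
        ("TU", "rCBV"): 185.0, ("NC", "rCBV"): 135.0, ("ED", "rCBV"): 115.0,
        ("TU", "PH"): 175.0, ("NC", "PH"): 125.0, ("ED", "FLAIR"): 130.0,
        ("ED", "T2"): 135.0, ("ED", "AX"): 125.0, ("ED", "RAD"): 120.0,
        ("TU", "PSR"): 55.0,
    },
}

# within-region voxel SD per archetype: irregular is the most heterogeneous
_REGION_SD = {"rim_enhancing": 6.0, "irregular": 12.0, "solid": 9.0}


def _intensity_params(name: str) -> dict[tuple[str, str], tuple[float, float]]:
    sd = _REGION_SD[name]
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for channel, (tu, nc, ed) in _BASE_MEANS.items():
        base = {"TU": tu, "NC": nc, "ED": ed}
        for region in REGIONS:
            mean = _OVERRIDES[name].get((region, channel), base[region])
            params[(region, channel)] = (mean, sd)
    return params


def default_archetypes() -> list[SubtypeArchetype]:
    """The three default planted subtypes: rim-enhancing, irregular, solid.

    Survival medians 19/12/6 months, EGFRvIII prevalence 12.5/39.02/30.61%,
    edema size irregular > rim > solid, irregularity irregular > solid > rim.
    """
    return [
        SubtypeArchetype(
            name="rim_enhancing",
            region_intensity_params=_intensity_params("rim_enhancing"),
            edema_scale=1.5,
            irregularity=0.8,
            survival_median=19.0,
            censoring_fraction=0.2,
            egfrviii_prevalence=0.125,
            molecular_mixture={"classical": 0.15, "mesenchymal": 0.15,
                               "proneural": 0.50, "neural": 0.20},
            spatial_center="frontal",
            idh1_mutant_prob=0.10,
        ),
        SubtypeArchetype(
            name="irregular",
            region_intensity_params=_intensity_params("irregular"),
            edema_scale=2.3,
            irregularity=2.2,
            survival_median=12.0,
            censoring_fraction=0.2,
            egfrviii_prevalence=0.3902,
            molecular_mixture={"classical": 0.15, "mesenchymal": 0.35,
                               "proneural": 0.10, "neural": 0.40},
            spatial_center="temporal",
            idh1_mutant_prob=0.03,
        ),
        SubtypeArchetype(
            name="solid",
            region_intensity_params=_intensity_params("solid"),
            edema_scale=0.9,
            irregularity=1.3,
            survival_median=6.0,
            censoring_fraction=0.2,
            egfrviii_prevalence=0.3061,
            molecular_mixture={"classical": 0.50, "mesenchymal": 0.20,
                               "proneural": 0.15, "neural": 0.15},
            spatial_center="temporal",
            idh1_mutant_prob=0.01,
        ),
    ]


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def make_atlas(shape: Sequence[int]) -> np.ndarray:
    """Deterministic 9-region parcellation of an ellipsoidal synthetic brain.

    Returns an integer label volume: 0 = outside brain, 1..9 = the anatomical
    regions in :data:`ATLAS_REGIONS` order. The parcellation is a stylized
    anatomy: frontal anterior-superior, occipital posterior, cerebellum and
    brain stem inferior, deep structures central — adequate for location
    features and spatial maps, with no claim of anatomical fidelity.
    """
    shape = tuple(int(s) for s in shape)
    zi, yi, xi = np.indices(shape).astype(float)
    c = [(s - 1) / 2.0 for s in shape]
    r = [0.45 * s for s in shape]
    # normalized coordinates in [-1, 1]; axis 0 = inferior->superior (z),
    # axis 1 = posterior->anterior (y), axis 2 = left->right (x)
    z = (zi - c[0]) / r[0]
    y = (yi - c[1]) / r[1]
    x = (xi - c[2]) / r[2]
    brain = z ** 2 + y ** 2 + x ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    region_id = {name: i + 1 for i, name in enumerate(ATLAS_REGIONS)}
    rad = np.sqrt(x ** 2 + y ** 2)

    inferior = z < -0.45
    labels[brain & inferior & (y < -0.15)] = region_id["cerebellum"]
    labels[brain & inferior & (y >= -0.15) & (rad < 0.3)] = region_id["brain_stem"]
    labels[brain & inferior & (y >= -0.15) & (rad >= 0.3)] = region_id["temporal"]

    mid = brain & ~inferior
    labels[mid & (y > 0.25)] = region_id["frontal"]
    labels[mid & (y < -0.45)] = region_id["occipital"]
    central = mid & (labels == 0)
    deep = central & (rad < 0.22) & (z < 0.35)
    labels[deep & (z < 0.1)] = region_id["cc_fornix"]
    labels[deep & (z >= 0.1)] = region_id["basal_ganglia"]
    remaining = central & (labels == 0)
    labels[remaining & (z < 0.0) & (np.abs(x) > 0.35)] = region_id["insula"]
    labels[remaining & (z < 0.0) & (np.abs(x) <= 0.35)] = region_id["temporal"]
    labels[remaining & (z >= 0.0)] = region_id["parietal"]
    return labels


def _region_seed_point(atlas: np.ndarray, region: str) -> np.ndarray:
    """Deepest-in-brain voxel of a region — a seed point guaranteed inside the
    (possibly non-convex) region with maximal margin to the brain boundary."""
    label = ATLAS_REGIONS.index(region) + 1
    in_region = atlas == label
    if not in_region.any():
        raise ValueError(f"atlas has no voxels for region {region!r}")
    depth = ndimage.distance_transform_edt(atlas > 0)
    depth[~in_region] = -1.0
    return np.array(np.unravel_index(np.argmax(depth), atlas.shape), dtype=float)


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def _draw_survival(rng: np.random.Generator, archetype: SubtypeArchetype) -> tuple[float, int]:
    """Exponential event time (rate ln2/median) with optional uniform censoring."""
    scale = archetype.survival_median / math.log(2.0)
    t = float(rng.exponential(scale))
    t = max(t, 1e-3)
    event = 1
    if rng.random() < archetype.censoring_fraction:
        c = float(rng.uniform(0.0, 3.0 * archetype.survival_median))
        c = max(c, 1e-3)
        if c < t:
            return c, 0
    return t, event


def _clinical_record(rng: np.random.Generator, subject_id: str,
                     archetype: SubtypeArchetype,
                     egfr_unknown_fraction: float = 0.0) -> SurvivalRecord:
    time, event = _draw_survival(rng, archetype)
    age = float(np.clip(rng.normal(60.0, 10.0), 20.0, 90.0))
    if rng.random() < egfr_unknown_fraction:
        egfr = "unknown"
    else:
        egfr = "present" if rng.random() < archetype.egfrviii_prevalence else "absent"
    idh1 = "mutant" if rng.random() < archetype.idh1_mutant_prob else "wildtype"
    mgmt = "methylated" if rng.random() < archetype.mgmt_methylated_prob else "unmethylated"
    mix = archetype.molecular_mixture
    mol = str(rng.choice(MOLECULAR_SUBTYPES, p=[mix[m] for m in MOLECULAR_SUBTYPES]))
    (dt_m, dt_s), (dw_m, dw_s), (fo_m, fo_s) = archetype.growth_params
    return SurvivalRecord(
        subject_id=subject_id, time=time, event=event, age=age,
        egfrviii=egfr, idh1=idh1, mgmt=mgmt, molecular_subtype=mol,
        growth_dt=float(rng.normal(dt_m, dt_s)),
        growth_dw=float(max(rng.normal(dw_m, dw_s), 1e-3)),
        growth_foci=float(max(rng.normal(fo_m, fo_s), 1.0)),
    )


def _build_segmentation(rng: np.random.Generator, archetype: SubtypeArchetype,
                        spec: CohortSpec, atlas: np.ndarray,
                        max_attempts: int = 10) -> np.ndarray:
    """Ellipsoidal core (TU shell + NC interior) with an ED ring, perturbed boundary.

    A tumor is by definition a lesion with non-empty TU, NC and ED subregions;
    tail draws of the boundary-noise field can erode the core away, so the
    geometry draw is rejection-resampled (deterministically, within the
    subject's RNG stream) up to ``max_attempts`` times. A configuration that
    fails every attempt (e.g. a core radius that cannot fit in the volume)
    re-raises the last error.
    """
    last_err: ValueError | None = None
    for _ in range(max_attempts):
        try:
            return _build_segmentation_once(rng, archetype, spec, atlas)
        except ValueError as err:
            last_err = err
    raise last_err


def _build_segmentation_once(rng: np.random.Generator, archetype: SubtypeArchetype,
                             spec: CohortSpec, atlas: np.ndarray) -> np.ndarray:
    shape = spec.volume_shape
    mixture = archetype.spatial_mixture
    if mixture is None:
        others = [r for r in ("frontal", "temporal", "parietal")
                  if r != archetype.spatial_center]
        mixture = {archetype.spatial_center: 0.6, others[0]: 0.2, others[1]: 0.2}
    regions = sorted(mixture)
    seed_region = str(rng.choice(regions, p=[mixture[r] for r in regions]))
    center = _region_seed_point(atlas, seed_region)
    center = center + rng.uniform(-1.5, 1.5, size=3)

    # per-subject geometry: anisotropic semi-axes, jittered edema extent and
    # boundary irregularity (inter-patient variability)
    radii = archetype.core_radius * rng.uniform(0.85, 1.15, size=3)
    mean_radius = float(np.exp(np.mean(np.log(radii))))
    edema_scale = archetype.edema_scale * float(
        np.exp(rng.normal(0.0, archetype.edema_jitter)))
    irregularity = archetype.irregularity * float(rng.uniform(0.7, 1.3))
    outer_margin = mean_radius * ((1.0 + edema_scale) ** (1.0 / 3.0) - 1.0)

    # bounds check: whole lesion (core + ED ring + perturbation) must fit
    for axis, (c_a, r_a, s_a) in enumerate(zip(center, radii, shape)):
        extent = r_a + outer_margin + irregularity + 1.0
        if c_a - extent < 0 or c_a + extent > s_a - 1:
            raise ValueError(
                f"tumor exceeds volume bounds along dimension {axis} "
                f"(center {c_a:.1f}, extent {extent:.1f}, size {s_a})")

    idx = np.indices(shape).astype(float)
    d_norm = np.sqrt(sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3)))
    # signed distance from the unperturbed core boundary, in voxel units
    s = (d_norm - 1.0) * mean_radius

    if irregularity > 0:
        noise = rng.normal(size=shape)
        noise = ndimage.gaussian_filter(noise, sigma=3.0)
        noise /= max(noise.std(), 1e-12)
        s = s - irregularity * noise

    shell = max(0.35 * mean_radius, 1.2)
    core = s <= 0.0
    if not core.any():
        raise ValueError("generated core is empty; increase core_radius")
    # NC = deepest part of the core. The nominal shell depth defines the
    # TU/NC boundary, but NC always keeps at least 15% of the core: real
    # glioblastoma cores retain a substantial non-enhancing component, and an
    # eroded near-empty NC would make ratio features degenerate.
    s_core = s[core]
    n_core = int(s_core.size)
    if n_core < 2:
        raise ValueError("generated core too small to split into TU and NC")
    deep_count = int(np.count_nonzero(s_core <= -shell))
    deep_count = max(deep_count, -(-15 * n_core // 100))  # ceil(0.15 n)
    deep_count = min(max(deep_count, 1), n_core - 1)
    nc_thresh = float(np.partition(s_core, deep_count - 1)[deep_count - 1])
    nc = core & (s <= nc_thresh)
    tu = core & ~nc
    ed = (s <= outer_margin) & ~core

    seg = np.zeros(shape, dtype=np.int16)
    seg[ed] = SEG_LABELS["ED"]
    seg[nc] = SEG_LABELS["NC"]
    seg[tu] = SEG_LABELS["TU"]
    for region, mask in (("TU", tu), ("NC", nc), ("ED", ed)):
        if not mask.any():
            raise ValueError(f"generated subregion {region} is empty; "
                             f"increase core_radius or volume_shape")
    return seg


# latent patient factors: (channels affected, per-factor-unit shift) applied in
# tumor regions; a global intensity factor shifts every channel everywhere
_FACTOR_LOADINGS: dict[str, dict[str, float]] = {
    "vascularity": {"rCBV": 12.0, "PH": 10.0, "PSR": -8.0, "T1CE": 8.0},
    "cellularity": {"TR": -10.0, "AX": -8.0, "RAD": -8.0, "FA": 6.0},
    "edema_water": {"FLAIR": 12.0, "T2": 10.0},
}


def _subject_mean_shifts(rng: np.random.Generator,
                         archetype: SubtypeArchetype) -> dict[tuple[str, str], float]:
    """Per-subject offsets of the region/channel means: a few shared latent
    factors (coherent shifts across many channels) plus independent residuals.
    The factor structure makes within-archetype variation low-rank, as in real
    radiomic tables."""
    s = archetype.factor_scale
    global_intensity = rng.normal(0.0, 10.0 * s)
    factors = {name: rng.normal(0.0, s) for name in _FACTOR_LOADINGS}
    shifts: dict[tuple[str, str], float] = {}
    for region in REGIONS:
        for channel in CHANNELS:
            delta = global_intensity
            for name, loadings in _FACTOR_LOADINGS.items():
                delta += factors[name] * loadings.get(channel, 0.0)
            delta += rng.normal(0.0, archetype.between_subject_sd)
            shifts[(region, channel)] = float(delta)
    return shifts


def generate_subject(archetype: SubtypeArchetype, spec: CohortSpec,
                     subject_seed: int, subject_id: str | None = None,
                     atlas: np.ndarray | None = None,
                     egfr_unknown_fraction: float | None = None) -> ImagingStudy:
    """Generate one ImagingStudy; deterministic for fixed (archetype, spec, seed)."""
    rng = np.random.default_rng(subject_seed)
    if atlas is None:
        atlas = make_atlas(spec.volume_shape)
    if subject_id is None:
        subject_id = f"sub-{subject_seed:06d}"
    if egfr_unknown_fraction is None:
        egfr_unknown_fraction = spec.egfr_unknown_fraction

    seg = _build_segmentation(rng, archetype, spec, atlas)
    brain = atlas > 0

    subject_shift = _subject_mean_shifts(rng, archetype)

    channels: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        vol = np.zeros(spec.volume_shape, dtype=np.float64)
        vol[brain] = rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, size=int(brain.sum()))
        for region in REGIONS:
            mask = seg == SEG_LABELS[region]
            mean, sd = archetype.region_intensity_params[(region, channel)]
            subj_mean = mean + subject_shift[(region, channel)]
            vol[mask] = rng.normal(subj_mean, sd, size=int(mask.sum()))
        if spec.voxel_noise_sd > 0:
            vol += rng.normal(0.0, spec.voxel_noise_sd, size=spec.volume_shape)
        channels[channel] = vol

    clinical = _clinical_record(rng, subject_id, archetype, egfr_unknown_fraction)
    study = ImagingStudy(subject_id=subject_id, channels=channels,
                         segmentation=seg, clinical=clinical,
                         truth_archetype=archetype.name)
    study.validate()
    return study


def _subject_seeds(spec: CohortSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.random_seed)
    return rng.integers(0, 2 ** 31 - 1, size=spec.n_subjects)


def _assign_archetypes(spec: CohortSpec, n_archetypes: int) -> np.ndarray:
    rng = np.random.default_rng(spec.random_seed + 1)
    return rng.choice(n_archetypes, size=spec.n_subjects,
                      p=np.asarray(spec.archetype_proportions))


def clinical_table(studies: Sequence[ImagingStudy]) -> pd.DataFrame:
    """CSV-ready clinical table for a cohort."""
    rows = []
    for st in studies:
        c = st.clinical
        rows.append({
            "subject_id": c.subject_id, "age": c.age,
            "survival_months": c.time, "event": c.event,
            "egfrviii": c.egfrviii, "idh1": c.idh1, "mgmt": c.mgmt,
            "molecular_subtype": c.molecular_subtype,
            "truth_archetype": st.truth_archetype,
            "growth_dt": c.growth_dt, "growth_dw": c.growth_dw,
            "growth_foci": c.growth_foci,
        })
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec,
                    archetypes: Sequence[SubtypeArchetype] | None = None,
                    ) -> tuple[list[ImagingStudy], pd.DataFrame]:
    """Generate a full cohort: archetype assignment is multinomial with
    ``spec.archetype_proportions``; per-subject seeds derive from
    ``spec.random_seed``. Returns the studies and the clinical table."""
    if archetypes is None:
        archetypes = default_archetypes()
    seeds = _subject_seeds(spec)
    assignment = _assign_archetypes(spec, len(archetypes))
    atlas = make_atlas(spec.volume_shape)
    studies = []
    for i in range(spec.n_subjects):
        studies.append(generate_subject(
            archetypes[assignment[i]], spec, int(seeds[i]),
            subject_id=f"sub-{i:04d}", atlas=atlas))
    return studies, clinical_table(studies)


def iter_cohort(spec: CohortSpec,
                archetypes: Sequence[SubtypeArchetype] | None = None):
    """Yield the same studies as :func:`generate_cohort`, one at a time.

    Useful for survival-scale cohorts where holding every volume in memory is
    wasteful; consume each study (e.g. compute its features) and discard it.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    seeds = _subject_seeds(spec)
    assignment = _assign_archetypes(spec, len(archetypes))
    atlas = make_atlas(spec.volume_shape)
    for i in range(spec.n_subjects):
        yield generate_subject(archetypes[assignment[i]], spec, int(seeds[i]),
                               subject_id=f"sub-{i:04d}", atlas=atlas)


def generate_clinical_cohort(spec: CohortSpec,
                             archetypes: Sequence[SubtypeArchetype] | None = None,
                             ) -> pd.DataFrame:
    """Clinical table only (no volumes) — same clinical draws as
    :func:`generate_cohort` uses for the same spec are NOT guaranteed; this is
    a fast path for survival-scale cohorts where imaging is not needed."""
    if archetypes is None:
        archetypes = default_archetypes()
    seeds = _subject_seeds(spec)
    assignment = _assign_archetypes(spec, len(archetypes))
    rows = []
    for i in range(spec.n_subjects):
        arch = archetypes[assignment[i]]
        rng = np.random.default_rng(int(seeds[i]) + 7_654_321)
        rec = _clinical_record(rng, f"sub-{i:04d}", arch, spec.egfr_unknown_fraction)
        row = rec.__dict__.copy()
        row["truth_archetype"] = arch.name
        rows.append(row)
    df = pd.DataFrame(rows).rename(columns={"time": "survival_months"})
    return df


def archetypes_from_json(path) -> list[SubtypeArchetype]:
    """Load archetype overrides from JSON: a list of objects whose fields
    override the same-named default archetype's fields."""
    defaults = {a.name: a for a in default_archetypes()}
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for entry in payload:
        name = entry["name"]
        base = copy.deepcopy(defaults[name]) if name in defaults else None
        if base is None:
            raise ValueError(f"unknown archetype {name!r}; overrides must "
                             f"target one of {sorted(defaults)}")
        for key, value in entry.items():
            if key in ("name", "region_intensity_params"):
                continue
            setattr(base, key, value)
        if "region_intensity_params" in entry:
            for key, (mean, sd) in entry["region_intensity_params"].items():
                region, channel = key.split("/")
                base.region_intensity_params[(region, channel)] = (float(mean), float(sd))
        base.__post_init__()
        out.append(base)
    return out


def planted_signature_table(n_subjects: int = 300,
                            n_features: int = 20,
                            n_signature: int = 3,
                            effect_size: float = 1.5,
                            prevalences: Mapping[str, float] | None = None,
                            proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                            seed: int = 0,
                            ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature table with subtype-specific mutation signatures.

    Emulates the radiogenomic setting directly at the feature-matrix level:
    standard-normal features, with mutation status shifting a *disjoint* block
    of ``n_signature`` features by ``effect_size`` inside each of the
    irregular and solid subtypes (the rim-enhancing subtype carries no
    signature — its low prevalence makes the constant-absent null model the
    intended classifier). Mutation prevalence per subtype defaults to the
    archetype values.

    Returns ``(frame, mutation_labels, subtype_labels)``.
    """
    if prevalences is None:
        prevalences = {a.name: a.egfrviii_prevalence for a in default_archetypes()}
    names = list(prevalences)
    rng = np.random.default_rng(seed)
    subtype = rng.choice(names, size=n_subjects, p=np.asarray(proportions))
    mutation = np.where(
        rng.random(n_subjects) < np.array([prevalences[s] for s in subtype]),
        "present", "absent")
    X = rng.normal(size=(n_subjects, n_features))
    signature_of = {}
    block = 0
    for s in names:
        if s == "rim_enhancing":
            continue
        cols = list(range(block * n_signature, (block + 1) * n_signature))
        if cols[-1] >= n_features:
            raise ValueError("n_features too small for disjoint signatures")
        signature_of[s] = cols
        mask = (subtype == s) & (mutation == "present")
        X[np.ix_(mask, cols)] += effect_size
        block += 1
    frame = pd.DataFrame(X, index=[f"sub-{i:04d}" for i in range(n_subjects)],
                         columns=[f"FEAT_{j:03d}" for j in range(n_features)])
    return frame, mutation, subtype
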