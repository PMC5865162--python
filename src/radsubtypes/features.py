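"""Five-family radiomic feature catalog and per-subject extraction.

Families and default counts:

* volumetric & shape (11): three subregion volumes normalized by brain size,
  ED/(ED+NC+TU) and TU/NC ratios, plus circularity (2D) and sphericity (3D)
  of NC, NC+TU and NC+TU+ED;
* intensity (66): mean and SD per subregion (TU, NC, ED) per channel (11);
* histogram (165): percentage of subregion voxels in each of 5 equal-width
  bins of the per-subject normalized [0, 1] intensity scale, per subregion
  and channel;
* GLCM texture (24): energy, contrast, entropy, correlation, dissimilarity,
  homogeneity over the whole tumor (TU+NC+ED) for the four structural
  channels (T1, T1CE, T2, FLAIR); 32 gray levels, 26 principal 3D
  directions, distances 1 and 2 voxels;
* location (9): percentage of tumor core (TU+NC) per atlas region;
* growth (3): biophysical growth-model parameters passed through from the
  clinical table.

Feature names follow the ``Subregion_KIND_Channel[_Bin]`` convention, e.g.
``ED_BINS_FLAIR_3`` (third histogram bin of FLAIR in edema) or
``TU_MEAN_rCBV``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from radsubtypes.synthetic import (
    ATLAS_REGIONS, CHANNELS, REGIONS, SEG_LABELS, ImagingStudy,
)

STRUCTURAL_CHANNELS: tuple[str, ...] = ("T1", "T1CE", "T2", "FLAIR")
GLCM_MEASURES: tuple[str, ...] = (
    "energy", "contrast", "entropy", "correlation", "dissimilarity", "homogeneity",
)

#: the 26 nonzero sign-vectors in {-1, 0, 1}^3
DIRECTIONS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


@dataclass(frozen=True)
class FeatureSpec:
    family: str      # volumetric_shape | intensity | histogram | texture | location | growth
    region: str      # subregion or combination label ("" for none)
    channel: str     # channel label or ""
    name: str


@dataclass
class TextureConfig:
    gray_levels: int = 32
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_26
    max_distance: int = 2
    measures: tuple[str, ...] = GLCM_MEASURES

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")


class FeatureCatalog:
    """Ordered feature definitions; supports name exclusions."""

    def __init__(self, specs: Sequence[FeatureSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique within a catalog")
        self.specs = list(specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.specs:
            counts[s.family] = counts.get(s.family, 0) + 1
        return counts

    def exclude(self, names: Iterable[str]) -> "FeatureCatalog":
        drop = set(names)
        unknown = drop - set(self.names)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return FeatureCatalog([s for s in self.specs if s.name not in drop])

    def to_json_obj(self) -> list[dict]:
        return [s.__dict__ for s in self.specs]

    @classmethod
    def from_json_obj(cls, payload: list[dict]) -> "FeatureCatalog":
        return cls([FeatureSpec(**entry) for entry in payload])


def default_catalog(exclusions: Iterable[str] = ()) -> FeatureCatalog:
    """The default catalog: family counts (11, 66, 165, 24, 9, 3)."""
    specs: list[FeatureSpec] = []
    # volumetric & shape
    for region in REGIONS:
        specs.append(FeatureSpec("volumetric_shape", region, "", f"{region}_VOLNORM"))
    specs.append(FeatureSpec("volumetric_shape", "ED", "", "ED_WHOLE_RATIO"))
    specs.append(FeatureSpec("volumetric_shape", "TU", "", "TU_NC_RATIO"))
    for combo in ("NC", "NCTU", "NCTUED"):
        specs.append(FeatureSpec("volumetric_shape", combo, "", f"{combo}_CIRC"))
    for combo in ("NC", "NCTU", "NCTUED"):
        specs.append(FeatureSpec("volumetric_shape", combo, "", f"{combo}_SPHER"))
    # intensity
    for region in REGIONS:
        for channel in CHANNELS:
            specs.append(FeatureSpec("intensity", region, channel, f"{region}_MEAN_{channel}"))
            specs.append(FeatureSpec("intensity", region, channel, f"{region}_STD_{channel}"))
    # histogram
    for region in REGIONS:
        for channel in CHANNELS:
            for b in range(1, 6):
                specs.append(FeatureSpec("histogram", region, channel,
                                         f"{region}_BINS_{channel}_{b}"))
    # texture (whole tumor, structural channels)
    for channel in STRUCTURAL_CHANNELS:
        for measure in GLCM_MEASURES:
            specs.append(FeatureSpec("texture", "WT", channel,
                                     f"WT_GLCM_{channel}_{measure.upper()}"))
    # location
    for region in ATLAS_REGIONS:
        specs.append(FeatureSpec("location", region, "", f"LOC_{region.upper()}"))
    # growth (pass-through)
    for name in ("GROWTH_DT", "GROWTH_DW", "GROWTH_FOCI"):
        specs.append(FeatureSpec("growth", "", "", name))
    catalog = FeatureCatalog(specs)
    return catalog.exclude(exclusions) if exclusions else catalog


@dataclass
class FeatureTable:
    """Subjects x features matrix with its catalog."""

    frame: pd.DataFrame          # index = subject ids, columns = feature names
    catalog: FeatureCatalog
    imputed: pd.DataFrame | None = None   # boolean mask of imputed cells

    def __post_init__(self) -> None:
        if list(self.frame.columns) != self.catalog.names:
            raise ValueError("table columns do not match catalog order")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# volumetric & shape
# ---------------------------------------------------------------------------

def compute_volumetric_features(segmentation: np.ndarray,
                                brain_mask: np.ndarray) -> list[float]:
    """[vol(ED), vol(NC), vol(TU)] / vol(brain), ED/(ED+NC+TU), TU/NC.

    ``TU/NC`` is NaN when NC is empty (imputed at table level).
    """
    n_brain = int(np.count_nonzero(brain_mask))
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    vols = {r: int(np.count_nonzero(segmentation == SEG_LABELS[r])) for r in REGIONS}
    whole = vols["ED"] + vols["NC"] + vols["TU"]
    ed_whole = vols["ED"] / whole if whole > 0 else 0.0
    tu_nc = vols["TU"] / vols["NC"] if vols["NC"] > 0 else float("nan")
    return [vols["ED"] / n_brain, vols["NC"] / n_brain, vols["TU"] / n_brain,
            ed_whole, tu_nc]


def _perimeter_4conn(mask2d: np.ndarray) -> int:
    """Exposed-edge count of the boundary under 4-connectivity."""
    m = np.asarray(mask2d, dtype=bool)
    p = 0
    padded = np.pad(m, 1)
    for axis in (0, 1):
        diff = padded != np.roll(padded, 1, axis=axis)
        p += int(diff.sum())
    return p


def compute_circularity(mask_2d: np.ndarray) -> float:
    """4*pi*Area / Perimeter^2 with voxel-count area and exposed-edge perimeter."""
    m = np.asarray(mask_2d, dtype=bool)
    area = int(m.sum())
    if area == 0:
        raise ValueError("empty 2D mask")
    per = _perimeter_4conn(m)
    return 4.0 * math.pi * area / per ** 2


def _surface_faces(mask3d: np.ndarray) -> int:
    m = np.asarray(mask3d, dtype=bool)
    faces = 0
    padded = np.pad(m, 1)
    for axis in (0, 1, 2):
        diff = padded != np.roll(padded, 1, axis=axis)
        faces += int(diff.sum())
    return faces


def compute_sphericity(mask_3d: np.ndarray) -> float:
    """pi^(1/3) * (6V)^(2/3) / A with V = voxel count, A = exposed-face count.

    Face counting over-estimates the surface of smooth bodies (a rasterized
    ball converges to ~0.66 rather than 1), so values are comparable across
    masks of the same resolution but are not resolution-free.
    """
    m = np.asarray(mask_3d, dtype=bool)
    v = int(m.sum())
    if v == 0:
        raise ValueError("empty 3D mask")
    a = _surface_faces(m)
    return math.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a


def _max_area_axial_slice(mask3d: np.ndarray) -> np.ndarray:
    """Axial slice (last axis) with maximal in-mask area."""
    m = np.asarray(mask3d, dtype=bool)
    areas = m.sum(axis=(0, 1))
    return m[:, :, int(np.argmax(areas))]


def compute_shape_features(segmentation: np.ndarray) -> dict[str, float]:
    """Circularity and sphericity of NC, NC+TU, NC+TU+ED."""
    nc = segmentation == SEG_LABELS["NC"]
    tu = segmentation == SEG_LABELS["TU"]
    ed = segmentation == SEG_LABELS["ED"]
    combos = {"NC": nc, "NCTU": nc | tu, "NCTUED": nc | tu | ed}
    out: dict[str, float] = {}
    for name, mask in combos.items():
        if mask.any():
            out[f"{name}_CIRC"] = compute_circularity(_max_area_axial_slice(mask))
            out[f"{name}_SPHER"] = compute_sphericity(mask)
        else:
            out[f"{name}_CIRC"] = float("nan")
            out[f"{name}_SPHER"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# intensity & histogram
# ---------------------------------------------------------------------------

def compute_intensity_stats(channel_volume: np.ndarray,
                            region_mask: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of in-mask voxel intensities."""
    vals = np.asarray(channel_volume)[np.asarray(region_mask, dtype=bool)]
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.std())


def normalize_channel(channel_volume: np.ndarray, brain_mask: np.ndarray,
                      lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Map a channel to [0, 1] per subject: clip at the 1st/99th percentile of
    in-brain intensities, then min-max scale."""
    vol = np.asarray(channel_volume, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    lo, hi = np.percentile(vol[brain], [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(vol)
    return np.clip((vol - lo) / (hi - lo), 0.0, 1.0)


def compute_histogram_features(channel_volume: np.ndarray,
                               region_mask: np.ndarray,
                               n_bins: int = 5) -> np.ndarray:
    """Percentage of in-mask voxels per equal-width bin on [0, 1].

    Bins are right-open except the last ([0.8, 1.0] is closed). The input is
    expected on the normalized [0, 1] scale. Empty region -> NaNs.
    """
    vals = np.asarray(channel_volume)[np.asarray(region_mask, dtype=bool)]
    if vals.size == 0:
        return np.full(n_bins, np.nan)
    idx = np.minimum((vals * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return counts / vals.size * 100.0


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def quantize_region(channel_volume: np.ndarray, region_mask: np.ndarray,
                    gray_levels: int = 32) -> np.ndarray:
    """Quantize in-mask intensities to ``gray_levels`` equal-width levels over
    the region's own [min, max]; constant regions map to level 0. Returns an
    int volume with -1 outside the mask."""
    mask = np.asarray(region_mask, dtype=bool)
    vol = np.asarray(channel_volume, dtype=float)
    out = np.full(vol.shape, -1, dtype=np.int32)
    vals = vol[mask]
    if vals.size == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        out[mask] = 0
        return out
    levels = np.minimum(((vals - lo) / (hi - lo) * gray_levels).astype(int),
                        gray_levels - 1)
    out[mask] = levels
    return out


def _glcm_for_offset(levels: np.ndarray, offset: tuple[int, int, int],
                     gray_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one spatial offset, masked voxels only."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, o in enumerate(offset):
        if o > 0:
            src[axis] = slice(0, levels.shape[axis] - o)
            dst[axis] = slice(o, levels.shape[axis])
        elif o < 0:
            src[axis] = slice(-o, levels.shape[axis])
            dst[axis] = slice(0, levels.shape[axis] + o)
    a = levels[tuple(src)].ravel()
    b = levels[tuple(dst)].ravel()
    valid = (a >= 0) & (b >= 0)
    a, b = a[valid], b[valid]
    counts = np.bincount(a * gray_levels + b,
                         minlength=gray_levels * gray_levels
                         ).reshape(gray_levels, gray_levels).astype(float)
    return counts + counts.T


def glcm_measures_from_matrix(counts: np.ndarray) -> dict[str, float]:
    """Six standard second-order measures from a (non-normalized) GLCM."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    p = counts / total
    n = p.shape[0]
    i, j = np.indices((n, n))
    diff = i - j
    energy = float((p ** 2).sum())
    contrast = float((p * diff ** 2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    pi = p.sum(axis=1)
    mu = float((np.arange(n) * pi).sum())
    var = float(((np.arange(n) - mu) ** 2 * pi).sum())
    if var <= 0:
        correlation = float("nan")
    else:
        correlation = float((p * (i - mu) * (j - mu)).sum() / var)
    return {"energy": energy, "contrast": contrast, "entropy": entropy,
            "correlation": correlation, "dissimilarity": dissimilarity,
            "homogeneity": homogeneity}


def compute_glcm_measures(channel_volume: np.ndarray, region_mask: np.ndarray,
                          config: TextureConfig | None = None) -> dict[str, float]:
    """Average GLCM measures over 26 directions x distances {1, .., max_distance}.

    Intensities are quantized to ``gray_levels`` equal-width levels over the
    region's own range; each (direction, distance) yields a symmetric
    co-occurrence matrix over voxel pairs both inside the mask; measures are
    averaged over matrices with at least one pair. A constant region gives
    energy = homogeneity = 1, contrast = entropy = dissimilarity = 0 and NaN
    correlation (zero variance).
    """
    if config is None:
        config = TextureConfig()
    mask = np.asarray(region_mask, dtype=bool)
    if int(mask.sum()) < 2:
        raise ValueError("region must contain at least 2 voxels")
    levels = quantize_region(channel_volume, mask, config.gray_levels)
    sums = {m: 0.0 for m in config.measures}
    counts_per_measure = {m: 0 for m in config.measures}
    for direction in config.directions:
        for dist in range(1, config.max_distance + 1):
            offset = tuple(d * dist for d in direction)
            counts = _glcm_for_offset(levels, offset, config.gray_levels)
            if counts.sum() == 0:
                continue
            vals = glcm_measures_from_matrix(counts)
            for m in config.measures:
                if not math.isnan(vals[m]):
                    sums[m] += vals[m]
                    counts_per_measure[m] += 1
    out = {}
    for m in config.measures:
        out[m] = sums[m] / counts_per_measure[m] if counts_per_measure[m] else float("nan")
    return out


# ---------------------------------------------------------------------------
# location
# ---------------------------------------------------------------------------

def compute_location_features(core_mask: np.ndarray,
                              atlas_label_map: np.ndarray) -> np.ndarray:
    """Percentage of tumor-core voxels in each of the 9 atlas regions.

    Sums to 100 when the core lies entirely inside atlas-covered voxels.
    """
    core = np.asarray(core_mask, dtype=bool)
    n_core = int(core.sum())
    if n_core == 0:
        raise ValueError("empty tumor core")
    labels = np.asarray(atlas_label_map)[core]
    counts = np.bincount(labels[labels > 0], minlength=len(ATLAS_REGIONS) + 1)
    return counts[1:len(ATLAS_REGIONS) + 1] / n_core * 100.0


# ---------------------------------------------------------------------------
# table extraction
# ---------------------------------------------------------------------------

def compute_subject_features(study: ImagingStudy, atlas: np.ndarray,
                             catalog: FeatureCatalog,
                             texture_config: TextureConfig | None = None,
                             growth: dict[str, float] | None = None,
                             ) -> dict[str, float]:
    """All catalog features for one subject (missing values as NaN)."""
    if texture_config is None:
        texture_config = TextureConfig()
    wanted = set(catalog.names)
    seg = study.segmentation
    brain = atlas > 0
    values: dict[str, float] = {}

    vol = compute_volumetric_features(seg, brain)
    for name, v in zip(("ED_VOLNORM", "NC_VOLNORM", "TU_VOLNORM",
                        "ED_WHOLE_RATIO", "TU_NC_RATIO"), vol):
        values[name] = v
    values.update(compute_shape_features(seg))

    region_masks = {r: study.region_mask(r) for r in REGIONS}
    normalized: dict[str, np.ndarray] = {}
    for channel, volume in study.channels.items():
        normalized[channel] = normalize_channel(volume, brain)
        for region in REGIONS:
            mean, sd = compute_intensity_stats(volume, region_masks[region])
            values[f"{region}_MEAN_{channel}"] = mean
            values[f"{region}_STD_{channel}"] = sd
            bins = compute_histogram_features(normalized[channel], region_masks[region])
            for b in range(5):
                values[f"{region}_BINS_{channel}_{b + 1}"] = float(bins[b])

    wt = region_masks["TU"] | region_masks["NC"] | region_masks["ED"]
    for channel in STRUCTURAL_CHANNELS:
        if not any(f"WT_GLCM_{channel}_" in n for n in wanted):
            continue
        glcm = compute_glcm_measures(study.channels[channel], wt, texture_config)
        for measure, v in glcm.items():
            values[f"WT_GLCM_{channel}_{measure.upper()}"] = v

    loc = compute_location_features(study.core_mask(), atlas)
    for region, v in zip(ATLAS_REGIONS, loc):
        values[f"LOC_{region.upper()}"] = float(v)

    if growth is None:
        c = study.clinical
        growth = {"GROWTH_DT": c.growth_dt, "GROWTH_DW": c.growth_dw,
                  "GROWTH_FOCI": c.growth_foci}
    values.update(growth)
    return {name: values[name] for name in catalog.names}


def extract_feature_table(cohort: Sequence[ImagingStudy], atlas: np.ndarray,
                          catalog: FeatureCatalog | None = None,
                          texture_config: TextureConfig | None = None,
                          impute: bool = True) -> FeatureTable:
    """One row per subject, in catalog order; missing values imputed by the
    per-feature cohort median (provenance kept in ``FeatureTable.imputed``)."""
    if catalog is None:
        catalog = default_catalog()
    required = set(CHANNELS)
    rows, ids = [], []
    for study in cohort:
        missing = required - set(study.channels)
        if missing:
            raise ValueError(f"subject {study.subject_id} is missing "
                             f"channel(s) {sorted(missing)}")
        rows.append(compute_subject_features(study, atlas, catalog, texture_config))
        ids.append(study.subject_id)
    frame = pd.DataFrame(rows, index=ids, columns=catalog.names)
    imputed = frame.isna()
    if impute and imputed.to_numpy().any():
        frame = frame.fillna(frame.median())
    return FeatureTable(frame=frame, catalog=catalog,
                        imputed=imputed if imputed.to_numpy().any() else None)


class RadiomicFeatureExtractor:
    """Thin transformer-style wrapper: ``transform(cohort) -> FeatureTable``."""

    def __init__(self, catalog: FeatureCatalog | None = None,
                 texture_config: TextureConfig | None = None):
        self.catalog = catalog
        self.texture_config = texture_config

    def transform(self, cohort: Sequence[ImagingStudy],
                  atlas: np.ndarray) -> FeatureTable:
        return extract_feature_table(cohort, atlas, self.catalog, self.texture_config)


def clinical_location_frame(spec, archetypes=None) -> pd.DataFrame:
    """Clinical table plus the 9 location features, streamed subject-by-subject.

    Survival-scale cohorts only need the clinical record and tumor location;
    streaming avoids holding hundreds of 11-channel volumes in memory.
    """
    from radsubtypes.synthetic import iter_cohort, make_atlas

    atlas = make_atlas(spec.volume_shape)
    rows = []
    for study in iter_cohort(spec, archetypes):
        c = study.clinical
        row = {"subject_id": c.subject_id, "age": c.age,
               "survival_months": c.time, "event": c.event,
               "egfrviii": c.egfrviii, "idh1": c.idh1, "mgmt": c.mgmt,
               "molecular_subtype": c.molecular_subtype,
               "truth_archetype": study.truth_archetype}
        loc = compute_location_features(study.core_mask(), atlas)
        for region, v in zip(ATLAS_REGIONS, loc):
            row[f"LOC_{region.upper()}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)
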