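"""Voxelwise subtype probability maps and atlas-region tumor proportions.

All masks are assumed pre-registered to a common (atlas) grid; the synthetic
generator produces data directly in atlas space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from radsubtypes.features import compute_location_features
from radsubtypes.synthetic import ATLAS_REGIONS


@dataclass
class ProbabilityMap:
    """Per-voxel fraction of a subtype's tumors covering the voxel."""

    subtype: str
    volume: np.ndarray
    n_tumors: int


def subtype_probability_map(core_masks: Sequence[np.ndarray],
                            subtype_labels: Sequence) -> dict[str, ProbabilityMap]:
    """For each subtype s and voxel i: |{tumors of s covering i}| / |tumors of s|.

    Subtypes with zero subjects are omitted with a warning.
    """
    if len(core_masks) != len(subtype_labels):
        raise ValueError("one label per mask required")
    if len(core_masks) == 0:
        raise ValueError("no masks given")
    shape = np.asarray(core_masks[0]).shape
    for m in core_masks:
        if np.asarray(m).shape != shape:
            raise ValueError("all masks must share one grid")
    labels = np.asarray(subtype_labels)
    maps: dict[str, ProbabilityMap] = {}
    for subtype in pd.unique(labels):
        idx = np.nonzero(labels == subtype)[0]
        if idx.size == 0:
            warnings.warn(f"subtype {subtype!r} has no subjects; map omitted")
            continue
        acc = np.zeros(shape, dtype=float)
        for i in idx:
            acc += np.asarray(core_masks[i], dtype=bool)
        maps[str(subtype)] = ProbabilityMap(subtype=str(subtype),
                                            volume=acc / idx.size,
                                            n_tumors=int(idx.size))
    return maps


def regional_tumor_proportions(core_mask: np.ndarray,
                               atlas: np.ndarray) -> np.ndarray:
    """Percentage of tumor-core voxels per atlas region (9 values).

    Shared implementation with the location feature family.
    """
    return compute_location_features(core_mask, atlas)


def subtype_regional_summary(core_masks: Sequence[np.ndarray],
                             subtype_labels: Sequence,
                             atlas: np.ndarray) -> pd.DataFrame:
    """Mean regional proportions per subtype (rows = subtypes)."""
    labels = np.asarray(subtype_labels)
    rows = {}
    for subtype in pd.unique(labels):
        idx = np.nonzero(labels == subtype)[0]
        vecs = [regional_tumor_proportions(core_masks[i], atlas) for i in idx]
        rows[str(subtype)] = np.mean(vecs, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"LOC_{r.upper()}" for r in ATLAS_REGIONS])
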