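"""Formats and serialization: NIfTI volumes, CSV tables, JSON reports.

Conventions: segmentation labels are BraTS-style (1 = NC, 2 = ED, 4 = TU,
0 = background/brain), all tables are CSV with a header row, floating point
is written with 10 significant digits, and all volumes are NIfTI-1 .nii.gz.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from radsubtypes.clustering import SubtypeModel
from radsubtypes.features import FeatureCatalog, FeatureTable
from radsubtypes.synthetic import (
    CHANNELS, SEG_LABELS, ImagingStudy, SurvivalRecord,
)

FLOAT_FORMAT = "%.10g"


def write_volume(volume: np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_study(study: ImagingStudy, directory: str | Path) -> None:
    """One .nii.gz per channel plus the segmentation."""
    directory = Path(directory) / study.subject_id
    directory.mkdir(parents=True, exist_ok=True)
    for channel, vol in study.channels.items():
        write_volume(vol.astype(np.float32), directory / f"{channel}.nii.gz")
    write_volume(study.segmentation.astype(np.int16), directory / "segmentation.nii.gz")


def read_study(directory: str | Path, clinical_row: Mapping | None = None,
               seg_labels: Mapping[str, int] = SEG_LABELS) -> ImagingStudy:
    """Read a per-subject directory written by :func:`write_study`.

    All volumes must share one shape; the segmentation may only contain 0 and
    the configured labels.
    """
    directory = Path(directory)
    channels = {}
    for channel in CHANNELS:
        path = directory / f"{channel}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing channel volume: {path}")
        channels[channel] = read_volume(path).astype(np.float64)
    seg = read_volume(directory / "segmentation.nii.gz").astype(np.int16)
    shapes = {v.shape for v in channels.values()} | {seg.shape}
    if len(shapes) > 1:
        raise ValueError(f"volume shapes differ in {directory}: {sorted(shapes)}")
    allowed = {0, *seg_labels.values()}
    present = set(np.unique(seg).tolist())
    if not present <= allowed:
        raise ValueError(f"segmentation {directory} contains unexpected labels "
                         f"{sorted(present - allowed)}; allowed: {sorted(allowed)}")
    if clinical_row is not None:
        clinical = SurvivalRecord(
            subject_id=str(clinical_row["subject_id"]),
            time=float(clinical_row["survival_months"]),
            event=int(clinical_row["event"]),
            age=float(clinical_row["age"]),
            egfrviii=str(clinical_row.get("egfrviii", "unknown")),
            idh1=str(clinical_row.get("idh1", "unknown")),
            mgmt=str(clinical_row.get("mgmt", "unknown")),
            molecular_subtype=str(clinical_row.get("molecular_subtype", "unknown")),
            growth_dt=float(clinical_row.get("growth_dt", float("nan"))),
            growth_dw=float(clinical_row.get("growth_dw", float("nan"))),
            growth_foci=float(clinical_row.get("growth_foci", float("nan"))),
        )
    else:
        clinical = SurvivalRecord(subject_id=directory.name, time=1.0, event=0,
                                  age=float("nan"), egfrviii="unknown",
                                  idh1="unknown", mgmt="unknown",
                                  molecular_subtype="unknown",
                                  growth_dt=float("nan"), growth_dw=float("nan"),
                                  growth_foci=float("nan"))
    truth = clinical_row.get("truth_archetype") if clinical_row is not None else None
    study = ImagingStudy(subject_id=directory.name, channels=channels,
                         segmentation=seg, clinical=clinical,
                         truth_archetype=truth)
    study.validate()
    return study


def write_feature_table(table: FeatureTable, csv_path: str | Path,
                        catalog_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(csv_path, index_label="subject_id", float_format=FLOAT_FORMAT)
    if catalog_path is not None:
        with open(catalog_path, "w") as fh:
            json.dump(table.catalog.to_json_obj(), fh, indent=1)


def read_feature_table(csv_path: str | Path,
                       catalog_path: str | Path | None = None) -> FeatureTable:
    frame = pd.read_csv(csv_path, index_col="subject_id")
    if catalog_path is not None:
        with open(catalog_path) as fh:
            catalog = FeatureCatalog.from_json_obj(json.load(fh))
    else:
        from radsubtypes.features import FeatureSpec
        catalog = FeatureCatalog(
            [FeatureSpec("unknown", "", "", name) for name in frame.columns])
    return FeatureTable(frame=frame, catalog=catalog)


def catalog_hash(catalog: FeatureCatalog) -> str:
    payload = json.dumps(catalog.to_json_obj(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_subtype_model(model: SubtypeModel, path: str | Path,
                        extra: Mapping | None = None) -> None:
    payload = model.to_json_obj()
    if extra:
        payload["meta"] = dict(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_subtype_model(path: str | Path) -> SubtypeModel:
    with open(path) as fh:
        return SubtypeModel.from_json_obj(json.load(fh))


def write_labels(subject_ids: Sequence[str], labels: Sequence,
                 names: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"subject_id": list(subject_ids),
                  "cluster": list(labels),
                  "subtype": [names[int(l)] for l in labels]}
                 ).to_csv(path, index=False)


def write_json_report(payload: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default, allow_nan=True)
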