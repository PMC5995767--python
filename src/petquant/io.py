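"""File I/O: dynamic NIfTI images with JSON frame-timing sidecars, ROI label
maps with CSV label tables, blood-sample CSVs and participant metadata.

CSV dialect throughout: comma-separated, header row, UTF-8, '.' decimal.
The timing sidecar carries ``FrameTimesStart`` / ``FrameDuration`` (seconds
from acquisition start), ``InjectionStart`` (seconds) and ``DecayCorrected``;
frames not already decay-corrected are corrected to injection time on load.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import DiscreteSampleTable, SampledCurve
from .errors import FormatError, ValidationError
from .timing import F18_HALF_LIFE_S, FrameSchedule

SUBGROUPS = ("control", "epilepsy", "epilepsy_antidepressant")


@dataclass
class ParticipantMeta:
    """Covariates used for SUV and PBIF normalisation."""

    id: str
    weight_kg: float
    injected_dose_mbq: float
    age_years: float
    subgroup: str = "control"

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValidationError("weight must be positive")
        if self.injected_dose_mbq <= 0:
            raise ValidationError("injected dose must be positive")
        if self.age_years < 0:
            raise ValidationError("age must be >= 0")
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(f"subgroup must be one of {SUBGROUPS}")


@dataclass
class ROIMap:
    """Integer-labelled 3-D volume (0 = background) with a label table."""

    labels: np.ndarray
    label_table: dict[int, str]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("ROI map must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("ROI labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValidationError(f"labels in volume missing from table: {sorted(missing)}")

    @property
    def regions(self) -> list[str]:
        return [self.label_table[k] for k in sorted(self.label_table)]


@dataclass
class DynamicImage:
    """4-D activity array (x, y, z, frame) in Bq/mL plus its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("dynamic image must be 4-D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"image has {self.data.shape[3]} frames but the schedule lists "
                f"{self.schedule.n_frames}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def roi_tac(self, roi_map: ROIMap, label_id: int) -> np.ndarray:
        sel = roi_map.labels == label_id
        if not np.any(sel):
            raise ValidationError(f"ROI label {label_id} has no voxels")
        return self.data[sel].mean(axis=0)


# --------------------------------------------------------------------------
# Dynamic images
# --------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_dynamic_pet(dyn: DynamicImage, image_path, timing_path) -> None:
    img = nib.Nifti1Image(dyn.data.astype(np.float32), _affine(dyn.voxel_size_mm))
    nib.save(img, str(image_path))
    sidecar = dyn.schedule.to_dict()
    sidecar["DecayCorrected"] = True
    sidecar["Units"] = "Bq/mL"
    Path(timing_path).write_text(json.dumps(sidecar, indent=1))


def read_dynamic_pet(image_path, timing_path,
                     half_life_s: float = F18_HALF_LIFE_S) -> DynamicImage:
    """Load a 4-D dynamic PET image and its frame-timing sidecar.

    Activity is decay-corrected to injection time on load unless the sidecar
    declares it already corrected.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    sidecar = json.loads(Path(timing_path).read_text())
    schedule = FrameSchedule.from_dict(sidecar)
    if schedule.n_frames != data.shape[3]:
        raise FormatError(
            f"image has {data.shape[3]} frames but the sidecar lists {schedule.n_frames}")
    if not sidecar.get("DecayCorrected", False):
        mids = schedule.mid_pi
        data = data * (1.0 / np.exp(-np.log(2.0) / half_life_s * mids))
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicImage(data, schedule, vs)


def write_roi_map(roi_map: ROIMap, image_path, table_path) -> None:
    img = nib.Nifti1Image(roi_map.labels.astype(np.int16), _affine(roi_map.voxel_size_mm))
    nib.save(img, str(image_path))
    rows = [{"label": k, "region": v} for k, v in sorted(roi_map.label_table.items())]
    pd.DataFrame(rows).to_csv(table_path, index=False)


def read_roi_map(image_path, table_path) -> ROIMap:
    img = nib.load(str(image_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(table_path)
    if not {"label", "region"} <= set(table.columns):
        raise FormatError("ROI label table needs 'label' and 'region' columns")
    mapping = {int(r.label): str(r.region) for r in table.itertuples()}
    vs = tuple(float(v) for v in img.header.get_zooms()[:3])
    return ROIMap(labels, mapping, vs)


# --------------------------------------------------------------------------
# Blood tables and metadata
# --------------------------------------------------------------------------

def write_blood_tables(continuous: SampledCurve, discrete: DiscreteSampleTable,
                       continuous_csv, discrete_csv) -> None:
    pd.DataFrame({"time_s": continuous.time, "wholeblood_Bq_per_mL": continuous.value}
                 ).to_csv(continuous_csv, index=False, float_format="%.8g")
    pd.DataFrame({
        "time_s": discrete.time,
        "wholeblood_Bq_per_mL": discrete.wholeblood,
        "plasma_Bq_per_mL": discrete.plasma,
        "parent_fraction": discrete.parent_fraction,
    }).to_csv(discrete_csv, index=False, float_format="%.8g")


def read_blood_tables(continuous_csv, discrete_csv) -> tuple[SampledCurve, DiscreteSampleTable]:
    """Load the continuous whole-blood curve and the discrete sample table.

    Rows are sorted ascending in time; validation (monotonicity after the
    sort, nonnegative activities, parent fraction in [0, 1]) is enforced by
    the container types.
    """
    cont = pd.read_csv(continuous_csv)
    if not {"time_s", "wholeblood_Bq_per_mL"} <= set(cont.columns):
        raise FormatError("continuous table needs time_s and wholeblood_Bq_per_mL")
    if len(cont) == 0:
        raise ValidationError("empty continuous blood table")
    cont = cont.sort_values("time_s")
    continuous = SampledCurve(cont["time_s"].to_numpy(), cont["wholeblood_Bq_per_mL"].to_numpy())

    disc = pd.read_csv(discrete_csv)
    needed = {"time_s", "wholeblood_Bq_per_mL", "plasma_Bq_per_mL", "parent_fraction"}
    if not needed <= set(disc.columns):
        raise FormatError(f"discrete table needs columns {sorted(needed)}")
    disc = disc.sort_values("time_s")
    discrete = DiscreteSampleTable(
        disc["time_s"].to_numpy(), disc["wholeblood_Bq_per_mL"].to_numpy(),
        disc["plasma_Bq_per_mL"].to_numpy(), disc["parent_fraction"].to_numpy())
    return continuous, discrete


def write_participants(metas: list[ParticipantMeta], path) -> None:
    pd.DataFrame([{
        "id": m.id, "weight_kg": m.weight_kg, "injected_dose_MBq": m.injected_dose_mbq,
        "age_years": m.age_years, "subgroup": m.subgroup,
    } for m in metas]).to_csv(path, index=False, float_format="%.8g")


def read_participants(path) -> list[ParticipantMeta]:
    df = pd.read_csv(path)
    needed = {"id", "weight_kg", "injected_dose_MBq", "age_years", "subgroup"}
    if not needed <= set(df.columns):
        raise FormatError(f"participant table needs columns {sorted(needed)}")
    return [ParticipantMeta(str(r.id), float(r.weight_kg), float(r.injected_dose_MBq),
                            float(r.age_years), str(r.subgroup))
            for r in df.itertuples()]


def write_input_function(input_fn, path) -> None:
    pd.DataFrame({"time_s": input_fn.time, "Bq_per_mL": input_fn.values}
                 ).to_csv(path, index=False, float_format="%.8g")


def read_input_function(path, participant_id: str = "", provenance: str = "ppif"):
    from .curves import InputFunction
    df = pd.read_csv(path)
    if not {"time_s", "Bq_per_mL"} <= set(df.columns):
        raise FormatError("input-function CSV needs time_s and Bq_per_mL")
    t = df["time_s"].to_numpy(dtype=float)
    dts = np.diff(t)
    if t.size < 2 or not np.allclose(dts, dts[0]):
        raise FormatError("input-function grid must be uniform")
    return InputFunction(df["Bq_per_mL"].to_numpy(dtype=float), float(dts[0]),
                         participant_id, provenance)


def write_vt_volume(vt_vol: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(np.nan_to_num(vt_vol, nan=0.0).astype(np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))
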