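"""Readers/writers for the external formats of the pipeline.

Trace tables go to HDF5 (one dataset per channel, markers as attributes) or
CSV with the column convention ``time_s, dc_e1_mV, ion_e1_mV, dc_e2_mV,
ion_e2_mV, ldf_au`` (markers in a JSON sidecar); imaging stacks to
multi-page TIFF; MRI volumes and masks to NIfTI; events, stereology tables
and ground truth to CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .ephys import MultimodalRecording, SDEvent, SeizureEvent
from .imaging import FrameStack
from .lesion_mri import MRIVolume

TRACE_COLUMNS = ("time_s", "dc_e1_mV", "ion_e1_mV", "dc_e2_mV", "ion_e2_mV", "ldf_au")


def _markers(rec: MultimodalRecording) -> dict:
    return {
        "pt_time_s": rec.pt_time_s,
        "fourap_time_s": rec.fourap_time_s,
        "dye_injection_times_s": list(rec.dye_injection_times_s),
        "electrode_distance_to_border_um": list(rec.electrode_distance_to_border_um),
    }


def write_traces_h5(rec: MultimodalRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=rec.time_s)
        f.create_dataset("ecog_mV", data=rec.ecog_mV)
        f.create_dataset("ion_mV", data=rec.ion_mV)
        f.create_dataset("ldf_au", data=rec.ldf_au)
        for key, val in _markers(rec).items():
            if val is not None:
                f.attrs[key] = val


def read_traces_h5(path: str | Path) -> MultimodalRecording:
    with h5py.File(path, "r") as f:
        kwargs = {
            "time_s": f["time_s"][...],
            "ecog_mV": f["ecog_mV"][...],
            "ion_mV": f["ion_mV"][...],
            "ldf_au": f["ldf_au"][...],
        }
        for key in ("pt_time_s", "fourap_time_s"):
            if key in f.attrs:
                kwargs[key] = float(f.attrs[key])
        if "dye_injection_times_s" in f.attrs:
            kwargs["dye_injection_times_s"] = tuple(f.attrs["dye_injection_times_s"])
        if "electrode_distance_to_border_um" in f.attrs:
            kwargs["electrode_distance_to_border_um"] = tuple(
                f.attrs["electrode_distance_to_border_um"]
            )
    return MultimodalRecording(**kwargs)


def write_traces_csv(rec: MultimodalRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "dc_e1_mV": rec.ecog_mV[0],
            "ion_e1_mV": rec.ion_mV[0],
            "dc_e2_mV": rec.ecog_mV[1] if rec.n_electrodes > 1 else np.nan,
            "ion_e2_mV": rec.ion_mV[1] if rec.n_electrodes > 1 else np.nan,
            "ldf_au": rec.ldf_au,
        }
    )
    df.to_csv(path, index=False)
    Path(str(path) + ".markers.json").write_text(json.dumps(_markers(rec), indent=2))


def read_traces_csv(path: str | Path) -> MultimodalRecording:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table misses columns: {sorted(missing)}")
    markers: dict = {}
    sidecar = Path(str(path) + ".markers.json")
    if sidecar.exists():
        markers = json.loads(sidecar.read_text())
    return MultimodalRecording(
        time_s=df["time_s"].to_numpy(),
        ecog_mV=np.vstack([df["dc_e1_mV"], df["dc_e2_mV"]]),
        ion_mV=np.vstack([df["ion_e1_mV"], df["ion_e2_mV"]]),
        ldf_au=df["ldf_au"].to_numpy(),
        pt_time_s=markers.get("pt_time_s"),
        fourap_time_s=markers.get("fourap_time_s"),
        dye_injection_times_s=tuple(markers.get("dye_injection_times_s", ())),
        electrode_distance_to_border_um=tuple(
            markers.get("electrode_distance_to_border_um", (340.0, 870.0))
        ),
    )


def events_to_frame(sds: list[SDEvent], seizures: list[SeizureEvent]) -> pd.DataFrame:
    rows = []
    for ev in sds:
        rows.append(
            {
                "kind": "sd",
                "onset_s": ev.onset_s,
                "end_s": ev.onset_s + ev.duration_s,
                "dc_amp_mV": ev.dc_amp_mV,
                "k_peak_mM": ev.k_peak_mM,
                "duration_s": ev.duration_s,
                "k_recovery_s": ev.k_recovery_s,
                "class": ev.sd_class,
                "direction": ev.direction,
            }
        )
    for sz in seizures:
        rows.append(
            {
                "kind": "seizure",
                "onset_s": sz.start_s,
                "end_s": sz.end_s,
                "dc_amp_mV": sz.dc_shift_mV,
                "k_peak_mM": sz.k_peak_mM,
                "duration_s": sz.duration_s,
                "power_mV2s": sz.power_mV2s,
                "interrupted_by_sd": sz.interrupted_by_sd,
            }
        )
    return pd.DataFrame(rows)


def write_stack_tiff(stack: FrameStack, path: str | Path) -> None:
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={
            "frame_rate_hz": stack.frame_rate_hz,
            "injection_frame_index": stack.injection_frame_index,
            "pixel_size_um": stack.pixel_size_um,
            "timepoint_label": stack.timepoint_label,
            "modality": stack.modality,
        },
    )


def read_stack_tiff(path: str | Path, **overrides) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    kwargs = {
        k: meta[k]
        for k in (
            "frame_rate_hz",
            "injection_frame_index",
            "pixel_size_um",
            "timepoint_label",
            "modality",
        )
        if k in meta
    }
    kwargs.update(overrides)
    return FrameStack(frames=frames, **kwargs)


def write_mri_nifti(vol: MRIVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_mri_nifti(path: str | Path, **kwargs) -> MRIVolume:
    img = nib.load(str(path))
    voxes = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MRIVolume(data=np.asanyarray(img.dataobj), voxel_size_mm=voxes, **kwargs)


def write_mask_nifti(mask: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_slices_csv(path: str | Path):
    """Histology counting table: slice_id, x_um, y_um, injured."""
    from shapely.geometry import box

    from .stereology import SliceSample

    df = pd.read_csv(path)
    needed = {"slice_id", "x_um", "y_um", "injured"}
    if not needed <= set(df.columns):
        raise ValueError(f"slice table requires columns {sorted(needed)}")
    slices = []
    for _, sub in df.groupby("slice_id"):
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        pad = 1.0
        roi = box(
            pts[:, 0].min() - pad, pts[:, 1].min() - pad,
            pts[:, 0].max() + pad, pts[:, 1].max() + pad,
        )
        slices.append(
            SliceSample(roi=roi, points_um=pts, injured=sub["injured"].to_numpy(dtype=bool))
        )
    return slices


def write_slices_csv(slices, path: str | Path) -> None:
    rows = []
    for i, sl in enumerate(slices):
        for (x, y), inj in zip(sl.points_um, sl.injured):
            rows.append({"slice_id": i, "x_um": x, "y_um": y, "injured": bool(inj)})
    pd.DataFrame(rows).to_csv(path, index=False)


def dataclass_to_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(obj), indent=2, default=str))
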