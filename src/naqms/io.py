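"""File interfaces: FID JSON records, CSV series and tables, NIfTI
images, and YAML study configuration.

FIDs travel as JSON objects ``{"metadata": {...}, "real": [...],
"imag": [...]}``; echo and dynamic series as headed CSV; images and
masks as NIfTI via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicSeries
from .spectro_fit import EchoAmplitudeSeries, Fid
from .synthetic_data import AcquisitionTimeline, CohortSpec

__all__ = [
    "save_fid_json", "load_fid_json",
    "save_echo_series_csv", "load_echo_series_csv",
    "save_dynamic_series_csv", "load_dynamic_series_csv",
    "save_nifti", "load_nifti",
    "load_study_config", "cohort_spec_from_config",
]


def save_fid_json(fid: Fid, path) -> None:
    meta = {"dwell_ms": fid.dwell, "t0_ms": fid.t0, "nucleus": fid.nucleus}
    if fid.voxel_dims is not None:
        meta["voxel_dims_mm"] = list(fid.voxel_dims)
    if fid.timestamp is not None:
        meta["timestamp_s"] = fid.timestamp
    record = {"metadata": meta,
              "real": fid.samples.real.tolist(),
              "imag": fid.samples.imag.tolist()}
    Path(path).write_text(json.dumps(record))


def load_fid_json(path) -> Fid:
    record = json.loads(Path(path).read_text())
    meta = record["metadata"]
    samples = np.asarray(record["real"]) + 1j * np.asarray(record["imag"])
    vox = meta.get("voxel_dims_mm")
    return Fid(samples=samples, dwell=float(meta["dwell_ms"]),
               t0=float(meta.get("t0_ms", 0.0)),
               nucleus=meta.get("nucleus", "23Na"),
               voxel_dims=tuple(vox) if vox else None,
               timestamp=meta.get("timestamp_s"))


def save_echo_series_csv(series: EchoAmplitudeSeries, path) -> None:
    pd.DataFrame({"te_ms": series.echo_times,
                  "amplitude": series.amplitudes}).to_csv(path, index=False)


def load_echo_series_csv(path, source: str = "synthetic") -> EchoAmplitudeSeries:
    df = pd.read_csv(path)
    return EchoAmplitudeSeries(echo_times=df["te_ms"].to_numpy(),
                               amplitudes=df["amplitude"].to_numpy(),
                               source=source)


def save_dynamic_series_csv(series: DynamicSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.timestamps, "value": series.values})
    df["modality"] = series.modality
    df["baseline_value"] = series.baseline_value
    df["subject_id"] = series.subject_id
    df["group"] = series.group
    df.to_csv(path, index=False)


def load_dynamic_series_csv(path) -> DynamicSeries:
    df = pd.read_csv(path)
    sid = df["subject_id"].iloc[0] if "subject_id" in df else None
    return DynamicSeries(
        timestamps=df["time_s"].to_numpy(), values=df["value"].to_numpy(),
        modality=str(df["modality"].iloc[0]),
        baseline_value=float(df["baseline_value"].iloc[0]),
        subject_id=None if pd.isna(sid) else str(sid),
        group=str(df["group"].iloc[0]) if "group" in df else None)


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def load_study_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def cohort_spec_from_config(config: dict, seed: int | None = None) -> CohortSpec:
    """Build a CohortSpec from a study config's ``cohort:`` block.

    Recognised keys: n_per_group, seed, timeline (na_scan_duration,
    h_scan_duration, n_cycles, post_exercise_span), group_params
    (group -> field -> [mean, sd]), render, noise.  ``seed`` overrides
    the config value (the command-line style ``--seed`` hook).
    """
    block = config.get("cohort", {})
    kwargs = {}
    if "n_per_group" in block:
        kwargs["n_per_group"] = int(block["n_per_group"])
    kwargs["seed"] = int(seed if seed is not None else block.get("seed", 0))
    if "timeline" in block:
        kwargs["timeline"] = AcquisitionTimeline(**block["timeline"])
    if "render" in block:
        kwargs["render"] = bool(block["render"])
    if "noise" in block:
        kwargs["noise"] = dict(block["noise"])
    spec = CohortSpec(**kwargs)
    if "group_params" in block:
        for group, params in block["group_params"].items():
            for name, pair in params.items():
                spec.group_params[group][name] = (float(pair[0]), float(pair[1]))
    return spec
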