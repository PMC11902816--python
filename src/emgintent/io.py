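"""Trial persistence: one CSV per recording (time_ms, ch1..ch6), an
optional HDF5 container, and a JSON sidecar manifest listing every trial
with its label and ground-truth onsets."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import h5py
import numpy as np
import pandas as pd

from .types import (
    N_CHANNELS,
    SAMPLE_RATE_HZ,
    EMGTrial,
    MotionClass,
    TrialGroundTruth,
)

MANIFEST_NAME = "manifest.json"


def _gt_dict(gt: Optional[TrialGroundTruth]) -> Optional[dict]:
    if gt is None:
        return None
    return {
        "electrical_onsets_ms": gt.electrical_onsets_ms.tolist(),
        "electrical_offsets_ms": gt.electrical_offsets_ms.tolist(),
        "emd_ms": gt.emd_ms.tolist(),
        "kinematic_onsets_ms": gt.kinematic_onsets_ms.tolist(),
        "preactivation_lead_ms": gt.preactivation_lead_ms,
    }


def _gt_from_dict(d: Optional[dict]) -> Optional[TrialGroundTruth]:
    if d is None:
        return None
    return TrialGroundTruth(
        np.array(d["electrical_onsets_ms"]),
        np.array(d["electrical_offsets_ms"]),
        np.array(d["emd_ms"]),
        np.array(d["kinematic_onsets_ms"]),
        d.get("preactivation_lead_ms", 0.0),
    )


def write_trial_csv(trial: EMGTrial, path: Union[str, Path]) -> None:
    t_ms = np.arange(trial.n_samples) * 1000.0 / SAMPLE_RATE_HZ
    df = pd.DataFrame({"time_ms": t_ms})
    for c in range(N_CHANNELS):
        df[f"ch{c + 1}"] = trial.samples[c]
    df.to_csv(path, index=False, float_format="%.6g")


def read_trial_csv(
    path: Union[str, Path],
    subject_id: str,
    label: MotionClass,
    ground_truth: Optional[TrialGroundTruth] = None,
    trial_id: str = "",
) -> EMGTrial:
    df = pd.read_csv(path)
    samples = np.vstack([df[f"ch{c + 1}"].to_numpy() for c in range(N_CHANNELS)])
    return EMGTrial(
        subject_id=subject_id,
        label=label,
        samples=samples,
        ground_truth=ground_truth,
        trial_id=trial_id or Path(path).stem,
    )


def write_dataset(
    trials: List[EMGTrial], out_dir: Union[str, Path], fmt: str = "csv"
) -> Path:
    """Write all trials plus the sidecar manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    if fmt == "hdf5":
        with h5py.File(out / "trials.h5", "w") as h5:
            for trial in trials:
                g = h5.create_group(trial.trial_id)
                g.create_dataset("samples", data=trial.samples)
                g.attrs["subject_id"] = trial.subject_id
                g.attrs["motion_type"] = trial.label.motion_type
                g.attrs["magnitude"] = trial.label.magnitude
                if trial.ground_truth is not None:
                    g.attrs["ground_truth"] = json.dumps(_gt_dict(trial.ground_truth))
    for trial in trials:
        entry = {
            "trial_id": trial.trial_id,
            "subject_id": trial.subject_id,
            "motion_type": trial.label.motion_type,
            "magnitude": trial.label.magnitude,
            "ground_truth": _gt_dict(trial.ground_truth),
        }
        if fmt == "csv":
            fname = f"{trial.trial_id}.csv"
            write_trial_csv(trial, out / fname)
            entry["file"] = fname
        else:
            entry["file"] = "trials.h5"
        entries.append(entry)
    manifest = out / MANIFEST_NAME
    manifest.write_text(json.dumps({"format": fmt, "trials": entries}, indent=1))
    return manifest


def read_dataset(in_dir: Union[str, Path]) -> List[EMGTrial]:
    """Read back every trial listed in a directory's manifest."""
    root = Path(in_dir)
    meta = json.loads((root / MANIFEST_NAME).read_text())
    trials = []
    h5 = h5py.File(root / "trials.h5", "r") if meta["format"] == "hdf5" else None
    try:
        for entry in meta["trials"]:
            label = MotionClass(entry["motion_type"], entry["magnitude"])
            gt = _gt_from_dict(entry["ground_truth"])
            if meta["format"] == "csv":
                trials.append(
                    read_trial_csv(
                        root / entry["file"],
                        entry["subject_id"],
                        label,
                        gt,
                        entry["trial_id"],
                    )
                )
            else:
                samples = h5[entry["trial_id"]]["samples"][()]
                trials.append(
                    EMGTrial(
                        subject_id=entry["subject_id"],
                        label=label,
                        samples=samples,
                        ground_truth=gt,
                        trial_id=entry["trial_id"],
                    )
                )
    finally:
        if h5 is not None:
            h5.close()
    return trials
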