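"""Core data container for parcellated multichannel time series.

A recording is a ``channels x time`` real matrix with a sampling rate and an
optional group label (e.g. patient vs control).  This is the only ingestion
surface of the package: any source-reconstruction toolchain can export to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class SubjectTimeSeries:
    """One subject's parcellated recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array.
    fs
        Sampling rate in Hz.
    subject_id
        Unique identifier within a cohort.
    group
        Optional group label (``"A"``/``"B"`` for the two-group designs).
    """

    data: np.ndarray
    fs: float
    subject_id: str = "s0"
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "SubjectTimeSeries":
        return replace(self, data=self.data.copy())

    def standardized(self) -> "SubjectTimeSeries":
        """Return a copy with every channel z-scored (mean 0, variance 1)."""
        mu = self.data.mean(axis=1, keepdims=True)
        sd = self.data.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        return replace(self, data=(self.data - mu) / sd)


def save_cohort_hdf5(path: str | Path, subjects: list[SubjectTimeSeries],
                     ground_truth=None, spec_json: str | None = None) -> None:
    """Persist a cohort (and optionally its ground truth) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("subjects")
        for ts in subjects:
            g = grp.create_group(ts.subject_id)
            g.create_dataset("data", data=ts.data)
            g.attrs["fs"] = ts.fs
            if ts.group is not None:
                g.attrs["group"] = ts.group
        if ground_truth is not None:
            gt = f.create_group("ground_truth")
            for sid, path_arr in ground_truth.state_paths.items():
                g = gt.create_group(sid)
                g.create_dataset("state_path", data=np.asarray(path_arr))
                g.create_dataset(
                    "flips", data=np.asarray(ground_truth.applied_flips[sid]))
        if spec_json is not None:
            f.attrs["cohort_spec"] = spec_json


def load_cohort_hdf5(path: str | Path):
    """Load subjects (and ground truth if present) written by
    :func:`save_cohort_hdf5`.  Returns ``(subjects, ground_truth_or_None)``."""
    from .simulate import GroundTruth

    subjects = []
    gt = None
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            subjects.append(SubjectTimeSeries(
                data=g["data"][()], fs=float(g.attrs["fs"]),
                subject_id=sid,
                group=g.attrs.get("group", None)))
        if "ground_truth" in f:
            paths = {}
            flips = {}
            for sid in f["ground_truth"]:
                g = f["ground_truth"][sid]
                paths[sid] = g["state_path"][()]
                flips[sid] = g["flips"][()]
            gt = GroundTruth(state_paths=paths, applied_flips=flips,
                             effect_manifest=[])
    return subjects, gt


def cohort_to_csv(path: str | Path, subjects: list[SubjectTimeSeries]) -> None:
    """Long-format CSV export: subject, channel, sample, value."""
    frames = []
    for ts in subjects:
        c, t = np.meshgrid(np.arange(ts.n_channels), np.arange(ts.n_samples),
                           indexing="ij")
        frames.append(pd.DataFrame({
            "subject": ts.subject_id,
            "channel": c.ravel(),
            "sample": t.ravel(),
            "value": ts.data.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
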