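"""Readers and writers for the package's on-disk formats.

Signals and tracks travel as plain CSV (and optionally HDF5 groups); models
and fitted distributions as JSON; detections as long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .delay_dist import ShiftedGamma
from .synthetic_data import DetectionFrames, Signal, TransferFunctionModel
from .tracking3d import Track3D

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_track_csv",
    "read_track_csv",
    "write_detections_csv",
    "write_model_json",
    "read_model_json",
    "write_dist_json",
    "read_dist_json",
    "write_trajectory_h5",
    "read_trajectory_h5",
]


def write_signal_csv(sig: Signal, path) -> None:
    pd.DataFrame({"t": sig.t, "value": sig.samples}).to_csv(path, index=False)


def read_signal_csv(path) -> Signal:
    df = pd.read_csv(path)
    for col in ("t", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV missing required column {col!r}")
    t = df["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return Signal(samples=df["value"].to_numpy(), fs=fs, t0=float(t[0]))


def write_track_csv(track: Track3D, path) -> None:
    pd.DataFrame(
        {
            "t": track.t,
            "x": track.positions[:, 0],
            "y": track.positions[:, 1],
            "z": track.positions[:, 2],
            "valid": track.valid.astype(int),
            "imputed": track.imputed.astype(int),
            "label": track.label,
        }
    ).to_csv(path, index=False)


def read_track_csv(path) -> Track3D:
    df = pd.read_csv(path)
    for col in ("t", "x", "y", "z", "valid"):
        if col not in df.columns:
            raise ValueError(f"track CSV missing required column {col!r}")
    return Track3D(
        t=df["t"].to_numpy(),
        positions=df[["x", "y", "z"]].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        label=int(df["label"].iloc[0]) if "label" in df.columns else 0,
        imputed=df["imputed"].to_numpy().astype(bool) if "imputed" in df.columns else None,
    )


def write_detections_csv(frames: DetectionFrames, path) -> None:
    rows = []
    for k, tk in enumerate(frames.t):
        for c in range(frames.n_cameras):
            pts = frames.points[k][c]
            ids = frames.truth_ids[k][c]
            for p, i in zip(pts, ids):
                rows.append((tk, c, p[0], p[1], i))
    pd.DataFrame(rows, columns=["t", "camera", "u", "v", "truth_id"]).to_csv(
        path, index=False
    )


def write_model_json(model: TransferFunctionModel, criteria, path) -> None:
    payload = {
        "num": list(map(float, model.num)),
        "den": list(map(float, model.den)),
        "delay_s": float(model.tau),
        "delay_kind": model.delay_kind,
    }
    if criteria is not None:
        payload["criteria"] = {
            "fit_percent": criteria.fit_percent,
            "mse": criteria.mse,
            "fpe": criteria.fpe,
            "n_poles": criteria.n_poles,
            "n_zeros": criteria.n_zeros,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model_json(path) -> TransferFunctionModel:
    d = json.loads(Path(path).read_text())
    return TransferFunctionModel(
        num=d["num"], den=d["den"], delay_kind=d["delay_kind"], tau=d["delay_s"]
    )


def write_dist_json(dist: ShiftedGamma, path, diagnostics: dict | None = None) -> None:
    payload = {"m": dist.m, "a": dist.a, "tau_m": dist.tau_m, "unit": dist.unit}
    if diagnostics:
        payload["diagnostics"] = diagnostics
    Path(path).write_text(json.dumps(payload, indent=2))


def read_dist_json(path) -> ShiftedGamma:
    d = json.loads(Path(path).read_text())
    return ShiftedGamma(m=d["m"], a=d["a"], tau_m=d["tau_m"], unit=d.get("unit", "ms"))


def write_trajectory_h5(traj, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.t)
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("delays", data=traj.delays.tau)
        f.attrs["alpha"] = traj.params.alpha
        f.attrs["beta"] = traj.params.beta
        f.attrs["B_r"] = traj.params.B_r
        f.attrs["D_r"] = traj.params.D_r
        f.attrs["delay_mode"] = traj.delays.mode
        f.attrs["diverged"] = traj.diverged


def read_trajectory_h5(path):
    import h5py

    from .swarm_dde import DelayMatrix, SwarmParams, SwarmTrajectory

    with h5py.File(path, "r") as f:
        pos = f["positions"][()]
        params = SwarmParams(
            alpha=float(f.attrs["alpha"]),
            beta=float(f.attrs["beta"]),
            B_r=float(f.attrs["B_r"]),
            D_r=float(f.attrs["D_r"]),
            N=pos.shape[1],
        )
        return SwarmTrajectory(
            t=f["t"][()],
            positions=pos,
            params=params,
            delays=DelayMatrix(tau=f["delays"][()], mode=str(f.attrs["delay_mode"])),
            diverged=bool(f.attrs["diverged"]),
        )
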