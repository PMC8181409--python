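"""Delimited-text and HDF5 persistence.

Time series travel as tab-separated text with one header row (``t`` plus
value columns; complex channels as ``*_re``/``*_im`` pairs) and ``#``
comment lines carrying generator provenance.  Learned weights and trained
reservoirs are stored as small structured text files.  Large trajectories
can be written to HDF5.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import Trajectory
from .coupling import SolutionMap
from .generative import MultichannelTarget, ReadoutWeights
from .reservoir import TeachingSignal, TrainedReservoir

PathLike = Union[str, Path]
_REL_JITTER = 1e-9


def write_timeseries(obj, path: PathLike) -> None:
    """Write a TeachingSignal or MultichannelTarget as delimited text."""
    path = Path(path)
    if isinstance(obj, TeachingSignal):
        t = obj.t
        if obj.is_complex:
            df = pd.DataFrame({"t": t, "value_re": obj.samples.real,
                               "value_im": obj.samples.imag})
        else:
            df = pd.DataFrame({"t": t, "value": obj.samples})
        meta = obj.meta
    elif isinstance(obj, MultichannelTarget):
        t = np.arange(obj.Y.shape[0]) * obj.dt
        df = pd.DataFrame({"t": t})
        for m in range(obj.M):
            df[f"ch{m + 1}"] = obj.Y[:, m]
        meta = obj.meta
    else:
        raise TypeError("expected TeachingSignal or MultichannelTarget")
    with path.open("w") as fh:
        header = {k: v for k, v in meta.items() if k in ("seed", "band", "domain")}
        if header:
            fh.write("# " + json.dumps(header, default=str) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_timeseries(path: PathLike):
    """Read delimited text back into a TeachingSignal (1 channel, real or
    complex) or MultichannelTarget (several channels).

    The time grid must be uniform to within a relative jitter of 1e-9; the
    first offending row is named otherwise.  A missing header row is a
    format error.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].strip().split("\t")
    if header[0] != "t":
        raise ValueError(f"{path}: missing header row (expected first column 't')")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = t[1] - t[0]
    steps = np.diff(t)
    bad = np.where(np.abs(steps - dt) > _REL_JITTER * max(abs(dt), 1.0))[0]
    if bad.size:
        raise ValueError(f"{path}: non-uniform time grid at row {bad[0] + 3}")
    cols = [c for c in df.columns if c != "t"]
    if cols == ["value"]:
        return TeachingSignal(samples=df["value"].to_numpy(), dt=float(dt))
    if cols == ["value_re", "value_im"]:
        z = df["value_re"].to_numpy() + 1j * df["value_im"].to_numpy()
        return TeachingSignal(samples=z, dt=float(dt))
    Y = df[cols].to_numpy()
    return MultichannelTarget(Y=Y, dt=float(dt))


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    """Trajectory as delimited text (columns t, r_k, phi_k, ...)."""
    traj.to_frame().to_csv(path, sep="\t", index=False)


def write_trajectory_h5(traj: Trajectory, path: PathLike) -> None:
    """Trajectory in a simple hierarchical binary container (HDF5)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for name in ("t", "r", "phi", "omega", "theta", "A", "alpha",
                     "output", "error", "epoch_error"):
            arr = getattr(traj, name)
            if arr is not None:
                h5.create_dataset(name, data=np.asarray(arr))
        h5.attrs["dt"] = traj.dt


def write_weights(A: np.ndarray, theta: np.ndarray, path: PathLike) -> None:
    """Learned lateral weights as rows (i, j, A_ij, theta_ij)."""
    rows = []
    N = A.shape[0]
    for i in range(N):
        for j in range(N):
            if i != j and A[i, j] != 0.0:
                rows.append((i, j, A[i, j], theta[i, j]))
    pd.DataFrame(rows, columns=["i", "j", "A", "theta"]).to_csv(
        path, sep="\t", index=False)


def read_weights(path: PathLike, N: int):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    A = np.zeros((N, N))
    th = np.zeros((N, N))
    for _, row in df.iterrows():
        A[int(row.i), int(row.j)] = row.A
        th[int(row.i), int(row.j)] = row.theta
    return A, th


def write_reservoir(trained: TrainedReservoir, path: PathLike) -> None:
    """TrainedReservoir as one structured text file."""
    path = Path(path)
    payload = {
        "mode": trained.mode,
        "mu": trained.mu,
        "dt": trained.dt,
        "init_r": trained.init_r,
        "init_phi": trained.init_phi,
        "omegas": trained.omegas.tolist(),
        "alphas": trained.alphas.tolist(),
        "A": trained.A.tolist(),
        "theta": trained.theta.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))


def read_reservoir(path: PathLike) -> TrainedReservoir:
    payload = json.loads(Path(path).read_text())
    return TrainedReservoir(
        omegas=np.array(payload["omegas"]), alphas=np.array(payload["alphas"]),
        A=np.array(payload["A"]), theta=np.array(payload["theta"]),
        mode=payload["mode"], mu=payload["mu"], dt=payload["dt"],
        init_r=payload["init_r"], init_phi=payload["init_phi"])


def write_readout(readout: ReadoutWeights, path: PathLike) -> None:
    """ReadoutWeights as rows (i, j, K, zeta)."""
    M, N = readout.K.shape
    rows = [(i, j, readout.K[i, j], readout.zeta[i, j])
            for i in range(M) for j in range(N)]
    pd.DataFrame(rows, columns=["i", "j", "K", "zeta"]).to_csv(
        path, sep="\t", index=False)


def read_readout(path: PathLike) -> ReadoutWeights:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    M = int(df.i.max()) + 1
    N = int(df.j.max()) + 1
    K = np.zeros((M, N))
    zeta = np.zeros((M, N))
    for _, row in df.iterrows():
        K[int(row.i), int(row.j)] = row.K
        zeta[int(row.i), int(row.j)] = row.zeta
    return ReadoutWeights(K=K, zeta=zeta)


def write_solution_map(sol: SolutionMap, path: PathLike,
                       report_path: PathLike = None) -> None:
    """SolutionMap as one row per grid point (phases..., sigma or NA),
    plus an optional cluster-summary report file."""
    N = sol.points.shape[1]
    df = pd.DataFrame(sol.points, columns=[f"phi{k + 1}_0" for k in range(N)])
    df["sigma"] = ["NA" if not np.isfinite(s) else repr(float(s)) for s in sol.sigma]
    df.to_csv(path, sep="\t", index=False)
    if report_path is not None:
        if sol.solutions is None:
            sol.cluster()
        rep = pd.DataFrame({"solution": sol.solutions, "count": sol.counts})
        rep.to_csv(report_path, sep="\t", index=False)


def provenance_record(config: dict, seed) -> dict:
    """Provenance sufficient to reproduce a run bit-for-bit."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"version": __version__, "seed": seed,
            "config_hash": hashlib.sha256(blob).hexdigest(), "config": config}


def write_provenance(config: dict, seed, path: PathLike) -> None:
    Path(path).write_text(json.dumps(provenance_record(config, seed), indent=1,
                                     default=str))
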