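"""On-disk layout for simulated sessions.

* trial table -> CSV (trial, type, direction, ssd_ms, rt_ms, outcome)
* signals -> HDF5 groups ``/emg/<trial>/<muscle>`` and ``/eeg/<trial>``,
  with ``fs`` and ``t0`` stored as attributes
* ground truth -> JSON records
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .emg import EmgTrace
from .eeg import EegEpoch


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_json(truth: pd.DataFrame, path) -> None:
    recs = truth.replace({np.nan: None}).to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(recs, fh)


def read_truth_json(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))


def write_signals_h5(path, emg: dict[int, dict[str, EmgTrace]] | None = None,
                     eeg: dict[int, EegEpoch] | None = None) -> None:
    with h5py.File(path, "w") as fh:
        if emg:
            g = fh.create_group("emg")
            for trial, muscles in emg.items():
                gt = g.create_group(str(trial))
                for muscle, trace in muscles.items():
                    ds = gt.create_dataset(muscle, data=trace.samples)
                    ds.attrs["fs"] = trace.fs
                    ds.attrs["t0"] = trace.t0
        if eeg:
            g = fh.create_group("eeg")
            for trial, epoch in eeg.items():
                ds = g.create_dataset(str(trial), data=epoch.samples)
                ds.attrs["fs"] = epoch.fs
                ds.attrs["t0"] = epoch.t_start_ms
                if epoch.injected_burst_ms is not None:
                    ds.attrs["injected_burst_ms"] = epoch.injected_burst_ms


def read_signals_h5(path):
    """Returns (emg, eeg) mappings mirroring :func:`write_signals_h5`."""
    emg: dict[int, dict[str, EmgTrace]] = {}
    eeg: dict[int, EegEpoch] = {}
    with h5py.File(path, "r") as fh:
        if "emg" in fh:
            for trial, gt in fh["emg"].items():
                emg[int(trial)] = {}
                for muscle, ds in gt.items():
                    emg[int(trial)][muscle] = EmgTrace(
                        samples=ds[()], fs=float(ds.attrs["fs"]),
                        t0=float(ds.attrs["t0"]), muscle=muscle, trial=int(trial))
        if "eeg" in fh:
            for trial, ds in fh["eeg"].items():
                eeg[int(trial)] = EegEpoch(
                    samples=ds[()], fs=float(ds.attrs["fs"]),
                    t_start_ms=float(ds.attrs["t0"]), trial=int(trial),
                    injected_burst_ms=float(ds.attrs["injected_burst_ms"])
                    if "injected_burst_ms" in ds.attrs else None)
    return emg, eeg


def save_session(out_dir, trials, truth, emg=None, eeg=None, mep=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials_csv(trials, out / "trials.csv")
    write_truth_json(truth, out / "truth.json")
    if emg is not None or eeg is not None:
        write_signals_h5(out / "signals.h5", emg=emg, eeg=eeg)
    if mep is not None:
        mep.to_csv(out / "meps.csv", index=False)
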