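"""Sweep-bundle file format: HDF5 primary, NPZ fallback.

A bundle stores one :class:`~synquant.events.SweepSet`: a float32
``traces`` dataset (sweeps x samples) with a units attribute, the sampling
rate, stimulus times, per-sweep timestamps, and string metadata (genotype,
connection id, clamp mode, polarity, protocol tag). Reads are
schema-validated and report the offending field on failure.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .events import SweepSet

__all__ = ["write_bundle", "read_bundle"]

_REQUIRED_DATASETS = ("traces", "stim_times", "sweep_timestamps")
_REQUIRED_ATTRS = ("sample_rate", "clamp_mode", "polarity", "units")


def write_bundle(path: str, sweeps: SweepSet, units: str | None = None) -> None:
    """Write a sweep set to ``path`` (.h5/.hdf5 for HDF5, .npz for NPZ)."""
    units = units or sweeps.metadata.get(
        "units", "pA" if sweeps.clamp_mode == "voltage" else "mV")
    ext = os.path.splitext(path)[1].lower()
    meta = {k: v for k, v in sweeps.metadata.items() if k != "units"}
    if ext == ".npz":
        np.savez(path, traces=sweeps.traces.astype(np.float32),
                 stim_times=sweeps.stim_times,
                 sweep_timestamps=sweeps.sweep_timestamps,
                 sample_rate=sweeps.sample_rate,
                 clamp_mode=sweeps.clamp_mode, polarity=sweeps.polarity,
                 units=units,
                 meta_keys=np.array(list(meta), dtype=object),
                 meta_values=np.array([str(v) for v in meta.values()],
                                      dtype=object))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=sweeps.traces.astype(np.float32))
        f.create_dataset("stim_times", data=sweeps.stim_times)
        f.create_dataset("sweep_timestamps", data=sweeps.sweep_timestamps)
        f.attrs["sample_rate"] = sweeps.sample_rate
        f.attrs["clamp_mode"] = sweeps.clamp_mode
        f.attrs["polarity"] = sweeps.polarity
        f.attrs["units"] = units
        for k, v in meta.items():
            f.attrs[f"meta_{k}"] = str(v)


def read_bundle(path: str) -> SweepSet:
    """Read and validate a sweep bundle; raises with the missing field name."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".npz":
        with np.load(path, allow_pickle=True) as f:
            for name in _REQUIRED_DATASETS + ("sample_rate", "clamp_mode",
                                              "polarity", "units"):
                if name not in f:
                    raise ValueError(f"bundle missing field {name!r}")
            meta = dict(zip(f["meta_keys"].tolist(),
                            f["meta_values"].tolist()))
            meta["units"] = str(f["units"])
            return SweepSet(traces=np.asarray(f["traces"], float),
                            sample_rate=float(f["sample_rate"]),
                            stim_times=f["stim_times"],
                            sweep_timestamps=f["sweep_timestamps"],
                            clamp_mode=str(f["clamp_mode"]),
                            polarity=int(f["polarity"]), metadata=meta)
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise ValueError(f"bundle missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise ValueError(f"bundle missing attribute {name!r}")
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        meta["units"] = f.attrs["units"]
        return SweepSet(traces=np.asarray(f["traces"], float),
                        sample_rate=float(f.attrs["sample_rate"]),
                        stim_times=np.asarray(f["stim_times"]),
                        sweep_timestamps=np.asarray(f["sweep_timestamps"]),
                        clamp_mode=str(f.attrs["clamp_mode"]),
                        polarity=int(f.attrs["polarity"]), metadata=meta)
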