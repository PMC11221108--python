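"""Persistence helpers: HDF5 stores for DTOF series, CSV exports."""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .acquisition import DTOFSeries
from .forward_models import ReflectanceCurve, TimeGrid

__all__ = [
    "save_dtof_series",
    "load_dtof_series",
    "curve_to_csv",
    "spectrum_to_csv",
]


def save_dtof_series(path, series: DTOFSeries, group: Optional[str] = None) -> None:
    """Write one DTOF series (counts + provenance) into an HDF5 group.

    The group defaults to ``wl<wavelength>_sdd<sdd>``; existing groups of
    the same name are replaced.
    """
    name = group or f"wl{series.wavelength:g}_sdd{series.sdd:g}"
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("counts", data=series.counts, compression="gzip")
        g.create_dataset("frame_times", data=series.frame_times)
        g.create_dataset("baseline_expectation", data=series.baseline_expectation)
        g.attrs["t_start"] = series.time_grid.t_start
        g.attrs["t_end"] = series.time_grid.t_end
        g.attrs["dt"] = series.time_grid.dt
        g.attrs["wavelength"] = series.wavelength
        g.attrs["sdd"] = series.sdd
        g.attrs["n_tot_avg"] = series.n_tot_avg
        g.attrs["meta"] = json.dumps(series.meta, default=str)


def load_dtof_series(path, group: str) -> DTOFSeries:
    with h5py.File(path, "r") as f:
        g = f[group]
        grid = TimeGrid(g.attrs["t_start"], g.attrs["t_end"], g.attrs["dt"])
        return DTOFSeries(
            counts=g["counts"][...],
            time_grid=grid,
            frame_times=g["frame_times"][...],
            wavelength=float(g.attrs["wavelength"]),
            sdd=float(g.attrs["sdd"]),
            n_tot_avg=float(g.attrs["n_tot_avg"]),
            baseline_expectation=g["baseline_expectation"][...],
            meta=json.loads(g.attrs["meta"]),
        )


def curve_to_csv(path, curve: ReflectanceCurve) -> None:
    """Plain (t, R) export of a reflectance curve for inspection."""
    pd.DataFrame(
        {"t_ns": curve.time_grid.centers(), "reflectance": curve.values}
    ).to_csv(path, index=False)


def spectrum_to_csv(path, spectrum) -> None:
    data = {"frequency_hz": spectrum.frequencies, "psd": spectrum.psd}
    if spectrum.contrast_db is not None:
        data["contrast_db"] = spectrum.contrast_db
    pd.DataFrame(data).to_csv(path, index=False)
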