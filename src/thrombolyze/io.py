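"""Output writers: gridded field snapshots (HDF5) and scalar series (text)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .parameters import ALL_FIELDS
from .transport import SimulationResult

__all__ = ["save_fields_h5", "save_scalar_series", "load_fields_h5"]

_UNITS = {name: "uM" for name in ALL_FIELDS}


def save_fields_h5(result: SimulationResult, path: str | Path) -> None:
    """Write field snapshots with dimensions (time, x, species) plus the
    scalar series, with units attributes per variable."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=result.snapshot_times).attrs["units"] = "s"
        f.create_dataset("x", data=result.grid.x).attrs["units"] = "m"
        f.create_dataset("species", data=np.array(ALL_FIELDS, dtype="S"))
        d = f.create_dataset("fields", data=result.snapshots)
        d.attrs["units"] = "uM"
        d.attrs["dims"] = "time,x,species"
        g = f.create_group("series")
        for name, data, units in [
            ("time", result.times, "s"),
            ("Q", result.q, "m^3/s"),
            ("L_clot_rem", result.l_rem, "m"),
            ("E_L_min", result.e_l_min, "-"),
            ("E_L_max", result.e_l_max, "-"),
            ("u_clot", result.u_clot, "m/s"),
        ]:
            g.create_dataset(name, data=data).attrs["units"] = units
        f.attrs["scenario"] = result.scenario.name
        f.attrs["recanalised"] = result.recanalised
        if result.recanalisation_time is not None:
            f.attrs["recanalisation_time_s"] = result.recanalisation_time
        for k, v in result.metadata.items():
            f.attrs[f"meta_{k}"] = v


def load_fields_h5(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "time": f["time"][:],
            "x": f["x"][:],
            "species": [s.decode() for s in f["species"][:]],
            "fields": f["fields"][:],
            "attrs": dict(f.attrs),
        }


def save_scalar_series(result: SimulationResult, path: str | Path) -> None:
    """Tabular text: Q, remaining clot length, min/mean lysis extent and
    the recanalisation flag, with a units row under the header."""
    df = pd.DataFrame(
        {
            "time": result.times,
            "Q": result.q,
            "L_clot_rem": result.l_rem,
            "E_L_min": result.e_l_min,
            "E_L_max": result.e_l_max,
            "u_clot": result.u_clot,
        }
    )
    units = ["s", "m^3/s", "m", "-", "-", "m/s"]
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(units) + "\n")
        df.to_csv(fh, header=False, index=False)
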