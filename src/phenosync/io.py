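"""CSV schemas shared by the pipeline stages.

Observations travel as one long table with columns
``site_id, biome, species, year, process, organ, time_unit, time, value``;
``time_unit`` is ``doy`` or ``month`` (month numbers are converted to
mid-month day of year on read).  Fitted curves are written with their
family and parameter columns so downstream stages can reconstruct the
:class:`~phenosync.curves.CurveSpec` without refitting.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CurveFamily, CurveSpec, SkewNormalParams, VExpParams
from .fitting import Biome, FittedCurve, Organ, Process, SeasonalSeries, month_axis_to_doy

__all__ = [
    "series_to_frame",
    "frame_to_series",
    "write_observations",
    "read_observations",
    "fits_to_frame",
    "spec_from_row",
]

OBS_COLUMNS = [
    "site_id", "biome", "species", "year", "process", "organ",
    "time_unit", "time", "value",
]


def series_to_frame(series: list[SeasonalSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        rows.append(
            pd.DataFrame(
                {
                    "site_id": s.site_id,
                    "biome": s.biome.value,
                    "species": s.species or "",
                    "year": s.year if s.year is not None else "",
                    "process": s.process.value,
                    "organ": s.organ.value,
                    "time_unit": "doy",
                    "time": s.times,
                    "value": s.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[OBS_COLUMNS]


def frame_to_series(df: pd.DataFrame) -> list[SeasonalSeries]:
    out = []
    keys = ["site_id", "biome", "species", "year", "process", "organ"]
    for (site, biome, species, year, proc, organ), g in df.groupby(keys, sort=True, dropna=False):
        g = g.sort_values("time")
        times = g["time"].to_numpy(dtype=float)
        if (g["time_unit"] == "month").any():
            times = month_axis_to_doy(times.astype(int))
        species = None if (isinstance(species, float) and math.isnan(species)) else (
            str(species) if str(species) not in ("", "nan") else None
        )
        year_val = None
        if str(year) not in ("", "nan"):
            year_val = int(float(year))
        out.append(
            SeasonalSeries(
                process=Process(proc),
                organ=Organ(organ),
                biome=Biome(biome),
                site_id=str(site),
                species=species,
                year=year_val,
                times=times,
                values=g["value"].to_numpy(dtype=float),
            )
        )
    return out


def write_observations(series: list[SeasonalSeries], path: Path | str) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_observations(path: Path | str) -> list[SeasonalSeries]:
    return frame_to_series(pd.read_csv(path))


def fits_to_frame(fits: list[dict]) -> pd.DataFrame:
    """Rows of fit context + FittedCurve diagnostics + curve parameters."""
    rows = []
    for entry in fits:
        fit: FittedCurve = entry["fit"]
        row = {k: v for k, v in entry.items() if k != "fit"}
        row.update(
            converged=fit.converged,
            family=fit.family.value if fit.family else "",
            sse=fit.sse,
            rse=fit.rse,
            p_value=fit.p_value,
            n_obs=fit.n_obs,
        )
        if fit.spec is not None:
            p = fit.spec.params
            if fit.spec.family is CurveFamily.SKEW_NORMAL:
                row.update(xi=p.xi, omega=p.omega, alpha=p.alpha,
                           amplitude=p.amplitude, ymax=np.nan, mu=np.nan,
                           xmax=np.nan)
            else:
                row.update(xi=np.nan, omega=np.nan, alpha=np.nan,
                           amplitude=np.nan, ymax=p.ymax, mu=p.mu, xmax=p.xmax)
            row["peak_doy"] = fit.peak_time
        rows.append(row)
    return pd.DataFrame(rows)


def spec_from_row(row) -> CurveSpec:
    """Rebuild a CurveSpec from a fits-table row."""
    family = CurveFamily(row["family"])
    if family is CurveFamily.SKEW_NORMAL:
        return CurveSpec(
            family,
            SkewNormalParams(
                xi=float(row["xi"]), omega=float(row["omega"]),
                alpha=float(row["alpha"]), amplitude=float(row["amplitude"]),
            ),
        )
    return CurveSpec(
        family,
        VExpParams(ymax=float(row["ymax"]), mu=float(row["mu"]),
                   xmax=float(row["xmax"])),
    )
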