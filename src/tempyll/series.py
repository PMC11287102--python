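"""City daily time-series container and its CSV round-trip.

One city's aligned daily outcome (YLL), exposure (mean temperature) and
meteorological covariates with calendar metadata.  The CSV dialect written
here is the one every reader in the pipeline consumes; header comment
lines (``#``) carry provenance (seed, config hash).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CityDailySeries", "read_series", "write_series"]

SERIES_COLUMNS = ["yll", "temp", "rh", "ws", "sunshine", "ap", "holiday"]


@dataclass
class CityDailySeries:
    """Aligned daily vectors for one city.

    Attributes
    ----------
    city_id
        Label used in outputs and error messages.
    data
        DataFrame indexed by a strictly consecutive daily DatetimeIndex with
        columns yll (person-years/day), temp (degC), rh (%), ws (m/s),
        sunshine (h), ap (hPa), holiday (bool).
    """

    city_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SERIES_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{self.city_id}: missing series columns {missing}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError(f"{self.city_id}: index must be a DatetimeIndex")
        if len(df) == 0:
            raise ValueError(f"{self.city_id}: empty series")
        deltas = np.diff(df.index.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            i = int(np.argmax(deltas != 1))
            raise ValueError(
                f"{self.city_id}: dates not strictly consecutive around "
                f"{df.index[i].date()} -> {df.index[i + 1].date()}"
            )
        rh = df["rh"].to_numpy(dtype=float)
        if np.nanmin(rh) < 0 or np.nanmax(rh) > 100:
            raise ValueError(f"{self.city_id}: relative humidity outside [0, 100]")
        ss = df["sunshine"].to_numpy(dtype=float)
        if np.nanmin(ss) < 0 or np.nanmax(ss) > 24:
            raise ValueError(f"{self.city_id}: sunshine duration outside [0, 24]")
        if np.nanmin(df["ws"].to_numpy(dtype=float)) < 0:
            raise ValueError(f"{self.city_id}: negative wind speed")
        self.data = df[SERIES_COLUMNS].copy()
        self.data["holiday"] = self.data["holiday"].astype(bool)
        self.data.index.name = "date"

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def yll(self) -> np.ndarray:
        return self.data["yll"].to_numpy(dtype=float)

    @property
    def temp(self) -> np.ndarray:
        return self.data["temp"].to_numpy(dtype=float)


def write_series(series: CityDailySeries, path, header_meta: dict | None = None) -> None:
    """Write one city's series as CSV with ``#`` provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"# city_id: {series.city_id}\n")
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        out = series.data.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out["holiday"] = out["holiday"].astype(int)
        out.to_csv(fh, index=False, lineterminator="\n")


def read_series(path, city_id: str | None = None) -> CityDailySeries:
    """Read a series CSV; validates schema, duplicate and non-consecutive dates."""
    if city_id is None:
        city_id = _city_id_from_header(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ["date", *SERIES_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    dupes = dates[dates.duplicated()].dt.date.unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate dates {list(map(str, dupes))}")
    df = df.drop(columns=["date"]).set_index(pd.DatetimeIndex(dates, name="date"))
    df["holiday"] = df["holiday"].astype(bool)
    return CityDailySeries(city_id=city_id, data=df)


def _city_id_from_header(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("# city_id:"):
                return line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
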