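"""The fermentation time-series container and its CSV dialect.

A :class:`FermentationSeries` holds one experiment's sampled trajectory:
time (hours), viable counts (cfu/g), titratable acidity (g/L as lactic
acid) and pH.  Any channel other than time may be absent.

CSV dialect: comma-separated, UTF-8, '.' decimal, header
``time_hr,cfu_per_g,acidity_g_per_l,pH``.  Acidity is also accepted as
percent lactic acid (w/v) under the header ``acidity_pct`` and converted at
ingest with the standard factor 1% w/v = 10 g/L (a logged note records the
conversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["FermentationSeries", "read_series_csv", "write_series_csv", "PCT_TO_G_PER_L"]

logger = logging.getLogger(__name__)

#: 1 % (w/v) lactic acid = 10 g/L
PCT_TO_G_PER_L = 10.0

_CSV_COLUMNS = ("time_hr", "cfu_per_g", "acidity_g_per_l", "pH")


def _channel(name: str, values, n: int, positive: bool, nonneg: bool) -> Optional[np.ndarray]:
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise DataError(f"{name} must be 1-d with the same length as t ({n})")
    if positive and np.any(arr[np.isfinite(arr)] <= 0):
        raise DataError(f"{name} must be > 0 where present")
    if nonneg and np.any(arr[np.isfinite(arr)] < 0):
        raise DataError(f"{name} must be >= 0 where present")
    return arr


@dataclass
class FermentationSeries:
    """One experiment's sampled fermentation trajectory.

    Attributes
    ----------
    t:
        Sampling times, strictly increasing (``time_unit``, hours default).
    cfu:
        Viable counts, cfu/g (> 0), optional.
    acidity:
        Titratable acidity as lactic acid, g/L (>= 0), optional.
    pH:
        pH readings, optional.
    N0:
        Baseline count for the log10(N/N0) response.  When ``None`` the
        first cfu observation is used, which pins the observed log-ratio to
        zero at the first sample; a generator that knows the true inoculum
        sets it explicitly.
    """

    t: np.ndarray
    cfu: Optional[np.ndarray] = None
    acidity: Optional[np.ndarray] = None
    pH: Optional[np.ndarray] = None
    N0: Optional[float] = None
    time_unit: str = "hr"
    acidity_unit: str = "g/L"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise DataError("t must be 1-d with at least 2 points")
        if np.any(~np.isfinite(self.t)) or np.any(np.diff(self.t) <= 0):
            raise DataError("t must be finite and strictly increasing")
        n = self.t.size
        self.cfu = _channel("cfu", self.cfu, n, positive=True, nonneg=False)
        self.acidity = _channel("acidity", self.acidity, n, positive=False, nonneg=True)
        self.pH = _channel("pH", self.pH, n, positive=True, nonneg=False)
        if self.N0 is not None and self.N0 <= 0:
            raise DataError("N0 must be > 0")

    def __len__(self) -> int:
        return int(self.t.size)

    def log_ratio(self) -> np.ndarray:
        """Observed response log10(N/N0); N0 defaults to the first count."""
        if self.cfu is None:
            raise DataError("series has no cfu channel")
        baseline = self.N0 if self.N0 is not None else self.cfu[0]
        return np.log10(self.cfu / baseline)


def read_series_csv(path) -> FermentationSeries:
    """Read a fermentation series from the package CSV dialect."""
    df = pd.read_csv(path)
    if "time_hr" not in df.columns:
        raise DataError(f"missing required column 'time_hr' in {path}")
    if len(df) < 2:
        raise DataError(f"{path}: need at least 2 rows")
    acidity = None
    if "acidity_g_per_l" in df.columns:
        acidity = df["acidity_g_per_l"].to_numpy(dtype=float)
    elif "acidity_pct" in df.columns:
        acidity = df["acidity_pct"].to_numpy(dtype=float) * PCT_TO_G_PER_L
        logger.info("converted acidity_pct to g/L (x%g)", PCT_TO_G_PER_L)
    return FermentationSeries(
        t=df["time_hr"].to_numpy(dtype=float),
        cfu=df["cfu_per_g"].to_numpy(dtype=float) if "cfu_per_g" in df.columns else None,
        acidity=acidity,
        pH=df["pH"].to_numpy(dtype=float) if "pH" in df.columns else None,
    )


def write_series_csv(series: FermentationSeries, path) -> None:
    """Write a series in the package CSV dialect (absent channels as NaN)."""
    n = len(series)
    data = {
        "time_hr": series.t,
        "cfu_per_g": series.cfu if series.cfu is not None else np.full(n, np.nan),
        "acidity_g_per_l": series.acidity
        if series.acidity is not None
        else np.full(n, np.nan),
        "pH": series.pH if series.pH is not None else np.full(n, np.nan),
    }
    pd.DataFrame(data, columns=list(_CSV_COLUMNS)).to_csv(path, index=False)
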