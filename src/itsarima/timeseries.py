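"""Calendar-aware univariate time-series container and CSV I/O.

A :class:`TimeSeries` holds an equally spaced, gap-free sequence of
observations ``Y_t`` together with its seasonal period ``s`` (12 for
monthly data, 4 for quarterly) and, when the data are calendar-based, a
:class:`pandas.PeriodIndex`.  All user-facing I/O speaks calendar periods
("2014-01", "2014Q1"); internally positions are 0-based integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_series_csv", "write_series_csv"]


def _parse_period(token: str) -> pd.Period:
    """Parse 'YYYY-MM' (monthly) or 'YYYY-Qn' / 'YYYYQn' (quarterly)."""
    token = str(token).strip()
    if "Q" in token.upper():
        return pd.Period(token, freq="Q")
    parts = token.split("-")
    if len(parts) == 2 and len(parts[0]) == 4:
        return pd.Period(token, freq="M")
    raise ValueError(
        f"cannot parse period {token!r}: expected 'YYYY-MM' or 'YYYY-Qn'"
    )


@dataclass(frozen=True)
class TimeSeries:
    """Equally spaced, strictly ordered series of finite observations.

    Parameters
    ----------
    values:
        Observations (counts or rates); must all be finite.
    period:
        Seasonal length ``s`` (>= 1): 12 for monthly, 4 for quarterly,
        1 for non-seasonal data.
    index:
        Optional contiguous :class:`pandas.PeriodIndex`.  When absent the
        series lives on an anonymous 0-based integer timeline.
    label:
        Free-text description.
    transform:
        Name of the transform already applied to the values ("log" or
        None); recorded so effects and forecasts can be reported on the
        original scale.
    """

    values: np.ndarray
    period: int = 1
    index: Optional[pd.PeriodIndex] = None
    label: str = ""
    transform: Optional[str] = None
    _diff_lags: tuple = field(default=())

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size < 1:
            raise ValueError("series must contain at least one observation")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                "series contains missing or non-finite values; "
                "complete equally spaced data are required"
            )
        if int(self.period) < 1:
            raise ValueError("seasonal period must be >= 1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "period", int(self.period))
        if self.index is not None:
            idx = pd.PeriodIndex(self.index)
            if len(idx) != vals.size:
                raise ValueError("index length does not match values")
            if len(idx) > 1:
                steps = np.diff(idx.asi8)
                if not np.all(steps == 1):
                    raise ValueError(
                        "index has gaps or is out of order; the series must "
                        "be equally spaced with no missing periods"
                    )
            object.__setattr__(self, "index", idx)

    # ------------------------------------------------------------- helpers
    @classmethod
    def monthly(cls, values: Sequence[float], start: str, **kw) -> "TimeSeries":
        idx = pd.period_range(start=pd.Period(start, freq="M"),
                              periods=len(values), freq="M")
        return cls(np.asarray(values, float), period=12, index=idx, **kw)

    @classmethod
    def quarterly(cls, values: Sequence[float], start: str, **kw) -> "TimeSeries":
        idx = pd.period_range(start=pd.Period(start, freq="Q"),
                              periods=len(values), freq="Q")
        return cls(np.asarray(values, float), period=4, index=idx, **kw)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    def position_of(self, when: Union[str, int, pd.Period]) -> int:
        """0-based position of a calendar period (or pass through an int).

        Positions may fall outside ``[0, n)`` — callers that build
        intervention indicators rely on that to place an onset just past
        the observed range.
        """
        if isinstance(when, (int, np.integer)):
            return int(when)
        if self.index is None:
            raise ValueError(
                "series has no calendar index; specify the position as an integer"
            )
        p = when if isinstance(when, pd.Period) else _parse_period(when)
        p = p.asfreq(self.index.freq)
        return int(p.ordinal - self.index[0].ordinal)

    def period_at(self, pos: int):
        """Calendar period at 0-based position (or the position itself)."""
        if self.index is None:
            return pos
        return self.index[0] + pos

    def with_values(self, values: np.ndarray, drop_front: int = 0) -> "TimeSeries":
        idx = self.index[drop_front:] if self.index is not None else None
        return replace(self, values=np.asarray(values, float), index=idx)

    def to_frame(self) -> pd.DataFrame:
        if self.index is not None:
            dates = [str(p) for p in self.index]
        else:
            dates = list(range(self.n))
        return pd.DataFrame({"date": dates, "value": self.values})


def read_series_csv(path, date_col: str = "date", value_col: str = "value",
                    label: str = "") -> TimeSeries:
    """Read a two-column CSV (header required) into a :class:`TimeSeries`.

    Dates must be 'YYYY-MM' (monthly, s=12) or 'YYYY-Qn' (quarterly, s=4);
    any gap or disorder in the dates is an error, not silently filled.
    """
    df = pd.read_csv(path)
    for col in (date_col, value_col):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path} (columns: {list(df.columns)})"
            )
    periods = [_parse_period(tok) for tok in df[date_col]]
    freq = periods[0].freq
    if any(p.freq != freq for p in periods):
        raise ValueError("mixed monthly/quarterly dates in input")
    idx = pd.PeriodIndex(periods, freq=freq)
    s = 12 if freq.freqstr.startswith("M") else 4
    vals = pd.to_numeric(df[value_col], errors="raise").to_numpy(float)
    return TimeSeries(vals, period=s, index=idx, label=label or str(path))


def write_series_csv(series: TimeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
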