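"""Intervention indicator series and rational transfer functions.

An intervention entering an interrupted time series is encoded as an
indicator input X_t — a *step* (0 before onset, 1 after), a *pulse* (1
only at onset) or a *ramp* (counts periods since onset) — passed through
a rational transfer function omega(B)/delta(B).  With numerator order
h = 0 and denominator order r = 0 the impact is simply omega_0 times the
indicator (abrupt, sustained for a step; one-off for a pulse; a slope
change for a ramp).  With r = 1 the impact builds up or decays
geometrically at rate delta_1 (|delta_1| < 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .timeseries import TimeSeries

__all__ = [
    "InterventionSpec", "TransferParams",
    "step_indicator", "pulse_indicator", "ramp_indicator",
    "indicator", "apply_transfer", "theoretical_response",
    "load_intervention_specs",
]

_SHAPES = ("step", "pulse", "ramp")


@dataclass(frozen=True)
class InterventionSpec:
    """One hypothesised impact: shape, onset, delay and transfer orders.

    ``onset`` is a calendar period ("2014-01") or a 0-based position;
    ``delay`` shifts the effective onset forward by whole periods.
    ``h`` and ``r`` are the transfer-function numerator and denominator
    orders: h = 0 with r in {0, 1} covers the abrupt and gradual impact
    shapes used in practice; higher orders are accepted but experimental.
    """

    shape: str
    onset: Union[str, int]
    delay: int = 0
    h: int = 0
    r: int = 0
    label: str = ""

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if self.delay < 0 or self.h < 0 or self.r < 0:
            raise ValueError("delay, h and r must be non-negative")
        if self.h > 0 or self.r > 1:
            warnings.warn(
                f"transfer orders h={self.h}, r={self.r} are experimental; "
                "only h=0, r<=1 are fully supported",
                stacklevel=2,
            )

    @property
    def n_omega(self) -> int:
        return self.h + 1

    def with_delay(self, delay: int) -> "InterventionSpec":
        return InterventionSpec(self.shape, self.onset, delay=delay,
                                h=self.h, r=self.r, label=self.label)

    def describe(self) -> str:
        tag = self.label or self.shape
        d = f"+{self.delay}" if self.delay else ""
        return f"{tag}@{self.onset}{d}"


@dataclass(frozen=True)
class TransferParams:
    """Numerator (omega, outcome units) and denominator (delta) coefficients."""

    omega: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        om = np.atleast_1d(np.asarray(self.omega, float))
        de = np.atleast_1d(np.asarray(self.delta, float)) if np.size(self.delta) \
            else np.zeros(0)
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "delta", de)
        if de.size == 1 and abs(de[0]) >= 1.0:
            raise ValueError(
                f"unstable transfer function: |delta_1| = {abs(de[0]):.3f} >= 1"
            )


def _onset_position(series: TimeSeries, onset, delay: int = 0) -> int:
    return series.position_of(onset) + int(delay)


def _blank(series: TimeSeries, label: str) -> np.ndarray:
    return np.zeros(series.n)


def step_indicator(series: TimeSeries, onset, delay: int = 0) -> TimeSeries:
    """S_t = 0 before onset, 1 from onset on (a sustained level shift)."""
    t0 = _onset_position(series, onset, delay)
    x = np.zeros(series.n)
    if t0 >= series.n:
        warnings.warn("intervention onset falls after the series end; "
                      "indicator is all zero", stacklevel=2)
    x[max(t0, 0):] = 1.0
    return series.with_values(x)


def pulse_indicator(series: TimeSeries, onset, delay: int = 0) -> TimeSeries:
    """P_t = 1 only at the onset period (a one-off disturbance)."""
    t0 = _onset_position(series, onset, delay)
    x = np.zeros(series.n)
    if t0 >= series.n or t0 < 0:
        warnings.warn("intervention onset falls outside the series; "
                      "indicator is all zero", stacklevel=2)
    else:
        x[t0] = 1.0
    return series.with_values(x)


def ramp_indicator(series: TimeSeries, onset, delay: int = 0) -> TimeSeries:
    """R_t = 0 before onset, then t - T0 + 1 (a change in slope)."""
    t0 = _onset_position(series, onset, delay)
    x = np.zeros(series.n)
    if t0 >= series.n:
        warnings.warn("intervention onset falls after the series end; "
                      "indicator is all zero", stacklevel=2)
    t = np.arange(series.n)
    x[t >= t0] = t[t >= t0] - t0 + 1
    return series.with_values(x)


_INDICATORS = {"step": step_indicator, "pulse": pulse_indicator,
               "ramp": ramp_indicator}


def indicator(series: TimeSeries, spec: InterventionSpec) -> TimeSeries:
    """Build the raw indicator X_t for a spec on a series' timeline."""
    return _INDICATORS[spec.shape](series, spec.onset, spec.delay)


def apply_transfer(x: TimeSeries, params: TransferParams) -> TimeSeries:
    """Filter an input through omega(B)/delta(B) with zero initial state.

    y_t = sum_j delta_j y_{t-j} + sum_i omega_i x_{t-i}; before the onset
    the input is zero so the impact is zero — effects are measured
    relative to the no-intervention baseline.
    """
    om, de = params.omega, params.delta
    xv = x.values
    y = np.zeros_like(xv)
    for t in range(xv.size):
        acc = 0.0
        for i in range(om.size):
            if t - i >= 0:
                acc += om[i] * xv[t - i]
        for j in range(1, de.size + 1):
            if t - j >= 0:
                acc += de[j - 1] * y[t - j]
        y[t] = acc
    return x.with_values(y)


def theoretical_response(shape: str, params: TransferParams, k: int) -> float:
    """Closed-form impact k periods after onset (k = 0 at the onset).

    step, r=0:   omega_0 at every k (permanent level shift)
    step, r=1:   omega_0 * (1 + delta + ... + delta^k) -> omega_0/(1-delta)
    pulse, r=0:  omega_0 at k=0, then 0
    pulse, r=1:  omega_0 * delta^k (geometric decay)
    ramp, r=0:   (k+1) * omega_0 (slope change)
    """
    if k < 0:
        raise ValueError("horizon k must be >= 0")
    om, de = params.omega, params.delta
    if om.size != 1 or de.size > 1:
        raise ValueError(
            f"no closed form implemented for h={om.size - 1}, r={de.size}"
        )
    w0 = float(om[0])
    d1 = float(de[0]) if de.size else None
    if shape == "step":
        if d1 is None:
            return w0
        return w0 * float(np.sum(d1 ** np.arange(k + 1)))
    if shape == "pulse":
        if d1 is None:
            return w0 if k == 0 else 0.0
        return w0 * d1 ** k
    if shape == "ramp":
        if d1 is None:
            return (k + 1) * w0
        raise ValueError("ramp with r=1 is not a supported closed form")
    raise ValueError(f"unknown shape {shape!r}")


def load_intervention_specs(path) -> list[InterventionSpec]:
    """Read a list of intervention specs from a YAML or JSON file.

    Each entry: {shape, onset, delay?, h?, r?, label?}. A single mapping
    is promoted to a one-element list.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = data.get("interventions", [data])
    specs = []
    for entry in data:
        specs.append(InterventionSpec(
            shape=entry["shape"], onset=entry["onset"],
            delay=int(entry.get("delay", 0)), h=int(entry.get("h", 0)),
            r=int(entry.get("r", 0)), label=entry.get("label", ""),
        ))
    return specs
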