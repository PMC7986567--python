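"""Synthetic interrupted-time-series generators (all data here is synthetic).

Two generators cover testing and demonstration without any external
download:

* :func:`make_sarima_dataset` — a generic SARIMA realisation plus
  transfer-function impact signal, with a truth record for recovery
  scoring;
* :func:`make_quetiapine_like_fixture` — a synthetic stand-in for a
  4-year monthly dispensing series of the kind produced by Australian
  claims data under Safety-Net seasonality: rising trend, December peak
  and January trough, and a policy intervention at month 37 of 48 that
  removes prescription refills, modelled as a negative step plus a
  negative ramp.  The injected effect sizes (step -3285, ramp -1397
  dispensings) and the noise scale are fixed so the fixture's
  signal-to-noise ratio matches a realistic national dispensing series
  (step ~ 10% of the series level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .interventions import InterventionSpec, TransferParams, apply_transfer, indicator
from .sarima import ArimaOrder, simulate_from
from .timeseries import TimeSeries

__all__ = ["make_sarima_dataset", "make_quetiapine_like_fixture",
           "SyntheticDataset", "QUETIAPINE_LIKE_TRUTH"]


@dataclass
class SyntheticDataset:
    series: TimeSeries
    truth: dict = field(default_factory=dict)

    def truth_json(self) -> dict:
        out = {}
        for k, v in self.truth.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, ArimaOrder):
                out[k] = str(v)
            elif isinstance(v, (list, tuple)):
                out[k] = [x if not isinstance(x, InterventionSpec)
                          else x.describe() for x in v]
            else:
                out[k] = v
        return out


def make_sarima_dataset(order: ArimaOrder, n: int, seed: int,
                        phi=(), theta=(), sphi=(), stheta=(),
                        const: float = 0.0, sigma: float = 1.0,
                        interventions: Sequence[InterventionSpec] = (),
                        transfer_params: Sequence[TransferParams] = (),
                        level: float = 0.0) -> SyntheticDataset:
    """SARIMA noise + transfer-function impact signal, with truth record.

    The impact of each intervention spec is its indicator filtered
    through the supplied (true) transfer parameters, added on the level
    scale after integration.  Deterministic given ``seed``.
    """
    if len(interventions) != len(transfer_params):
        raise ValueError("one TransferParams per InterventionSpec required")
    noise = simulate_from(order, n, seed, phi=phi, theta=theta, sphi=sphi,
                          stheta=stheta, const=const, sigma=sigma)
    y = noise.values + level
    ts = TimeSeries(y, period=order.s, label="synthetic")
    for spec, params in zip(interventions, transfer_params):
        x = indicator(ts, spec)
        y = y + apply_transfer(x, params).values
    series = TimeSeries(y, period=order.s, label="synthetic")
    truth = {
        "order": order, "phi": np.asarray(phi, float),
        "theta": np.asarray(theta, float),
        "seasonal_phi": np.asarray(sphi, float),
        "seasonal_theta": np.asarray(stheta, float),
        "const": const, "sigma": sigma, "level": level, "seed": seed,
        "interventions": list(interventions),
        "omega": [p.omega.tolist() for p in transfer_params],
        "delta": [p.delta.tolist() for p in transfer_params],
    }
    return SyntheticDataset(series=series, truth=truth)


# Fixed generation parameters of the synthetic dispensing-like fixture.
# Monthly seasonal deviations (January..December, sum zero): December
# stockpiling peak, January trough — the Safety-Net co-payment pattern.
_SEASONAL_PROFILE = np.array([
    -2600.0, -700.0, -200.0, -250.0, -100.0, 0.0,
    -150.0, 0.0, 0.0, 0.0, 800.0, 3200.0,
])

QUETIAPINE_LIKE_TRUTH = {
    "start": "2011-01", "n": 48, "period": 12,
    "baseline": 29000.0, "trend_per_month": 110.0,
    "seasonal_profile": _SEASONAL_PROFILE.tolist(),
    "order": "(2,1,0)(0,1,1)[12]",
    "phi": [-0.45, -0.35], "seasonal_theta": [-0.6], "sigma": 600.0,
    "intervention_onset": "2014-01",
    "step_omega0": -3285.0, "ramp_omega0": -1397.0,
}


def make_quetiapine_like_fixture(seed: int = 12345,
                                 sigma: float = 600.0) -> SyntheticDataset:
    """Synthetic 48-month dispensing-count series with a step+ramp break.

    Synthetic stand-in for a monthly 25 mg quetiapine dispensing series
    (Jan 2011 – Dec 2014): baseline 29,000 dispensings rising 110/month,
    Safety-Net seasonality (December peak, January trough), and from
    January 2014 an injected sustained drop of 3,285 dispensings plus a
    further 1,397 per month, on top of SARIMA (2,1,0)(0,1,1)_12 noise.
    """
    truth = dict(QUETIAPINE_LIKE_TRUTH)
    truth.update({"sigma": sigma, "seed": seed})
    n = truth["n"]
    order = ArimaOrder(2, 1, 0, 0, 1, 1, 12)
    noise = simulate_from(order, n, seed, phi=truth["phi"],
                          stheta=truth["seasonal_theta"], sigma=sigma)
    t = np.arange(n)
    base = (truth["baseline"] + truth["trend_per_month"] * t
            + np.tile(_SEASONAL_PROFILE, n // 12 + 1)[:n])
    ts = TimeSeries.monthly(base + noise.values, start=truth["start"],
                            label="synthetic dispensing-like fixture")
    step = InterventionSpec("step", truth["intervention_onset"], label="step")
    ramp = InterventionSpec("ramp", truth["intervention_onset"], label="ramp")
    impact = (truth["step_omega0"] * indicator(ts, step).values
              + truth["ramp_omega0"] * indicator(ts, ramp).values)
    series = TimeSeries.monthly(ts.values + impact, start=truth["start"],
                                label="synthetic dispensing-like fixture")
    truth["interventions"] = [step, ramp]
    truth["omega"] = [[truth["step_omega0"]], [truth["ramp_omega0"]]]
    truth["delta"] = [[], []]
    return SyntheticDataset(series=series, truth=truth)
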