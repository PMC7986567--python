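"""Shared test helpers."""

import numpy as np

from itsarima import ArimaOrder, InterventionSpec, TimeSeries
from itsarima.sarima import FittedModel


def published_style_model(step_coef=-3285.0, ramp_coef=-1397.0,
                          step_se=602.3, ramp_se=106.6, log_scale=False):
    """A step+ramp model with externally given coefficients (no fitting),
    for checking the pure effect arithmetic."""
    vals = np.full(48, 100.0)
    ts = TimeSeries.monthly(vals, start="2011-01")
    if log_scale:
        object.__setattr__(ts, "transform", "log")
    step = InterventionSpec("step", "2014-01", label="step")
    ramp = InterventionSpec("ramp", "2014-01", label="ramp")
    return FittedModel(
        order=ArimaOrder(0, 0, 0), series=ts, interventions=(step, ramp),
        phi=np.zeros(0), theta=np.zeros(0), seasonal_phi=np.zeros(0),
        seasonal_theta=np.zeros(0),
        beta=np.array([step_coef, ramp_coef]),
        deltas=[np.zeros(0), np.zeros(0)], include_constant=False,
        sigma2=1.0, loglik=0.0, n_effective=48,
        coef_names=["step.omega0", "ramp.omega0"],
        coef_cov=np.diag([step_se ** 2, ramp_se ** 2]),
        residuals=ts, fitted_level=vals,
        _beta_slices={"iv0": slice(0, 1), "iv1": slice(1, 2)},
    )
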