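"""Fit the final SARIMA model with step+ramp inputs and check residuals.

The intervention (a prescribing restriction at 2014-01) is modelled as an
immediate sustained drop (step) plus a monthly slope change (ramp), both
with transfer orders h=0, r=0.  Residuals of an adequate model should be
white noise: the Ljung-Box test should NOT reject.
"""

import warnings

from itsarima import ArimaOrder, InterventionSpec, fit, residual_report
from itsarima.synthetic import make_quetiapine_like_fixture

series = make_quetiapine_like_fixture().series
step = InterventionSpec("step", "2014-01", label="step")
ramp = InterventionSpec("ramp", "2014-01", label="ramp")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = fit(series, ArimaOrder(2, 1, 0, 0, 1, 1, 12), [step, ramp])

print(model.summary())

check = residual_report(model, lags=24)
lb = check.ljung_box
print(f"\nLjung-Box at {lb.lags} lags (df={lb.df}): Q={lb.statistic:.2f}, "
      f"p={lb.p_value:.2f}")
print(f"Jarque-Bera normality p={check.jarque_bera_p:.2f}")
print("verdict:", "white noise - model is adequate" if check.white_noise
      else "residual autocorrelation remains - revisit the orders")
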