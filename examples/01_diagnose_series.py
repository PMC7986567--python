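"""Step 1-3a of the workflow: inspect a series and decide differencing.

Builds the synthetic monthly dispensing-like series (48 months, rising
trend, December-peak seasonality, policy break at 2014-01) and asks: is
it stationary, and which differences would make it so?
"""

from itsarima import acf, adf_test, choose_differencing, difference, pacf
from itsarima.synthetic import make_quetiapine_like_fixture

series = make_quetiapine_like_fixture().series
print(f"series: {series.label}, n={series.n}, "
      f"{series.index[0]}..{series.index[-1]}")

adf = adf_test(series)
print(f"\nADF on the raw series: stat={adf.statistic:.2f} "
      f"p={adf.p_value:.3f} -> "
      f"{'stationary' if adf.reject_unit_root else 'unit root: difference it'}")

advice = choose_differencing(series)
print(f"recommended differencing: d={advice.d}, D={advice.D}")
print(f"  ({advice.rationale})")

stationary = difference(difference(series, lag=12), lag=1)
r = acf(stationary, max_lag=12)
p = pacf(stationary, max_lag=12)
print(f"\nACF/PACF of the differenced series ({stationary.n} obs left, "
      f"+-{r.ci_bound:.2f} white-noise band):")
print("lag   acf    pacf")
for k in range(1, 13):
    mark = "*" if abs(r.values[k]) > r.ci_bound else " "
    print(f"{k:3d} {r.values[k]:+.2f}{mark}  {p.values[k]:+.2f}")
print("\nBars beyond the band flag autocorrelation the ARMA part must absorb.")
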