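"""Impact shapes: step, pulse and ramp through rational transfer functions.

omega_0 is the initial effect; with denominator order r=1 the effect
builds up or decays geometrically at rate delta_1.
"""

import numpy as np

from itsarima import (TimeSeries, TransferParams, apply_transfer,
                      pulse_indicator, ramp_indicator, step_indicator)

timeline = TimeSeries(np.zeros(10), period=1)
onset = 2

cases = [
    ("abrupt, sustained step (h=0, r=0)", step_indicator,
     TransferParams([-10.0])),
    ("gradual step, delta=0.6 (h=0, r=1)", step_indicator,
     TransferParams([-10.0], [0.6])),
    ("one-off pulse (h=0, r=0)", pulse_indicator, TransferParams([-10.0])),
    ("decaying pulse, delta=0.6 (h=0, r=1)", pulse_indicator,
     TransferParams([-10.0], [0.6])),
    ("slope change / ramp (h=0, r=0)", ramp_indicator, TransferParams([-2.0])),
]

print(f"impact paths (onset at t={onset}):")
for label, build, params in cases:
    path = apply_transfer(build(timeline, onset), params).values
    print(f"{label:40s}", " ".join(f"{v:6.2f}" for v in path))
print("\nA gradual step approaches omega0/(1-delta) = "
      f"{-10/(1-0.6):.1f}; a decaying pulse shrinks by a factor "
      "delta each period.")
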