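"""Automatic order selection: stepwise information-criterion search.

With d=1 and D=1 pre-specified (trend and seasonality), the search walks
the (p,q,P,Q) grid from a few seed models, moving to whichever neighbour
improves the criterion, and stops at a local minimum.
"""

from itsarima import InterventionSpec, auto_search
from itsarima.synthetic import make_quetiapine_like_fixture

series = make_quetiapine_like_fixture().series
step = InterventionSpec("step", "2014-01", label="step")
ramp = InterventionSpec("ramp", "2014-01", label="ramp")

result = auto_search(series, d=1, D=1, interventions=[step, ramp],
                     criterion="aicc")
print(f"selected: {result.best_order}  "
      f"(AICc={result.best_model.aicc:.2f})")
print("\nsearch trace (every candidate evaluated):")
print(result.trace.to_string(index=False))
print("\nThe chosen model minimises the criterion among all neighbours; "
      "in a 48-month series several orders typically sit within a few "
      "criterion points of each other.")
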