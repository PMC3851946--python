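"""Combine protein triangles into a phenotype and measure the gap.

Two activators and one inhibitor are combined with the Lukasiewicz
bounded-sum operators; the result is compared with the default fluctuating
environmental target.  The printed gap g is the integral of
|f_E - f_P| over [0, 1]: 0 means perfect adaptation, and the gap of the
empty phenotype equals the target's area.
"""

from digevol import (
    EnvironmentSpec,
    Triangle,
    build_target,
    combine_phenotype,
    compute_gap,
    selection_weight,
)
from digevol.phenotype import PiecewiseLinearFunction

# activators sitting where the target demands activity, an inhibitor in
# the valley the target keeps at zero
activators = [Triangle(m=0.65, w=0.005, H=0.5),
              Triangle(m=0.80, w=0.004, H=0.4)]
inhibitors = [Triangle(m=0.50, w=0.003, H=0.3)]

f_p = combine_phenotype(activators, inhibitors)
f_e = build_target(EnvironmentSpec())

empty_gap = compute_gap(PiecewiseLinearFunction.zero(), f_e)
gap = compute_gap(f_p, f_e)
print(f"target area (gap of an organism with no genes): {empty_gap:.6f}")
print(f"gap of this three-protein phenotype:            {gap:.6f}")
print(f"selection weight exp(-k*g) at k=750:            "
      f"{selection_weight(gap, 750.0):.3e}")
print(f"relative to a gene-less competitor:             "
      f"{selection_weight(gap, 750.0) / selection_weight(empty_gap, 750.0):.1f}x")
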