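"""Characterize the model surface: wells, saddles, barriers, intersection.

The two-state surface encodes why helically twisted alkenes are
*electronically prochiral*: a small ground-state inversion barrier (the
enantiomers racemize thermally) against a large excited-state one (the
enantiomers are configurationally trapped once excited).
"""

import math

from prochir.pes import characterize_surface, preset

for name in ("stilbene", "stiff_stilbene"):
    rep = characterize_surface(preset(name))
    print(f"== {name} ==")
    print(f"  P well at tau = {math.degrees(rep.well_P.tau):+6.2f} deg, "
          f"phi = {math.degrees(rep.well_P.phi):+6.2f} deg")
    print(f"  S0 helical-inversion barrier : {rep.barrier_S0:6.3f} kcal/mol "
          "(thermally accessible -> racemic ground state)")
    print(f"  S1 helical-inversion barrier : {rep.barrier_S1:6.3f} kcal/mol "
          "(frozen chirality on the excited state)")
    print(f"  S1/S0 minimum gap {rep.min_gap:.2e} kcal/mol at tau = "
          f"{math.degrees(rep.min_gap_point.tau):.1f} deg "
          "(the photoisomerization funnel)")
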