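"""Generate a synthetic town survey from an explicit design spec.

Samples are placed on a regular hexagonal network, concentrations drawn
lognormal with a configured mean and coefficient of variation, and a
town-centre hotspot applied multiplicatively.
"""

import numpy as np

import soilrisk as sr

spec = sr.TownSpec(
    name="Demo town",
    region=(0, 0, 3000, 2000),            # metres
    n_samples=40,
    means={"Cd": 1.0, "Pb": 35.0},        # mg/kg
    cv=0.5,
    hotspots=(sr.Hotspot(1500, 1000, 500, {"Pb": 3.0}),),
    seed=7,
)
survey = sr.simulate_survey(spec)

print(survey.head().round(3).to_string(index=False))
d = np.hypot(survey["x"] - 1500, survey["y"] - 1000)
print(f"\nn = {len(survey)}, Pb mean = {survey['Pb'].mean():.1f} mg/kg")
print(f"Pb nearest hotspot centre: {survey.loc[d.idxmin(), 'Pb']:.1f} mg/kg; "
      f"farthest: {survey.loc[d.idxmax(), 'Pb']:.1f} mg/kg")

# The hexagonal network gives near-uniform coverage (equal nearest-
# neighbour distances); the hotspot raises Pb up to 3x at its centre with
# linear decay to the 500 m radius.  Reruns with the same seed are
# byte-identical.
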