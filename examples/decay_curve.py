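"""Exponential-decay exposure weights under the characteristic travel
distance (CTD) model.

The CTD is the distance at which 63% of a volatilized chemical's mass
has been degraded or deposited, so the weight applied to a source at
distance d is 0.37^(d/CTD).  This prints the per-km decay-rate constant
for each study CTD and the weight profile for the literature value for
chlorpyrifos (62 km).
"""

from localuse import DEFAULT_CTDS, decay_coefficient

print("CTD (km)   per-km decay-rate constant 0.37^(1/CTD)")
for ctd in DEFAULT_CTDS:
    print(f"{ctd:7.0f}    {decay_coefficient(1.0, ctd):.3f}")

print("\nWeight profile at CTD = 62 km (chlorpyrifos literature estimate):")
for d in (0, 10, 31, 62, 124):
    w = decay_coefficient(float(d), 62.0)
    print(f"  d = {d:3d} km -> weight {w:.3f}  ({100 * (1 - w):.0f}% of mass lost)")

# A weight of 0.37 at d = CTD is the model's defining property; larger
# CTDs decay more slowly per km, so local use integrates a wider area.
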