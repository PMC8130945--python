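"""Build a background mortality surface and look up hazards on it.

Background rates drive both the expected-survival simulation and the
expected-death counts of the excess-risk tabulation.  Here we synthesise a
Gompertz-Makeham table (constant accident hazard plus exponentially rising
senescent hazard, with a 1%/year secular decline) and query it.
"""

import lifetimerisk as lr

table = lr.make_synthetic_lifetable(
    makeham_a=5e-4, gompertz_b=3e-5, gompertz_c=0.09,
    years=(1975, 2020), secular_decline=0.01,
)

print("annual death hazard, females:")
for age in (40, 63, 80, 100):
    for year in (1975, 2016):
        m = table.get_rate("female", age, year)
        print(f"  age {age:>3}, year {year}: m = {m:.4f} per person-year")

# lookups clamp: ages above the open top group and years outside the table
print("\nage 140 clamps to the 110+ group:",
      table.get_rate("female", 140, 2016) == table.get_rate("female", 110, 2016))

# the Mx_1x1 text dialect round-trips
lr.write_hmd_mx(table, "/tmp/mx_demo.txt")
again = lr.read_hmd_mx("/tmp/mx_demo.txt")
print("round-trip max rate error:", abs(table.rates - again.rates).max())
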