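"""Cross-check dehydration weight losses against molecular stoichiometry."""

import ramanmcr as rm

for name, formula in [
    ("theophylline", rm.THEOPHYLLINE),
    ("nitrofurantoin", rm.NITROFURANTOIN),
]:
    pct = rm.water_mass_fraction(formula, n_water=1)
    print(f"{name:15s} {formula:10s} monohydrate water loss: "
          f"{pct:.2f}% (~{round(pct)}%)")
# A thermogravimetric step of this size confirms a 1:1 drug-to-water hydrate
# dehydrating completely.
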