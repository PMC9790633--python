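"""Percent ratios from bundled per-genotype mean diameters.

Feeds the example per-genotype mean retinal vessel diameters (wild type
vs two Mitf-variant mouse genotypes) through the percent helpers and
prints the resulting percent-of-reference and percent-increase columns —
the arithmetic used in genotype comparison tables.
"""

from fundusvessel.experiments import reference_ratio_table

table = reference_ratio_table()
print(table.to_string(index=False))
vein = table[(table.label == "vein") & (table.genotype == "enu22")].iloc[0]
print(f"\nheadline: enu22 venular diameter is {vein.percent_increase}% "
      f"larger than wild type ({vein.percent_of_reference}% of reference)")
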