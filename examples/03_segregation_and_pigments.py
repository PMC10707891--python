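"""Phenotype statistics: Mendelian segregation test and pigment content.

The chi-square test asks whether observed wild-type:mutant counts are
consistent with the 3:1 ratio expected for a recessive mutation segregating
from a selfed heterozygote (p > 0.05 means no evidence against it).  The
pigment computation converts extract absorbances into chlorophyll a/b and
carotenoid content per gram fresh weight.
"""

from bsa_mutfind import (
    PigmentReading,
    SegregationObservation,
    chisq_segregation,
    pigment_content,
)

result = chisq_segregation(SegregationObservation(102, 30, ratio=(3, 1)))
print(f"102 wt : 30 mutant vs 3:1 -> chi2({result.df}) = {result.chi2:.2f}, "
      f"p = {result.pvalue:.3f}")

reading = PigmentReading(od470=0.8, od649=0.12, od665=0.30, volume=10, mass=0.1)
content = pigment_content(reading)
print(f"Chl a = {content.chl_a:.2f}, Chl b = {content.chl_b:.2f}, "
      f"carotenoid = {content.carotenoid:.2f} (formula units per g fresh weight)")
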