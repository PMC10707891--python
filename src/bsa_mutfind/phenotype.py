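"""Closed-form phenotype computations: segregation test and pigment content.

Mendelian segregation of a recessive mutation among selfed progeny of a
heterozygote predicts a 3:1 wild-type:mutant phenotype ratio, tested here
with the Pearson chi-square goodness-of-fit statistic (1 degree of freedom,
no continuity correction).

Pigment content is computed from ethanol/acetone-extract absorbances with
the standard spectrophotometric formulas

    Chl a = (12.21 * OD665 - 2.81 * OD649) * V/W
    Chl b = (20.13 * OD649 - 5.03 * OD665) * V/W
    Caro  = (1000 * OD470 * V/W - 3.27 * Chl a - 104 * Chl b) / 198

with V the extract volume (mL) and W the fresh weight (g), evaluated
literally.  The formulas' native output scale is the calibration's
concentration unit per gram fresh weight; see the methods note on the
ambiguity between ug/g and mg/g reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .errors import ValidationError

__all__ = [
    "PigmentContent",
    "PigmentReading",
    "SegregationObservation",
    "SegregationResult",
    "chisq_segregation",
    "pigment_content",
]


@dataclass(frozen=True)
class SegregationObservation:
    """Observed phenotype counts and the expected Mendelian ratio (wt:mut)."""

    n_wt_phenotype: int
    n_mut_phenotype: int
    ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_wt_phenotype < 0 or self.n_mut_phenotype < 0:
            raise ValidationError("phenotype counts must be non-negative")
        if self.n_wt_phenotype + self.n_mut_phenotype == 0:
            raise ValidationError("total count must be positive")
        if self.ratio[0] <= 0 or self.ratio[1] <= 0:
            raise ValidationError("ratio components must be positive")


class SegregationResult(NamedTuple):
    chi2: float
    df: int
    pvalue: float


def chisq_segregation(obs: SegregationObservation) -> SegregationResult:
    """Pearson chi-square test of the observed counts against the ratio.

    No Yates continuity correction is applied; expected counts come from
    the stated ratio and the observed total, and the p-value from the
    chi-square survival function with 1 df.
    """
    total = obs.n_wt_phenotype + obs.n_mut_phenotype
    ratio_sum = obs.ratio[0] + obs.ratio[1]
    expected = [total * obs.ratio[0] / ratio_sum, total * obs.ratio[1] / ratio_sum]
    chi2, pvalue = stats.chisquare(
        [obs.n_wt_phenotype, obs.n_mut_phenotype], f_exp=expected
    )
    return SegregationResult(chi2=float(chi2), df=1, pvalue=float(pvalue))


@dataclass(frozen=True)
class PigmentReading:
    """Absorbances at 470/649/665 nm plus extract volume V (mL) and fresh weight W (g)."""

    od470: float
    od649: float
    od665: float
    volume: float
    mass: float

    def __post_init__(self) -> None:
        if min(self.od470, self.od649, self.od665) < 0:
            raise ValidationError("absorbances must be non-negative")
        if self.volume <= 0 or self.mass <= 0:
            raise ValidationError("volume and mass must be positive")


class PigmentContent(NamedTuple):
    chl_a: float
    chl_b: float
    carotenoid: float
    flagged: bool  # True when any value is negative (reading outside calibration)


def pigment_content(reading: PigmentReading) -> PigmentContent:
    """Evaluate the three pigment formulas literally, in order.

    Chl a and Chl b feed the carotenoid formula.  Negative outputs are
    returned as computed but flagged (and a warning is issued): physically
    they indicate absorbances outside the formulas' calibration range.
    """
    v_over_w = reading.volume / reading.mass
    chl_a = (12.21 * reading.od665 - 2.81 * reading.od649) * v_over_w
    chl_b = (20.13 * reading.od649 - 5.03 * reading.od665) * v_over_w
    caro = (1000 * reading.od470 * v_over_w - 3.27 * chl_a - 104 * chl_b) / 198
    flagged = min(chl_a, chl_b, caro) < 0
    if flagged:
        warnings.warn(
            "negative pigment content computed; absorbances likely outside "
            "the formulas' calibration range",
            stacklevel=2,
        )
    return PigmentContent(chl_a=chl_a, chl_b=chl_b, carotenoid=caro, flagged=flagged)
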