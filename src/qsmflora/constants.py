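"""Reference parameter sets for wild cherry (*Prunus avium*).

These are the fitted coefficient sets and resource constants of the field
study this pipeline emulates.  They serve two purposes:

* ground truth for the synthetic-data generator, so every stage of the
  pipeline can be tested against a known generating process, and
* worked-example inputs for tree-level predictions and resource budgets.

The hurdle dispersion ``theta`` and the random-intercept standard deviations
were not reported; the defaults here (theta = 1.5, SDs = 0.3) are generator
configuration, not field estimates.
"""

from __future__ import annotations

from .hurdle import HurdleCoefficients, PartCoefficients

#: Branch-level flower-occurrence part (logit link).  Reference levels are
#: crown layer "out" and crown stratum "bot".
OCCURRENCE_COEFS = PartCoefficients(
    intercept=-2.85,
    ln_diameter=2.16,
    dbh=0.13,
    layer_in=-3.38,
    stratum_mid=-1.54,
    stratum_top=-0.15,
    in_mid=3.86,
    in_top=0.76,
    ln_diameter_dbh=None,
)

#: Standard errors of the occurrence part, same order as the coefficients.
OCCURRENCE_SES = PartCoefficients(
    intercept=1.25,
    ln_diameter=0.67,
    dbh=0.06,
    layer_in=0.74,
    stratum_mid=0.77,
    stratum_top=1.24,
    in_mid=1.09,
    in_top=1.34,
    ln_diameter_dbh=None,
)

#: Branch-level flower-abundance part (log link, zero-truncated NB).
ABUNDANCE_COEFS = PartCoefficients(
    intercept=0.42,
    ln_diameter=1.22,
    dbh=-0.06,
    layer_in=-1.18,
    stratum_mid=0.54,
    stratum_top=0.89,
    in_mid=0.35,
    in_top=0.62,
    ln_diameter_dbh=0.04,
)

ABUNDANCE_SES = PartCoefficients(
    intercept=0.71,
    ln_diameter=0.34,
    dbh=0.04,
    layer_in=0.23,
    stratum_mid=0.18,
    stratum_top=0.22,
    in_mid=0.29,
    in_top=0.35,
    ln_diameter_dbh=0.02,
)

#: Default hurdle truth used by the synthetic generator.
REFERENCE_HURDLE = HurdleCoefficients(
    occurrence=OCCURRENCE_COEFS,
    abundance=ABUNDANCE_COEFS,
    theta=1.5,
    sd_tree=0.3,
    sd_branch=0.3,
)

#: Tree-level NB models (log link): ln(flowers) = b0 + b1 * predictor.
TREE_DBH_MODEL = {"intercept": 8.03, "slope": 0.17}  # dbh in cm
TREE_CV_MODEL = {"intercept": 9.80, "slope": 0.01}  # crown volume in m^3

#: Per-percent growth rate of the dbh model at a 10 cm baseline:
#: increasing dbh by x % multiplies predicted flowers by exp(RATE * x).
DBH_PERCENT_RATE = 0.01662

#: Flower totals predicted at dbh 10 and 25 cm in the reference study.
REFERENCE_FLOWERS_DBH10 = 16_163
REFERENCE_FLOWERS_DBH25 = 195_535

#: Tree-row scenario: trees per 100 m row at non-overlapping crown spacing.
ROW_TREES_DBH10 = 34
ROW_TREES_DBH25 = 14

#: Pollen measurement summary (per flower).
POLLEN_GRAINS_MEAN = 16_059.0
POLLEN_GRAINS_SE = 3_327.0
POLLEN_DIAMETER_UM = 32.63
POLLEN_DIAMETER_SE_UM = 0.73

#: Nectar production and sugar content for Prunus spp., 24 h basis.
NECTAR_MG_PER_FLOWER = 3.7
NECTAR_RANGE_MG = (1.4, 6.0)
SUGAR_FRACTION = 0.235
SUGAR_RANGE = (0.10, 0.37)

#: Per-larva pollen requirements (mm^3).  Back-solved from the reference
#: study's printed pollen volume / larvae pairs, NOT taken from the primary
#: bee-biology literature; treat as configuration defaults.
BEE_REQUIREMENTS_MM3 = {
    "Lasioglossum laticeps": 10.98,
    "Bombus terrestris": 61.6,
}
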