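"""Roster of pregnancy and perinatal outcomes.

The multi-cohort collaboration this package models analysed 20 a priori
selected binary outcomes (plus four continuous birth-size traits).  The
roster below carries, for each outcome, the published total sample size and
case count pooled across contributing studies; these serve as pipeline
configuration (which outcomes to simulate, at what prevalence) and as the
arithmetic inputs for the case-percentage bookkeeping.

Miscarriage and stillbirth appear twice: the index-pregnancy definitions
were used for the regression-based arms, the previous-pregnancy definitions
for Mendelian randomisation (self-report in the index pregnancy is too rare
to instrument).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OutcomeDefinition:
    name: str
    kind: str  # "binary" | "continuous"
    definition: str
    n: int
    n_cases: int | None = None
    offspring_adjusted_mr: bool = False  # flagged for genotype-adjusted sensitivity MR

    @property
    def case_percentage(self) -> float | None:
        """Percentage of cases among the pooled sample (binary outcomes)."""
        if self.n_cases is None:
            return None
        return 100.0 * self.n_cases / self.n


OUTCOME_ROSTER: tuple[OutcomeDefinition, ...] = (
    OutcomeDefinition("miscarriage_index", "binary",
                      "Self-reported miscarriage in index pregnancy", 91_757, 107),
    OutcomeDefinition("miscarriage_previous", "binary",
                      "Self-reported miscarriage in previous pregnancies", 376_434, 70_181),
    OutcomeDefinition("stillbirth_index", "binary",
                      "Self-reported stillbirth in index pregnancy", 91_942, 292),
    OutcomeDefinition("stillbirth_previous", "binary",
                      "Self-reported stillbirth in previous pregnancies", 174_440, 4_613),
    OutcomeDefinition("hypertensive_disorders", "binary",
                      "Gestational hypertension or preeclampsia", 416_803, 26_867),
    OutcomeDefinition("gestational_hypertension", "binary",
                      "Elevated blood pressure without proteinuria", 406_103, 17_607),
    OutcomeDefinition("preeclampsia", "binary",
                      "Elevated blood pressure with proteinuria", 401_184, 9_827),
    OutcomeDefinition("gestational_diabetes", "binary",
                      "Hyperglycaemia first diagnosed in pregnancy", 446_526, 14_338),
    OutcomeDefinition("maternal_anaemia", "binary",
                      "Hb < 110 g/L (1st trim.) or < 105 g/L (2nd/3rd trim.)", 92_002, 2_425),
    OutcomeDefinition("perinatal_depression", "binary",
                      "Self-reported diagnosis or depression symptom scales", 113_614, 9_320),
    OutcomeDefinition("membrane_rupture", "binary",
                      "Membrane rupture before onset of contractions", 249_265, 19_339,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("induction_of_labour", "binary",
                      "Labour needed induction", 114_075, 17_351,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("caesarean_section", "binary",
                      "Delivery by caesarean section", 204_093, 27_967,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("preterm_birth", "binary",
                      "Gestational age at birth < 37 weeks", 261_473, 14_090,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("large_for_gestational_age", "binary",
                      "> 90th percentile birthweight z-score", 118_667, 12_386,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("small_for_gestational_age", "binary",
                      "< 10th percentile birthweight z-score", 118_667, 8_958,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("low_birthweight", "binary",
                      "Birthweight < 2500 g", 247_716, 14_964,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("high_birthweight", "binary",
                      "Birthweight >= 4000 g", 239_460, 8_142,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("low_apgar_1min", "binary",
                      "Apgar score at 1 min < 7", 98_868, 5_760,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("low_apgar_5min", "binary",
                      "Apgar score at 5 min < 7", 99_434, 1_167,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("nicu_admission", "binary",
                      "Neonate admitted to NICU", 93_522, 8_262,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("breastfeeding_initiation", "binary",
                      "Ever breastfed", 94_116, 78_472,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("birthweight", "continuous", "Birthweight", 326_537,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("birth_length", "continuous", "Birth length", 95_649,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("ponderal_index", "continuous", "Ponderal index at birth", 95_562,
                      offspring_adjusted_mr=True),
    OutcomeDefinition("gestational_age", "continuous", "Gestational age at birth", 118_723,
                      offspring_adjusted_mr=True),
)


def get_outcome(name: str) -> OutcomeDefinition:
    for o in OUTCOME_ROSTER:
        if o.name == name:
            return o
    raise KeyError(f"unknown outcome: {name!r}")


def case_percentage(name: str) -> float:
    """Case percentage recomputed from the roster's printed counts."""
    out = get_outcome(name)
    if out.case_percentage is None:
        raise ValueError(f"{name!r} is a continuous outcome")
    return out.case_percentage
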