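"""Triangulation verdicts: combining the three analysis arms per outcome.

Agreement across approaches with different bias structures strengthens a
causal interpretation.  The verdict rule operationalises the qualitative
reading used in the source analyses:

* ``supported`` — multivariable regression and Mendelian randomisation
  share a non-null direction, and the paternal negative control is either
  compatible with the null or clearly attenuated relative to the mutually
  adjusted maternal estimate;
* ``not_supported`` — every arm is compatible with the null and the MR
  estimate is precise enough for that null to be informative;
* ``inconclusive`` — anything else (conflicting directions, an elevated
  paternal estimate, or an MR confidence interval too wide to adjudicate).

The attenuation factor (0.5 on the log scale) and the MR precision bound
(CI width < log 4) are explicit, configurable thresholds.  All rules are
pure functions of log-scale effects and Wald CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import ArmEstimate

logger = logging.getLogger(__name__)

PATERNAL_ATTENUATION_FACTOR = 0.5
MR_CI_WIDTH_MAX = float(np.log(4.0))


@dataclass
class Verdict:
    """Per-outcome triangulation classification with its rationale."""

    outcome: str
    classification: str  # supported | not_supported | inconclusive
    arms: dict = field(default_factory=dict)  # approach -> ArmEstimate
    rationale: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"outcome": self.outcome, "classification": self.classification,
               "rationale": ";".join(self.rationale)}
        for name, arm in self.arms.items():
            if arm is None:
                continue
            row[f"{name}_effect"] = arm.effect
            row[f"{name}_ci_low"] = arm.ci_low
            row[f"{name}_ci_high"] = arm.ci_high
        return row


def classify_direction(arm: ArmEstimate) -> str:
    """positive / negative / null_compatible from the log-scale Wald CI."""
    if not (arm.ci_low < arm.ci_high):
        raise ValueError("invalid confidence interval")
    if arm.ci_low > 0:
        return "positive"
    if arm.ci_high < 0:
        return "negative"
    return "null_compatible"


def triangulate_outcome(mvr: ArmEstimate | None, mr: ArmEstimate | None,
                        maternal_mutual: ArmEstimate | None,
                        paternal: ArmEstimate | None,
                        paternal_attenuation: float = PATERNAL_ATTENUATION_FACTOR,
                        mr_ci_width_max: float = MR_CI_WIDTH_MAX) -> Verdict:
    """Combine the four arm estimates for one outcome into a verdict."""
    arms = {"mvr": mvr, "mr": mr, "maternal_mutual": maternal_mutual,
            "paternal": paternal}
    outcome = next((a.outcome for a in arms.values() if a is not None), "?")
    if any(a is None for a in arms.values()):
        return Verdict(outcome, "inconclusive", arms, ["arm_missing"])

    d_mvr = classify_direction(mvr)
    d_mr = classify_direction(mr)
    d_pat = classify_direction(paternal)
    rationale: list[str] = []

    agree_non_null = d_mvr == d_mr and d_mvr != "null_compatible"
    if agree_non_null:
        rationale.append("direction_agreement")
    elif d_mvr != d_mr:
        rationale.append("arm_conflict")

    paternal_ok = (d_pat == "null_compatible"
                   or abs(paternal.effect)
                   < paternal_attenuation * abs(maternal_mutual.effect))
    if paternal_ok:
        rationale.append("paternal_attenuation")

    mr_width = mr.ci_high - mr.ci_low
    mr_precise = mr_width < mr_ci_width_max
    if not mr_precise:
        rationale.append("mr_imprecise")

    if agree_non_null and paternal_ok:
        return Verdict(outcome, "supported", arms, rationale)
    all_null = (d_mvr == d_mr == d_pat == "null_compatible"
                and classify_direction(maternal_mutual) == "null_compatible")
    if all_null and mr_precise:
        return Verdict(outcome, "not_supported", arms, rationale)
    return Verdict(outcome, "inconclusive", arms, rationale)


def verdict_counts(verdicts) -> dict[str, int]:
    counts = {"supported": 0, "not_supported": 0, "inconclusive": 0}
    for v in verdicts:
        counts[v.classification] += 1
    return counts


def _forest_plot(verdict: Verdict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names, effects, los, his = [], [], [], []
    for name, arm in verdict.arms.items():
        if arm is None:
            continue
        names.append(name)
        effects.append(np.exp(arm.effect))
        los.append(np.exp(arm.ci_low))
        his.append(np.exp(arm.ci_high))
    ypos = np.arange(len(names))[::-1]
    fig, ax = plt.subplots(figsize=(5, 2 + 0.4 * len(names)))
    ax.errorbar(effects, ypos,
                xerr=[np.array(effects) - np.array(los),
                      np.array(his) - np.array(effects)],
                fmt="s", color="black", capsize=3)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos, names)
    ax.set_xscale("log")
    ax.set_xlabel("OR per SD maternal BMI")
    ax.set_title(f"{verdict.outcome}: {verdict.classification}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def build_report(verdicts: list[Verdict], arm_estimates: list[ArmEstimate],
                 diagnostics: pd.DataFrame | None, out_dir,
                 make_plots: bool = False) -> dict[str, int]:
    """Write the tidy arm table, verdict table, diagnostics, and figures.

    Returns the supported / not_supported / inconclusive counts (also
    logged).  An empty verdict list produces empty-but-valid files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    arm_df = pd.DataFrame([a.to_row() for a in arm_estimates]) if arm_estimates \
        else pd.DataFrame(columns=["outcome", "approach", "effect", "se",
                                   "ci_low", "ci_high", "n", "n_cases"])
    arm_df.to_csv(out / "arms.tsv", sep="\t", index=False, float_format="%.8g")

    verdict_df = pd.DataFrame([v.to_row() for v in verdicts]) if verdicts \
        else pd.DataFrame(columns=["outcome", "classification", "rationale"])
    verdict_df.to_csv(out / "verdicts.tsv", sep="\t", index=False,
                      float_format="%.8g")

    if diagnostics is not None:
        diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False,
                           float_format="%.8g")

    if make_plots:
        for v in verdicts:
            _forest_plot(v, out / f"forest_{v.outcome}.svg")

    counts = verdict_counts(verdicts)
    logger.info("triangulation verdicts: %d supported, %d not supported, "
                "%d inconclusive", counts["supported"], counts["not_supported"],
                counts["inconclusive"])
    return counts
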