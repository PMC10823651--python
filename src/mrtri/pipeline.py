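"""End-to-end orchestration: simulate -> associate -> pool -> MR ->
negative control -> triangulate.

A :class:`PipelineConfig` (YAML-serialisable) names the scenario, embeds
the :class:`~mrtri.simulate.SimulationConfig`, and carries the analysis
toggles (adjustment set, meta-analysis method, MR estimators, verdict
thresholds).  All randomness flows from the single seed through a
deterministic per-cohort seed hierarchy, so each stage can regenerate the
cohorts it needs from the config alone: running stages one by one produces
byte-identical outputs to a single ``run-all``.

Every run writes a manifest (config hash, seed, package version) next to
its outputs; reruns of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (ArmEstimate, arm_estimates_to_tsv, mvr_estimate,
                          paternal_negative_control, snp_outcome_scan)
from .meta import meta_analyse, pool_per_snp
from .mr import TwoSampleMR, mr_leave_one_study_out
from .outcomes import get_outcome
from .simulate import (OutcomeSpec, SimulationConfig, config_to_dict,
                       simulate_reference_gwas, simulate_study)
from .summary import AssociationTable
from .triangulate import Verdict, build_report, triangulate_outcome

logger = logging.getLogger(__name__)

STAGES = ("simulate", "associate", "meta", "mr", "nc", "triangulate")


@dataclasses.dataclass
class PipelineConfig:
    scenario: str
    simulation: SimulationConfig
    reference_n: int = 171_977
    adjustment: str = "full"
    meta_method: str = "fixed"
    mr_methods: tuple = ("ivw", "egger", "weighted_median", "weighted_mode")
    mr_effects_model: str = "fixed"
    n_boot: int = 200
    paternal_attenuation: float = 0.5
    mr_ci_width_max: float = float(np.log(4.0))
    seed: int = 0
    write_genotypes: bool = False
    make_plots: bool = False

    def __post_init__(self):
        self.simulation.seed = int(self.seed)
        self.validate()

    def validate(self) -> None:
        if self.adjustment not in ("minimal", "full"):
            raise ValueError("adjustment must be minimal or full")
        for spec in self.simulation.outcomes:
            get_outcome(spec.name)  # KeyError for names outside the roster
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        d["simulation"]["outcomes"] = [dataclasses.asdict(o)
                                       for o in self.simulation.outcomes]
        d["mr_methods"] = list(self.mr_methods)
        # numpy scalars -> plain floats so YAML/JSON serialisation is clean
        return json.loads(json.dumps(d, default=float))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation")
        sim["outcomes"] = [OutcomeSpec(**o) for o in sim.get("outcomes", [])]
        for key in ("allele_freqs", "snp_effects"):
            if sim.get(key) is not None:
                sim[key] = np.asarray(sim[key], float)
        d["mr_methods"] = tuple(d.get("mr_methods", cls.mr_methods))
        return cls(simulation=SimulationConfig(**sim), **d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cohorts(config: PipelineConfig):
    return simulate_study(config.simulation)


def _pooled_arm(arms: list[ArmEstimate], approach: str,
                method: str) -> ArmEstimate:
    res = meta_analyse([a.effect for a in arms], [a.se for a in arms],
                       method=method)
    lo, hi = res.ci
    n = int(sum(a.n for a in arms))
    n_cases = sum(a.n_cases for a in arms) if arms[0].n_cases is not None else None
    return ArmEstimate(arms[0].outcome, approach, res.pooled_effect,
                       res.pooled_se, lo, hi, n, n_cases)


def stage_simulate(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    cohorts = _cohorts(config)
    for c in cohorts:
        c.to_tsv(workdir / "cohorts", genotypes=config.write_genotypes)
    ref = simulate_reference_gwas(config.simulation, config.reference_n)
    (workdir / "summary").mkdir(parents=True, exist_ok=True)
    ref.to_tsv(workdir / "summary" / "reference_gwas.tsv")
    logger.info("simulate: %d cohorts (%s families) + reference GWAS n=%d",
                len(cohorts), [c.n_families for c in cohorts], config.reference_n)


def stage_associate(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    cohorts = _cohorts(config)
    scan_dir = workdir / "scans"
    scan_dir.mkdir(parents=True, exist_ok=True)
    arms: list[ArmEstimate] = []
    for spec in config.simulation.outcomes:
        roster = get_outcome(spec.name)
        for c in cohorts:
            arms.append(mvr_estimate(c, spec.name, adjustment="minimal"))
            arms.append(mvr_estimate(c, spec.name, adjustment="full"))
            tab = snp_outcome_scan(c, spec.name, adjust_offspring=False)
            tab.to_tsv(scan_dir / f"{spec.name}__{c.cohort_id}__unadjusted.tsv")
            if roster.offspring_adjusted_mr:
                adj = snp_outcome_scan(c, spec.name, adjust_offspring=True)
                adj.to_tsv(scan_dir / f"{spec.name}__{c.cohort_id}__adjusted.tsv")
    arm_estimates_to_tsv(arms, workdir / "arms_per_cohort.tsv")
    logger.info("associate: %d per-cohort regression arms", len(arms))


def stage_nc(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    cohorts = _cohorts(config)
    arms: list[ArmEstimate] = []
    for spec in config.simulation.outcomes:
        for c in cohorts:
            maternal, paternal = paternal_negative_control(c, spec.name)
            arms.extend([maternal, paternal])
    arm_estimates_to_tsv(arms, workdir / "nc_per_cohort.tsv")
    logger.info("nc: %d negative-control arms", len(arms))


def _load_arms(path: Path) -> list[ArmEstimate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        n_cases = None if pd.isna(r.n_cases) else int(r.n_cases)
        out.append(ArmEstimate(r.outcome, r.approach, r.effect, r.se,
                               r.ci_low, r.ci_high, int(r.n), n_cases))
    return out


def stage_meta(config: PipelineConfig, workdir: Path) -> None:
    """Pool per-cohort arms and per-SNP tables across cohorts."""
    workdir = Path(workdir)
    per_cohort = _load_arms(workdir / "arms_per_cohort.tsv")
    nc_per_cohort = _load_arms(workdir / "nc_per_cohort.tsv")
    pooled: list[ArmEstimate] = []
    for spec in config.simulation.outcomes:
        for approach in ("mvr_min", "mvr_full"):
            arms = [a for a in per_cohort
                    if a.outcome == spec.name and a.approach == approach]
            pooled.append(_pooled_arm(arms, approach, config.meta_method))
        for approach in ("mvr_mutual", "paternal_nc"):
            arms = [a for a in nc_per_cohort
                    if a.outcome == spec.name and a.approach == approach]
            pooled.append(_pooled_arm(arms, approach, config.meta_method))
    arm_estimates_to_tsv(pooled, workdir / "arms_pooled.tsv")

    pooled_dir = workdir / "pooled_scans"
    pooled_dir.mkdir(parents=True, exist_ok=True)
    scan_dir = workdir / "scans"
    for spec in config.simulation.outcomes:
        for label in ("unadjusted", "adjusted"):
            paths = sorted(scan_dir.glob(f"{spec.name}__*__{label}.tsv"))
            if not paths:
                continue
            tables = [AssociationTable.from_tsv(p, trait=spec.name,
                                                sample=p.stem.split("__")[1])
                      for p in paths]
            pool_per_snp(tables, method=config.meta_method).to_tsv(
                pooled_dir / f"{spec.name}__{label}.tsv")
    logger.info("meta: pooled %d arm groups", len(pooled))


def stage_mr(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    ref = AssociationTable.from_tsv(workdir / "summary" / "reference_gwas.tsv",
                                    trait="bmi", sample="reference_gwas")
    pooled_dir = workdir / "pooled_scans"
    scan_dir = workdir / "scans"
    rows, loo_rows = [], []
    for spec in config.simulation.outcomes:
        for label in ("unadjusted", "adjusted"):
            pooled_path = pooled_dir / f"{spec.name}__{label}.tsv"
            if not pooled_path.exists():
                continue
            outcome_tab = AssociationTable.from_tsv(pooled_path, trait=spec.name)
            model = TwoSampleMR(ref, outcome_tab)
            if label == "adjusted":
                fit = model.fit("ivw", effects_model=config.mr_effects_model)
                rows.append({"outcome": spec.name, "analysis": "mr_adjusted",
                             **fit.to_row()})
                continue
            for method in config.mr_methods:
                kwargs = {}
                if method == "ivw":
                    kwargs["effects_model"] = config.mr_effects_model
                if method in ("weighted_median", "weighted_mode"):
                    kwargs.update(n_boot=config.n_boot, seed=config.seed)
                fit = model.fit(method, **kwargs)
                rows.append({"outcome": spec.name, "analysis": "mr_main",
                             **fit.to_row()})
            cohort_paths = sorted(scan_dir.glob(f"{spec.name}__*__unadjusted.tsv"))
            if len(cohort_paths) >= 2:
                tables = [AssociationTable.from_tsv(p, trait=spec.name,
                                                    sample=p.stem.split("__")[1])
                          for p in cohort_paths]
                for omitted, fit in mr_leave_one_study_out(
                        tables, ref, method=config.meta_method,
                        effects_model=config.mr_effects_model):
                    loo_rows.append({"outcome": spec.name, "omitted": omitted,
                                     **fit.to_row()})
    pd.DataFrame(rows).to_csv(workdir / "mr.tsv", sep="\t", index=False,
                              float_format="%.8g")
    pd.DataFrame(loo_rows).to_csv(workdir / "mr_loo.tsv", sep="\t", index=False,
                                  float_format="%.8g")
    logger.info("mr: %d fits, %d leave-one-out fits", len(rows), len(loo_rows))


def _mr_arm(row) -> ArmEstimate:
    return ArmEstimate(row["outcome"], "mr_ivw", row["estimate"], row["se"],
                       row["ci_low"], row["ci_high"], 0, None)


def stage_triangulate(config: PipelineConfig, workdir: Path) -> dict:
    workdir = Path(workdir)
    pooled = _load_arms(workdir / "arms_pooled.tsv")
    mr_df = pd.read_csv(workdir / "mr.tsv", sep="\t")
    verdicts: list[Verdict] = []
    for spec in config.simulation.outcomes:
        by_approach = {a.approach: a for a in pooled if a.outcome == spec.name}
        ivw = mr_df[(mr_df["outcome"] == spec.name)
                    & (mr_df["analysis"] == "mr_main")
                    & (mr_df["method"].isin(["ivw", "wald"]))]
        mr_arm = _mr_arm(ivw.iloc[0]) if len(ivw) else None
        verdicts.append(triangulate_outcome(
            by_approach.get("mvr_full" if config.adjustment == "full" else "mvr_min"),
            mr_arm, by_approach.get("mvr_mutual"), by_approach.get("paternal_nc"),
            paternal_attenuation=config.paternal_attenuation,
            mr_ci_width_max=config.mr_ci_width_max))
    diagnostics = mr_df[mr_df["analysis"] != "mr_main"] if len(mr_df) else None
    counts = build_report(verdicts, pooled, diagnostics, workdir,
                          make_plots=config.make_plots)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "associate": stage_associate,
    "nc": stage_nc,
    "meta": stage_meta,
    "mr": stage_mr,
    "triangulate": stage_triangulate,
}

#: execution order: nc must precede meta (meta pools nc arms)
STAGE_ORDER = ("simulate", "associate", "nc", "meta", "mr", "triangulate")


def run_stage(name: str, config: PipelineConfig, workdir) -> None:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGE_ORDER}")
    try:
        return _STAGE_FUNCS[name](config, Path(workdir))
    except Exception as err:
        raise RuntimeError(f"stage {name!r} failed: {err}") from err


def write_manifest(config: PipelineConfig, workdir) -> None:
    manifest = {"scenario": config.scenario, "seed": config.seed,
                "config_hash": config.config_hash(), "version": __version__,
                "stages": list(STAGE_ORDER)}
    (Path(workdir) / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(config: PipelineConfig, workdir,
                 stages=STAGE_ORDER) -> dict | None:
    """Run the requested stages in order; returns verdict counts if the
    triangulate stage ran."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "config_used.yaml")
    counts = None
    for name in STAGE_ORDER:
        if name not in stages:
            continue
        result = run_stage(name, config, workdir)
        if name == "triangulate":
            counts = result
    write_manifest(config, workdir)
    return counts


def demo_config(scenario: str = "demo", n_cohorts: int = 3,
                n_families: int = 1500, n_snps: int = 12,
                seed: int = 0) -> PipelineConfig:
    """A small bundled scenario exercising every stage.

    Three outcomes: a true maternal effect (gestational hypertension), a
    null (perinatal depression), and a continuous trait (birthweight).
    """
    outcomes = [
        OutcomeSpec("gestational_hypertension", "binary", 0.15,
                    maternal_effect=float(np.log(1.67)),
                    couple_effect=0.05,
                    covariate_effects={"age": 0.1, "smoking": 0.2}),
        OutcomeSpec("perinatal_depression", "binary", 0.15,
                    covariate_effects={"smoking": 0.2}),
        OutcomeSpec("birthweight", "continuous", None,
                    maternal_effect=0.2,
                    offspring_score_effect=0.3),
    ]
    sim = SimulationConfig(n_families=n_families, n_snps=n_snps, seed=seed,
                           total_r2=0.1, couple_loading=np.sqrt(0.2),
                           confounder_loading_bmi=0.3,
                           covariate_loadings_bmi={"smoking": 0.1, "age": 0.1},
                           outcomes=outcomes, n_cohorts=n_cohorts)
    return PipelineConfig(scenario=scenario, simulation=sim,
                          reference_n=171_977, n_boot=100, seed=seed)
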