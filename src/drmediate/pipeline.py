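"""End-to-end pipeline: simulate -> impute -> score -> associate -> DR -> mediate.

Each stage reads/writes plain-text artifacts (CSV/TSV/JSON) under the output
directory and a run manifest records the config hash, per-stage seeds and the
emitted files, so a fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import AssociationModel, ModelSpec, fit_exposure_mediator_model
from .doubly_robust import DoublyRobustModel, e_value
from .imputation import ImputationConfig, rf_impute
from .measures import dichotomize_outcome, get_cutoffs, reverse_wellbeing
from .mediation import MediationModel
from .synthetic import OUTCOMES, GenerationConfig, apply_missingness, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_OUTCOME_CASE = {
    "smfq": "depression_case",
    "anxiety": "anxiety_case",
    "apss": "psychotic_case",
    "who5": "low_wellbeing_case",
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, stage configs and per-stage seeds for one pipeline run."""

    output_dir: str = "results"
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    n_boot: int = 1000
    interaction_n_boot: int = 200
    truncate_weights: tuple[float, float] | None = None  # IPW percentile truncation
    seeds: dict[str, int] = field(
        default_factory=lambda: {"dr_bootstrap": 11, "interaction": 12}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            gen = GenerationConfig(**raw.get("generation", {}))
            gen.validate()
            imp = ImputationConfig(**raw.get("imputation", {}))
            imp.validate()
            return cls(
                output_dir=raw.get("output_dir", "results"),
                generation=gen,
                imputation=imp,
                n_boot=int(raw.get("n_boot", 1000)),
                interaction_n_boot=int(raw.get("interaction_n_boot", 200)),
                truncate_weights=(
                    tuple(raw["truncate_weights"]) if raw.get("truncate_weights") else None
                ),
                seeds={**{"dr_bootstrap": 11, "interaction": 12}, **raw.get("seeds", {})},
            )
        except (TypeError, ValueError) as exc:
            raise PipelineError("config", str(exc)) from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    config.generation.validate()
    cohort = generate_cohort(config.generation)
    cohort = apply_missingness(cohort, config.generation)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "cohort.config.json").write_text(config.generation.to_json())
    return cohort


@_stage("impute")
def stage_impute(config: PipelineConfig, cohort: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    log: list = []
    completed = rf_impute(cohort, config.imputation, log=log)
    completed.to_csv(outdir / "cohort_completed.csv", index=False)
    (outdir / "imputation_log.json").write_text(json.dumps(log, indent=2))
    return completed


@_stage("score")
def stage_score(completed: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    rules = get_cutoffs()
    scored = completed.copy()
    scored["gaming_high"] = (scored["mediator_score"] >= rules.gaming_high_min).astype(int)
    scored["who5_w3_rev"] = reverse_wellbeing(scored["who5_w3"].to_numpy())

    # anxiety T reference: gender-specific wave-3 stats from the analysis sample
    ref = {
        g: {"mean": float(sub["anxiety_w3"].mean()), "sd": float(sub["anxiety_w3"].std(ddof=1))}
        for g, sub in scored.groupby("gender")
    }
    frame = scored.rename(
        columns={"smfq_w3": "smfq", "anxiety_w3": "anxiety",
                 "apss_w3": "apss", "who5_w3": "who5"}
    )[["smfq", "anxiety", "apss", "who5", "gender"]]
    cases = dichotomize_outcome(frame, rules, reference_stats=ref)
    scored = pd.concat([scored, cases], axis=1)
    scored.to_csv(outdir / "cohort_scored.csv", index=False)
    return scored


@_stage("associate")
def stage_associate(scored: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    rows = []
    overall_sd = float(scored["mediator_score"].std(ddof=1))
    for o in OUTCOMES:
        for tier in (1, 2, 3):
            spec = ModelSpec(tier=tier, exposure_sd=overall_sd)
            model = AssociationModel(scored, f"{o}_w3", "mediator_score", spec)
            rows.append(model.fit().summary())
            for res in model.fit_stratified("gender").values():
                rows.append(res.summary())
    # exposure -> mediator, fully adjusted
    est = fit_exposure_mediator_model(scored, ModelSpec(tier=3, roster_kind="mediator"))
    rows.append(pd.DataFrame([{
        "outcome": "mediator_score", "exposure": "exposure_score",
        "model": est.model, "stratum": est.stratum, "scale": est.scale,
        "estimate": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
        "se": est.se, "p": est.p_value,
    }]))
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    return table


@_stage("dr")
def stage_dr(scored: pd.DataFrame, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    extras: dict[str, dict] = {}
    for o in OUTCOMES:
        case = _OUTCOME_CASE[o]
        model = DoublyRobustModel(
            scored, case, "gaming_high", truncate_weights=config.truncate_weights
        )
        res = model.fit(n_boot=config.n_boot, seed=config.seeds["dr_bootstrap"])
        summ = res.summary()
        summ.insert(0, "label", o)
        rows.append(summ)

        ev = res.e_value()
        inter = model.interaction(
            modifier="gender", reference_modifier=1.0,
            n_boot=config.interaction_n_boot, seed=config.seeds["interaction"],
        )
        extras[o] = {
            "e_value_point": ev.evalue_point,
            "e_value_ci": ev.evalue_ci,
            "reri": inter.reri,
            "reri_ci": inter.reri_ci,
            "rrr": inter.rrr,
            "rrr_ci": inter.rrr_ci,
            "rr10": inter.rr10,
            "rr01": inter.rr01,
            "rr11": inter.rr11,
            "reference": inter.reference,
        }
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(outdir / "dr_estimates.tsv", sep="\t", index=False)
    (outdir / "interaction_evalues.json").write_text(json.dumps(extras, indent=2))
    return table


@_stage("mediate")
def stage_mediate(scored: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    rows = []
    pms: dict[str, dict] = {}
    for o in OUTCOMES:
        ycol = "who5_w3_rev" if o == "who5" else f"{o}_w3"
        model = MediationModel(scored, ycol)
        res = model.fit()
        summ = res.summary()
        summ.insert(0, "stratum", "overall")
        summ["p_tie"] = res.result.p_tie
        rows.append(summ)
        pms[o] = {"overall": summ.attrs["proportion_mediated_pct"]}
        for g, sres in model.fit_stratified("gender").items():
            ssumm = sres.summary()
            ssumm.insert(0, "stratum", f"gender={g:g}")
            ssumm["p_tie"] = sres.result.p_tie
            rows.append(ssumm)
            pms[o][f"gender={g:g}"] = ssumm.attrs["proportion_mediated_pct"]
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
    (outdir / "proportion_mediated.json").write_text(json.dumps(pms, indent=2))
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory stage results and writes
    all artifacts plus ``manifest.json`` under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = stage_simulate(config, outdir)
    completed = stage_impute(config, cohort, outdir)
    scored = stage_score(completed, outdir)
    assoc = stage_associate(scored, outdir)
    dr = stage_dr(scored, config, outdir)
    med = stage_mediate(scored, outdir)

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.name != "manifest.json"
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "cohort": cohort, "completed": completed, "scored": scored,
        "associations": assoc, "dr": dr, "mediation": med, "manifest": manifest,
    }
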