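"""End-to-end pipeline: simulate/load -> describe -> decompose -> growth ->
fit -> probe (-> recover), with a reproducible result bundle on disk.

Every stage is a pure function of its inputs and the config seed; reruns
with the same configuration reproduce all numeric outputs.  Stages fail
fast with stage-named errors so downstream tables never silently build on
a non-converged upstream model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analytical import (fit_analytical, predict_trajectories, simple_slopes,
                         test_fourway, test_threeway)
from .cohort import Cohort
from .config import (AnalysisConfig, AttritionConfig, GeneratorConfig,
                     PlantedTruth)
from .experiments import recovery_experiment
from .growth import compare_growth_forms
from .io import descriptives, read_cohort, write_cohort
from .synthetic import generate_cohort, truth_report

_FLOAT_FMT = "%.15g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _config_from_dict(d: dict) -> tuple[GeneratorConfig | None,
                                        AnalysisConfig, dict]:
    gen = None
    if "generator" in d:
        g = dict(d["generator"])
        if "planted" in g:
            p = dict(g["planted"])
            if "structural_betas" in p:
                p["structural_betas"] = {
                    k: tuple(v) for k, v in p["structural_betas"].items()}
            g["planted"] = PlantedTruth(**p)
        if "attrition" in g and g["attrition"] is not None:
            g["attrition"] = AttritionConfig(**g["attrition"])
        gen = GeneratorConfig(**g)
    analysis = AnalysisConfig(**d.get("analysis", {}))
    return gen, analysis, d


def load_config(path) -> tuple[GeneratorConfig | None, AnalysisConfig, dict]:
    """Read a YAML/JSON pipeline configuration."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return _config_from_dict(d or {})


def config_hash(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineRun:
    config_snapshot: dict
    config_hash: str
    seed: int
    out_dir: str
    stages: dict[str, str] = field(default_factory=dict)   # name -> status
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # name -> path
    results: dict = field(default_factory=dict, repr=False)

    def manifest(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "stages": self.stages, "timings_s": self.timings,
            "outputs": self.outputs,
        }


def run_pipeline(out_dir, *, generator: GeneratorConfig | None = None,
                 analysis: AnalysisConfig | None = None,
                 cohort_paths: tuple[str, str] | None = None,
                 stages: tuple[str, ...] = ("simulate", "describe",
                                            "decompose", "growth", "fit",
                                            "probe"),
                 recover_reps: int = 0) -> PipelineRun:
    """Execute the pipeline and write the result bundle under ``out_dir``."""
    if generator is None and cohort_paths is None:
        raise PipelineError("config", "need a generator block or cohort "
                            "file paths")
    analysis = analysis or AnalysisConfig()
    analysis.validate()
    stages = set(stages)
    if {"probe", "decompose"} & stages:
        stages |= {"fit"}   # probing/score tables derive from the joint fit
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = {
        "generator": None if generator is None else generator.to_dict(),
        "analysis": dataclasses.asdict(analysis),
        "cohort_paths": cohort_paths,
    }
    run = PipelineRun(config_snapshot=snapshot,
                      config_hash=config_hash(snapshot),
                      seed=(generator.seed if generator else analysis.seed),
                      out_dir=str(out))

    def stage(name):
        def deco(fn):
            if name not in stages and name not in ("simulate",):
                run.stages[name] = "skipped"
                return None
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # fail fast, stage-named
                run.stages[name] = f"failed: {exc}"
                _write_manifest(run, out)
                raise PipelineError(name, str(exc)) from exc
            run.stages[name] = "ok"
            run.timings[name] = round(time.perf_counter() - t0, 3)
            return result
        return deco

    # ---- cohort ----------------------------------------------------------
    if cohort_paths is not None:
        @stage("simulate")
        def cohort() -> Cohort:
            return read_cohort(*cohort_paths)
    else:
        @stage("simulate")
        def cohort() -> Cohort:
            c = generate_cohort(generator)
            paths = write_cohort(c, out / "cohort")
            run.outputs.update(paths)
            tr = truth_report(generator)
            p = out / "planted_truth.csv"
            tr.to_csv(p, index=False, float_format=_FLOAT_FMT)
            run.outputs["planted_truth"] = str(p)
            return c
    run.results["cohort"] = cohort

    if "describe" in stages:
        @stage("describe")
        def table1():
            t = descriptives(cohort)
            p = out / "descriptives.csv"
            t.to_csv(p, index=False, float_format=_FLOAT_FMT)
            run.outputs["descriptives"] = str(p)
            return t
        run.results["descriptives"] = table1

    if "growth" in stages:
        @stage("growth")
        def growth():
            cmp_ = compare_growth_forms(cohort, analysis.growth_forms,
                                        config=analysis)
            p = out / "growth_comparison.csv"
            cmp_.table.to_csv(p, index=False, float_format=_FLOAT_FMT)
            run.outputs["growth_comparison"] = str(p)
            run.results["growth_selected"] = cmp_.selected
            run.results["growth_rationale"] = cmp_.rationale
            return cmp_
        run.results["growth"] = growth

    if "fit" in stages or "probe" in stages or "decompose" in stages:
        @stage("fit")
        def fitted():
            res = fit_analytical(cohort,
                                 include_amyloid=analysis.include_amyloid,
                                 config=analysis)
            if not res.fit.converged:
                raise RuntimeError("joint analytical model did not converge")
            tab = res.coefficient_table()
            p = out / "analytical_coefficients.csv"
            tab.to_csv(p, index=False, float_format=_FLOAT_FMT)
            run.outputs["analytical_coefficients"] = str(p)
            return res
        run.results["analytical"] = fitted

        if "decompose" in stages and fitted is not None:
            @stage("decompose")
            def decomp():
                dec = fitted.decomposition
                sp = out / "decomposition_scores.csv"
                dec.scores.to_csv(sp, index=False, float_format=_FLOAT_FMT)
                vp = out / "decomposition_variance.json"
                with open(vp, "w") as fh:
                    json.dump({"components": dec.variance_components,
                               "shares": {k: v / dec.total_variance
                                          for k, v in
                                          dec.variance_components.items()},
                               "brain_weights": dec.brain_weights,
                               "demographic_weights":
                                   dec.demographic_weights}, fh, indent=2)
                run.outputs["decomposition_scores"] = str(sp)
                run.outputs["decomposition_variance"] = str(vp)
                return dec
            run.results["decomposition"] = decomp

        if "probe" in stages and fitted is not None:
            @stage("probe")
            def probe():
                tests = test_threeway(fitted)
                if analysis.include_amyloid:
                    tests += test_fourway(fitted)
                tests_df = pd.DataFrame([dataclasses.asdict(t)
                                         for t in tests])
                ss = simple_slopes(fitted)
                traj = predict_trajectories(fitted)
                for name, df in (("interaction_tests", tests_df),
                                 ("simple_slopes", ss),
                                 ("trajectory_grid", traj)):
                    p = out / f"{name}.csv"
                    df.to_csv(p, index=False, float_format=_FLOAT_FMT)
                    run.outputs[name] = str(p)
                return {"tests": tests_df, "simple_slopes": ss,
                        "trajectories": traj}
            run.results["probe"] = probe

    if recover_reps >= 2 and generator is not None:
        @stage("recover")
        def recover():
            rep = recovery_experiment(generator, reps=recover_reps,
                                      seed=generator.seed)
            p = out / "recovery.csv"
            rep.table.to_csv(p, index=False, float_format=_FLOAT_FMT)
            run.outputs["recovery"] = str(p)
            return rep
        run.results["recovery"] = recover

    _write_manifest(run, out)
    return run


def _write_manifest(run: PipelineRun, out: Path) -> None:
    with open(out / "run_manifest.json", "w") as fh:
        json.dump({**run.manifest(),
                   "config": run.config_snapshot}, fh, indent=2,
                  default=str)
    run.outputs["manifest"] = str(out / "run_manifest.json")
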