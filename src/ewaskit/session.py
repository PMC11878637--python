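"""Procedural analysis session: staged pipeline with logged artifacts.

Stages mirror the procedural EWAS workflow: ``init → load → trans →
batch → dmp → {boot, plot, enrich}``, with ``dmr`` independent of ``dmp``
and ``simulate`` available to materialize synthetic inputs. Each stage
writes its outputs into the session working directory and appends a
machine-readable log entry recording the parameters that produced them;
prerequisite stages are enforced.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import core, dmp as dmp_mod, dmr as dmr_mod, bootstrap as boot_mod
from . import batch as batch_mod, enrichment as enr_mod, plots as plot_mod, simulate as sim_mod

STAGES = ("init", "load", "trans", "batch", "dmp", "dmr", "plot", "boot", "enrich", "simulate")

#: stage → stages that must have completed first
PREREQUISITES = {
    "init": (),
    "simulate": ("init",),
    "load": ("init",),
    "trans": ("load",),
    "batch": ("load",),
    "dmp": ("load",),
    "dmr": ("load",),  # region calling does not require the DMP stage
    "plot": ("dmp",),
    "boot": ("dmp",),
    "enrich": ("dmp",),
}


class StageError(ValueError):
    """User-facing pipeline error (missing prerequisite, unknown stage...)."""


@dataclass
class SessionState:
    workdir: Path
    completed: list[str] = field(default_factory=list)
    artifacts: dict[str, dict] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    @property
    def state_path(self) -> Path:
        return self.workdir / "session.json"

    def save(self) -> None:
        payload = {
            "workdir": str(self.workdir),
            "completed": self.completed,
            "artifacts": self.artifacts,
            "log": self.log,
        }
        self.state_path.write_text(json.dumps(payload, indent=2, default=str))

    @classmethod
    def load(cls, workdir: str | Path) -> "SessionState":
        workdir = Path(workdir)
        path = workdir / "session.json"
        if not path.exists():
            raise StageError(f"no session in {workdir}; run the 'init' stage first")
        payload = json.loads(path.read_text())
        return cls(
            workdir=workdir,
            completed=payload.get("completed", []),
            artifacts=payload.get("artifacts", {}),
            log=payload.get("log", []),
        )

    def record(self, stage: str, params: dict, outputs: dict) -> None:
        self.artifacts[stage] = {k: str(v) for k, v in outputs.items()}
        if stage not in self.completed:
            self.completed.append(stage)
        self.log.append(
            {"stage": stage, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
             "params": params, "outputs": {k: str(v) for k, v in outputs.items()}}
        )
        self.save()

    def require(self, stage: str) -> None:
        for pre in PREREQUISITES[stage]:
            if pre not in self.completed:
                raise StageError(
                    f"stage {stage!r} requires stage {pre!r} to have completed first"
                )

    def path_of(self, stage: str, key: str) -> Path:
        try:
            return Path(self.artifacts[stage][key])
        except KeyError as exc:
            raise StageError(f"stage {stage!r} produced no artifact {key!r}") from exc


def _load_inputs(state: SessionState):
    src = "batch" if "batch" in state.completed else "load"
    mat_path = state.path_of(src, "matrix")
    value_type = state.artifacts["load"].get("value_type", "beta")
    matrix = core.load_methylation_matrix(mat_path, value_type=value_type)
    sheet_stage = "trans" if "trans" in state.completed else "load"
    sheet = core.load_sample_sheet(state.path_of(sheet_stage, "sheet"))
    factors_file = state.workdir / "factors.json"
    if factors_file.exists():
        spec = json.loads(factors_file.read_text())
        sheet = core.convert_variable_types(sheet, spec)
    ann = None
    if "annotation" in state.artifacts.get("load", {}):
        ann = core.load_annotation(
            state.path_of("load", "annotation"),
            state.artifacts["load"].get("platform", "450K"),
        )
    return matrix, sheet, ann


def _model_spec_from(config: dict) -> core.ModelSpec:
    return core.ModelSpec(
        model=config.get("model", "glm"),
        exposure=config.get("exposure"),
        covariates=list(config.get("covariates", [])),
        scaling=config.get("scale", "unit"),
        random_group=config.get("random_group"),
        time_var=config.get("time"),
        event_var=config.get("event"),
    )


def run_stage(stage: str, config: dict) -> SessionState:
    """Execute one pipeline stage; returns the updated session state.

    ``config`` must contain ``workdir``; remaining keys are stage-specific
    (documented in the CLI help). Raises :class:`StageError` on unknown
    stages or missing prerequisites.
    """
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}; valid stages: {list(STAGES)}")
    workdir = Path(config.get("workdir", "."))

    if stage == "init":
        workdir.mkdir(parents=True, exist_ok=True)
        state = SessionState(workdir=workdir)
        state.record("init", {k: v for k, v in config.items()}, {"workdir": workdir})
        return state

    state = SessionState.load(workdir)
    state.require(stage)
    params = {k: v for k, v in config.items() if k != "workdir"}

    if stage == "simulate":
        preset = config.get("preset", "glm")
        seed = int(config.get("seed", 0))
        out = {}
        if preset == "coxph":
            matrix, sheet, _ = sim_mod.simulate_survival_dataset(seed=seed)
            ann = None
        elif preset == "dmr":
            matrix, sheet, ann, _ = sim_mod.simulate_dmr_dataset(seed=seed)
        elif preset == "lmm":
            matrix, sheet, ann, _ = sim_mod.simulate_ewas_dataset(
                n_samples=60, n_probes=2000, n_timepoints=2, subject_sd=0.1, seed=seed
            )
        elif preset == "batch":
            matrix, sheet, ann, _ = sim_mod.simulate_ewas_dataset(
                n_probes=2000, batch_spec={"n_batches": 2, "shift": 0.1}, seed=seed
            )
        else:
            matrix, sheet, ann, _ = sim_mod.simulate_ewas_dataset(seed=seed)
        matrix.save(workdir / "matrix.csv")
        sheet.save(workdir / "sheet.csv")
        out = {"matrix": workdir / "matrix.csv", "sheet": workdir / "sheet.csv",
               "value_type": matrix.value_type}
        if ann is not None:
            core._write_table(ann.drop(columns=["platform"]), workdir / "annotation.csv")
            out["annotation"] = workdir / "annotation.csv"
            out["platform"] = "450K"
        factor_spec = {name: "factor" for name in sheet.factors}
        (workdir / "factors.json").write_text(json.dumps(factor_spec))
        state.record("simulate", params, out)
        # a simulate stage doubles as the load stage for downstream steps
        state.record("load", {"from": "simulate"}, out)
        return state

    if stage == "load":
        matrix = core.load_methylation_matrix(
            config["matrix"], value_type=config.get("value_type", "beta")
        )
        sheet = core.load_sample_sheet(config["sheet"])
        matrix, sheet = core.align_samples(matrix, sheet)
        matrix.save(workdir / "matrix.csv")
        sheet.save(workdir / "sheet.csv")
        out = {"matrix": workdir / "matrix.csv", "sheet": workdir / "sheet.csv",
               "value_type": matrix.value_type}
        if config.get("annotation"):
            ann = core.load_annotation(config["annotation"], config.get("platform", "450K"))
            core._write_table(ann.drop(columns=["platform"]), workdir / "annotation.csv")
            out["annotation"] = workdir / "annotation.csv"
            out["platform"] = config.get("platform", "450K")
        state.record("load", params, out)
        return state

    if stage == "trans":
        matrix, sheet, _ = _load_inputs(state)
        spec = config.get("types", {})
        sheet = core.convert_variable_types(sheet, spec)
        sheet.save(workdir / "sheet.csv")
        (workdir / "factors.json").write_text(json.dumps(spec))
        state.record("trans", params, {"sheet": workdir / "sheet.csv"})
        return state

    if stage == "batch":
        matrix, sheet, _ = _load_inputs(state)
        batch_var = config["batch_var"]
        if not sheet.is_factor(batch_var):
            sheet = core.convert_variable_types(sheet, {batch_var: "factor"})
        corrected, _model = batch_mod.combat_adjust(
            matrix, sheet, batch_var, config.get("protect", [])
        )
        corrected.save(workdir / "matrix_corrected.csv")
        state.record("batch", params, {"matrix": workdir / "matrix_corrected.csv"})
        return state

    if stage == "dmp":
        matrix, sheet, ann = _load_inputs(state)
        spec = _model_spec_from(config)
        table = dmp_mod.run_dmp(matrix, sheet, spec, ann,
                                n_workers=int(config.get("workers", 1)))
        table.to_csv(workdir / "dmp.csv", index=False)
        state.record("dmp", params, {"table": workdir / "dmp.csv", "model": spec.model})
        return state

    if stage == "dmr":
        matrix, sheet, ann = _load_inputs(state)
        if ann is None:
            raise StageError("dmr requires an annotation file at the load stage")
        dparams = dmr_mod.DMRParams(
            bandwidth_lambda=float(config.get("bandwidth", 1000.0)),
            scaling_C=float(config.get("C", 2.0)),
            site_fdr_threshold=float(config.get("fdr", 0.05)),
            min_cpgs=int(config.get("min_cpgs", 2)),
        )
        table = dmr_mod.run_dmr(matrix, sheet, config["exposure"], ann,
                                list(config.get("covariates", [])), dparams)
        table.to_csv(workdir / "dmr.csv", index=False)
        out = {"table": workdir / "dmr.csv"}
        if config.get("bed"):
            core.dmrs_to_bed(table, workdir / "dmr.bed")
            out["bed"] = workdir / "dmr.bed"
        state.record("dmr", params, out)
        return state

    if stage == "plot":
        table = pd.read_csv(state.path_of("dmp", "table"))
        cfg = plot_mod.PlotConfig(layout=config.get("layout", "rectangular"))
        kind = config.get("kind", "manhattan")
        out = {}
        if kind == "manhattan":
            out["plot"] = plot_mod.manhattan_plot(table, workdir / "manhattan.png", cfg)
        elif kind == "qq":
            path, lam = plot_mod.qq_plot(table, workdir / "qq.png", cfg)
            out["plot"], out["lambda"] = path, lam
        elif kind == "density":
            _, _, ann = _load_inputs(state)
            if ann is None:
                raise StageError("density plot requires annotation")
            out["plot"] = plot_mod.cpg_density_plot(ann, workdir / "density.png")
        else:
            raise StageError(f"unknown plot kind {kind!r}")
        state.record("plot", params, out)
        return state

    if stage == "boot":
        matrix, sheet, _ = _load_inputs(state)
        table = pd.read_csv(state.path_of("dmp", "table"))
        spec = _model_spec_from(config)
        criterion = config.get("select", "fdr<0.05")
        probes = (
            [p.strip() for p in Path(config["probes"]).read_text().split()]
            if config.get("probes")
            else boot_mod.select_sites(table, criterion)
        )
        result = boot_mod.run_bootstrap_validation(
            matrix, sheet, spec, probes,
            ci_types=list(config.get("ci_types", ["percentile"])),
            B=int(config.get("B", 999)),
            level=float(config.get("level", 0.95)),
            seed=int(config.get("seed", 0)),
        )
        result.to_csv(workdir / "boot.csv", index=False)
        state.record("boot", params, {"table": workdir / "boot.csv"})
        return state

    if stage == "enrich":
        table = pd.read_csv(state.path_of("dmp", "table"))
        sig, universe = enr_mod.map_sites_to_genes(table, config.get("select", "fdr<0.05"))
        sets = enr_mod.read_gmt(config["gmt"])
        result = enr_mod.overrepresentation_test(
            sig, universe, sets,
            min_size=int(config.get("min_size", 10)),
            max_size=int(config.get("max_size", 500)),
        )
        result.to_csv(workdir / "enrich.csv", index=False)
        out = {"table": workdir / "enrich.csv"}
        if config.get("plot") and not result.empty:
            out["plot"] = enr_mod.enrichment_plot(
                result, workdir / f"enrich_{config['plot']}.png", kind=config["plot"]
            )
        state.record("enrich", params, out)
        return state

    raise StageError(f"unhandled stage {stage!r}")  # pragma: no cover
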