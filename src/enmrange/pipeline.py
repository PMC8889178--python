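"""End-to-end orchestration from a single flat configuration.

``run_all`` drives the complete analysis for every species in an
occurrence compilation: record filtering, absence derivation,
collinearity filtering of continuous layers, the 10-method × 3-run
candidate model set, ROC-gated weighted-mean ensembles with variable
importance, projection onto current and future scenario stacks,
consensus binary maps, transition classification, dispersal/no-dispersal
range change, and fragmentation reports.  Outputs are plain CSV tables
and ESRI ASCII grids under one run directory, plus a machine-readable
JSON run log capturing seeds, thresholds and per-stage counts.

The configuration is a flat YAML mapping with exactly the keys of
:class:`RunConfig`; unknown keys are rejected so settings cannot drift
silently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geodata, varsel, modeling, ensemble as ens, range_dynamics as rd
from . import fragstats, synth
from .geodata import EnvStack, ExtentConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # inputs: either synthetic generation or on-disk layers/occurrences
    synthetic: bool = True
    layers_dir: str = ""
    categorical_layers: tuple[str, ...] = ("soil",)
    occurrences: str = ""
    scenario_dirs: dict = field(default_factory=dict)  # name -> layer dir
    out_dir: str = "enmrange_run"
    # synthetic-world settings (ignored when synthetic=False)
    world_shape: tuple[int, int] = (100, 100)
    n_species: int = 14
    n_sites: int = 400
    scenario_deltas: dict = field(
        default_factory=lambda: dict(synth.DEFAULT_SCENARIO_DELTAS))
    # study extent
    lat_min: float = -49.0
    lat_max: float = -32.0
    lon_min: float = 165.0
    lon_max: float = 180.0
    # analysis settings (defaults are the study settings)
    vif_threshold: float = 0.85
    vif_scope: str = "points"  # or "raster"
    methods: tuple[str, ...] = tuple(modeling.METHODS)
    n_runs: int = 3
    calibration_fraction: float = 0.8
    prevalence: float = 0.5
    n_importance_perms: int = 3
    roc_gate: float = 0.9
    roc_fallback: float = 0.8
    consensus: float = 0.5
    connectivity: int = 8
    min_patch_km2: float = 0.1
    cutoff_rule: str = "tss_max"
    min_presences: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a flat key/value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "categorical_layers", "world_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def extent(self) -> ExtentConfig:
        return ExtentConfig(lat_min=self.lat_min, lat_max=self.lat_max,
                            lon_min=self.lon_min, lon_max=self.lon_max)


def _load_inputs(config: RunConfig):
    """Returns (current stack, {scenario name: stack}, raw occurrences)."""
    if config.synthetic:
        spec = synth.WorldSpec(shape=tuple(config.world_shape))
        world = synth.generate_world(spec, seed=config.seed)
        niches = synth.default_niches(world, n_species=config.n_species,
                                      seed=config.seed)
        occ = synth.sample_occurrences(world, niches, n_sites=config.n_sites,
                                       seed=config.seed + 1)
        scenarios = {}
        for name, delta in config.scenario_deltas.items():
            if name == "current":
                continue
            scenarios[name] = synth.apply_scenario(
                world, synth.ScenarioSpec(name=name, temperature_delta=delta))
        return world, scenarios, occ

    layers_dir = Path(config.layers_dir)
    if not layers_dir.is_dir():
        raise ConfigError(f"layers_dir not found: {layers_dir}")
    paths = sorted(layers_dir.glob("*.asc"))
    if not paths:
        raise ConfigError(f"no .asc layers in {layers_dir}")
    names = [p.stem for p in paths]
    kinds = ["categorical" if n in config.categorical_layers else "continuous"
             for n in names]
    stack = geodata.read_env_stack(paths, kinds, names)
    stack = geodata.crop_extent(stack, config.extent)
    scenarios = {}
    for name, sdir in config.scenario_dirs.items():
        spaths = [Path(sdir) / f"{n}.asc" for n in names]
        missing = [p for p in spaths if not p.exists()]
        if missing:
            raise ConfigError(f"scenario {name}: missing layer files {missing}")
        sstack = geodata.read_env_stack(spaths, kinds, names)
        scenarios[name] = geodata.crop_extent(sstack, config.extent)
    occ_path = Path(config.occurrences)
    if not occ_path.exists():
        raise ConfigError(f"occurrences file not found: {occ_path}")
    occ = geodata.read_occurrences(occ_path)
    return stack, scenarios, occ


def _select_variables(config: RunConfig, stack: EnvStack,
                      X_points: pd.DataFrame) -> tuple[list[str], varsel.VifReport]:
    cont = stack.continuous_names
    if len(cont) < 2:
        report = varsel.VifReport(vif={c: 1.0 for c in cont}, retained=list(cont),
                                  threshold=config.vif_threshold)
        return cont + stack.categorical_names, report
    if config.vif_scope == "raster":
        rows, cols = np.nonzero(stack.mask)
        Xc = stack.design_matrix(rows, cols)[cont]
    else:
        Xc = X_points[cont]
    report = varsel.vif_filter(Xc, threshold=config.vif_threshold)
    return report.retained + stack.categorical_names, report


def run_species(config: RunConfig, stack: EnvStack, scenarios: dict,
                occ: pd.DataFrame, species: str, variables: list[str],
                out_dir: Path, log: dict) -> dict | None:
    """Full per-species analysis; returns the species log entry."""
    entry: dict = {"species": species}
    table = geodata.derive_absences(occ, species, stack)
    X, y, n_dropped = geodata.extract_covariates(stack, table)
    entry["n_presences"] = int((y == 1).sum())
    entry["n_absences"] = int((y == 0).sum())
    entry["n_dropped_masked"] = n_dropped
    if entry["n_presences"] < config.min_presences or entry["n_absences"] < 2:
        entry["status"] = "skipped: too few records"
        return entry
    X = X[variables]
    categorical = [v for v in variables if v in stack.categorical_names]

    models, failures = modeling.fit_all(
        X, y, categorical=categorical, methods=list(config.methods),
        n_runs=config.n_runs, seed=config.seed,
        calibration_fraction=config.calibration_fraction,
        prevalence=config.prevalence,
        n_importance_permutations=config.n_importance_perms)
    entry["n_models_fitted"] = len(models)
    entry["n_models_failed"] = len(failures)
    if not models:
        entry["status"] = "skipped: every model failed"
        return entry

    sp_dir = out_dir / species
    sp_dir.mkdir(parents=True, exist_ok=True)
    modeling.evaluation_table(models, species).to_csv(
        sp_dir / "evaluation.csv", index=False)
    modeling.importance_table(models, species).to_csv(
        sp_dir / "importance.csv", index=False)

    try:
        emodel = ens.build_ensemble(models, threshold=config.roc_gate,
                                    fallback=config.roc_fallback,
                                    n_methods=len(config.methods),
                                    X_test=X, y_test=y)
    except ens.NoEnsembleError as exc:
        entry["status"] = f"skipped: {exc}"
        return entry
    entry["ensemble_threshold"] = emodel.threshold_used
    entry["ensemble_n_members"] = len(emodel.members)
    entry["ensemble_roc"] = emodel.scores.roc
    ens.ensemble_report(emodel, species).to_csv(
        sp_dir / "ensemble.csv", index=False)
    emodel.emwm_importance.rename("pct").rename_axis("variable").to_csv(
        sp_dir / "emwm_importance.csv")

    all_scen = {"current": stack, **scenarios}
    cutoffs = [m.cutoff for m in models]
    binaries: dict[str, rd.BinaryMap] = {}
    cell_areas = stack.cell_areas()
    rc_rows, frag_reports = [], {}
    for name, scen_stack in all_scen.items():
        maps = rd.project_models(models, scen_stack, variables)
        suit = rd.project_ensemble(emodel, scen_stack, variables)
        geodata.write_ascii_grid(sp_dir / f"suitability_{name}.asc", suit,
                                 scen_stack.extent, scen_stack.resolution)
        binary = rd.binarize_consensus(maps, cutoffs, scen_stack.mask,
                                       consensus=config.consensus)
        binaries[name] = binary
        geodata.write_ascii_grid(sp_dir / f"binary_{name}.asc", binary.grid,
                                 scen_stack.extent, scen_stack.resolution)
        frag_reports[name] = fragstats.frag_report(
            binary, connectivity=config.connectivity,
            min_area=config.min_patch_km2, cell_areas=cell_areas)

    for name in scenarios:
        trans = rd.classify_transitions(binaries["current"], binaries[name])
        grid = np.where(trans.mask, trans.classes, np.nan).astype(float)
        geodata.write_ascii_grid(sp_dir / f"transition_{name}.asc", grid,
                                 stack.extent, stack.resolution)
        entry[f"transitions_{name}"] = trans.counts()
        try:
            rc_rows.append(rd.range_change_table(trans, species, name,
                                                 connectivity=config.connectivity))
        except rd.EmptyRangeError:
            entry["status"] = "no current consensus range; change undefined"
    if rc_rows:
        pd.concat(rc_rows, ignore_index=True).to_csv(
            sp_dir / "range_change.csv", index=False)
    fragstats.compare_reports(frag_reports).assign(species=species).to_csv(
        sp_dir / "fragmentation.csv", index=False)
    entry["status"] = "ok"
    return entry


def run_all(config: RunConfig) -> Path:
    """Run the complete analysis; returns the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(config).items()},
                 "species": []}

    stack, scenarios, occ_raw = _load_inputs(config)
    occ, filt = geodata.filter_occurrences(occ_raw, config.extent)
    log["filtering"] = asdict(filt)
    occ.to_csv(out_dir / "occurrences_filtered.csv", index=False)

    # variable selection on the pooled presence design matrix
    X_all, _, _ = geodata.extract_covariates(stack, occ)
    variables, vif_report = _select_variables(config, stack, X_all)
    vif_report.to_frame().to_csv(out_dir / "vif_report.csv", index=False)
    log["variables_retained"] = variables

    species_list = sorted(occ.loc[occ["presence"] == 1, "species"].unique())
    for sp in species_list:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            entry = run_species(config, stack, scenarios, occ, sp, variables,
                                out_dir, log)
        if entry is not None:
            log["species"].append(entry)

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    report_table(out_dir).to_csv(out_dir / "summary.csv", index=False)
    return out_dir


def report_table(run_dir: str | Path) -> pd.DataFrame:
    """Per-species summary: top ensemble variable and net range changes.

    One row per completed species with its most important predictor
    (highest ensemble importance percentage) and the net range-change
    percentage for every scenario × dispersal mode, rounded to the
    nearest integer as in the study's summary table.
    """
    run_dir = Path(run_dir)
    rows = []
    for sp_dir in sorted(p for p in run_dir.iterdir() if p.is_dir()):
        imp_path = sp_dir / "emwm_importance.csv"
        rc_path = sp_dir / "range_change.csv"
        if not (imp_path.exists() and rc_path.exists()):
            continue
        imp = pd.read_csv(imp_path, index_col=0)["pct"]
        rc = pd.read_csv(rc_path)
        row = {"species": sp_dir.name,
               "top_variable": imp.idxmax(),
               "top_variable_pct": round(float(imp.max()), 1)}
        for _, r in rc.iterrows():
            row[f"net_{r['scenario']}_{r['mode']}"] = int(round(r["net_change_pct"]))
        rows.append(row)
    return pd.DataFrame(rows)
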