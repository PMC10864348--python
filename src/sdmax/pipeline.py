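"""Config-driven orchestration: simulate → screen → fit → evaluate →
project → range change, with seeded reproducibility and a run manifest.

The YAML config (see :class:`RunConfig`) names the raster directory, the
occurrence CSVs, and the analysis settings; ``run_pipeline`` loops over
species and writes, per species, the collinearity report, the fitted model,
the evaluation and importance tables, current and future suitability and
binary maps, and one combined gain/loss/change CSV across species and
scenarios. ``simulate`` writes a fully synthetic dataset of identical
schema (plus the generating-truth YAML) so the pipeline can be exercised
end-to-end without external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collinearity import FilterConfig, greedy_collinearity_filter, pearson_matrix
from .evaluate import (
    EvalConfig,
    importance_table,
    jackknife,
    kfold_cv,
    percent_contribution,
    permutation_importance,
)
from .grids import GridStack, read_raster_stack, write_ascii_grid
from .maxent import FeatureSpec, fit_maxent
from .occurrences import dedupe_to_cells, read_occurrences
from .projection import ScenarioSet, binarize, project, run_scenarios
from .sampling import extract_values, sample_background
from .synth import ScenarioShift, TrueModel, apply_shift, generate_landscape, \
    sample_presences, true_suitability

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is structurally invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Validated pipeline settings (see ``examples/`` for a worked config)."""

    raster_dir: str
    occurrences: list[dict]              # [{species, path}, ...]
    output_dir: str
    layers: list[str] | None = None
    seed: int = 0
    background_size: int = 10_000
    dedupe: bool = True
    filter_threshold: float = 0.70
    filter_priority: list[str] = field(default_factory=list)
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    beta0: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    k_folds: int = 10
    permutation_repeats: int = 10
    scenarios: list[dict] = field(default_factory=list)
    # [{label, horizon, raster_dir} or {label, horizon, member_dirs: [...]}]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        missing = {"raster_dir", "occurrences", "output_dir"} - set(raw)
        if missing:
            raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
        raw["feature_classes"] = tuple(raw.get("feature_classes", ("linear", "quadratic")))
        cfg = cls(**raw)
        base = Path(path).parent
        cfg._resolve_paths(base)
        return cfg

    def _resolve_paths(self, base: Path) -> None:
        def res(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        self.raster_dir = res(self.raster_dir)
        self.output_dir = res(self.output_dir)
        for occ in self.occurrences:
            occ["path"] = res(occ["path"])
        for sc in self.scenarios:
            if "raster_dir" in sc:
                sc["raster_dir"] = res(sc["raster_dir"])
            if "member_dirs" in sc:
                sc["member_dirs"] = [res(d) for d in sc["member_dirs"]]

    def digest(self) -> str:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        doc["feature_classes"] = list(doc["feature_classes"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_stack(directory: str | Path, layers: list[str] | None) -> GridStack:
    directory = Path(directory)
    if layers:
        paths = [directory / f"{name}.asc" for name in layers]
        names = list(layers)
    else:
        paths = sorted(directory.glob("*.asc"))
        names = [p.stem for p in paths]
    if not paths:
        raise StageError(f"load: no .asc rasters found in {directory}")
    return read_raster_stack(paths, names)


def _write_grid(path: Path, grid: np.ndarray, stack: GridStack) -> None:
    write_ascii_grid(path, grid, stack.transform, stack.nodata_value)


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        stack = _load_stack(config.raster_dir, config.layers)
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc

    seeds = np.random.SeedSequence(config.seed)
    bg_seed, eval_seed, pi_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in seeds.spawn(3)
    ]

    change_rows: list[pd.DataFrame] = []
    manifest: dict = {
        "sdmax_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stage_seeds": {"background": bg_seed, "eval": eval_seed, "permutation": pi_seed},
        "species": {},
    }

    for entry in config.occurrences:
        species = entry["species"]
        sp_out = out / species.replace(" ", "_")
        sp_out.mkdir(parents=True, exist_ok=True)
        artifacts: dict = {}

        try:
            occ = read_occurrences(entry["path"], species=species)
            if config.dedupe:
                occ = dedupe_to_cells(occ, stack)
            presences = extract_values(stack, occ, kind="presence")
            background = sample_background(stack, config.background_size, bg_seed)
        except Exception as exc:
            raise StageError(f"data[{species}]: {exc}") from exc

        try:
            matrix = pearson_matrix(background)
            report = greedy_collinearity_filter(
                matrix,
                FilterConfig(config.filter_threshold, list(config.filter_priority)),
            )
            report.write(sp_out / "correlation_matrix.csv", sp_out / "filter.yaml")
            artifacts["filter"] = str(sp_out / "filter.yaml")
            kept = report.kept
        except Exception as exc:
            raise StageError(f"filter[{species}]: {exc}") from exc

        settings = {
            "beta0": config.beta0,
            "tol": config.tol,
            "max_iter": config.max_iter,
        }
        try:
            eval_cfg = EvalConfig(
                k_folds=config.k_folds,
                seed=eval_seed,
                permutation_repeats=config.permutation_repeats,
            )
            evaluation = kfold_cv(
                presences.subset(kept),
                background.subset(kept),
                {"classes": config.feature_classes, **settings},
                eval_cfg,
            )
            evaluation.to_frame().to_csv(sp_out / "evaluation.csv", index=False)
            artifacts["evaluation"] = str(sp_out / "evaluation.csv")
        except Exception as exc:
            raise StageError(f"evaluate[{species}]: {exc}") from exc

        try:
            spec = FeatureSpec.from_background(
                background.subset(kept), classes=config.feature_classes
            )
            P = spec.build(presences)
            B = spec.build(background)
            model, trace = fit_maxent(P, B, spec, **settings)
            model.to_yaml(sp_out / "model.yaml")
            artifacts["model"] = str(sp_out / "model.yaml")

            pc = percent_contribution(trace, layers=kept)
            pi = permutation_importance(
                model,
                presences.subset(kept),
                background.subset(kept),
                repeats=config.permutation_repeats,
                seed=pi_seed,
            )
            jack = jackknife(
                presences.subset(kept),
                background.subset(kept),
                layers=kept,
                model_settings={"classes": config.feature_classes, **settings},
            )
            importance_table(pc, pi, jack).to_csv(sp_out / "importance.csv")
            artifacts["importance"] = str(sp_out / "importance.csv")
        except Exception as exc:
            raise StageError(f"fit[{species}]: {exc}") from exc

        try:
            suit = project(model, stack)
            _write_grid(sp_out / "suitability_current.asc", suit, stack)
            cur_map = binarize(suit, evaluation.threshold, label="current")
            _write_grid(
                sp_out / "binary_current.asc",
                np.where(cur_map.valid, cur_map.suitable.astype(float), np.nan),
                stack,
            )
            scenario_sets = []
            for sc in config.scenarios:
                dirs = sc.get("member_dirs") or [sc["raster_dir"]]
                members = [_load_stack(d, config.layers) for d in dirs]
                scenario_sets.append(
                    ScenarioSet(label=sc["label"], horizon=str(sc["horizon"]), members=members)
                )
            if scenario_sets:
                table = run_scenarios(
                    model, stack, scenario_sets, evaluation.threshold, species=species
                )
                change_rows.append(table)
                for sc_set in scenario_sets:
                    fut = project(model, apply_members_mean(sc_set))
                    tag = f"{sc_set.label}-{sc_set.horizon}"
                    _write_grid(sp_out / f"suitability_{tag}.asc", fut, stack)
        except Exception as exc:
            raise StageError(f"project[{species}]: {exc}") from exc

        manifest["species"][species] = {
            "n_presences": len(presences),
            "n_background": len(background),
            "kept_variables": kept,
            "mean_cv_auc": evaluation.mean_auc,
            "threshold": evaluation.threshold,
            "artifacts": artifacts,
        }

    if change_rows:
        change = pd.concat(change_rows, ignore_index=True)
        change_path = out / "range_change.csv"
        change.to_csv(change_path, index=False, float_format="%.10g")
        manifest["range_change"] = str(change_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def apply_members_mean(sc: ScenarioSet) -> GridStack:
    from .projection import average_members

    return average_members(sc)


# ---------------------------------------------------------------------------
# synthetic demo dataset
# ---------------------------------------------------------------------------

DEMO_TRUE_MODEL = TrueModel(linear={"env1": 2.0, "env2": -1.5})

DEMO_SHIFTS = [
    ScenarioShift("RCP4.5-2050", delta={"env1": -0.5}),
    ScenarioShift("RCP4.5-2070", delta={"env1": -0.8}),
    ScenarioShift("RCP8.5-2050", delta={"env1": -1.0}),
    ScenarioShift("RCP8.5-2070", delta={"env1": -1.6}),
]


def simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_layers: int = 9,
    shape: tuple[int, int] = (150, 150),
    smooth_radius: float = 3.0,
    n_presences: int = 300,
    true_model: TrueModel | None = None,
    shifts: list[ScenarioShift] | None = None,
    species: str = "virtual",
) -> dict:
    """Write a synthetic dataset (rasters, occurrences, futures, truth).

    The default emulates a modest survey: 9 autocorrelated predictor
    layers on a 150×150 grid, 300 presence records drawn from a Gibbs
    response on two of the layers, and four shifted future stacks labeled
    like RCP scenario/horizon combinations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    true_model = true_model or DEMO_TRUE_MODEL
    shifts = DEMO_SHIFTS if shifts is None else shifts

    rng = np.random.default_rng(seed)
    stack = generate_landscape(n_layers, shape, smooth_radius, seed=rng)
    current_dir = out / "current"
    stack.write(current_dir)

    suit = true_suitability(stack, true_model)
    occ = sample_presences(suit, stack, n_presences, seed=rng, species=species)
    occ_path = out / "occurrences.csv"
    occ.write_csv(occ_path)
    true_model.to_yaml(out / "truth.yaml")

    scenario_entries = []
    for shift in shifts:
        fut = apply_shift(stack, shift)
        d = out / f"future_{shift.label}"
        fut.write(d)
        label, _, horizon = shift.label.rpartition("-")
        scenario_entries.append(
            {"label": label or shift.label, "horizon": horizon, "raster_dir": d.name}
        )

    # paths in the config are relative to the config file's directory
    config = {
        "raster_dir": current_dir.name,
        "occurrences": [{"species": species, "path": occ_path.name}],
        "output_dir": "results",
        "seed": int(seed),
        "scenarios": scenario_entries,
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return {
        "config": str(cfg_path),
        "rasters": str(current_dir),
        "occurrences": str(occ_path),
        "truth": str(out / "truth.yaml"),
        "n_presences": len(occ),
        "scenarios": scenario_entries,
    }
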