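"""One-command orchestration: simulate -> preprocess -> per-day analyses.

``run_pipeline`` produces a deterministic report directory::

    cohort/          measurements.csv severity.csv outcomes.csv
    tests/           per-day Dunnett comparisons (sepsis and critical split)
    networks/        correlations, clusters, fold changes, GraphML/SIF graphs
    scores/          per-day combined-score tables and cut points
    associations/    Spearman grids vs SOFA / JAAM / ISTH
    survival/        time-dependent Cox table (unadjusted and SOFA-adjusted)
    roc/             day-1 penalized-ROC comparison table
    run_manifest.json, status.json

Stage failures are isolated: a failed stage records its error in
``status.json``, dependent stages are skipped, and the run reports failure.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cytonet import __version__
from cytonet.errors import ConfigError, CytonetError
from cytonet.group_tests import compare_day_to_controls, split_by_sofa
from cytonet.io import Cohort, build_day_matrix, control_matrix, read_cohort
from cytonet.markers import MEDIATORS, SCORE_SETS
from cytonet.network import (
    DEFAULT_CUT_HEIGHT,
    build_network,
    fold_changes,
    pearson_matrix,
    ward_cluster,
)
from cytonet.roc import roc_comparison_table
from cytonet.scoring import make_definition, score_table, severity_association_table
from cytonet.simulate import SimulationConfig, make_cohort
from cytonet.survival import acute_phase_cox_table


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read an existing cohort instead of simulating
    analysis_days: tuple[int, ...] = (1, 2, 4)
    acute_days: tuple[int, ...] = (1, 2, 4)
    later_days: tuple[int, ...] = (6, 8, 11)
    alpha: float = 0.05
    fold_change_threshold: float = 1.5
    sofa_cutoff: int = 12
    cluster_cut_height: float = DEFAULT_CUT_HEIGHT
    score_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in SCORE_SETS.items()}
    )
    seed: int = 0

    def validate(self, sampling_days: tuple[int, ...]) -> None:
        if self.alpha <= 0 or self.fold_change_threshold <= 0:
            raise ConfigError("alpha and fold-change threshold must be positive")
        missing = set(self.acute_days) - set(sampling_days)
        if missing:
            raise ConfigError(
                f"acute-phase days {sorted(missing)} absent from sampling days {sampling_days}"
            )
        if set(self.analysis_days) - set(sampling_days):
            raise ConfigError("analysis days must be a subset of sampling days")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**{k: _tuplify(v) for k, v in raw.items()})
        if sim:
            cfg.simulation = SimulationConfig(**{k: _tuplify(v) for k, v in sim.items()})
        if "seed" in raw:
            cfg.simulation = SimulationConfig(
                **{**asdict(cfg.simulation), "seed": cfg.seed}
            )
        return cfg


def _tuplify(v):
    if isinstance(v, list):
        return tuple(v)
    if isinstance(v, dict):
        return {k: _tuplify(x) for k, x in v.items()}
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the status dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, dict] = {}
    artifacts: list[Path] = []

    def stage(name: str, fn, *deps: str):
        failed_dep = next((d for d in deps if status.get(d, {}).get("state") != "ok"), None)
        if failed_dep is not None:
            status[name] = {"state": "skipped", "reason": f"stage {failed_dep} failed"}
            return None
        try:
            result = fn()
            status[name] = {"state": "ok"}
            return result
        except CytonetError as exc:
            status[name] = {"state": "error", "error": str(exc)}
            return None

    # --- cohort -----------------------------------------------------------
    def _cohort() -> Cohort:
        if config.input_dir:
            base = Path(config.input_dir)
            cohort = read_cohort(
                base / "measurements.csv", base / "severity.csv", base / "outcomes.csv"
            )
            config.validate(cohort.sampling_days)
        else:
            sim = SimulationConfig(**{**asdict(config.simulation), "seed": config.seed})
            config.validate(sim.sampling_days)  # fail before any computation
            cohort = make_cohort(sim)
        paths = cohort.write(out / "cohort")
        artifacts.extend(paths.values())
        return cohort

    cohort = stage("cohort", _cohort)

    day_mats = {}
    controls = None

    def _prep():
        nonlocal controls
        controls = control_matrix(cohort)
        for d in config.analysis_days:
            day_mats[d] = build_day_matrix(cohort, d)
        return True

    stage("preprocess", _prep, "cohort")

    # --- group tests ------------------------------------------------------
    sepsis_p: dict[int, dict[str, float]] = {}
    critical_p: dict[int, dict[str, float]] = {}

    def _tests():
        tdir = out / "tests"
        tdir.mkdir(exist_ok=True)
        frames = []
        for d, dm in day_mats.items():
            overall = compare_day_to_controls(dm, controls)
            split = split_by_sofa(dm, config.sofa_cutoff)
            strata = compare_day_to_controls(dm, controls, split=split)
            frames.extend([overall, strata])
            sepsis_p[d] = dict(
                zip(overall["marker"], overall["p_adjusted"])
            )
            crit = strata[strata["comparison"] == "critical"]
            critical_p[d] = dict(zip(crit["marker"], crit["p_adjusted"]))
        table = pd.concat(frames, ignore_index=True)
        path = tdir / "dunnett.csv"
        table.to_csv(path, index=False)
        artifacts.append(path)
        return True

    stage("group_tests", _tests, "preprocess")

    # --- networks ---------------------------------------------------------
    def _networks():
        ndir = out / "networks"
        ndir.mkdir(exist_ok=True)
        corr_frames, fc_frames, cluster_rows = [], [], []
        for d, dm in day_mats.items():
            corr = pearson_matrix(dm)
            fc = fold_changes(
                dm,
                controls,
                threshold=config.fold_change_threshold,
                sepsis_p=sepsis_p.get(d),
                critical_p=critical_p.get(d),
                alpha=config.alpha,
            )
            net = build_network(corr, fc, alpha=config.alpha)
            clustering = ward_cluster(corr, cut_height=config.cluster_cut_height)
            net.write_graphml(ndir / f"network_day{d}.graphml")
            net.write_sif(ndir / f"network_day{d}.sif")
            artifacts.extend([ndir / f"network_day{d}.graphml", ndir / f"network_day{d}.sif"])
            long = corr.r.rename_axis(index="marker_a", columns="marker_b").stack(
                future_stack=True
            ).rename("r").reset_index()
            long["p"] = corr.p.to_numpy().ravel()
            long["day"] = d
            corr_frames.append(long)
            fc_frames.append(fc)
            for m, c in clustering.labels.items():
                cluster_rows.append({"day": d, "marker": m, "cluster": c})
        for name, frame in (
            ("correlations.csv", pd.concat(corr_frames, ignore_index=True)),
            ("fold_changes.csv", pd.concat(fc_frames, ignore_index=True)),
            ("clusters.csv", pd.DataFrame(cluster_rows)),
        ):
            frame.to_csv(ndir / name, index=False)
            artifacts.append(ndir / name)
        return True

    stage("networks", _networks, "group_tests")

    # --- scores and associations -----------------------------------------
    defs_by_day = {}

    def _scores():
        sdir = out / "scores"
        sdir.mkdir(exist_ok=True)
        cut_rows = []
        for d, dm in day_mats.items():
            defs = [
                make_definition(name, dm, mediators)
                for name, mediators in config.score_sets.items()
            ]
            defs_by_day[d] = defs
            tab = score_table(dm, defs)
            tab.to_csv(sdir / f"scores_day{d}.csv")
            artifacts.append(sdir / f"scores_day{d}.csv")
            for df_ in defs:
                for m, cut in df_.cutpoints.items():
                    cut_rows.append(
                        {
                            "day": d,
                            "score": df_.name,
                            "marker": m,
                            "cutpoint_log10": cut,
                            "quantile_rule": df_.quantile_rule,
                        }
                    )
        pd.DataFrame(cut_rows).to_csv(sdir / "cutpoints.csv", index=False)
        artifacts.append(sdir / "cutpoints.csv")
        return True

    stage("scores", _scores, "preprocess")

    def _assoc():
        adir = out / "associations"
        adir.mkdir(exist_ok=True)
        frames = [
            severity_association_table(dm, defs_by_day.get(d))
            for d, dm in day_mats.items()
        ]
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(adir / "spearman.csv", index=False)
        artifacts.append(adir / "spearman.csv")
        return True

    stage("associations", _assoc, "scores")

    # --- survival ---------------------------------------------------------
    def _survival():
        vdir = out / "survival"
        vdir.mkdir(exist_ok=True)
        table = acute_phase_cox_table(
            cohort,
            markers=tuple(m for m in MEDIATORS),
            score_sets=config.score_sets,
            update_days=tuple(config.acute_days),
        )
        table.to_csv(vdir / "cox.csv", index=False)
        artifacts.append(vdir / "cox.csv")
        return True

    stage("survival", _survival, "preprocess")

    # --- ROC --------------------------------------------------------------
    def _roc():
        rdir = out / "roc"
        rdir.mkdir(exist_ok=True)
        dm = day_mats[config.analysis_days[0]]
        feats = dm.log10.copy()
        feats = feats.join(score_table(dm, defs_by_day[config.analysis_days[0]]))
        feats["sofa"] = dm.severity["sofa"].astype(float)
        y = (
            cohort.outcomes.set_index("subject_id")["event"]
            .reindex(feats.index)
            .astype(float)
        )
        preds = tuple(dm.markers) + tuple(
            f"score_{n}" for n in config.score_sets
        )
        table = roc_comparison_table(feats, y, base_predictor="sofa", add_predictors=preds)
        table.to_csv(rdir / "roc.csv", index=False)
        artifacts.append(rdir / "roc.csv")
        return True

    stage("roc", _roc, "scores")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "cytonet_version": __version__,
        "python_version": sys.version.split()[0],
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "status.json").write_text(json.dumps(status, indent=2, sort_keys=True))
    return status
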