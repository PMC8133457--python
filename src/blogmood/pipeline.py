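"""Configuration-driven end-to-end runner.

Ties the stages together — cohort input (file or synthetic), final-sample
filtering, activity summaries, the between-subject permutation screen, the
PLS stage (full, restricted and multi-target models) and the within-subject
generalizability sweep — with per-stage seeds derived from one master seed
and a serialized copy of the effective configuration next to every output
bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import between, data, pls, synthetic, within
from .dataset import LongitudinalDataset

logger = logging.getLogger(__name__)

STAGES = ("summarize", "between", "pls", "within")


@dataclass
class RunConfig:
    """Effective pipeline configuration (flat key namespace)."""

    input_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    n_perm: int = 10_000
    n_boot: int = 10_000
    k_folds: int = 5
    k_features: int = 4
    max_ncomp: int = 10
    n_min_low: int = 3
    n_min_high: int = 18
    seed: int = 0
    outdir: str = "blogmood_out"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_json_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage seeds (< 2**31) derived from one master seed."""
    names = ("synthetic", "degrade", "permutation", "boot_ci", "cv", "select",
             "predobs", "multitarget")
    state = np.random.SeedSequence(master_seed).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _load_cohort(config: RunConfig, seeds: dict) -> LongitudinalDataset:
    if config.input_path:
        return data.read_individual_data(config.input_path)
    syn_kwargs = dict(config.synthetic)
    syn_kwargs.setdefault("n_participants", 38)
    syn_kwargs.setdefault("seed", seeds["synthetic"])
    cfg = synthetic.SyntheticConfig(**syn_kwargs)
    return synthetic.generate_cohort(cfg)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns a manifest of written outputs.

    Stage failures are recorded in the run log and downstream stages that
    depend on the failed stage are skipped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"outputs": [], "seeds": seeds, "errors": {}, "exclusions": {}}

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(str(path))
        return path

    _write("run_config.json", lambda p: p.write_text(
        json.dumps(config.to_json_dict(), indent=2), encoding="utf-8"))

    cohort = _load_cohort(config, seeds)
    _write("cohort_individualdata.csv",
           lambda p: data.write_individual_data(cohort, p))
    if not config.input_path:
        syn_kwargs = dict(config.synthetic)
        syn_kwargs.setdefault("n_participants", 38)
        syn_kwargs.setdefault("seed", seeds["synthetic"])
        cfg = synthetic.SyntheticConfig(**syn_kwargs)
        _write("synthetic_config.json", lambda p: p.write_text(
            json.dumps(cfg.to_json_dict(), indent=2), encoding="utf-8"))

    n_before = cohort.n_participants
    final = data.filter_final_sample(cohort)
    manifest["exclusions"]["participants_removed_by_final_filter"] = (
        n_before - final.n_participants
    )
    table = data.cross_section(final)
    _write("cohort_meandata.csv", lambda p: table.write(p))

    if "summarize" in config.stages:
        try:
            summary = data.summarize_activity(final)
            _write("activity_per_participant.csv",
                   lambda p: summary.per_participant.to_csv(p, index=False))
            _write("activity_summary.json", lambda p: p.write_text(
                json.dumps(summary.to_json_dict(), indent=2), encoding="utf-8"))
        except Exception as exc:  # noqa: BLE001 - reported per stage
            logger.exception("stage 'summarize' failed")
            manifest["errors"]["summarize"] = str(exc)

    if "between" in config.stages:
        try:
            results, null = between.between_subject_analysis(
                table,
                n_perm=config.n_perm,
                n_boot=config.n_boot,
                alpha=config.alpha,
                seed=seeds["permutation"],
            )
            _write("between_subject_correlations.csv",
                   lambda p: between.results_table(results).to_csv(p, index=False))
            _write("permutation_null.json", lambda p: p.write_text(
                json.dumps(null.to_json_dict(), indent=2), encoding="utf-8"))
        except Exception as exc:  # noqa: BLE001
            logger.exception("stage 'between' failed")
            manifest["errors"]["between"] = str(exc)

    models: dict[str, pls.PLSModel] = {}
    if "pls" in config.stages:
        try:
            X = table.features_matrix()
            Y = table.targets_matrix()
            feature_names = table.feature_names
            for t, target in enumerate(table.target_names):
                y = Y[:, t]
                curve = pls.cv_select_ncomp(
                    X, y, k_folds=config.k_folds, max_ncomp=config.max_ncomp,
                    seed=seeds["cv"],
                )
                _write(f"cv_curve_full_{target}.csv",
                       lambda p, c=curve: c.to_frame().to_csv(p, index=False))
                full = pls.fit_pls(
                    X, y, n_components=max(curve.selected_ncomp, 1),
                    feature_names=feature_names, target_names=[target],
                )
                full.meta["cv_selected_ncomp"] = int(curve.selected_ncomp)
                full.meta["cv_relative_change_pct"] = float(
                    curve.relative_change_pct)
                _write(f"pls_full_{target}.json", lambda p, m=full: m.save(p))

                sel = pls.bootstrap_select_features(
                    X, y, n_boot=config.n_boot, k=config.k_features,
                    seed=seeds["select"], feature_names=feature_names,
                )
                _write(f"feature_selection_{target}.csv",
                       lambda p, s=sel: s.to_frame().to_csv(p, index=False))
                cols = [feature_names.index(f) for f in sel.selected]
                Xr = X[:, cols]
                curve_r = pls.cv_select_ncomp(
                    Xr, y, k_folds=config.k_folds,
                    max_ncomp=min(config.max_ncomp, len(cols)), seed=seeds["cv"],
                )
                _write(f"cv_curve_restricted_{target}.csv",
                       lambda p, c=curve_r: c.to_frame().to_csv(p, index=False))
                restricted = pls.fit_pls(
                    Xr, y, n_components=max(curve_r.selected_ncomp, 1),
                    feature_names=sel.selected, target_names=[target],
                    restricted=True,
                )
                restricted.meta["cv_selected_ncomp"] = int(curve_r.selected_ncomp)
                restricted.meta["cv_relative_change_pct"] = float(
                    curve_r.relative_change_pct)
                restricted.meta["selected_features"] = sel.selected
                _write(f"pls_restricted_{target}.json",
                       lambda p, m=restricted: m.save(p))
                models[target] = restricted

                po = pls.predicted_vs_observed(
                    restricted, Xr, y, n_boot=min(config.n_boot, 2000),
                    seed=seeds["predobs"],
                )
                _write(f"predicted_vs_observed_{target}.csv",
                       lambda p, rows=po: _predobs_frame(rows).to_csv(p, index=False))

            multi, curve_m = pls.fit_multitarget(
                X, Y, k_folds=config.k_folds, max_ncomp=config.max_ncomp,
                seed=seeds["multitarget"], feature_names=feature_names,
                target_names=table.target_names,
            )
            _write("cv_curve_multitarget.csv",
                   lambda p: curve_m.to_frame().to_csv(p, index=False))
            _write("pls_multitarget.json", lambda p: multi.save(p))
        except Exception as exc:  # noqa: BLE001
            logger.exception("stage 'pls' failed")
            manifest["errors"]["pls"] = str(exc)

    if "within" in config.stages:
        if not models:
            manifest["errors"].setdefault(
                "within", "skipped: no fitted group-level models available"
            )
        else:
            try:
                per_frames, agg_frames = [], []
                for target, model in models.items():
                    res = within.within_subject_analysis(
                        model, final,
                        n_min_range=range(config.n_min_low, config.n_min_high + 1),
                    )
                    per_frames.append(res.per_participant)
                    agg_frames.append(res.aggregates)
                    for key, cnt in res.n_excluded.items():
                        manifest["exclusions"][f"within_{target}_{key}"] = cnt
                import pandas as pd

                _write("within_subject_per_participant.csv",
                       lambda p: pd.concat(per_frames).to_csv(p, index=False))
                _write("within_subject_aggregates.csv",
                       lambda p: pd.concat(agg_frames).to_csv(p, index=False))
            except Exception as exc:  # noqa: BLE001
                logger.exception("stage 'within' failed")
                manifest["errors"]["within"] = str(exc)

    _write("run_log.json", lambda p: p.write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"))
    return manifest


def _predobs_frame(rows):
    import pandas as pd

    return pd.DataFrame(
        {
            "target": [r.target for r in rows],
            "r": [r.r for r in rows],
            "r_squared": [r.r_squared for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
        }
    )
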