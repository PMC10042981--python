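"""End-to-end orchestration: simulate -> preprocess -> fit -> cluster -> report.

A single :class:`PipelineConfig` (YAML or JSON) carries every tunable with
defaults reproducing the standard analysis: replicate-presence filter
(min_present 3), log2 + QC drift/batch correction, 3-df spline trend models
with BH at 0.05, signed network clustering (beta 12, minModuleSize 10,
deepSplit 2, minKME 0.5, mergeCutHeight 0.25), +/-6 heat-map truncation and
the 90%-missing FC exclusion. Every run writes a manifest with the config
hash and per-stage row/compound counts so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import AbundanceMatrix, biological_mask
from .exceptions import ConfigError, DataError
from .io import read_tables, write_frame, write_tables
from .network import TOMModuleClustering, concatenate_trends, linkage_to_newick
from .preprocess import filter_features, log2_transform, qc_correct
from .reports import (
    compute_logfc,
    cultivation_model,
    flavour_report,
    hca_order,
    pca_scores,
    truncate_logfc,
)
from .simulate import DesignSpec, VarietySpec, default_design_spec, simulate_study
from .trend import SplineTrendModel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "fit", "cluster", "report")


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults encode the standard analysis values."""

    # inputs (ignored when the simulate stage is enabled)
    samples_path: str | None = None
    compounds_path: str | None = None
    matrix_path: str | None = None
    # stage toggles
    stages: tuple = STAGES
    # simulate
    n_compounds: int = 366
    residual_sd: float = 0.3
    missing_threshold: float | None = 11.5
    design: dict | None = None          # optional explicit variety series
    # preprocess
    min_present: int = 3
    filter_mode: str = "any_group"
    log_offset: float = 0.0
    drift_correction: bool = True
    # trend model
    spline_df: int = 3
    alpha: float = 0.05
    min_weeks: int = 6
    varieties: list | None = None
    platform_split: bool = True
    # clustering
    beta: float = 12.0
    min_module_size: int = 10
    deep_split: int = 2
    min_kme: float = 0.5
    merge_cut_height: float = 0.25
    # reports
    truncate_lo: float = -6.0
    truncate_hi: float = 6.0
    missing_fc_cutoff: float = 0.90
    flavour_panel: list | None = None
    # reproducibility
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "PipelineConfig":
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; allowed: {STAGES}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.truncate_lo >= self.truncate_hi:
            raise ConfigError("truncate_lo must be < truncate_hi")
        if self.deep_split not in range(5):
            raise ConfigError(f"deep_split must be in 0..4, got {self.deep_split}")
        if "simulate" not in self.stages and "preprocess" in self.stages:
            for key in ("samples_path", "compounds_path", "matrix_path"):
                if getattr(self, key) is None:
                    raise ConfigError(f"{key} is required when the simulate stage is disabled")
        return self

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def design_spec(self) -> DesignSpec:
        if self.design is None:
            return default_design_spec(seed=self.seed)
        try:
            varieties = tuple(VarietySpec(**v) for v in self.design["varieties"])
            extra = {k: v for k, v in self.design.items() if k != "varieties"}
            return DesignSpec(varieties=varieties, seed=self.seed, **extra)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid design block: {exc}") from exc


def _truth_to_json(truth) -> dict:
    return {
        "series": list(truth.series),
        "weeks": {k: int(v) for k, v in truth.weeks.items()},
        "template_names": list(truth.template_names),
        "curves": {
            str(t): {k: [float(x) for x in v] for k, v in per.items()}
            for t, per in truth.curves.items()
        },
        "template_id": [int(x) for x in truth.template_id],
        "baselines": [float(x) for x in truth.baselines],
        "variety_offsets": [[float(x) for x in row] for row in truth.variety_offsets],
        "batch_effects": {k: float(v) for k, v in truth.batch_effects.items()},
        "drift_slopes": {k: float(v) for k, v in truth.drift_slopes.items()},
        "residual_sd": truth.residual_sd,
        "missing_threshold": truth.missing_threshold,
        "missing_steepness": truth.missing_steepness,
        "compound_ids": list(truth.compound_ids),
    }


def select_model_series(samples: pd.DataFrame, varieties=None, min_weeks: int = 6) -> pd.DataFrame:
    """Restrict the sample table to one qualifying series per modelled variety.

    For every requested (or auto-selected) variety, the cultivation series
    with the most distinct harvest weeks is kept; QC rows are always kept.
    """
    bio = samples[biological_mask(samples)]
    per_series = bio.groupby(["variety", "cultivation"])["harvest_week_index"].nunique()
    chosen = []
    for v, sub in per_series.groupby(level=0):
        best = sub.sort_values(ascending=False)
        if varieties is not None and v not in varieties:
            continue
        if best.iloc[0] >= min_weeks:
            chosen.append(best.index[0])
    if not chosen:
        raise DataError(f"no variety has >= {min_weeks} harvest weeks in one series")
    keep = samples["is_qc"].astype(bool) | pd.MultiIndex.from_frame(
        samples[["variety", "cultivation"]]
    ).isin(chosen)
    return samples[keep]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the enabled stages; returns the manifest dict (also written)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    samples = compounds = matrix = truth = None
    stage = "init"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            samples, compounds, matrix, truth = simulate_study(
                spec=config.design_spec(),
                n_compounds=config.n_compounds,
                seed=config.seed,
                missing_threshold=config.missing_threshold,
                residual_sd=config.residual_sd,
            )
            write_tables(out, samples=samples, compounds=compounds, matrix=matrix)
            (out / "ground_truth.json").write_text(json.dumps(_truth_to_json(truth), indent=1, sort_keys=True))
            manifest["stages"]["simulate"] = {
                "n_samples": int(len(samples)),
                "n_qc": int(samples["is_qc"].sum()),
                "n_compounds": int(matrix.data.shape[1]),
            }
        elif {"preprocess", "fit", "cluster", "report"} & set(config.stages):
            stage = "read"
            samples, compounds, matrix = read_tables(
                config.samples_path, config.compounds_path, config.matrix_path
            )

        corrected = None
        if "preprocess" in config.stages:
            stage = "preprocess"
            filtered, removed = filter_features(
                matrix, samples, min_present=config.min_present, mode=config.filter_mode
            )
            logged = log2_transform(filtered, offset=config.log_offset)
            corrected = qc_correct(logged, samples) if config.drift_correction else logged.with_data(logged.data, scale="corrected")
            write_tables(out, matrix=corrected)
            if removed:
                write_frame(out / "filtered_compounds.tsv", pd.DataFrame({"compound_id": removed}))
            manifest["stages"]["preprocess"] = {
                "n_compounds_in": int(matrix.data.shape[1]),
                "n_removed_by_filter": len(removed),
                "n_compounds_out": int(corrected.data.shape[1]),
            }

        model = None
        trends = None
        if "fit" in config.stages:
            stage = "fit"
            if corrected is None:
                raise DataError("fit stage requires the preprocess stage (or its outputs)")
            model_samples = select_model_series(samples, config.varieties, config.min_weeks)
            model = SplineTrendModel(
                df=config.spline_df,
                alpha=config.alpha,
                min_weeks=config.min_weeks,
                varieties=config.varieties,
                platform_split=config.platform_split,
            ).fit(corrected.data, model_samples, compounds)
            trends = model.predict_trends()
            stats_out = model.stats_.copy()
            stats_out["effect_class"] = model.classes_
            write_frame(out / "trend_stats.tsv", stats_out, index=True)
            write_frame(out / "trend_curves.tsv", trends)
            coef = pd.DataFrame(
                model.fit_.coef, index=model.fit_.compounds, columns=model.design_.columns
            )
            write_frame(out / "trend_coefficients.tsv", coef, index=True)
            counts = model.classes_.value_counts().to_dict()
            manifest["stages"]["fit"] = {
                "varieties": list(model.design_.varieties),
                "n_fitted": int(model.fit_.fitted.sum()),
                "effect_classes": {str(k): int(v) for k, v in sorted(counts.items())},
                "d0": _jsonable_d0(model.prior_.d0),
                "n_changing": len(model.changing_compounds_),
            }

        if "cluster" in config.stages:
            stage = "cluster"
            if model is None:
                raise DataError("cluster stage requires the fit stage")
            changing = model.changing_compounds_
            # a compound unobserved in a whole variety has no complete
            # concatenated profile and cannot enter the network
            n_positions = sum(len(w) for w in model.design_.weeks.values())
            have = trends.groupby("compound_id").size()
            complete = set(have[have == n_positions].index)
            clusterable = [c for c in changing if c in complete]
            if len(clusterable) < len(changing):
                logger.info(
                    "cluster: %d changing compound(s) lack complete curves and are excluded",
                    len(changing) - len(clusterable),
                )
            if len(clusterable) < 2:
                manifest["stages"]["cluster"] = {"n_changing": len(changing), "skipped": True}
            else:
                trend_matrix = concatenate_trends(trends, clusterable)
                clu = TOMModuleClustering(
                    beta=config.beta,
                    min_module_size=config.min_module_size,
                    deep_split=config.deep_split,
                    min_kme=config.min_kme,
                    merge_cut_height=config.merge_cut_height,
                ).fit(trend_matrix)
                asg = clu.assignment_
                mod_table = pd.DataFrame(
                    {
                        "module": asg.labels,
                        "kME": asg.kme,
                        "unassigned_reason": asg.unassigned_reason,
                    }
                )
                mod_table.index.name = "compound_id"
                write_frame(out / "modules.tsv", mod_table, index=True)
                eig = asg.eigengenes.copy()
                if isinstance(eig.columns, pd.MultiIndex):
                    eig.columns = [f"{v}:w{w}" for v, w in eig.columns]
                eig.index.name = "module"
                write_frame(out / "module_eigengenes.tsv", eig, index=True)
                (out / "module_dendrogram.newick").write_text(
                    linkage_to_newick(clu.linkage_, trend_matrix.index)
                )
                sizes = asg.labels.value_counts().to_dict()
                manifest["stages"]["cluster"] = {
                    "n_changing": len(changing),
                    "n_clustered_input": len(clusterable),
                    "n_modules": int(len(asg.eigengenes)),
                    "module_sizes": {str(k): int(v) for k, v in sorted(sizes.items())},
                    "n_unassigned": int((asg.labels == "unassigned").sum()),
                }

        if "report" in config.stages:
            stage = "report"
            if corrected is None:
                raise DataError("report stage requires the preprocess stage")
            fc = compute_logfc(corrected, samples, missing_cutoff=config.missing_fc_cutoff)
            analysis = fc.matrix.copy()
            analysis.columns = [f"{v}/{c}:w{w}" for v, c, w in analysis.columns]
            write_frame(out / "logfc_analysis.tsv", analysis, index=True)
            display = truncate_logfc(analysis, config.truncate_lo, config.truncate_hi)
            write_frame(out / "logfc_display.tsv", display, index=True)
            if fc.excluded:
                write_frame(out / "logfc_excluded.tsv", pd.DataFrame({"compound_id": fc.excluded}))
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                order, Z, kept = hca_order(fc.matrix)
                (out / "hca_dendrogram.newick").write_text(linkage_to_newick(Z, kept))
                write_frame(out / "hca_order.tsv", pd.DataFrame({"compound_id": order}))
                scores, loadings, explained = pca_scores(corrected)
            write_frame(out / "pca_scores.tsv", scores, index=True)
            write_frame(out / "pca_loadings.tsv", loadings, index=True)
            write_frame(
                out / "pca_explained.tsv",
                pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(explained))], "fraction": explained}),
            )
            rep_manifest = {"n_fc_compounds": int(fc.matrix.shape[0]), "n_fc_excluded": len(fc.excluded)}
            if model is not None:
                kwargs = {"panel": tuple(config.flavour_panel)} if config.flavour_panel else {}
                fr, nd = flavour_report(trends, model.stats_, model.classes_, compounds, **kwargs)
                write_frame(out / "flavour_report.tsv", fr)
                if nd:
                    write_frame(out / "flavour_not_detected.tsv", pd.DataFrame({"panel_name": nd}))
                rep_manifest["n_flavour_detected"] = int(len(fr))
                rep_manifest["n_flavour_not_detected"] = len(nd)
            # variety x cultivation contrasts at every calendar week with >= 2 groups
            bio = samples[biological_mask(samples)]
            cults = []
            for wk, sub in bio.groupby(bio["calendar_week"].astype(int)):
                groups = sub.groupby(["variety", "cultivation"]).size()
                if (groups >= 2).sum() >= 2:
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        res = cultivation_model(corrected, samples, int(wk))
                    res = res.reset_index()
                    res.insert(0, "calendar_week", int(wk))
                    cults.append(res)
            if cults:
                write_frame(out / "cultivation_stats.tsv", pd.concat(cults, ignore_index=True))
                rep_manifest["n_cultivation_weeks"] = len(cults)
            manifest["stages"]["report"] = rep_manifest
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(
            f"stage {stage!r} failed: {exc}; resume with "
            f"`metabotrend {stage if stage in STAGES else 'run'} --config {out / 'config.yaml'} --out {out}`"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _jsonable_d0(d0) -> object:
    arr = np.unique(np.asarray(d0, dtype=float).ravel())
    arr = arr[~np.isnan(arr)]
    vals = ["inf" if np.isinf(x) else round(float(x), 4) for x in arr]
    return vals[0] if len(vals) == 1 else vals
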