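"""End-to-end orchestration: simulate -> screen -> nested CV -> permutation
calibration -> selection-frequency inference.

A single :class:`RunConfig` (loadable from YAML/JSON) fixes every stage's
parameters and a master seed; the seed is split into named substreams
(cohort, features, cv, permutations) so stages can be rerun in isolation
while the end-to-end run stays bit-reproducible.  Every run writes a
provenance JSON carrying the full config and a hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boruta import RFConfig
from .cv import CVConfig, CVResult, run_nested_cv, selection_frequency
from .inference import (
    NullModel,
    SignificanceReport,
    run_permutation_calibration,
    significant_features,
)
from .schema import FeatureSchema, build_default_schema
from .screening import ScreenResult, anova_filter, zscore_normalize
from .simulate import (
    DEFAULT_EFFECTS,
    CohortConfig,
    NoiseConfig,
    generate_cohort,
    generate_feature_table,
)
from .tables import GROUP_COLUMN, FeatureTable

__all__ = ["RunConfig", "PipelineResult", "simulate_dataset", "run_pipeline"]

log = logging.getLogger("radsel")

_STREAMS = ("cohort", "features", "cv", "permutations")


@dataclass
class RunConfig:
    """All knobs of a pipeline run plus the master seed."""

    seed: int = 0
    n_case: int = 59
    n_control: int = 69
    screen_alpha: float = 0.05
    cv_k: int = 5
    cv_repeats: int = 100
    stratified: bool = True
    n_trees: int = 1000
    selector_max_iter: int = 100
    selector_alpha: float = 0.01
    n_permutations: int = 1000
    perm_cv_repeats: int | None = None   # reduced repeats inside permutations
    inference_alpha: float = 0.05
    min_freq: float = 0.5
    noise_block_size: int = 16
    noise_corr: float = 0.3

    def substream(self, name: str) -> np.random.Generator:
        if name not in _STREAMS:
            raise KeyError(f"unknown RNG stream {name!r}")
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(len(_STREAMS))[_STREAMS.index(name)])

    @property
    def cv(self) -> CVConfig:
        return CVConfig(self.cv_k, self.cv_repeats, self.stratified)

    @property
    def perm_cv(self) -> CVConfig:
        repeats = self.perm_cv_repeats or self.cv_repeats
        return CVConfig(self.cv_k, repeats, self.stratified)

    @property
    def rf(self) -> RFConfig:
        return RFConfig(n_trees=self.n_trees)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PipelineResult:
    config: RunConfig
    screen: ScreenResult
    cv_result: CVResult
    frequencies: pd.Series
    null_model: NullModel
    report: SignificanceReport
    flags: dict = field(default_factory=dict)

    @property
    def significant_ids(self) -> list[str]:
        return self.report.significant_ids


def simulate_dataset(
    config: RunConfig,
    schema: FeatureSchema | None = None,
    effects=DEFAULT_EFFECTS,
) -> tuple[pd.DataFrame, FeatureTable]:
    """Generate the demographics table and the feature table for a run."""
    schema = schema or build_default_schema()
    cohort_cfg = CohortConfig().resized(config.n_case, config.n_control)
    demo = generate_cohort(cohort_cfg, seed=config.substream("cohort"))
    table = generate_feature_table(
        schema,
        demo[GROUP_COLUMN],
        effects=effects,
        noise=NoiseConfig(config.noise_block_size, config.noise_corr),
        seed=config.substream("features"),
    )
    return demo, table


def run_pipeline(table: FeatureTable, config: RunConfig) -> PipelineResult:
    """Execute screen -> nested CV -> permutation calibration -> inference."""
    log.info("input: %d subjects x %d features", table.n_subjects, len(table.feature_ids))

    scaled, constant = zscore_normalize(table)
    screen = anova_filter(scaled, alpha=config.screen_alpha)
    log.info("screen: %d -> %d features (alpha=%g)",
             len(table.feature_ids), screen.n_kept, config.screen_alpha)
    screened = scaled.subset_features(screen.kept_ids)

    flags: dict = {"constant_features": constant}
    if screen.n_kept == 0:
        log.warning("no features survived the screen; nothing to select")
        empty = pd.Series(dtype=float, index=pd.Index([], name="feature_id"))
        null = NullModel(0.0, config.cv.n_iterations, 0, degenerate=True)
        report = significant_features(empty, null, config.inference_alpha,
                                      config.min_freq, n_tests=1)
        from .cv import MetricSummary
        cvres = CVResult(MetricSummary({}, {}, 0), pd.DataFrame(), [])
        return PipelineResult(config, screen, cvres, empty, null, report, flags)

    cv_rng = config.substream("cv")
    cvres = run_nested_cv(
        screened, cv=config.cv, rf=config.rf,
        max_iter=config.selector_max_iter,
        selector_alpha=config.selector_alpha, seed=cv_rng,
    )
    freqs = selection_frequency(cvres.records, screen.kept_ids, config.cv.n_iterations)
    log.info("cv: %d iterations, mean accuracy %.3f",
             cvres.n_iterations, cvres.summary.mean.get("accuracy", float("nan")))

    # permuted datasets are re-screened under their own labels so the null
    # carries the same screen leakage as the original run
    null = run_permutation_calibration(
        scaled, config.n_permutations, cv=config.perm_cv, rf=config.rf,
        max_iter=config.selector_max_iter, selector_alpha=config.selector_alpha,
        screen_alpha=config.screen_alpha, seed=config.substream("permutations"),
    )
    # the binomial M is the original run's iteration count
    null = dataclasses.replace(null, n_iterations=config.cv.n_iterations)
    log.info("null: p0=%.4f from %d permutations", null.p0, null.n_permutations)

    report = significant_features(
        freqs, null, alpha=config.inference_alpha,
        min_freq=config.min_freq, n_tests=screen.n_kept,
    )
    log.info("inference: %d significant of %d tested",
             len(report.significant_ids), report.n_tests)
    return PipelineResult(config, screen, cvres, freqs, null, report, flags)


def describe_report(
    result: PipelineResult, schema: FeatureSchema, table: FeatureTable
) -> pd.DataFrame:
    """Significant-feature table in the published layout: frequency %,
    hemisphere, label, feature type, statistic, per-group mean +/- SD
    (computed from the *input* table)."""
    rows = []
    y = table.labels
    groups = sorted(y.unique())
    for fid in result.significant_ids:
        d = schema.lookup(fid)
        vals = table.data[fid]
        row = {
            "selection_frequency_pct": 100 * result.frequencies[fid],
            "hemisphere": d.hemisphere,
            "label": d.atlas_label,
            "feature_type": d.measure,
            "statistic": d.statistic,
        }
        for g in groups:
            v = vals[y == g]
            row[f"{g}_mean"] = float(v.mean())
            row[f"{g}_sd"] = float(v.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir, schema=None, table=None) -> None:
    """Write metrics JSON, per-iteration CSV, selection records CSV, the
    significance report CSV and a provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    summary = {
        "metrics_mean": result.cv_result.summary.mean,
        "metrics_sd": result.cv_result.summary.sd,
        "n_iterations": result.cv_result.summary.n_iterations,
        "null_p0": result.null_model.p0,
        "n_permutations": result.null_model.n_permutations,
        "n_significant": len(result.significant_ids),
        "significant_features": result.significant_ids,
    }
    (outdir / "metrics.json").write_text(json.dumps(summary, indent=2))
    result.cv_result.per_iteration.to_csv(outdir / "per_iteration_metrics.csv")
    pd.DataFrame(
        [(r.iteration, fid) for r in result.cv_result.records for fid in sorted(r.selected)],
        columns=["iteration", "feature_id"],
    ).to_csv(outdir / "selection_records.csv", index=False)
    result.report.table.to_csv(outdir / "significance_report.csv")
    if schema is not None and table is not None:
        describe_report(result, schema, table).to_csv(
            outdir / "significant_features.csv", index=False
        )
    prov = {"config": cfg.to_dict(), "config_hash": cfg.config_hash}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
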