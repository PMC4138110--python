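"""End-to-end pipeline orchestration and report assembly.

Runs read/generate -> dataset filters -> score conversion -> pooled
default-threshold performance -> per-gene MCC calibration -> inter-method
statistics, and writes five tab-separated report tables plus a manifest:

* ``performance.tsv``     — pooled missing rate / FNR / FPR / MCC per method
  at the default thresholds.
* ``calibration.tsv``     — per (gene, method): default and redefined
  thresholds with FNR/FPR/MCC under each (in-sample).
* ``correlation.tsv``     — Spearman rho / p / n between methods on
  disease-label records.
* ``gene_stats.tsv``      — per-gene descriptives per method, with the
  across-gene one-way ANOVA F and p.
* ``mcc_comparison.tsv``  — pairwise average differences of gene-level
  redefined MCCs with paired t-test p-values.

Machine TSVs keep full float precision; percent formatting belongs to
human-readable front ends only.  The manifest records the seed, a config
hash and the filter/skip logs; re-running with the same seed and config
reproduces every file byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    data_model,
    score_conversion,
    stats_compare,
    synthetic_data,
    threshold_optimizer,
)
from .data_model import Dataset, Label

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "summarize_filters"]

REPORT_FILES = (
    "performance.tsv",
    "calibration.tsv",
    "correlation.tsv",
    "gene_stats.tsv",
    "mcc_comparison.tsv",
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; exactly one of ``input_path`` / ``synthetic``."""

    output_dir: Path
    input_path: Path | None = None
    synthetic: bool = False
    synthetic_layout: str = "per_gene"  # "per_gene" (per-gene) or "pooled"
    seed: int = 0
    strict_conversion: bool = False
    min_disease_count: int = 30
    registry_config: Path | None = None

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.synthetic):
            raise ValueError("exactly one of input_path / synthetic must be set")


@dataclass
class ReportBundle:
    dataset: Dataset
    converted: pd.DataFrame
    performance: pd.DataFrame
    calibration: pd.DataFrame
    correlation: pd.DataFrame
    gene_stats: pd.DataFrame
    mcc_comparison: pd.DataFrame
    manifest: dict
    skips: list = field(default_factory=list)


def summarize_filters(stages: list[tuple[str, Dataset, Dataset]]) -> list[dict]:
    """Machine-readable per-filter log: records removed and retained."""
    log = []
    for name, before, after in stages:
        log.append({
            "filter": name,
            "n_before": len(before),
            "n_after": len(after),
            "n_removed": len(before) - len(after),
        })
    return log


def _load_registry(rc: RunConfig):
    if rc.registry_config is None:
        return score_conversion.default_registry()
    import yaml

    with open(rc.registry_config) as fh:
        return score_conversion.registry_from_config(yaml.safe_load(fh))


def _config_hash(rc: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(rc).items()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pooled_performance(ds: Dataset, registry, converted) -> pd.DataFrame:
    labels = np.array([r.label is Label.DISEASE for r in ds.records])
    rows = []
    from . import metrics

    for spec in registry:
        cc = metrics.tabulate(converted[spec.name], labels,
                              spec.default_threshold)
        rows.append({
            "method": spec.name,
            "scope": "pooled",
            "threshold": spec.default_threshold,
            "missing_rate": metrics.missing_rate(cc),
            "fnr": metrics.fnr(cc),
            "fpr": metrics.fpr(cc),
            "mcc": metrics.mcc(cc),
            "n_cases": cc.tp + cc.fn + cc.n_unscored_cases,
            "n_controls": cc.fp + cc.tn + cc.n_unscored_controls,
        })
    return pd.DataFrame(rows)


def _calibration_table(results) -> pd.DataFrame:
    rows = []
    for (gene, method), (tr, drow, rrow) in sorted(results.items()):
        rows.append({
            "gene": gene, "method": method,
            "default_threshold": drow.threshold,
            "redefined_threshold": tr.redefined_threshold,
            "default_fnr": drow.fnr, "default_fpr": drow.fpr,
            "default_mcc": drow.mcc,
            "redefined_fnr": rrow.fnr, "redefined_fpr": rrow.fpr,
            "redefined_mcc": rrow.mcc,
            "n_cases": tr.n_cases, "n_controls": tr.n_controls,
        })
    return pd.DataFrame(rows)


def _correlation_table(cells, methods) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            c = cells[(a, b)]
            rows.append({"method_a": a, "method_b": b, "rho": c.rho,
                         "p": c.p, "n_pairs": c.n_pairs,
                         "insufficient": c.insufficient})
    return pd.DataFrame(rows)


def _gene_stats_table(gs, anova) -> pd.DataFrame:
    rows = []
    for s in gs:
        f, p = anova.get(s.method, (math.nan, math.nan))
        rows.append({
            "method": s.method, "gene": s.gene, "mean": s.mean, "sd": s.sd,
            "n": s.n, "max": s.max, "q75": s.q75, "median": s.median,
            "q25": s.q25, "min": s.min, "anova_F": f, "anova_p": p,
        })
    return pd.DataFrame(rows)


def _mcc_comparison_table(cells, methods) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            c = cells[(a, b)]
            rows.append({"method_a": a, "method_b": b,
                         "avg_diff": c.avg_diff, "p": c.p,
                         "n_genes": c.n_genes, "degenerate": c.degenerate})
    return pd.DataFrame(rows)


def run_pipeline(rc: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to disk."""
    registry = _load_registry(rc)
    names = [s.name for s in registry]

    if rc.synthetic:
        cfg_fn = (synthetic_data.per_gene_default_config
                  if rc.synthetic_layout == "per_gene"
                  else synthetic_data.default_config)
        ds_raw, _truth = synthetic_data.generate(cfg_fn(seed=rc.seed), registry)
    else:
        fc = data_model.FormatConfig(methods=tuple(names))
        ds_raw = data_model.read_table(rc.input_path, fc)

    ds_genes = data_model.filter_min_mutation_count(ds_raw, rc.min_disease_count)
    ds = data_model.filter_for_analysis(ds_genes)
    filter_log = summarize_filters([
        ("min_disease_count", ds_raw, ds_genes),
        ("drop_nonsense_stop_loss", ds_genes, ds),
    ])

    converted = score_conversion.convert_dataset(
        ds, registry, strict=rc.strict_conversion)

    performance = _pooled_performance(ds, registry, converted)
    results, skips = threshold_optimizer.calibrate_all(ds, registry, converted)
    calibration = _calibration_table(results)

    is_case = np.array([r.label is Label.DISEASE for r in ds.records])
    genes = pd.Series([r.gene for r in ds.records])
    disease_scores = converted.loc[is_case].reset_index(drop=True)
    corr_cells = stats_compare.spearman_matrix(disease_scores)
    correlation = _correlation_table(corr_cells, names)

    gs = stats_compare.gene_descriptives(disease_scores,
                                         genes[is_case].reset_index(drop=True))
    anova = {}
    for spec in registry:
        try:
            anova[spec.name] = stats_compare.anova_across_genes(
                disease_scores, genes[is_case].reset_index(drop=True),
                spec.name)
        except ValueError:
            anova[spec.name] = (math.nan, math.nan)
    gene_stats = _gene_stats_table(gs, anova)

    gene_mccs = pd.DataFrame(
        {m: {g: results[(g, m)][0].max_mcc
             for g in ds.gene_set if (g, m) in results}
         for m in names})
    comp_cells = stats_compare.mcc_pairwise_comparison(gene_mccs)
    mcc_comparison = _mcc_comparison_table(comp_cells, names)

    manifest = {
        "seed": rc.seed,
        "config_hash": _config_hash(rc),
        "n_records_input": len(ds_raw),
        "n_records_analyzed": len(ds),
        "filters": filter_log,
        "skips": [{"gene": s.gene, "method": s.method, "reason": s.reason}
                  for s in skips],
        "registry": [s.name for s in registry],
    }

    out = Path(rc.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "performance.tsv": performance,
        "calibration.tsv": calibration,
        "correlation.tsv": correlation,
        "gene_stats.tsv": gene_stats,
        "mcc_comparison.tsv": mcc_comparison,
    }
    for fname, df in tables.items():
        df.to_csv(out / fname, sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        dataset=ds, converted=converted, performance=performance,
        calibration=calibration, correlation=correlation,
        gene_stats=gene_stats, mcc_comparison=mcc_comparison,
        manifest=manifest, skips=skips,
    )
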