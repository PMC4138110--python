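"""Gene-specific threshold redefinition by MCC maximization.

For one (gene, method) pair the procedure screens a series of cutoffs over
the pooled case/control converted scores, records the ROC point
(sensitivity, specificity) and the MCC at each, and redefines the
deleterious threshold as the cutoff attaining the maximum MCC.  Candidate
cutoffs are the midpoints between consecutive distinct score values plus
sentinels outside the observed range, so every achievable binary split of
the data is evaluated exactly once; the method's default threshold is
always added to the candidate set, which guarantees the redefined
threshold never performs worse than the default on the calibration data.

Calibration and evaluation use the same data (in-sample), mirroring the
reference-matrix use case where the panel *is* the catalogue of known
mutations; reported MCCs are training-set values, not generalization
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import metrics
from .data_model import Dataset, Label
from .score_conversion import MethodSpec

__all__ = [
    "ROCPoint",
    "ThresholdResult",
    "CalibrationError",
    "SkipRecord",
    "candidate_cutoffs",
    "optimize",
    "optimize_arrays",
    "calibrate_all",
]


class CalibrationError(ValueError):
    """A (gene, method) pair lacks scored records in one class."""


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    mcc_at: float


@dataclass(frozen=True)
class ThresholdResult:
    """Redefined gene-specific cutoff with its ROC trace and maximum MCC."""

    gene: str
    method: str
    redefined_threshold: float
    max_mcc: float
    default_mcc: float
    roc: tuple[ROCPoint, ...]
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class SkipRecord:
    """A (gene, method) pair skipped by calibrate_all, with the reason."""

    gene: str
    method: str
    reason: str


def candidate_cutoffs(scores) -> np.ndarray:
    """Candidate cutoffs covering every achievable split of the data.

    Midpoints between consecutive distinct sorted values, plus one sentinel
    below the minimum and one above the maximum (offset by the last distinct
    gap, or 1 if all values coincide).  Strictly increasing.
    """
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no scored values to screen")
    u = np.unique(s)
    if u.size == 1:
        gap = 1.0
        mids = np.empty(0)
    else:
        mids = (u[:-1] + u[1:]) / 2.0
        gap = u[-1] - u[-2]
        gap = gap if gap > 0 else 1.0
    return np.concatenate(([u[0] - gap], mids, [u[-1] + gap]))


def _evaluate_cutoffs(cases: np.ndarray, controls: np.ndarray,
                      cuts: np.ndarray):
    """Sensitivity, specificity and MCC at each cutoff (vectorized).

    A record is called deleterious when its score strictly exceeds the
    cutoff; counts come from searchsorted on the sorted class arrays, which
    matches metrics.tabulate call-for-call.
    """
    cs = np.sort(cases)
    ks = np.sort(controls)
    n1, n0 = cs.size, ks.size
    tp = n1 - np.searchsorted(cs, cuts, side="right")
    fp = n0 - np.searchsorted(ks, cuts, side="right")
    fn = n1 - tp
    tn = n0 - fp
    sens = np.divide(tp, n1, out=np.full(cuts.shape, np.nan), where=n1 > 0)
    spec = np.divide(tn, n0, out=np.full(cuts.shape, np.nan), where=n0 > 0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = np.zeros(cuts.shape)
    nz = denom > 0
    mcc[nz] = (tp[nz] * tn[nz] - fp[nz] * fn[nz]) / np.sqrt(
        denom[nz].astype(float))
    return sens, spec, mcc


def optimize_arrays(gene: str, method_name: str, cases, controls,
                    default_threshold: float) -> ThresholdResult:
    """MCC-maximizing cutoff for explicit case/control score arrays.

    Ties in MCC break toward the higher specificity (fewer false positives);
    remaining ties toward the smallest cutoff.  The default threshold is
    always inserted into the candidate set.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    cases = cases[~np.isnan(cases)]
    controls = controls[~np.isnan(controls)]
    if cases.size == 0 or controls.size == 0:
        raise CalibrationError(
            f"{gene}/{method_name}: needs >=1 scored case and control "
            f"(got {cases.size} cases, {controls.size} controls)"
        )
    cuts = candidate_cutoffs(np.concatenate((cases, controls)))
    cuts = np.unique(np.concatenate((cuts, [default_threshold])))
    sens, spec, mcc = _evaluate_cutoffs(cases, controls, cuts)
    # lexicographic argmax: MCC desc, specificity desc, cutoff asc
    order = np.lexsort((cuts, -spec, -mcc))
    best = order[0]
    default_mcc = float(mcc[cuts == default_threshold][0])
    roc = tuple(
        ROCPoint(float(c), float(se), float(sp), float(m))
        for c, se, sp, m in zip(cuts, sens, spec, mcc)
    )
    assert mcc[best] >= mcc.max() - 1e-15
    return ThresholdResult(
        gene=gene,
        method=method_name,
        redefined_threshold=float(cuts[best]),
        max_mcc=float(mcc[best]),
        default_mcc=default_mcc,
        roc=roc,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def optimize(gene: str, method: MethodSpec, ds: Dataset,
             converted) -> ThresholdResult:
    """Redefine one gene's threshold for one method.

    ``converted`` is the (records x methods) converted-score frame produced
    by score_conversion.convert_dataset, aligned with ``ds`` record order.
    """
    col = np.asarray(converted[method.name], dtype=float)
    is_gene = np.array([r.gene == gene for r in ds.records])
    is_case = np.array([r.label is Label.DISEASE for r in ds.records])
    return optimize_arrays(
        gene, method.name,
        col[is_gene & is_case], col[is_gene & ~is_case],
        method.default_threshold,
    )


def _performance_row(method: str, scope: str, threshold: float,
                     cases: np.ndarray, controls: np.ndarray) -> metrics.PerformanceRow:
    scores = np.concatenate((cases, controls))
    labels = np.concatenate(
        (np.ones(cases.size, bool), np.zeros(controls.size, bool)))
    cc = metrics.tabulate(scores, labels, threshold)
    return metrics.PerformanceRow(
        method=method, scope=scope, threshold=threshold,
        missing_rate=metrics.missing_rate(cc) if cc.total else math.nan,
        fnr=metrics.fnr(cc), fpr=metrics.fpr(cc), mcc=metrics.mcc(cc),
        n_cases=int(cases.size), n_controls=int(controls.size),
    )


def calibrate_all(ds: Dataset, registry: tuple[MethodSpec, ...], converted):
    """Per-(gene, method) calibration over the whole panel.

    Returns ``(results, skips)`` where ``results`` maps each calibrated
    (gene, method) to a tuple (ThresholdResult, default PerformanceRow,
    redefined PerformanceRow) and ``skips`` lists pairs lacking scored
    records in one class.  Skips are recorded, never raised.
    """
    results: dict[tuple[str, str], tuple] = {}
    skips: list[SkipRecord] = []
    is_case = np.array([r.label is Label.DISEASE for r in ds.records])
    genes_arr = np.array([r.gene for r in ds.records])
    for spec in registry:
        col = np.asarray(converted[spec.name], dtype=float)
        for gene in ds.gene_set:
            g = genes_arr == gene
            cases = col[g & is_case]
            controls = col[g & ~is_case]
            cases_s = cases[~np.isnan(cases)]
            controls_s = controls[~np.isnan(controls)]
            if cases_s.size == 0 or controls_s.size == 0:
                skips.append(SkipRecord(
                    gene, spec.name,
                    f"{cases_s.size} scored cases, "
                    f"{controls_s.size} scored controls"))
                continue
            tr = optimize_arrays(gene, spec.name, cases_s, controls_s,
                                 spec.default_threshold)
            default_row = _performance_row(
                spec.name, gene, spec.default_threshold, cases, controls)
            redefined_row = _performance_row(
                spec.name, gene, tr.redefined_threshold, cases, controls)
            results[(gene, spec.name)] = (tr, default_row, redefined_row)
    return results, skips
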