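"""Synthetic case/control score panels with the structure the analysis assumes.

Real calibration panels combine licensed disease-mutation catalogues with
population-sequencing controls and cannot be redistributed; this module
generates stand-in panels so every pipeline stage runs and is testable
offline.  Scores are drawn per (gene, method) from truncated normal
distributions on the *converted* scale — the family honors both the
reported mean/SD character and the hard score bounds with minimal
parameters — then mapped back through the inverse conversion rules so the
emitted panel carries raw-scale scores (with auxiliary data where a rule
needs them) and the full conversion path is exercised downstream.

The shipped default configuration emulates a seven-gene monogenic diabetes
panel: per-gene case/control counts of the reference catalogue, per-method
missingness rates, case-score locations/spreads/bounds taken from published
per-gene summaries, and control distributions placed on the benign side of
each method's default threshold (real control score distributions are
unpublished; these are declared stand-ins, not estimates).  Missingness is
independent completely-at-random.  Alongside the panel the generator
returns the generating parameters and the induced equal-variance Bayes
boundary per (gene, method), enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import (
    Dataset,
    Label,
    MutationClass,
    MutationRecord,
    Phenotype,
)
from .score_conversion import MethodSpec, default_registry, invert

__all__ = [
    "TruncNormal",
    "MethodSim",
    "SyntheticPanelConfig",
    "CellTruth",
    "GroundTruth",
    "generate",
    "default_config",
    "per_gene_default_config",
    "GENE_COUNTS",
    "MISSING_RATES",
]

# Per-gene (n_cases, n_controls) of the seven-gene monogenic diabetes panel.
GENE_COUNTS: tuple[tuple[str, int, int], ...] = (
    ("HNF4A", 86, 57),
    ("GCK", 479, 22),
    ("HNF1A", 324, 78),
    ("HNF1B", 36, 52),
    ("INS", 41, 14),
    ("ABCC8", 64, 185),
    ("KCNJ11", 61, 65),
)

# Marginal fraction of records each predictor leaves unscored.
MISSING_RATES: dict[str, float] = {
    "PhyloP": 0.0,
    "GERP_RS": 0.0,
    "SiPhy": 0.0,
    "SIFT": 0.13,
    "PolyPhen2_HDIV": 0.15,
    "PolyPhen2_HVAR": 0.15,
    "LRT": 0.18,
    "MutationTaster": 0.03,
    "MutationAssessor": 0.15,
    "FATHMM": 0.14,
    "RadialSVM": 0.08,
    "LR": 0.08,
}

# Case-score summaries on the converted scale: (mean, sd, max, min) per
# (method, gene), from published per-gene descriptive matrices.
_CASE_CELLS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "PhyloP": {
        "GCK": (2.120, 0.693, 2.941, -0.445),
        "INS": (1.206, 0.852, 2.069, -1.023),
        "KCNJ11": (2.046, 0.444, 2.548, -0.009),
        "ABCC8": (2.219, 0.556, 2.941, -0.403),
        "HNF1A": (1.793, 0.791, 2.882, -3.003),
        "HNF1B": (2.377, 0.652, 2.890, 0.768),
        "HNF4A": (1.894, 0.841, 2.814, -1.309),
    },
    "GERP_RS": {
        "GCK": (4.969, 1.305, 6.170, -3.060),
        "INS": (2.353, 1.724, 4.020, -3.200),
        "KCNJ11": (4.807, 0.862, 5.430, -0.548),
        "ABCC8": (5.135, 0.803, 6.170, 0.768),
        "HNF1A": (4.185, 2.020, 6.060, -12.100),
        "HNF1B": (5.279, 0.773, 6.060, 3.230),
        "HNF4A": (4.591, 1.862, 5.930, -7.160),
    },
    "SiPhy": {
        "GCK": (16.241, 3.196, 20.490, 2.501),
        "INS": (9.288, 4.002, 14.890, 1.486),
        "KCNJ11": (15.732, 2.899, 19.243, 6.945),
        "ABCC8": (16.327, 2.609, 20.567, 10.313),
        "HNF1A": (13.956, 3.649, 19.609, 0.949),
        "HNF1B": (16.300, 3.457, 19.609, 8.432),
        "HNF4A": (15.254, 4.259, 20.336, 2.815),
    },
    "SIFT": {
        "GCK": (0.940, 0.151, 1.000, 0.000),
        "INS": (0.956, 0.140, 1.000, 0.360),
        "KCNJ11": (0.906, 0.172, 1.000, 0.210),
        "ABCC8": (0.888, 0.204, 1.000, 0.000),
        "HNF1A": (0.918, 0.184, 1.000, 0.000),
        "HNF1B": (0.922, 0.205, 1.000, 0.000),
        "HNF4A": (0.921, 0.168, 1.000, 0.250),
    },
    "PolyPhen2_HDIV": {
        "GCK": (0.917, 0.229, 1.000, 0.000),
        "INS": (0.906, 0.290, 1.000, 0.009),
        "KCNJ11": (0.964, 0.151, 1.000, 0.004),
        "ABCC8": (0.821, 0.330, 1.000, 0.001),
        "HNF1A": (0.870, 0.269, 1.000, 0.000),
        "HNF1B": (0.909, 0.252, 1.000, 0.000),
        "HNF4A": (0.883, 0.276, 1.000, 0.019),
    },
    "PolyPhen2_HVAR": {
        "GCK": (0.850, 0.280, 1.000, 0.000),
        "INS": (0.893, 0.292, 1.000, 0.005),
        "KCNJ11": (0.925, 0.174, 1.000, 0.016),
        "ABCC8": (0.704, 0.334, 1.000, 0.001),
        "HNF1A": (0.781, 0.319, 1.000, 0.000),
        "HNF1B": (0.882, 0.270, 1.000, 0.007),
        "HNF4A": (0.821, 0.324, 1.000, 0.002),
    },
    "LRT": {
        "GCK": (0.999, 0.005, 1.000, 0.936),
        "INS": (0.971, 0.137, 1.000, 0.341),
        "KCNJ11": (0.994, 0.046, 1.000, 0.668),
        "ABCC8": (1.000, 0.003, 1.000, 0.975),
        "HNF1A": (0.994, 0.029, 1.000, 0.704),
        "HNF1B": (1.000, 0.000, 1.000, 0.998),
        "HNF4A": (0.997, 0.012, 1.000, 0.948),
    },
    "MutationTaster": {
        "GCK": (0.988, 0.101, 1.000, 0.001),
        "INS": (0.752, 0.437, 1.000, 0.000),
        "KCNJ11": (0.983, 0.128, 1.000, 0.000),
        "ABCC8": (0.984, 0.125, 1.000, 0.000),
        "HNF1A": (0.968, 0.165, 1.000, 0.000),
        "HNF1B": (0.967, 0.173, 1.000, 0.087),
        "HNF4A": (0.991, 0.069, 1.000, 0.439),
    },
    "MutationAssessor": {
        "GCK": (0.720, 0.086, 0.837, 0.442),
        "INS": (0.752, 0.077, 0.816, 0.553),
        "KCNJ11": (0.660, 0.085, 0.802, 0.464),
        "ABCC8": (0.671, 0.083, 0.886, 0.356),
        "HNF1A": (0.638, 0.054, 0.697, 0.434),
        "HNF1B": (0.665, 0.047, 0.706, 0.547),
        "HNF4A": (0.707, 0.106, 0.887, 0.434),
    },
    "FATHMM": {
        "GCK": (0.587, 0.030, 0.683, 0.541),
        "INS": (0.531, 0.052, 0.640, 0.470),
        "KCNJ11": (0.531, 0.020, 0.563, 0.479),
        "ABCC8": (0.512, 0.032, 0.575, 0.405),
        "HNF1A": (0.577, 0.037, 0.685, 0.494),
        "HNF1B": (0.582, 0.034, 0.626, 0.537),
        "HNF4A": (0.542, 0.042, 0.612, 0.408),
    },
    "RadialSVM": {
        "GCK": (0.663, 0.034, 0.685, 0.393),
        "INS": (0.626, 0.062, 0.684, 0.374),
        "KCNJ11": (0.598, 0.120, 0.682, 0.234),
        "ABCC8": (0.584, 0.110, 0.682, 0.246),
        "HNF1A": (0.644, 0.066, 0.725, 0.275),
        "HNF1B": (0.667, 0.017, 0.683, 0.611),
        "HNF4A": (0.628, 0.104, 0.682, 0.274),
    },
    "LR": {
        "GCK": (0.945, 0.061, 0.996, 0.495),
        "INS": (0.863, 0.103, 0.992, 0.470),
        "KCNJ11": (0.778, 0.235, 0.966, 0.110),
        "ABCC8": (0.744, 0.215, 0.978, 0.075),
        "HNF1A": (0.892, 0.127, 0.994, 0.149),
        "HNF1B": (0.940, 0.036, 0.987, 0.871),
        "HNF4A": (0.856, 0.201, 0.989, 0.153),
    },
}

# Pooled case-score summaries (mean, sd, max, min), converted scale.
_CASE_OVERALL: dict[str, tuple[float, float, float, float]] = {
    "PhyloP": (1.983, 0.752, 2.941, -3.003),
    "GERP_RS": (4.624, 1.654, 6.170, -12.100),
    "SiPhy": (15.218, 3.738, 20.567, 0.949),
    "SIFT": (0.927, 0.169, 1.000, 0.000),
    "PolyPhen2_HDIV": (0.897, 0.253, 1.000, 0.000),
    "PolyPhen2_HVAR": (0.826, 0.297, 1.000, 0.000),
    "LRT": (0.997, 0.030, 1.000, 0.341),
    "MutationTaster": (0.974, 0.153, 1.000, 0.000),
    "MutationAssessor": (0.688, 0.087, 0.887, 0.356),
    "FATHMM": (0.570, 0.042, 0.685, 0.405),
    "RadialSVM": (0.644, 0.072, 0.725, 0.234),
    "LR": (0.895, 0.143, 0.996, 0.075),
}

# Disease-set mutation-class composition: 104 nonsense and 2 stop-loss
# among 1091 catalogued disease mutations, confined to the genes where the
# catalogue records them.
NONSENSE_FRACTION = 104 / 1091
STOP_LOSS_FRACTION = 2 / 1091
NONSENSE_GENES = ("GCK", "HNF1A", "HNF1B", "HNF4A", "INS")
STOP_LOSS_GENES = ("GCK",)

# Neonatal-diabetes phenotype counts per gene (155 of 1091 disease records;
# the remaining 936 carry the MODY phenotype).  The per-gene split beyond
# the published INS count is a modelling choice.
NEONATAL_COUNTS: dict[str, int] = {"INS": 34, "KCNJ11": 45, "ABCC8": 46, "GCK": 30}

_SD_FLOOR = 1e-3  # published SDs can print as 0.000; a degenerate normal is not usable


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal on the converted scale.

    ``mean``/``sd`` are the location/scale of the parent normal, not the
    post-truncation moments.
    """

    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self) -> list[str]:
        errs = []
        if not self.sd > 0:
            errs.append(f"sd must be > 0, got {self.sd}")
        if not self.lower < self.upper:
            errs.append(f"lower {self.lower} must be < upper {self.upper}")
        return errs

    def frozen(self) -> stats.rv_continuous:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.frozen().rvs(size=n, random_state=rng)

    def truncated_mean(self) -> float:
        return float(self.frozen().mean())


@dataclass(frozen=True)
class MethodSim:
    """Generating distributions for one method.

    ``case_dist``/``control_dist`` are either a single TruncNormal applied
    to every gene, or a mapping gene -> TruncNormal.
    """

    name: str
    case_dist: TruncNormal | dict[str, TruncNormal]
    control_dist: TruncNormal | dict[str, TruncNormal]
    missing_rate: float = 0.0

    def dist_for(self, which: str, gene: str) -> TruncNormal:
        d = self.case_dist if which == "case" else self.control_dist
        if isinstance(d, dict):
            return d[gene]
        return d


@dataclass(frozen=True)
class SyntheticPanelConfig:
    genes: tuple[tuple[str, int, int], ...] = GENE_COUNTS
    methods: tuple[MethodSim, ...] = ()
    nonsense_fraction: float = NONSENSE_FRACTION
    stop_loss_fraction: float = STOP_LOSS_FRACTION
    nonsense_genes: tuple[str, ...] = NONSENSE_GENES
    stop_loss_genes: tuple[str, ...] = STOP_LOSS_GENES
    neonatal_counts: dict[str, int] = field(
        default_factory=lambda: dict(NEONATAL_COUNTS))
    seed: int = 0

    def validate(self) -> None:
        errs: list[str] = []
        for g, nc, nk in self.genes:
            if nc <= 0 or nk <= 0:
                errs.append(f"{g}: counts must be > 0 (got {nc}, {nk})")
        gene_names = {g for g, _, _ in self.genes}
        for m in self.methods:
            if not 0.0 <= m.missing_rate <= 1.0:
                errs.append(f"{m.name}: missing_rate outside [0,1]")
            for which in ("case", "control"):
                for g in gene_names:
                    errs += [f"{m.name}/{g} {which}: {e}"
                             for e in m.dist_for(which, g).validate()]
        if self.nonsense_fraction + self.stop_loss_fraction > 1.0:
            errs.append("class-mix proportions sum above 1")
        for g, n in self.neonatal_counts.items():
            cases = {gg: nc for gg, nc, _ in self.genes}
            if g in cases and n > cases[g]:
                errs.append(f"{g}: neonatal count {n} exceeds case count")
        if errs:
            raise ValueError("invalid config: " + "; ".join(errs))


@dataclass(frozen=True)
class CellTruth:
    """Generating parameters and induced Bayes boundary for one cell.

    For equal-variance case/control normals the optimal cutoff is the
    midpoint of the two means; it always lies between them.
    """

    case: TruncNormal
    control: TruncNormal
    bayes_cutoff: float


@dataclass(frozen=True)
class GroundTruth:
    cells: dict[tuple[str, str], CellTruth]

    def cutoff(self, gene: str, method: str) -> float:
        return self.cells[(gene, method)].bayes_cutoff


def _control_dist(case: TruncNormal, spec: MethodSpec) -> TruncNormal:
    """Place the control distribution on the benign side of the default
    threshold, one case-SD below it, same spread.

    This makes the default threshold a usable but imperfect classifier, so
    gene-specific recalibration has something to improve, without asserting
    anything about real control score distributions.
    """
    sd = max(case.sd, _SD_FLOOR)
    mean = spec.default_threshold - sd
    if spec.bounded01:
        lower, upper = 0.0, 1.0
    else:
        lower = min(case.lower, mean - 4 * sd)
        upper = case.upper
    return TruncNormal(mean=mean, sd=sd, lower=lower, upper=upper)


def _case_dist(cell: tuple[float, float, float, float]) -> TruncNormal:
    mean, sd, hi, lo = cell
    return TruncNormal(mean=mean, sd=max(sd, _SD_FLOOR), lower=lo, upper=hi)


def _registry_by_name() -> dict[str, MethodSpec]:
    return {s.name: s for s in default_registry()}


def default_config(seed: int = 0) -> SyntheticPanelConfig:
    """Pooled configuration: one case distribution per method (overall
    summaries), shared across genes."""
    reg = _registry_by_name()
    methods = tuple(
        MethodSim(
            name=name,
            case_dist=_case_dist(_CASE_OVERALL[name]),
            control_dist=_control_dist(_case_dist(_CASE_OVERALL[name]), reg[name]),
            missing_rate=MISSING_RATES[name],
        )
        for name in _CASE_OVERALL
    )
    return SyntheticPanelConfig(methods=methods, seed=seed)


def per_gene_default_config(seed: int = 0) -> SyntheticPanelConfig:
    """Per-gene configuration seeded from the published per-gene case-score
    summaries (location, spread, hard bounds per gene x method).

    Control distributions are synthetic stand-ins (see module docstring);
    nothing here estimates real control scores.
    """
    reg = _registry_by_name()
    methods = []
    for name, cells in _CASE_CELLS.items():
        case = {g: _case_dist(c) for g, c in cells.items()}
        control = {g: _control_dist(case[g], reg[name]) for g in case}
        methods.append(MethodSim(
            name=name, case_dist=case, control_dist=control,
            missing_rate=MISSING_RATES[name],
        ))
    return SyntheticPanelConfig(methods=tuple(methods), seed=seed)


def _assign_exact(rng: np.random.Generator, eligible: np.ndarray,
                  count: int) -> np.ndarray:
    if count > eligible.size:
        count = eligible.size
    return rng.choice(eligible, size=count, replace=False)


def generate(config: SyntheticPanelConfig,
             registry: tuple[MethodSpec, ...] | None = None
             ) -> tuple[Dataset, GroundTruth]:
    """Draw a reproducible panel and its generating ground truth.

    Converted-scale draws per (gene, method, label) are mapped through the
    inverse conversion rules into raw scores (plus auxiliaries); class-mix
    and phenotype labels are assigned as exact counts so dataset bookkeeping
    is deterministic given the configuration.
    """
    config.validate()
    reg = {s.name: s for s in (registry or default_registry())}
    for m in config.methods:
        if m.name not in reg:
            raise ValueError(f"method {m.name!r} not in registry")
    rng = np.random.default_rng(config.seed)

    records: list[dict] = []
    truth: dict[tuple[str, str], CellTruth] = {}
    for gene, n_cases, n_controls in config.genes:
        for i in range(n_cases):
            records.append(dict(gene=gene, label=Label.DISEASE,
                                variant_id=f"{gene}:case:{i:04d}",
                                raw_scores={}, aux={}))
        for i in range(n_controls):
            records.append(dict(gene=gene, label=Label.CONTROL,
                                variant_id=f"{gene}:ctrl:{i:04d}",
                                raw_scores={}, aux={}))

    genes_arr = np.array([r["gene"] for r in records])
    is_case = np.array([r["label"] is Label.DISEASE for r in records])

    for m in config.methods:
        spec = reg[m.name]
        for gene, _, _ in config.genes:
            for which, mask in (("case", is_case), ("control", ~is_case)):
                idx = np.flatnonzero((genes_arr == gene) & mask)
                dist = m.dist_for(which, gene)
                values = dist.draw(idx.size, rng)
                missing = rng.random(idx.size) < m.missing_rate
                for k, rec_i in enumerate(idx):
                    if missing[k]:
                        continue
                    raw, aux = invert(spec, float(values[k]))
                    records[rec_i]["raw_scores"][m.name] = raw
                    if aux is not None:
                        records[rec_i]["aux"][m.name] = aux
            case_d = m.dist_for("case", gene)
            ctrl_d = m.dist_for("control", gene)
            truth[(gene, m.name)] = CellTruth(
                case=case_d, control=ctrl_d,
                bayes_cutoff=(case_d.mean + ctrl_d.mean) / 2.0)

    # exact-count class mix, confined to the genes that carry each class
    case_idx = np.flatnonzero(is_case)
    n_cases_total = case_idx.size
    n_nonsense = round(config.nonsense_fraction * n_cases_total)
    n_stop_loss = round(config.stop_loss_fraction * n_cases_total)
    classes = [MutationClass.MISSENSE] * len(records)
    elig_non = case_idx[np.isin(genes_arr[case_idx], config.nonsense_genes)]
    chosen_non = _assign_exact(rng, elig_non, n_nonsense)
    for i in chosen_non:
        classes[i] = MutationClass.NONSENSE
    elig_sl = case_idx[np.isin(genes_arr[case_idx], config.stop_loss_genes)
                       & ~np.isin(case_idx, chosen_non)]
    for i in _assign_exact(rng, elig_sl, n_stop_loss):
        classes[i] = MutationClass.STOP_LOSS

    phenotypes = [Phenotype.NONE] * len(records)
    for i in case_idx:
        phenotypes[i] = Phenotype.MODY
    for gene, count in config.neonatal_counts.items():
        elig = case_idx[genes_arr[case_idx] == gene]
        for i in _assign_exact(rng, elig, count):
            phenotypes[i] = Phenotype.NEONATAL

    recs = tuple(
        MutationRecord(
            gene=r["gene"], variant_id=r["variant_id"], label=r["label"],
            mutation_class=classes[i], phenotype=phenotypes[i],
            raw_scores=r["raw_scores"], aux=r["aux"],
        )
        for i, r in enumerate(records)
    )
    ds = Dataset(recs, tuple(g for g, _, _ in config.genes))
    return ds, GroundTruth(truth)
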