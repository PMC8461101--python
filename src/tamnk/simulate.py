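"""Synthetic data generators.

Two generators provide inputs with the statistical structure the
downstream analysis assumes:

* :func:`simulate_single_cell` — a multi-cell-type negative-binomial UMI
  count matrix with marker up-regulation, a mitochondrial gene block and
  planted doublets, emulating a dissociated-tumor scRNA-seq run.
* :func:`simulate_cohort` — a bulk expression cohort whose exponential
  survival hazard depends on a planted low/high TAM-to-NK group with a
  configurable hazard ratio and uniform censoring, emulating a
  TCGA-style survival cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import BUILTIN_LR_PAIRS, NK_TYPE_GENES, TAM_TYPE_GENES, builtin_gene_sets
from .matrix import ExpressionMatrix, SurvivalRecord, ValidationError

CELL_TYPES = ("M0", "M1", "M2", "MONOCYTE", "NK_LIKE", "TUMOR")

#: marker panel driving each simulated cell type (TUMOR has none)
_TYPE_PANEL = {
    "M0": "M0",
    "M1": "M1",
    "M2": "M2",
    "MONOCYTE": "MONOCYTE",
    "NK_LIKE": "NK_MARK",
    "TUMOR": None,
}

N_MITO_GENES = 10


@dataclass
class SimulationConfig:
    """Parameters of the single-cell count simulation.

    ``marker_log2_fc`` is the log2 fold-change applied to a cell type's
    marker panel; cell-type signature genes (the TAM/NK score lists)
    receive half that shift so per-cell signature scoring has signal
    without double-counting panel genes.
    """

    n_cells_per_type: dict[str, int] = field(
        default_factory=lambda: {t: 100 for t in CELL_TYPES}
    )
    n_background_genes: int = 200
    marker_log2_fc: float = 3.0
    nb_dispersion: float = 0.1
    lib_size_mean: float = 5000.0
    mito_fraction_mean: float = 0.05
    doublet_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.n_cells_per_type) - set(CELL_TYPES)
        if unknown:
            raise ValidationError(f"unknown cell types {sorted(unknown)}")
        if not any(v > 0 for v in self.n_cells_per_type.values()):
            raise ValidationError("at least one cell type must have count > 0")
        if self.n_background_genes < 50:
            raise ValidationError("n_background_genes must be >= 50")
        if self.marker_log2_fc < 0:
            raise ValidationError("marker_log2_fc must be >= 0")
        if self.nb_dispersion <= 0 or self.lib_size_mean <= 0:
            raise ValidationError("nb_dispersion and lib_size_mean must be > 0")
        if not (0 <= self.mito_fraction_mean < 1):
            raise ValidationError("mito_fraction_mean must be in [0, 1)")
        if not (0 <= self.doublet_rate < 1):
            raise ValidationError("doublet_rate must be in [0, 1)")


@dataclass
class CohortConfig:
    """Parameters of the survival-cohort simulation.

    ``score_shift`` is the log-expression difference planted between the
    prognostic groups on the TAM and NK signature lists (low group: TAM
    down, NK up).  ``true_hr_low_vs_high`` multiplies the baseline
    hazard for the low group, so HR > 1 encodes "low score, poor
    prognosis".
    """

    n_patients: int = 200
    true_hr_low_vs_high: float = 2.0
    score_shift: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    seed: int = 0
    n_background_genes: int = 100

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ValidationError("n_patients must be >= 10")
        if self.true_hr_low_vs_high <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazards must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with variance mean + mean^2 * dispersion."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _gene_universe(n_background: int) -> tuple[list[str], dict[str, list[str]]]:
    registry = builtin_gene_sets()
    signature: dict[str, None] = {}
    for name in ("M0", "M1", "M2", "MONOCYTE", "NK_MARK", "TAM_TYPE", "NK_TYPE"):
        for g in registry[name].genes:
            signature.setdefault(g, None)
    for pair in BUILTIN_LR_PAIRS:
        signature.setdefault(pair.ligand, None)
        signature.setdefault(pair.receptor, None)
    background = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    mito = [f"MT-{i}" for i in range(1, N_MITO_GENES + 1)]
    overlap = set(signature) & set(background)
    if overlap:
        raise ValidationError(f"marker panels collide with background names: {sorted(overlap)}")
    genes = list(signature) + background + mito
    panels = {t: list(registry[p].genes) if p else [] for t, p in _TYPE_PANEL.items()}
    return genes, panels


def simulate_single_cell(config: SimulationConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a UMI count matrix with known cell-type labels.

    Returns the counts matrix (genes × cells) and a per-cell label array
    holding the cell type, or ``"DOUBLET"`` for cells formed by summing
    the counts of two random parents of different types.
    Deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, panels = _gene_universe(config.n_background_genes)
    gi = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    mito_idx = np.array([gi[g] for g in genes if g.startswith("MT-")])
    non_mito = np.array([i for i in range(n_genes) if i not in set(mito_idx)])

    # baseline relative abundances: gamma-distributed, as in real libraries a
    # few genes dominate the library
    base = rng.gamma(shape=0.7, scale=1.0, size=n_genes) + 1e-3
    f = config.mito_fraction_mean
    base[non_mito] *= (1.0 - f) / base[non_mito].sum()
    if f > 0:
        base[mito_idx] = f / len(mito_idx)
    else:
        base[mito_idx] = 0.0

    registry = builtin_gene_sets()
    tam_sig = set(registry["TAM_TYPE"].genes)
    nk_sig = set(registry["NK_TYPE"].genes)

    type_means: dict[str, np.ndarray] = {}
    for ctype in CELL_TYPES:
        mean = base.copy()
        fc = 2.0 ** config.marker_log2_fc
        half_fc = 2.0 ** (config.marker_log2_fc / 2.0)
        panel = set(panels[ctype])
        if ctype in ("M0", "M1", "M2", "MONOCYTE"):
            for g in tam_sig - panel:
                mean[gi[g]] *= half_fc
        elif ctype == "NK_LIKE":
            for g in nk_sig - panel:
                mean[gi[g]] *= half_fc
        for g in panel:
            mean[gi[g]] *= fc
        # renormalize non-mito block so expected library size is preserved
        mean[non_mito] *= (1.0 - f) / mean[non_mito].sum()
        type_means[ctype] = mean * config.lib_size_mean

    labels: list[str] = []
    columns: list[np.ndarray] = []
    for ctype in CELL_TYPES:
        n = int(config.n_cells_per_type.get(ctype, 0))
        if n == 0:
            continue
        # per-cell library-size factor, lognormal with mean 1
        sigma = 0.3
        size_factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)
        for s in size_factors:
            columns.append(_nb_sample(rng, type_means[ctype] * s, config.nb_dispersion))
            labels.append(ctype)

    counts = np.column_stack(columns).astype(float)
    labels_arr = np.array(labels, dtype=object)
    n_cells = counts.shape[1]

    n_doub = int(round(config.doublet_rate * n_cells))
    if n_doub > 0 and len(set(labels)) >= 2:
        doublet_idx = rng.choice(n_cells, size=n_doub, replace=False)
        for i in doublet_idx:
            other = np.flatnonzero(labels_arr != labels_arr[i])
            other = other[~np.isin(other, doublet_idx)]
            if other.size == 0:  # pragma: no cover - degenerate composition
                continue
            j = int(rng.choice(other))
            counts[:, i] = counts[:, i] + counts[:, j]
        labels_arr[doublet_idx] = "DOUBLET"

    obs_ids = [f"CELL{i:05d}" for i in range(1, n_cells + 1)]
    matrix = ExpressionMatrix(counts, genes, obs_ids, layer_tag="counts")
    return matrix, labels_arr.astype(str)


def _censor_horizon(rate: float, hazards: np.ndarray) -> float:
    """Uniform(0, c) horizon achieving expected censoring fraction ``rate``.

    For exponential T with hazard l and U ~ Uniform(0, c),
    P(censored) = (1 - exp(-l c)) / (l c); we solve the mixture over
    subjects' hazards for c.
    """

    def frac(c: float) -> float:
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1.0
    while frac(hi) > rate:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            break
    return brentq(lambda c: frac(c) - rate, lo, hi)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, list[SurvivalRecord], np.ndarray]:
    """Simulate a bulk cohort with a planted prognostic low/high split.

    Half of the patients form the "low" TAM-to-NK group: their TAM-list
    genes are shifted down and NK-list genes up by ``score_shift`` /2
    each (and vice versa for "high").  Survival is exponential with
    hazard ``baseline_hazard * true_hr_low_vs_high`` for the low group.
    Returns (expression, survival records, true group per patient).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    genes = list(TAM_TYPE_GENES) + list(NK_TYPE_GENES) + background
    n_genes = len(genes)
    n = config.n_patients

    group = np.array(["high"] * n, dtype=object)
    low_idx = rng.permutation(n)[: n // 2]
    group[low_idx] = "low"

    base = rng.uniform(2.0, 8.0, size=n_genes)
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n))
    shift = config.score_shift / 2.0
    tam_rows = np.arange(len(TAM_TYPE_GENES))
    nk_rows = np.arange(len(TAM_TYPE_GENES), len(TAM_TYPE_GENES) + len(NK_TYPE_GENES))
    is_low = group == "low"
    expr[np.ix_(tam_rows, np.flatnonzero(is_low))] -= shift
    expr[np.ix_(nk_rows, np.flatnonzero(is_low))] += shift
    expr[np.ix_(tam_rows, np.flatnonzero(~is_low))] += shift
    expr[np.ix_(nk_rows, np.flatnonzero(~is_low))] -= shift
    expr = np.clip(expr, 0.0, None)

    hazards = np.where(is_low, config.baseline_hazard * config.true_hr_low_vs_high,
                       config.baseline_hazard)
    times = rng.exponential(1.0 / hazards)
    events = np.ones(n, dtype=int)
    if config.censor_rate > 0:
        horizon = _censor_horizon(config.censor_rate, hazards)
        cens = rng.uniform(0.0, horizon, size=n)
        events = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    times = np.maximum(times, 1e-9)  # SurvivalRecord requires time > 0

    patient_ids = [f"P{i:04d}" for i in range(1, n + 1)]
    records = [
        SurvivalRecord(pid, float(t), int(e))
        for pid, t, e in zip(patient_ids, times, events)
    ]
    matrix = ExpressionMatrix(expr, genes, patient_ids, layer_tag="lognorm")
    return matrix, records, group.astype(str)
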