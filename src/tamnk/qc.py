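"""Cell quality control, doublet flagging and log-normalization.

Filtering rules: keep cells with between ``min_genes`` and ``max_genes``
detected genes (inclusive), total UMI strictly below ``max_umi`` and
mitochondrial content strictly below ``max_pct_mito`` percent.
Normalization divides each cell by its total UMI, multiplies by a
scaling factor (default 10,000) and applies ln(1 + x).

Doublets are flagged when a cell scores highly (z > threshold across
cells) on two or more population-specific marker panels, operationally
capturing "more than one highly expressed population" without a
model-based detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import builtin_gene_sets
from .matrix import ContractError, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class QCThresholds:
    """Cell-filtering thresholds (gene bounds inclusive, UMI/mito strict)."""

    min_genes: int = 500
    max_genes: int = 50000
    max_umi: int = 30000
    max_pct_mito: float = 20.0

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")


def compute_qc_metrics(
    m: ExpressionMatrix,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
) -> pd.DataFrame:
    """Per-cell QC metrics: n_genes_detected, total_umi, pct_mito.

    ``pct_mito`` is 100 × (mitochondrial counts / total UMI), defined as
    0 for empty cells.  Requires a counts layer.
    """
    if m.layer_tag != "counts":
        raise ContractError("QC metrics are defined on raw counts, got lognorm layer")
    counts = m.values
    mito_mask = np.array(
        [any(g.upper().startswith(p.upper()) for p in mito_prefixes) for g in m.gene_symbols]
    )
    total = counts.sum(axis=0)
    mito = counts[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros(m.n_obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * mito / np.where(total > 0, total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": (counts > 0).sum(axis=0).astype(int),
            "total_umi": total.astype(int),
            "pct_mito": pct,
        },
        index=pd.Index(m.obs_ids, name="cell_id"),
    )


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> np.ndarray:
    """Indices of cells passing the QC thresholds (in input order)."""
    t = thresholds or QCThresholds()
    keep = (
        (metrics["n_genes_detected"] >= t.min_genes)
        & (metrics["n_genes_detected"] <= t.max_genes)
        & (metrics["total_umi"] < t.max_umi)
        & (metrics["pct_mito"] < t.max_pct_mito)
    )
    return np.flatnonzero(keep.to_numpy())


def _marker_set_zscores(
    m: ExpressionMatrix, marker_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-cell z-scores of mean log1p marker expression, one column per set."""
    gi = m.gene_index()
    log_counts = np.log1p(m.values)
    cols = {}
    for name, genes in marker_sets.items():
        idx = [gi[g] for g in genes if g in gi]
        if not idx:
            logger.warning("marker set %s has no genes in the matrix; skipped", name)
            continue
        score = log_counts[idx].mean(axis=0)
        sd = score.std()
        cols[name] = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    return pd.DataFrame(cols, index=pd.Index(m.obs_ids, name="cell_id"))


def flag_doublets(
    m: ExpressionMatrix,
    population_marker_sets: Mapping[str, Sequence[str]] | Iterable[GeneSet] | None = None,
    z_threshold: float = 2.0,
) -> np.ndarray:
    """Boolean flag per cell: True when ≥2 marker panels have z > threshold."""
    flagger = DoubletFlagger(marker_sets=population_marker_sets, z_threshold=z_threshold)
    return flagger.fit(m).flags_


def normalize_log(m: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Library-size normalize to ``scale`` counts per cell and ln(1+x) transform."""
    return LogNormalizer(scale=scale).transform(m)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class QCFilter(BaseEstimator):
    """Filter cells by detected genes, total UMI and mitochondrial content.

    ``fit`` computes per-cell metrics (``metrics_``) and the kept mask
    (``kept_mask_``, ``kept_idx_``); ``transform`` returns the filtered
    matrix.  Idempotent: filtering an already-filtered matrix removes
    nothing.
    """

    def __init__(
        self,
        min_genes: int = 500,
        max_genes: int = 50000,
        max_umi: int = 30000,
        max_pct_mito: float = 20.0,
        mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_umi = max_umi
        self.max_pct_mito = max_pct_mito
        self.mito_prefixes = mito_prefixes

    def _thresholds(self) -> QCThresholds:
        return QCThresholds(self.min_genes, self.max_genes, self.max_umi, self.max_pct_mito)

    def fit(self, X: ExpressionMatrix, y=None) -> "QCFilter":
        self.metrics_ = compute_qc_metrics(X, self.mito_prefixes)
        self.kept_idx_ = filter_cells(self.metrics_, self._thresholds())
        mask = np.zeros(X.n_obs, dtype=bool)
        mask[self.kept_idx_] = True
        self.kept_mask_ = mask
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        if not hasattr(self, "kept_idx_"):
            raise ContractError("QCFilter.transform called before fit")
        return X.subset_obs(self.kept_idx_)

    def fit_transform(self, X: ExpressionMatrix, y=None) -> ExpressionMatrix:
        return self.fit(X).transform(X)


class DoubletFlagger(BaseEstimator):
    """Flag putative doublets by multi-panel marker expression.

    Each panel's per-cell mean log1p count is z-scored across cells; a
    cell is flagged when at least two panels exceed ``z_threshold``.
    Panels with no genes in the matrix are skipped with a warning.
    """

    def __init__(
        self,
        marker_sets: Mapping[str, Sequence[str]] | Iterable[GeneSet] | None = None,
        z_threshold: float = 2.0,
    ):
        self.marker_sets = marker_sets
        self.z_threshold = z_threshold

    def _resolved_sets(self) -> dict[str, tuple[str, ...]]:
        sets = self.marker_sets
        if sets is None:
            reg = builtin_gene_sets()
            sets = {k: reg[k].genes for k in ("M0", "M1", "M2", "MONOCYTE", "NK_MARK")}
        elif not isinstance(sets, Mapping):
            sets = {gs.name: gs.genes for gs in sets}
        if len(sets) < 2:
            raise ContractError("doublet flagging needs at least 2 marker sets")
        return {k: tuple(v) for k, v in sets.items()}

    def fit(self, X: ExpressionMatrix, y=None) -> "DoubletFlagger":
        if X.layer_tag != "counts":
            raise ContractError("doublet flagging operates on raw counts")
        z = _marker_set_zscores(X, self._resolved_sets())
        if z.shape[1] < 2:
            raise ContractError("fewer than 2 usable marker sets after matching")
        self.set_zscores_ = z
        self.flags_ = ((z > self.z_threshold).sum(axis=1) >= 2).to_numpy()
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> np.ndarray:
        return self.fit(X).flags_


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Stateless library-size + log1p normalizer (scale default 10,000).

    Output value for gene g in cell c is ln(1 + scale * count_gc /
    total_umi_c); all-zero cells map to all-zero columns.  The transform
    is equivariant to scaling a cell's counts by a positive constant.
    """

    def __init__(self, scale: float = 10000.0):
        self.scale = scale

    def fit(self, X: ExpressionMatrix, y=None) -> "LogNormalizer":
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        if X.layer_tag != "counts":
            raise ContractError("normalize_log expects a counts layer")
        total = X.values.sum(axis=0)
        safe = np.where(total > 0, total, 1.0)
        norm = np.log1p(self.scale * X.values / safe)
        norm[:, total == 0] = 0.0
        return ExpressionMatrix(norm, list(X.gene_symbols), list(X.obs_ids), "lognorm")
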