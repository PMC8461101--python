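"""TAM-to-NK score, macrophage polarization annotation, cell-proportion
comparison and ligand–receptor interaction scoring.

The TAM-to-NK score combines a cell's (or patient's) single-sample
enrichment of a 12-gene monocyte/TAM signature with that of a 10-gene
NK-like signature, either as the literal ratio TAM/NK or, by default,
as the difference TAM − NK.  The difference preserves the ordering the
survival split uses while remaining defined when the NK enrichment is
zero or negative; the ratio drops observations whose NK enrichment lies
within ``epsilon`` of zero, and the number dropped is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, TransformerMixin

from .enrichment import EnrichmentScores
from .io import builtin_gene_sets
from .matrix import (
    ContractError,
    ExpressionMatrix,
    GeneSet,
    LigandReceptorPair,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class TamNkScore:
    """TAM-to-NK score of one observation.

    ``score`` is None when mode="ratio" and the NK enrichment is within
    ``epsilon`` of zero.
    """

    obs_id: str
    tam_enrichment: float
    nk_enrichment: float
    score: float | None
    mode: str


def tam_to_nk(
    scores: EnrichmentScores,
    mode: str = "difference",
    epsilon: float = 1e-8,
    tam_set: str = "TAM_TYPE",
    nk_set: str = "NK_TYPE",
) -> list[TamNkScore]:
    """Combine TAM and NK enrichment rows into per-observation scores."""
    if mode not in ("ratio", "difference"):
        raise ContractError(f"unknown mode {mode!r}")
    tam = scores.row(tam_set)
    nk = scores.row(nk_set)
    out: list[TamNkScore] = []
    n_undefined = 0
    for obs_id, t, k in zip(scores.obs_ids, tam, nk):
        if mode == "ratio":
            if abs(k) < epsilon:
                value = None
                n_undefined += 1
            else:
                value = float(t) / float(k)
        else:
            value = float(t) - float(k)
        out.append(TamNkScore(obs_id, float(t), float(k), value, mode))
    if n_undefined:
        logger.info(
            "tam_to_nk(mode=ratio): %d of %d observations undefined (|NK| < %.1e)",
            n_undefined, len(out), epsilon,
        )
    return out


class TamNkScorer(BaseEstimator, TransformerMixin):
    """Estimator computing TAM-to-NK scores from enrichment results."""

    def __init__(self, mode: str = "difference", epsilon: float = 1e-8):
        self.mode = mode
        self.epsilon = epsilon

    def fit(self, X: EnrichmentScores, y=None) -> "TamNkScorer":
        return self

    def transform(self, X: EnrichmentScores) -> pd.DataFrame:
        rows = tam_to_nk(X, mode=self.mode, epsilon=self.epsilon)
        return pd.DataFrame(
            {
                "obs_id": [r.obs_id for r in rows],
                "tam_enrichment": [r.tam_enrichment for r in rows],
                "nk_enrichment": [r.nk_enrichment for r in rows],
                "score": [math.nan if r.score is None else r.score for r in rows],
                "mode": self.mode,
            }
        ).set_index("obs_id")


# ---------------------------------------------------------------------------
# Polarization annotation
# ---------------------------------------------------------------------------

@dataclass
class PolarizationLabel:
    """Panel-based polarization call for one cell."""

    obs_id: str
    label: str
    panel_scores: dict[str, float] = field(default_factory=dict)


class PolarizationAnnotator(BaseEstimator):
    """Assign M0/M1/M2 state by the highest-scoring marker panel.

    The panel score is the mean log-normalized expression of the
    panel's genes.  A cell is labeled by the argmax panel only when its
    score exceeds the runner-up by more than ``margin``; otherwise (ties
    included) the cell is UNASSIGNED.
    """

    def __init__(
        self,
        panels: Mapping[str, Sequence[str]] | None = None,
        margin: float = 0.0,
    ):
        self.panels = panels
        self.margin = margin

    def _resolved_panels(self) -> dict[str, tuple[str, ...]]:
        if self.panels is not None:
            return {k: tuple(v) for k, v in self.panels.items()}
        reg = builtin_gene_sets()
        return {k: reg[k].genes for k in ("M0", "M1", "M2")}

    def score_panels(self, X: ExpressionMatrix) -> pd.DataFrame:
        if X.layer_tag != "lognorm":
            raise ContractError("polarization scoring expects log-normalized input")
        gi = X.gene_index()
        cols = {}
        for name, genes in self._resolved_panels().items():
            idx = [gi[g] for g in genes if g in gi]
            if not idx:
                raise ContractError(f"panel {name} has no genes in the matrix")
            cols[name] = X.values[idx].mean(axis=0)
        return pd.DataFrame(cols, index=pd.Index(X.obs_ids, name="cell_id"))

    def predict(self, X: ExpressionMatrix) -> np.ndarray:
        scores = self.score_panels(X)
        vals = scores.to_numpy()
        order = np.argsort(-vals, axis=1)
        best = order[:, 0]
        best_val = vals[np.arange(len(vals)), best]
        if vals.shape[1] > 1:
            runner_val = vals[np.arange(len(vals)), order[:, 1]]
        else:
            runner_val = np.full(len(vals), -np.inf)
        names = np.array(scores.columns, dtype=object)
        labels = np.where(best_val - runner_val > self.margin, names[best], "UNASSIGNED")
        self.panel_scores_ = scores
        return labels.astype(str)


def annotate_polarization(
    m: ExpressionMatrix,
    panels: Mapping[str, Sequence[str]] | None = None,
    margin: float = 0.0,
) -> list[PolarizationLabel]:
    """Per-cell polarization labels (M0/M1/M2/UNASSIGNED)."""
    annot = PolarizationAnnotator(panels=panels, margin=margin)
    labels = annot.predict(m)
    scores = annot.panel_scores_
    return [
        PolarizationLabel(obs, lab, dict(scores.loc[obs]))
        for obs, lab in zip(m.obs_ids, labels)
    ]


# ---------------------------------------------------------------------------
# Group-wise proportion comparison
# ---------------------------------------------------------------------------

@dataclass
class ProportionShiftResult:
    """Contingency counts, per-group proportions and Pearson chi-square."""

    counts: pd.DataFrame          # labels × groups
    proportions: pd.DataFrame     # columns sum to 1
    chi_square: float
    df: int
    p_value: float


def proportion_shift(labels: Sequence[str], groups: Sequence[str]) -> ProportionShiftResult:
    """Compare label composition across groups with a Pearson chi-square."""
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(groups, dtype=object)
    if labels.shape != groups.shape:
        raise ValidationError("labels and groups must align one per cell")
    table = pd.crosstab(pd.Series(labels, name="label"), pd.Series(groups, name="group"))
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise ValidationError("need at least 2 groups and 2 labels")
    if (table.sum(axis=0) == 0).any():
        raise ValidationError("every group must contain at least one cell")
    chi2, p, dof, _ = chi2_contingency(table.to_numpy(), correction=False)
    props = table / table.sum(axis=0)
    return ProportionShiftResult(table, props, float(chi2), int(dof), float(p))


# ---------------------------------------------------------------------------
# Ligand-receptor interaction scoring
# ---------------------------------------------------------------------------

@dataclass
class LRInteractionScore:
    """Interaction strength of one ligand→receptor axis between two populations."""

    pair: LigandReceptorPair
    sender_type: str
    receiver_type: str
    score: float
    per_sample_scores: list[float]


def lr_interaction(
    m: ExpressionMatrix,
    cell_types: Sequence[str],
    pairs: Iterable[LigandReceptorPair],
    sender_type: str,
    receiver_type: str,
    combine: str = "mean",
    sample_ids: Sequence[str] | None = None,
) -> list[LRInteractionScore]:
    """Score ligand–receptor pairs between a sender and receiver population.

    Per sample the ligand's mean log-normalized expression over sender
    cells (L) and the receptor's over receiver cells (R) are combined as
    (L + R)/2 (``mean``, the default) or L·R (``product``); the final
    score averages the per-sample values.  Pairs whose ligand or
    receptor is absent from the matrix are skipped with a warning.
    """
    if combine not in ("mean", "product"):
        raise ContractError(f"unknown combine {combine!r}")
    cell_types = np.asarray(cell_types, dtype=object)
    if cell_types.size != m.n_obs:
        raise ValidationError("cell_types must align with matrix observations")
    samples = (
        np.asarray(sample_ids, dtype=object)
        if sample_ids is not None
        else np.array(["sample1"] * m.n_obs, dtype=object)
    )
    sender_mask = cell_types == sender_type
    receiver_mask = cell_types == receiver_type
    if not sender_mask.any():
        raise ValidationError(f"no cells of sender type {sender_type!r}")
    if not receiver_mask.any():
        raise ValidationError(f"no cells of receiver type {receiver_type!r}")
    gi = m.gene_index()
    results: list[LRInteractionScore] = []
    for pair in pairs:
        if pair.ligand not in gi or pair.receptor not in gi:
            logger.warning("pair %s skipped: gene absent from matrix", pair.name)
            continue
        lig_row = m.values[gi[pair.ligand]]
        rec_row = m.values[gi[pair.receptor]]
        per_sample: list[float] = []
        for sample in pd.unique(samples):
            s_mask = sender_mask & (samples == sample)
            r_mask = receiver_mask & (samples == sample)
            if not s_mask.any() or not r_mask.any():
                continue
            lbar = float(lig_row[s_mask].mean())
            rbar = float(rec_row[r_mask].mean())
            per_sample.append((lbar + rbar) / 2.0 if combine == "mean" else lbar * rbar)
        if not per_sample:
            logger.warning("pair %s skipped: no sample with both populations", pair.name)
            continue
        results.append(
            LRInteractionScore(
                pair, sender_type, receiver_type, float(np.mean(per_sample)), per_sample
            )
        )
    return results
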