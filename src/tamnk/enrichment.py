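"""Single-sample gene-set enrichment.

Three methods are provided behind one interface:

``gsva``
    Kernel-CDF transform of each gene across observations (gaussian for
    continuous input with bandwidth SD/4, poisson for counts, or plain
    empirical-CDF ranks), followed per observation by a weighted
    Kolmogorov–Smirnov-like random walk over the gene ranking.
``ssgsea``
    Ranks of raw expression per observation, rank weights |r|^tau
    (tau default 0.25), and the running-sum area statistic normalized to
    [-1, 1] by the maximum area attainable with the same in-set weights.
``zscore``
    Per-gene standardization across observations; the set score is
    sum(z_g) / sqrt(|set|) (combined z-score).

Genes absent from the matrix are dropped from sets before scoring; sets
falling below ``min_set_genes`` matched genes are skipped with a
warning, which is how mouse-only symbols behave on human cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, poisson, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ContractError, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

METHODS = ("gsva", "ssgsea", "zscore")
_DEFAULT_TAU = {"gsva": 1.0, "ssgsea": 0.25, "zscore": 1.0}


@dataclass
class EnrichmentScores:
    """Gene sets × observations matrix of single-sample enrichment values."""

    values: np.ndarray
    set_names: list[str]
    obs_ids: list[str]
    method_tag: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.set_names, columns=self.obs_ids)

    def row(self, set_name: str) -> np.ndarray:
        try:
            i = self.set_names.index(set_name)
        except ValueError:
            raise ContractError(f"enrichment scores have no row for set {set_name!r}")
        return self.values[i]


# ---------------------------------------------------------------------------
# Kernel CDF transform
# ---------------------------------------------------------------------------

def _gaussian_kcdf_row(x: np.ndarray) -> np.ndarray:
    """Kernel CDF of each value of one gene under a gaussian kernel.

    Bandwidth is the sample SD / 4; a constant gene degenerates to 0.5
    everywhere.
    """
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    h = sd / 4.0
    if h == 0:
        return np.full_like(x, 0.5, dtype=float)
    return norm.cdf((x[:, None] - x[None, :]) / h).mean(axis=1)


def _poisson_kcdf_row(x: np.ndarray) -> np.ndarray:
    """Kernel CDF for integer counts: mean Poisson CDF with rates x_k + 0.5."""
    return poisson.cdf(x[:, None], x[None, :] + 0.5).mean(axis=1)


def _ecdf_row(x: np.ndarray) -> np.ndarray:
    """Empirical CDF ranks scaled into (0, 1), ties averaged."""
    return rankdata(x, method="average") / (x.size + 1)


def kcdf_transform(m: ExpressionMatrix, kernel: str = "gaussian") -> np.ndarray:
    """Transform each gene's profile across observations to CDF space.

    Requires ≥3 observations (the density is estimated across
    observations).  ``kernel`` is one of gaussian, poisson, none.
    """
    if m.n_obs < 3:
        raise ContractError("kernel CDF estimation needs at least 3 observations")
    if kernel == "gaussian":
        fn = _gaussian_kcdf_row
    elif kernel == "poisson":
        fn = _poisson_kcdf_row
    elif kernel == "none":
        fn = _ecdf_row
    else:
        raise ContractError(f"unknown kernel {kernel!r}")
    return np.vstack([fn(row) for row in m.values])


# ---------------------------------------------------------------------------
# Random-walk enrichment statistic
# ---------------------------------------------------------------------------

def _ranked_order(values: np.ndarray, symbols: Sequence[str]) -> np.ndarray:
    """Indices ordering genes by descending value; ties broken by symbol.

    Breaking ties lexicographically (rather than by row position) keeps
    scores invariant to the gene row order of the input matrix.
    """
    sym = np.asarray(symbols, dtype=object)
    return np.lexsort((sym, -np.asarray(values, dtype=float)))


def enrichment_walk(
    ordered_in_set: np.ndarray,
    weights: np.ndarray,
    tau: float = 1.0,
    es_mode: str = "diff",
) -> float:
    """Weighted KS-like running-sum enrichment score over a gene ranking.

    Parameters
    ----------
    ordered_in_set : boolean array over ranking positions (top first)
    weights : nonnegative rank weights aligned with the ranking; in-set
        positions step up by |w|^tau (normalized to sum 1), out-of-set
        positions step down uniformly.
    es_mode : "diff" returns (max positive deviation) + (min negative
        deviation); "max" returns the deviation of maximal magnitude
        with its sign.

    The result lies in [-1, 1].  If the set spans the whole ranking the
    walk has no out-of-set steps and the score is defined as 1.
    """
    mask = np.asarray(ordered_in_set, dtype=bool)
    n = mask.size
    m = int(mask.sum())
    if m == 0:
        raise ContractError("enrichment walk needs at least one in-set gene")
    if m == n:
        return 1.0
    w = np.abs(np.asarray(weights, dtype=float)) ** tau
    steps = np.where(mask, 0.0, -1.0 / (n - m))
    in_w = w[mask]
    total = in_w.sum()
    if total == 0:  # all-zero weights: fall back to unweighted steps
        steps[mask] = 1.0 / m
    else:
        steps[mask] = w[mask] / total
    running = np.cumsum(steps)
    if es_mode == "diff":
        return float(max(running.max(), 0.0) + min(running.min(), 0.0))
    if es_mode == "max":
        i = int(np.argmax(np.abs(running)))
        return float(running[i])
    raise ContractError(f"unknown es_mode {es_mode!r}")


def _walk_area(ordered_in_set: np.ndarray, weights: np.ndarray, tau: float) -> float:
    """Area under the running sum (ssGSEA statistic before normalization)."""
    mask = np.asarray(ordered_in_set, dtype=bool)
    n, m = mask.size, int(mask.sum())
    w = np.abs(np.asarray(weights, dtype=float)) ** tau
    steps = np.where(mask, 0.0, -1.0 / max(n - m, 1))
    total = w[mask].sum()
    steps[mask] = (w[mask] / total) if total > 0 else 1.0 / m
    return float(np.cumsum(steps).sum())


def _area_bounds(in_weights: np.ndarray, n: int, tau: float) -> tuple[float, float]:
    """Max/min attainable walk area for a fixed in-set weight multiset.

    The area is maximal with the in-set genes at the top of the ranking
    (largest weights first) and minimal with them at the bottom
    (smallest first); both follow from an exchange argument on the
    cumulative sums.
    """
    m = in_weights.size
    sorted_w = np.sort(np.abs(in_weights))[::-1]
    top = np.zeros(n, dtype=bool)
    top[:m] = True
    w_top = np.zeros(n)
    w_top[:m] = sorted_w
    area_max = _walk_area(top, w_top, tau=1.0)  # weights pre-raised by caller
    bottom = np.zeros(n, dtype=bool)
    bottom[n - m:] = True
    w_bot = np.zeros(n)
    w_bot[n - m:] = sorted_w[::-1]
    area_min = _walk_area(bottom, w_bot, tau=1.0)
    return area_max, area_min


# ---------------------------------------------------------------------------
# Scoring driver
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentParams:
    """Method switch and tuning knobs for single-sample enrichment."""

    method: str = "zscore"
    tau: float | None = None
    kernel: str = "gaussian"
    es_mode: str = "diff"
    min_set_genes: int = 2

    def resolved_tau(self) -> float:
        tau = _DEFAULT_TAU[self.method] if self.tau is None else self.tau
        if tau < 0:
            raise ContractError("tau must be >= 0")
        return tau


def _match_sets(
    sets: Iterable[GeneSet], symbols: Sequence[str], min_set_genes: int
) -> list[GeneSet]:
    matched = []
    for s in sets:
        sub = s.intersect(symbols)
        if sub is None or len(sub) < min_set_genes:
            logger.warning(
                "gene set %s has %d gene(s) in the matrix (< %d); skipped",
                s.name, 0 if sub is None else len(sub), min_set_genes,
            )
            continue
        matched.append(sub)
    return matched


def score_sets(
    m: ExpressionMatrix,
    sets: Sequence[GeneSet],
    params: EnrichmentParams | None = None,
) -> EnrichmentScores:
    """Score gene sets per observation with the configured method."""
    params = params or EnrichmentParams()
    if params.method not in METHODS:
        raise ContractError(f"unknown method {params.method!r}")
    if m.n_genes == 0 or m.n_obs == 0:
        raise ContractError("expression matrix is empty")
    matched = _match_sets(sets, m.gene_symbols, params.min_set_genes)
    if not matched:
        raise ContractError("all gene sets were skipped (too few matching genes)")
    tau = params.resolved_tau()
    gi = m.gene_index()
    n = m.n_genes

    if params.method == "zscore":
        mu = m.values.mean(axis=1, keepdims=True)
        sd = m.values.std(axis=1, ddof=1, keepdims=True)
        z = np.where(sd > 0, (m.values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        rows = [
            z[[gi[g] for g in s.genes]].sum(axis=0) / np.sqrt(len(s)) for s in matched
        ]
        values = np.vstack(rows)
    else:
        if params.method == "gsva":
            profile = kcdf_transform(m, params.kernel)
        else:  # ssgsea ranks raw expression
            profile = m.values
        set_masks = []
        for s in matched:
            mask = np.zeros(n, dtype=bool)
            mask[[gi[g] for g in s.genes]] = True
            set_masks.append(mask)
        values = np.zeros((len(matched), m.n_obs))
        ranks_template = np.arange(n, 0, -1, dtype=float)  # rank n at top
        for j in range(m.n_obs):
            order = _ranked_order(profile[:, j], m.gene_symbols)
            weights = ranks_template  # weight by rank position, top = n
            for si, mask in enumerate(set_masks):
                ordered_mask = mask[order]
                if params.method == "gsva":
                    values[si, j] = enrichment_walk(
                        ordered_mask, weights, tau=tau, es_mode=params.es_mode
                    )
                else:
                    mcount = int(ordered_mask.sum())
                    if mcount == n:
                        values[si, j] = 1.0
                        continue
                    w_tau = weights ** tau
                    area = _walk_area(ordered_mask, w_tau, tau=1.0)
                    amax, amin = _area_bounds(w_tau[ordered_mask], n, tau=1.0)
                    scale = max(amax, -amin)
                    values[si, j] = area / scale if scale > 0 else 0.0

    return EnrichmentScores(
        values=values,
        set_names=[s.name for s in matched],
        obs_ids=list(m.obs_ids),
        method_tag=params.method,
    )


class GeneSetScorer(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`score_sets`.

    Parameters mirror :class:`EnrichmentParams`; ``gene_sets`` defaults
    to the built-in TAM_TYPE / NK_TYPE signatures.
    """

    def __init__(
        self,
        gene_sets: Sequence[GeneSet] | None = None,
        method: str = "zscore",
        tau: float | None = None,
        kernel: str = "gaussian",
        es_mode: str = "diff",
        min_set_genes: int = 2,
    ):
        self.gene_sets = gene_sets
        self.method = method
        self.tau = tau
        self.kernel = kernel
        self.es_mode = es_mode
        self.min_set_genes = min_set_genes

    def _params(self) -> EnrichmentParams:
        return EnrichmentParams(
            method=self.method,
            tau=self.tau,
            kernel=self.kernel,
            es_mode=self.es_mode,
            min_set_genes=self.min_set_genes,
        )

    def _sets(self) -> Sequence[GeneSet]:
        if self.gene_sets is not None:
            return self.gene_sets
        from .io import builtin_gene_sets

        reg = builtin_gene_sets()
        return [reg["TAM_TYPE"], reg["NK_TYPE"]]

    def fit(self, X: ExpressionMatrix, y=None) -> "GeneSetScorer":
        return self

    def transform(self, X: ExpressionMatrix) -> EnrichmentScores:
        return score_sets(X, self._sets(), self._params())
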