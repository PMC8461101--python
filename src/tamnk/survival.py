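"""Survival stratification by a maximally selected statistic.

Given per-subject scores and follow-up, the module selects the score
cutpoint maximizing the absolute standardized log-rank statistic over a
candidate window (maxstat), assesses its significance by permutation
(the permutation null accounts for the selection of the maximum), and
quantifies prognosis of the resulting low/high groups with the
Kaplan–Meier estimator, the two-group log-rank test and a binary-
covariate Cox model (Breslow tie handling, Newton–Raphson).

The hazard ratio is reported for low-vs-high with "high" as reference,
so HR > 1 reads "low score, poor prognosis".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .matrix import ContractError, SurvivalRecord, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at all distinct observed times.

    Censored-only times appear in the grid (they reduce the at-risk
    count) but leave the survival probability unchanged.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    if not records:
        raise ContractError("km_estimate needs at least one record")
    times, events = _as_arrays(records)
    grid = np.unique(times)
    n = len(times)
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for t in grid:
        r = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if r > 0 and d > 0:
            s *= 1.0 - d / r
        at_risk.append(r)
        d_list.append(d)
        surv.append(s)
    return KMCurve(grid, np.array(surv), np.array(at_risk, dtype=int), np.array(d_list, dtype=int))


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def _logrank_oev(
    times: np.ndarray, events: np.ndarray, in_a: np.ndarray
) -> tuple[float, float]:
    """Observed-minus-expected events in group A and hypergeometric variance."""
    taus = np.unique(times[events == 1])
    oe = 0.0
    var = 0.0
    for t in taus:
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (times == t) & (events == 1)
        d_tot = int(dying.sum())
        d_a = int((dying & in_a).sum())
        oe += d_a - d_tot * n_a / n_tot
        if n_tot > 1:
            var += d_tot * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    return oe, var


def logrank_test(
    records_a: Sequence[SurvivalRecord], records_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value)."""
    if not records_a or not records_b:
        raise ContractError("both groups must be nonempty")
    ta, ea = _as_arrays(records_a)
    tb, eb = _as_arrays(records_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    if events.sum() == 0:
        logger.info("log-rank: zero events in both groups; statistic 0, p=1")
        return 0.0, 1.0
    in_a = np.zeros(len(times), dtype=bool)
    in_a[: len(ta)] = True
    oe, var = _logrank_oev(times, events, in_a)
    if var <= 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    return float(chi2), float(chi2_dist.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Maximally selected log-rank statistic
# ---------------------------------------------------------------------------

def _prefix_logrank_stats(
    times: np.ndarray,
    events: np.ndarray,
    orders: np.ndarray,
    ks: np.ndarray,
) -> np.ndarray:
    """Standardized log-rank statistics for prefix groups of given sizes.

    ``orders`` is a (B, n) batch of subject orderings (e.g. by score);
    for each ordering, group A for prefix size k is its first k
    subjects.  Returns a (B, len(ks)) array of signed standardized
    statistics (O-E)/sqrt(V).  Vectorized over both orderings and
    prefixes so that permutation nulls stay cheap.
    """
    orders = np.atleast_2d(orders)
    taus = np.unique(times[events == 1])
    if taus.size == 0:
        return np.zeros((orders.shape[0], ks.size))
    at_risk = times[None, :] >= taus[:, None]              # (T, n)
    dying = (times[None, :] == taus[:, None]) & (events == 1)[None, :]
    n_tot = at_risk.sum(axis=1).astype(float)              # (T,)
    d_tot = dying.sum(axis=1).astype(float)
    # per-ordering column reshuffle, cumulative over the prefix axis
    r_perm = at_risk[:, orders]                            # (T, B, n)
    d_perm = dying[:, orders]
    n_a = np.cumsum(r_perm, axis=2)[:, :, ks - 1].astype(float)   # (T, B, K)
    d_a = np.cumsum(d_perm, axis=2)[:, :, ks - 1].astype(float)
    frac = n_a / n_tot[:, None, None]
    oe = (d_a - d_tot[:, None, None] * frac).sum(axis=0)          # (B, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmult = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    var = (vmult[:, None, None] * frac * (1.0 - frac)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, oe / np.sqrt(var), 0.0)
    return z


@dataclass
class CutpointResult:
    """Maxstat cutpoint with its standardized statistic and permutation p."""

    cutpoint: float
    max_statistic: float
    perm_p: float
    n_low: int
    n_high: int
    candidate_cutpoints: np.ndarray = field(repr=False, default=None)
    candidate_statistics: np.ndarray = field(repr=False, default=None)


def maxstat_cutpoint(
    records: Sequence[SurvivalRecord],
    scores: Sequence[float] | None = None,
    q_low: float = 0.1,
    q_high: float = 0.9,
    n_perm: int = 1000,
    seed: int | None = None,
    _perm_batch: int = 64,
) -> CutpointResult:
    """Maximally selected standardized log-rank cutpoint on a score.

    Candidate cutpoints are midpoints between consecutive distinct
    scores inside the [q_low, q_high] score-quantile window.  The
    selected cutpoint maximizes |standardized log-rank| between the
    score≤c and score>c groups (smallest c on exact ties).  The
    permutation p-value is the add-one-smoothed fraction of score
    permutations whose maximal |statistic| reaches the observed one.
    """
    if scores is None:
        scores = [r.score for r in records]
    scores = np.asarray([np.nan if s is None else s for s in scores], dtype=float)
    defined = ~np.isnan(scores)
    times, events = _as_arrays(records)
    times, events, scores = times[defined], events[defined], scores[defined]
    n = len(scores)
    if n < 10:
        raise ValidationError("maxstat needs at least 10 defined-score records")
    lo, hi = np.quantile(scores, [q_low, q_high])
    distinct = np.unique(scores)
    window = distinct[(distinct >= lo) & (distinct <= hi)]
    if window.size < 2:
        raise ValidationError("fewer than 2 distinct scores inside the quantile window")
    cands = (window[:-1] + window[1:]) / 2.0
    if cands.size < 2:
        raise ValidationError("fewer than 2 candidate cutpoints")

    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    ks = np.searchsorted(sorted_scores, cands, side="right").astype(int)

    z_obs = _prefix_logrank_stats(times, events, order[None, :], ks)[0]
    best = int(np.argmax(np.abs(z_obs)))  # argmax returns first max → smallest c
    cut = float(cands[best])
    stat = float(z_obs[best])
    obs_max = float(np.abs(z_obs).max())

    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(_perm_batch, n_perm - done)
        perm_orders = np.argsort(rng.random((b, n)), axis=1)
        z = _prefix_logrank_stats(times, events, perm_orders, ks)
        exceed += int((np.abs(z).max(axis=1) >= obs_max).sum())
        done += b
    perm_p = (1 + exceed) / (1 + n_perm)

    n_low = int((scores <= cut).sum())
    return CutpointResult(
        cutpoint=cut,
        max_statistic=stat,
        perm_p=float(perm_p),
        n_low=n_low,
        n_high=n - n_low,
        candidate_cutpoints=cands,
        candidate_statistics=z_obs,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards, single binary covariate
# ---------------------------------------------------------------------------

@dataclass
class HazardRatio:
    """Binary-covariate Cox fit: HR with Wald CI and p-value."""

    hr: float
    log_hr_se: float
    ci95: tuple[float, float]
    wald_p: float
    beta: float
    n_iter: int
    diverged: bool = False


_BETA_CAP = 15.0


def cox_binary_hr(
    records: Sequence[SurvivalRecord],
    group: Sequence[str],
    reference: str = "high",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> HazardRatio:
    """Cox partial-likelihood HR for a binary group (Breslow ties).

    The non-reference group is coded 1, so with reference="high" the
    returned HR is low-vs-high.  Monotone likelihoods (e.g. all events
    in one group) are capped at |beta| = 15 and flagged as diverged.
    """
    times, events = _as_arrays(records)
    group = np.asarray(group, dtype=object)
    levels = set(group.tolist())
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not present in groups")
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 group levels, got {sorted(map(str, levels))}")
    x = (group != reference).astype(float)
    if events.sum() == 0:
        raise ValidationError("no events; hazard ratio undefined")

    taus = np.unique(times[events == 1])
    at_risk = times[None, :] >= taus[:, None]            # (T, n)
    dying = (times[None, :] == taus[:, None]) & (events == 1)[None, :]
    d_tot = dying.sum(axis=1).astype(float)
    d1 = (dying & (x == 1.0)[None, :]).sum(axis=1).astype(float)
    n1 = (at_risk & (x == 1.0)[None, :]).sum(axis=1).astype(float)
    n0 = at_risk.sum(axis=1).astype(float) - n1

    beta = 0.0
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        e = np.exp(beta)
        s0 = n0 + n1 * e
        p = n1 * e / s0                                   # E[x | risk set]
        u = float(d1.sum() - (d_tot * p).sum())
        info = float((d_tot * p * (1.0 - p)).sum())
        if info <= 0:
            diverged = True
            break
        step = u / info
        beta += step
        if abs(beta) > _BETA_CAP:
            beta = float(np.clip(beta, -_BETA_CAP, _BETA_CAP))
            diverged = True
            break
        if abs(step) < tol:
            break

    e = np.exp(beta)
    p = n1 * e / (n0 + n1 * e)
    info = float((d_tot * p * (1.0 - p)).sum())
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    if np.isfinite(se):
        # a capped (diverged) fit can push the CI bound past exp's range; inf is fine
        with np.errstate(over="ignore"):
            ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        wald_p = float(2.0 * norm.sf(abs(beta) / se)) if se > 0 else 1.0
    else:
        ci = (0.0, float("inf"))
        wald_p = 1.0
    if diverged:
        logger.warning("Cox fit diverged (monotone likelihood); estimate capped")
    return HazardRatio(float(np.exp(beta)), se, ci, wald_p, float(beta), it, diverged)


# ---------------------------------------------------------------------------
# Full stratified analysis
# ---------------------------------------------------------------------------

@dataclass
class StratifiedReport:
    """Complete low/high TAM-to-NK survival stratification report."""

    cutpoint: CutpointResult
    km_low: KMCurve
    km_high: KMCurve
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: HazardRatio
    groups: dict[str, str]
    n_input: int
    n_dropped: int
    n_analyzed: int
    direction: str = "HR is low-vs-high (reference: high score group)"

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "cutpoint": self.cutpoint.cutpoint,
            "max_statistic": self.cutpoint.max_statistic,
            "perm_p": self.cutpoint.perm_p,
            "n_low": self.cutpoint.n_low,
            "n_high": self.cutpoint.n_high,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hr": self.hazard_ratio.hr,
            "hr_ci95": list(self.hazard_ratio.ci95),
            "hr_wald_p": self.hazard_ratio.wald_p,
            "log_hr": self.hazard_ratio.beta,
            "log_hr_se": self.hazard_ratio.log_hr_se,
            "cox_diverged": self.hazard_ratio.diverged,
            "n_input": self.n_input,
            "n_dropped": self.n_dropped,
            "n_analyzed": self.n_analyzed,
        }


def stratified_analysis(
    scores: Mapping[str, float | None],
    records: Sequence[SurvivalRecord],
    q_low: float = 0.1,
    q_high: float = 0.9,
    n_perm: int = 1000,
    seed: int | None = None,
) -> StratifiedReport:
    """Join scores to survival, pick the maxstat cutpoint and quantify prognosis.

    ``scores`` maps subject_id → TAM-to-NK score (None/NaN dropped).
    Subjects missing a defined score or a survival record are dropped
    and counted in the report.
    """
    n_input = len(records)
    joined: list[tuple[SurvivalRecord, float]] = []
    for r in records:
        s = scores.get(r.subject_id)
        if s is None or (isinstance(s, float) and np.isnan(s)):
            continue
        joined.append((r, float(s)))
    n_analyzed = len(joined)
    if n_analyzed < 10:
        raise ValidationError(f"only {n_analyzed} subjects joined; need at least 10")
    recs = [r for r, _ in joined]
    vals = [s for _, s in joined]

    cut = maxstat_cutpoint(recs, vals, q_low=q_low, q_high=q_high, n_perm=n_perm, seed=seed)
    group = np.array(["low" if s <= cut.cutpoint else "high" for s in vals], dtype=object)
    low = [r for r, g in zip(recs, group) if g == "low"]
    high = [r for r, g in zip(recs, group) if g == "high"]
    chi2, p = logrank_test(low, high)
    hr = cox_binary_hr(recs, group, reference="high")
    return StratifiedReport(
        cutpoint=cut,
        km_low=km_estimate(low),
        km_high=km_estimate(high),
        logrank_chi2=chi2,
        logrank_p=p,
        hazard_ratio=hr,
        groups={r.subject_id: g for r, g in zip(recs, group)},
        n_input=n_input,
        n_dropped=n_input - n_analyzed,
        n_analyzed=n_analyzed,
    )


class MaxstatStratifier(BaseEstimator):
    """Estimator-shaped entry point for the survival stratification.

    ``fit(scores, y)`` takes a 1-D score array and ``y`` as an (n, 2)
    array of (time, event); fitted attributes expose the cutpoint and
    the downstream statistics; ``predict`` assigns "low"/"high" labels.
    """

    def __init__(
        self,
        q_low: float = 0.1,
        q_high: float = 0.9,
        n_perm: int = 1000,
        seed: int | None = None,
    ):
        self.q_low = q_low
        self.q_high = q_high
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X: Sequence[float], y: np.ndarray) -> "MaxstatStratifier":
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.size:
            raise ValidationError("y must be an (n, 2) array of (time, event)")
        records = [
            SurvivalRecord(f"S{i}", t, int(e)) for i, (t, e) in enumerate(y)
        ]
        report = stratified_analysis(
            {f"S{i}": s for i, s in enumerate(X)},
            records,
            q_low=self.q_low,
            q_high=self.q_high,
            n_perm=self.n_perm,
            seed=self.seed,
        )
        self.report_ = report
        self.cutpoint_ = report.cutpoint.cutpoint
        self.max_statistic_ = report.cutpoint.max_statistic
        self.perm_p_ = report.cutpoint.perm_p
        self.hazard_ratio_ = report.hazard_ratio.hr
        self.logrank_p_ = report.logrank_p
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        if not hasattr(self, "cutpoint_"):
            raise ContractError("MaxstatStratifier.predict called before fit")
        X = np.asarray(X, dtype=float).ravel()
        return np.where(X <= self.cutpoint_, "low", "high").astype(str)
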