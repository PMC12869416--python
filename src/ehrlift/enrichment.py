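"""Coverage-matched lift evaluation of risk scores against risk factors.

*Lift* is the ratio of outcome prevalence inside a flagged high-risk
group to prevalence in the whole evaluation population; equivalently
PPV / prevalence. *Coverage* is the flagged fraction of the population.
A risk factor defines its own high-risk group; a risk score defines one
at any coverage by thresholding. The central comparison is therefore
made at *equal coverage*: in each held-out fold the score's top-k group
is sized to the risk factor's flagged fraction in that fold, and the
two lifts are compared across folds with a one-sided Mann-Whitney test.

The combined variant keeps every risk-factor-positive individual and
fills the remaining slots with the highest-scoring factor-negative
individuals, tracing lift across a grid of target coverages; the grid
maximum is the "max lift by RF + model" summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .risk_factors import RiskFactorFlag

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LiftResult:
    """Enrichment of one flagged high-risk set, with its raw counts."""

    n_total: int
    n_flagged: int
    n_cases_total: int
    n_cases_flagged: int
    coverage: float
    prevalence: float
    ppv: float
    recall: float
    lift: float


def lift(labels, flags) -> LiftResult:
    """Lift of a flagged set over a labelled population.

    Raises if the population has no cases (prevalence undefined) or the
    flagged set is empty (PPV undefined) — the latter is deliberately
    distinct from a zero lift, which means "flagged but caught nobody".
    """
    labels = np.asarray(labels).astype(bool)
    flags = np.asarray(flags).astype(bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must have equal length")
    n_total = labels.size
    n_cases_total = int(labels.sum())
    if n_cases_total == 0:
        raise ValueError("population contains no cases; lift undefined")
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        raise ValueError("flagged set is empty; lift undefined (not zero)")
    n_cases_flagged = int((labels & flags).sum())
    prevalence = n_cases_total / n_total
    ppv = n_cases_flagged / n_flagged
    return LiftResult(
        n_total=n_total,
        n_flagged=n_flagged,
        n_cases_total=n_cases_total,
        n_cases_flagged=n_cases_flagged,
        coverage=n_flagged / n_total,
        prevalence=prevalence,
        ppv=ppv,
        recall=n_cases_flagged / n_cases_total,
        lift=ppv / prevalence,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _top_order(scores: np.ndarray, tie_key: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score, then ascending tie key."""
    return np.lexsort((tie_key, -scores))


def topk_flags(scores, target_coverage: float, tie_key=None) -> np.ndarray:
    """Flag the k = max(1, round(c·n)) highest scorers (half-up rounding).

    Ties are broken by descending score then ascending ``tie_key``
    (person id by default positional index), so the flagged set is a
    deterministic function of its inputs.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if not 0 < target_coverage <= 1:
        raise ValueError("target_coverage must be in (0, 1]")
    tie_key = np.arange(n) if tie_key is None else np.asarray(tie_key)
    k = max(1, _round_half_up(target_coverage * n))
    order = _top_order(scores, tie_key)
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return flags


def combined_flags(scores, rf_flags, target_coverage: float, tie_key=None) -> np.ndarray:
    """Risk-factor positives plus top-scoring negatives up to the target.

    The result is always a superset of ``rf_flags``: the total flagged
    count is max(|rf|, round(c·n)), filled from the highest-scoring
    factor-negative individuals. Raises if the target sits below the
    factor's own coverage.
    """
    scores = np.asarray(scores, dtype=float)
    rf_flags = np.asarray(rf_flags).astype(bool)
    n = scores.size
    if not 0 < target_coverage <= 1:
        raise ValueError("target_coverage must be in (0, 1]")
    n_rf = int(rf_flags.sum())
    if target_coverage * n < n_rf - 0.5:
        raise ValueError(
            f"target coverage {target_coverage:.4f} is below the risk factor's "
            f"coverage {n_rf / n:.4f}; use the risk factor alone"
        )
    total = max(n_rf, max(1, _round_half_up(target_coverage * n)))
    tie_key = np.arange(n) if tie_key is None else np.asarray(tie_key)
    flags = rf_flags.copy()
    need = total - n_rf
    if need > 0:
        neg = np.flatnonzero(~rf_flags)
        order = _top_order(scores[neg], tie_key[neg])
        flags[neg[order[:need]]] = True
    return flags


def fold_ci(
    values: Sequence[float], clip_low: float | None = 0.0
) -> tuple[float, float, float]:
    """Normal-approximation 95% CI across folds: mean ± 1.96·sd/√n.

    ``clip_low`` floors the lower bound (lifts cannot be negative);
    pass None to disable.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("fold CI requires at least 2 values")
    mean = float(values.mean())
    half = Z_95 * float(values.std(ddof=1)) / np.sqrt(values.size)
    lo, hi = mean - half, mean + half
    if clip_low is not None:
        lo = max(lo, clip_low)
    return mean, lo, hi


def mann_whitney_less(x, y) -> float:
    """One-sided Mann-Whitney p for "x stochastically less than y".

    Uses exact enumeration when both samples have ≤ 8 values and the
    pooled sample is tie-free; otherwise the tie-corrected normal
    approximation with continuity correction. A pooled sample with zero
    variance carries no evidence and returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and x.size <= 8 and y.size <= 8) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="less", method=method)
    return float(res.pvalue)


def paired_bootstrap_less(a, b, n_resamples: int = 1000, seed: int = 0) -> float:
    """One-sided paired bootstrap: p = P(mean(b − a) ≤ 0 over resamples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must be paired vectors of equal length")
    rng = np.random.default_rng(seed)
    diff = b - a
    idx = rng.integers(0, diff.size, size=(n_resamples, diff.size))
    means = diff[idx].mean(axis=1)
    return float(np.mean(means <= 0))


# ---------------------------------------------------------------------------
# fold-wise comparison


@dataclass(frozen=True)
class CurvePoint:
    """One target coverage on the combined RF + model curve."""

    target_coverage: float
    fold_lifts: tuple[float, ...]
    fold_results: tuple[LiftResult, ...]
    ci: tuple[float, float, float]
    p_vs_rf: float

    @property
    def mean_lift(self) -> float:
        return self.ci[0]


@dataclass
class ComparisonResult:
    """Coverage-matched comparison of one risk factor with the model."""

    rf_name: str
    rf_fold_results: list[LiftResult]
    ehr_fold_results: list[LiftResult]
    rf_ci: tuple[float, float, float]
    ehr_ci: tuple[float, float, float]
    mann_whitney_p: float
    dropped_folds: list[int] = field(default_factory=list)
    combined_curve: list[CurvePoint] = field(default_factory=list)
    max_combined: CurvePoint | None = None

    @property
    def rf_coverage(self) -> float:
        return float(np.mean([r.coverage for r in self.rf_fold_results]))


def _fold_groups(scored: pd.DataFrame):
    for fold_id, group in scored.sort_values("fold_id").groupby("fold_id"):
        yield int(fold_id), group


def matched_comparison(
    scored: pd.DataFrame, rf: RiskFactorFlag
) -> ComparisonResult:
    """Per-fold risk-factor lift vs model lift at matched coverage.

    In each held-out fold the model's high-risk group is sized to the
    risk factor's coverage *observed in that fold*; folds where the
    factor flags nobody (or that contain no cases) are dropped with a
    warning.
    """
    rf_results: list[LiftResult] = []
    ehr_results: list[LiftResult] = []
    dropped: list[int] = []
    for fold_id, group in _fold_groups(scored):
        labels = group["label"].to_numpy()
        person_ids = group["person_id"].to_numpy()
        rf_vals = rf.values_for(person_ids)
        if rf_vals.sum() == 0 or labels.sum() == 0:
            warnings.warn(
                f"fold {fold_id} dropped: risk factor {rf.name!r} flags nobody "
                "or fold has no cases",
                stacklevel=2,
            )
            dropped.append(fold_id)
            continue
        cov = rf_vals.mean()
        rf_results.append(lift(labels, rf_vals))
        ehr_flags = topk_flags(group["score"].to_numpy(), cov, tie_key=person_ids)
        ehr_results.append(lift(labels, ehr_flags))
    if not rf_results:
        raise ValueError(
            f"all folds dropped for risk factor {rf.name!r}; comparison undefined"
        )
    rf_lifts = [r.lift for r in rf_results]
    ehr_lifts = [r.lift for r in ehr_results]
    return ComparisonResult(
        rf_name=rf.name,
        rf_fold_results=rf_results,
        ehr_fold_results=ehr_results,
        rf_ci=fold_ci(rf_lifts),
        ehr_ci=fold_ci(ehr_lifts),
        mann_whitney_p=mann_whitney_less(rf_lifts, ehr_lifts),
        dropped_folds=dropped,
    )


def combined_curve(
    scored: pd.DataFrame,
    rf: RiskFactorFlag,
    coverage_grid: Sequence[float],
) -> tuple[list[CurvePoint], CurvePoint]:
    """Combined RF + model lift along a coverage grid, plus its maximum.

    Grid targets must be ascending and at or above the factor's
    coverage; within each fold the effective target is clamped up to
    that fold's factor coverage, so the factor positives are always
    retained in full.
    """
    grid = [float(c) for c in coverage_grid]
    if not grid:
        raise ValueError("coverage grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("coverage grid must be strictly ascending")

    folds = []
    rf_lifts = []
    for fold_id, group in _fold_groups(scored):
        labels = group["label"].to_numpy()
        person_ids = group["person_id"].to_numpy()
        rf_vals = rf.values_for(person_ids)
        if rf_vals.sum() == 0 or labels.sum() == 0:
            continue
        folds.append((labels, group["score"].to_numpy(), person_ids, rf_vals))
        rf_lifts.append(lift(labels, rf_vals).lift)
    if not folds:
        raise ValueError(f"no usable folds for risk factor {rf.name!r}")

    points: list[CurvePoint] = []
    for target in grid:
        fold_results = []
        for labels, scores, person_ids, rf_vals in folds:
            eff = max(target, rf_vals.mean())
            flags = combined_flags(scores, rf_vals, eff, tie_key=person_ids)
            fold_results.append(lift(labels, flags))
        lifts = [r.lift for r in fold_results]
        points.append(
            CurvePoint(
                target_coverage=target,
                fold_lifts=tuple(lifts),
                fold_results=tuple(fold_results),
                ci=fold_ci(lifts),
                p_vs_rf=mann_whitney_less(rf_lifts, lifts),
            )
        )
    best = max(points, key=lambda p: p.mean_lift)
    return points, best


def evaluate_risk_factor(
    scored: pd.DataFrame,
    rf: RiskFactorFlag,
    coverage_grid: Sequence[float] | None = None,
    grid_max: float = 0.30,
    grid_step: float = 0.01,
) -> ComparisonResult:
    """Full standalone + combined evaluation of one risk factor.

    The default combined grid runs from the factor's pooled coverage to
    ``grid_max`` in ``grid_step`` increments.
    """
    result = matched_comparison(scored, rf)
    if coverage_grid is None:
        start = result.rf_coverage
        grid = [start]
        c = np.ceil(start / grid_step) * grid_step
        while c <= grid_max + 1e-12:
            if c > start + 1e-12:
                grid.append(round(float(c), 10))
            c += grid_step
        coverage_grid = grid
    points, best = combined_curve(scored, rf, coverage_grid)
    result.combined_curve = points
    result.max_combined = best
    return result


# ---------------------------------------------------------------------------
# score-only summaries


def lift_at_coverage(scored: pd.DataFrame, coverage: float) -> list[LiftResult]:
    """Per-fold lift of the score's top-coverage group."""
    out = []
    for _, group in _fold_groups(scored):
        flags = topk_flags(
            group["score"].to_numpy(), coverage,
            tie_key=group["person_id"].to_numpy(),
        )
        out.append(lift(group["label"].to_numpy(), flags))
    return out


def candidate_coverage_range(
    scored: pd.DataFrame,
    ref_lift: float,
    grid: Sequence[float] | None = None,
) -> float | None:
    """Largest coverage at which mean out-of-fold lift stays ≥ ``ref_lift``.

    The reference is typically the best lift achieved by any known risk
    factor; the answer bounds a candidate threshold range for flagging.
    Default grid: 0.5% to 100% in 0.5% steps. Returns None when no
    grid coverage qualifies.
    """
    if ref_lift <= 0:
        raise ValueError("ref_lift must be > 0")
    if grid is None:
        grid = np.arange(0.005, 1.0 + 1e-9, 0.005)
    best = None
    for c in grid:
        mean_lift = float(np.mean([r.lift for r in lift_at_coverage(scored, c)]))
        if mean_lift >= ref_lift:
            best = float(c) if best is None else max(best, float(c))
    return best


def counterfactual_summary(labels, flags, index_dates, dx_dates) -> dict:
    """Counterfactual screening summary for one flagging rule.

    Reports how many people the rule would flag, how many true cancers
    it catches, the false-positive rate among the flagged, and the
    spread of index-to-diagnosis lead times for the catches.
    """
    labels = np.asarray(labels).astype(bool)
    flags = np.asarray(flags).astype(bool)
    index_dates = pd.DatetimeIndex(index_dates)
    dx_dates = pd.DatetimeIndex(dx_dates)
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return {
            "n_flagged": 0, "n_true_positive": 0, "n_false_positive": 0,
            "fp_rate": 0.0, "lead_time_days": None, "empty": True,
        }
    tp_mask = flags & labels
    n_tp = int(tp_mask.sum())
    n_fp = n_flagged - n_tp
    summary = {
        "n_flagged": n_flagged,
        "n_true_positive": n_tp,
        "n_false_positive": n_fp,
        "fp_rate": n_fp / n_flagged,
        "lead_time_days": None,
        "empty": False,
    }
    if n_tp:
        lead = (dx_dates[tp_mask] - index_dates[tp_mask]).days.to_numpy()
        summary["lead_time_days"] = {
            "min": int(lead.min()),
            "median": float(np.median(lead)),
            "max": int(lead.max()),
        }
    return summary
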