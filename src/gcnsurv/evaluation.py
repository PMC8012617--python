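"""Censoring-aware evaluation of prognostic risk scores.

Provides horizon classification (event by t years vs event-free at t) with
rank AUC and logistic accuracy, IPCW (Uno-type cumulative/dynamic)
time-dependent AUC, the IPCW Brier prediction-error curve, risk-group Cox
hazard ratios, and univariable odds ratios for clinical contingency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cox_core import CoxFit, predict_survival
from .datamodel_io import SurvivalTable
from .partial_cox import RiskGroupHR, RiskScoreTable, risk_group_hr

__all__ = [
    "EvaluationReport",
    "ContingencyResult",
    "HorizonMetrics",
    "horizon_labels",
    "horizon_metrics",
    "time_dependent_auc",
    "prediction_error",
    "univariable_or",
    "evaluation_report",
    "write_report",
]

EVENT_BY_T = "event_by_t"
EVENT_FREE = "event_free_at_t"
INEVALUABLE = "inevaluable"

DEFAULT_HORIZONS = (3.0, 5.0, 10.0, 15.0)


def horizon_labels(surv: SurvivalTable, t: float) -> pd.Series:
    """Classify each sample at horizon t: event by t, event-free at t, or
    inevaluable (censored before t)."""
    if t <= 0:
        raise ValueError("horizon must be positive")
    time, event = surv.time, surv.event
    lab = np.where(
        (event == 1) & (time <= t),
        EVENT_BY_T,
        np.where(time >= t, EVENT_FREE, INEVALUABLE),
    )
    return pd.Series(lab, index=surv.sample_ids, name=f"label@{t}")


def _scores_array(scores) -> np.ndarray:
    if isinstance(scores, RiskScoreTable):
        return scores.scores
    return np.asarray(scores, dtype=float)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordance of scores: P(pos > neg) with ties counted 1/2."""
    ns, nf = len(pos), len(neg)
    allr = stats.rankdata(np.r_[pos, neg])
    return (allr[:ns].sum() - ns * (ns + 1) / 2.0) / (ns * nf)


@dataclass
class HorizonMetrics:
    horizon: float
    n_evaluable: int
    n_events: int
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]
    flagged: bool = False  # single-class horizon: AUC/ACC undefined


def horizon_metrics(scores, labels: pd.Series) -> HorizonMetrics:
    """Accuracy and AUC of a risk score for the horizon classification.

    AUC is the rank concordance (ties 1/2) of score against the binary
    label, with a Hanley–McNeil confidence interval; accuracy comes from an
    unpenalized logistic fit of label on score, classifying at probability
    0.5.  Inevaluable samples are excluded.
    """
    s = _scores_array(scores)
    lab = labels.to_numpy()
    m = lab != INEVALUABLE
    y = (lab[m] == EVENT_BY_T).astype(int)
    sv = s[m]
    t = float(str(labels.name).split("@")[-1]) if labels.name else np.nan
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        return HorizonMetrics(t, len(y), n1, np.nan, np.nan, (np.nan, np.nan), flagged=True)
    auc = _rank_auc(sv[y == 1], sv[y == 0])
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    lr.fit(sv[:, None], y)
    pred = (lr.predict_proba(sv[:, None])[:, 1] >= 0.5).astype(int)
    acc = float((pred == y).mean())
    return HorizonMetrics(t, len(y), n1, acc, float(auc), ci)


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan–Meier estimate of the censoring survival function G.

    Returns (times, G) step values; evaluate with the helpers below.
    Censorings occurring at the same time as events are ranked after them
    (the usual convention: events first at tied times).
    """
    order = np.lexsort((1 - event, time))  # events (1) before censorings at ties
    t, e = time[order], event[order]
    n = len(t)
    at_risk = n - np.arange(n)
    uniq, start = np.unique(t, return_index=True)
    G = np.ones(len(uniq))
    g = 1.0
    for k, (u, s) in enumerate(zip(uniq, start)):
        stop = start[k + 1] if k + 1 < len(start) else n
        d_cens = int((e[s:stop] == 0).sum())
        n_risk = at_risk[s]
        if d_cens > 0:
            # censorings leave after events at the tied time
            n_eff = n_risk - int((e[s:stop] == 1).sum())
            g *= max(0.0, 1.0 - d_cens / n_eff) if n_eff > 0 else 0.0
        G[k] = g
    return uniq, G


def _eval_km(uniq: np.ndarray, G: np.ndarray, t: np.ndarray, *, left: bool = False) -> np.ndarray:
    t = np.asarray(t, float)
    side = "left" if left else "right"
    idx = np.searchsorted(uniq, t, side=side) - 1
    out = np.ones(len(t))
    ok = idx >= 0
    out[ok] = G[idx[ok]]
    return out


def time_dependent_auc(
    scores, surv: SurvivalTable, time_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """IPCW cumulative/dynamic AUC(t) over a time grid.

    Cases at t are samples with an observed event by t, weighted by
    1/G(T_i-) where G is the Kaplan–Meier censoring survival; controls are
    samples still at risk beyond t (their common weight cancels).  With no
    censoring this reduces exactly to the uncensored horizon AUC.  Grid
    points beyond the last observed time are dropped with a warning.
    """
    s = _scores_array(scores)
    time, event = surv.time, surv.event
    tmax = time.max()
    grid = np.asarray(list(time_grid), float)
    keep = grid <= tmax
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} grid time(s) beyond the last observed time",
            stacklevel=2,
        )
    grid = grid[keep]
    uniq, G = _censoring_km(time, event)
    w_case_all = 1.0 / np.clip(_eval_km(uniq, G, time, left=True), 1e-12, None)
    aucs = np.full(len(grid), np.nan)
    for k, t in enumerate(grid):
        case = (event == 1) & (time <= t)
        ctrl = time > t
        if not case.any() or not ctrl.any():
            continue
        sc, wc = s[case], w_case_all[case]
        sn = np.sort(s[ctrl])
        lo = np.searchsorted(sn, sc, side="left")
        hi = np.searchsorted(sn, sc, side="right")
        conc = lo + 0.5 * (hi - lo)
        aucs[k] = float((wc * conc).sum() / (wc.sum() * len(sn)))
    return grid, aucs


def prediction_error(
    pred, surv: SurvivalTable, time_grid: Sequence[float], *, X=None
) -> tuple[np.ndarray, np.ndarray]:
    """IPCW Brier score curve of predicted survival probabilities.

    ``pred`` is either a samples x grid matrix of predicted S(t | x), or a
    :class:`CoxFit` together with its design ``X`` (Breslow baseline).
    BS(t) averages (I(T>t) - S(t|x))^2 with inverse-censoring weights
    1/G(T-) for observed events by t and 1/G(t) for samples beyond t.
    """
    time, event = surv.time, surv.event
    tmax = time.max()
    grid = np.asarray(list(time_grid), float)
    keep = grid <= tmax
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} grid time(s) beyond the last observed time",
            stacklevel=2,
        )
    grid = grid[keep]
    if isinstance(pred, CoxFit):
        if X is None:
            raise ValueError("prediction from a CoxFit requires the design matrix X")
        S = predict_survival(pred, X, grid)
    else:
        S = np.asarray(pred, float)[:, keep]
    if S.shape != (len(surv), len(grid)):
        raise ValueError("predicted survival must be samples x grid")
    uniq, G = _censoring_km(time, event)
    w_event = 1.0 / np.clip(_eval_km(uniq, G, time, left=True), 1e-12, None)
    errs = np.empty(len(grid))
    n = len(surv)
    for k, t in enumerate(grid):
        g_t = max(float(_eval_km(uniq, G, np.array([t]))[0]), 1e-12)
        died = (event == 1) & (time <= t)
        alive = time > t
        term = np.zeros(n)
        term[died] = (S[died, k] ** 2) * w_event[died]
        term[alive] = ((1.0 - S[alive, k]) ** 2) / g_t
        errs[k] = float(term.sum() / n)
    return grid, errs


# ---------------------------------------------------------------------------
# contingency / odds ratios
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    """Univariable odds ratios of a (possibly k-level) factor for a binary
    outcome, with the underlying counts table.

    ``odds_ratios[level]`` is the cross-product odds ratio of that level
    against the reference level; p-values are logistic-regression Wald
    tests.  Zero cells flag the affected level (OR 0 or inf, p NaN).
    """

    counts: pd.DataFrame  # levels x {0, 1}
    reference: str
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    flagged_levels: list[str] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        (only,) = [lv for lv in self.counts.index if lv != self.reference] or [self.reference]
        return self.odds_ratios[only]

    @property
    def p(self) -> float:
        (only,) = [lv for lv in self.counts.index if lv != self.reference] or [self.reference]
        return self.p_values[only]


def univariable_or(x, y, *, reference=None) -> ContingencyResult:
    """Odds ratios of factor levels vs a reference for a binary outcome.

    For binary factors the OR equals the 2x2 cross-product ratio (a*d)/(b*c)
    exactly, and coincides with the exponentiated univariable logistic
    coefficient.  No continuity correction is applied: zero cells yield an
    infinite or zero OR and are flagged.
    """
    xs = pd.Series(x).astype(str)
    ys = pd.Series(np.asarray(y, dtype=int))
    if not ys.isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    if ys.nunique() < 2:
        raise ValueError("both outcome levels must be present")
    counts = pd.crosstab(xs, ys).reindex(columns=[0, 1], fill_value=0)
    counts.index.name = "level"
    levels = [str(lv) for lv in counts.index]
    ref = str(reference) if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among levels {levels}")
    a0 = float(counts.loc[ref, 0])
    a1 = float(counts.loc[ref, 1])
    ors: dict[str, float] = {}
    flagged: list[str] = []
    for lv in levels:
        if lv == ref:
            continue
        b0 = float(counts.loc[lv, 0])
        b1 = float(counts.loc[lv, 1])
        if 0 in (a0, a1, b0, b1):
            ors[lv] = np.inf if (b1 > 0 and a0 > 0) else 0.0
            flagged.append(lv)
        else:
            ors[lv] = (b1 * a0) / (b0 * a1)
    pvals = {lv: np.nan for lv in ors}
    if not flagged:
        import statsmodels.api as sm

        dummies = pd.get_dummies(xs, dtype=float).drop(columns=[ref])
        X = sm.add_constant(dummies[sorted(dummies.columns)])
        fit = sm.Logit(ys.to_numpy(), X.to_numpy()).fit(disp=0)
        for j, lv in enumerate(sorted(dummies.columns), start=1):
            pvals[str(lv)] = float(fit.pvalues[j])
    return ContingencyResult(
        counts=counts, reference=ref, odds_ratios=ors, p_values=pvals, flagged_levels=flagged
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    horizons: list[float]
    per_horizon: list[HorizonMetrics]
    td_auc_curve: tuple[np.ndarray, np.ndarray]
    pred_error_curve: tuple[np.ndarray, np.ndarray] | None
    risk_group: RiskGroupHR | None

    def horizon_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "horizon": h.horizon,
                    "n_evaluable": h.n_evaluable,
                    "n_events": h.n_events,
                    "accuracy": h.accuracy,
                    "auc": h.auc,
                    "auc_lo": h.auc_ci[0],
                    "auc_hi": h.auc_ci[1],
                }
                for h in self.per_horizon
            ]
        )


def evaluation_report(
    scores: RiskScoreTable,
    surv: SurvivalTable,
    *,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    time_grid: Sequence[float] | None = None,
    model: CoxFit | None = None,
    X=None,
    adjust: Sequence[str] = ("node",),
) -> EvaluationReport:
    """Assemble the full evaluation of one model's risk scores."""
    horizons = [h for h in horizons if h <= surv.time.max()]
    per_h = [horizon_metrics(scores, horizon_labels(surv, h)) for h in horizons]
    if time_grid is None:
        lo, hi = np.quantile(surv.time[surv.event == 1], [0.1, 0.9]) if surv.event.any() else (0, 0)
        time_grid = np.linspace(lo, hi, 20) if hi > lo else [surv.time.max() / 2]
    td = time_dependent_auc(scores, surv, time_grid)
    pe = None
    if model is not None and X is not None:
        pe = prediction_error(model, surv, time_grid, X=X)
    rg = None
    adjust_ok = all(np.isfinite(surv.covariate(c)).any() for c in adjust) if adjust else True
    if adjust_ok:
        try:
            rg = risk_group_hr(scores, surv, adjust=adjust)
        except ValueError:
            rg = None
    return EvaluationReport(list(horizons), per_h, td, pe, rg)


def write_report(report: EvaluationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-horizon metrics\n")
        fh.write(report.horizon_frame().to_csv(sep="\t", index=False))
        fh.write("# time-dependent AUC\n")
        t, a = report.td_auc_curve
        pd.DataFrame({"time": t, "auc": a}).to_csv(fh, sep="\t", index=False)
        if report.pred_error_curve is not None:
            fh.write("# prediction error\n")
            t, e = report.pred_error_curve
            pd.DataFrame({"time": t, "brier": e}).to_csv(fh, sep="\t", index=False)
        if report.risk_group is not None:
            rg = report.risk_group
            fh.write("# risk-group hazard ratios\n")
            fh.write("hr_continuous\tp_continuous\thr_high_vs_low\tp_high_vs_low\n")
            fh.write(f"{rg.hr_continuous}\t{rg.p_continuous}\t{rg.hr_high_vs_low}\t{rg.p_high_vs_low}\n")
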