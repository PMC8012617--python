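"""Cox proportional-hazards estimation and stepwise forward panel selection.

Implements the partial-likelihood Newton solver (Efron and Breslow tie
corrections), per-gene univariable screening adjusted for clinical
covariates, variance inflation factors, and the stepwise forward procedure
with significance-level-for-entry (SLE) 0.08, significance-level-for-stay
(SLS) 0.05 and a VIF < 10 collinearity guard — the selection rules used to
build the gene panels.

The solver is written directly on the partial likelihood so that both tie
corrections are available and so that the stepwise loop (hundreds of small
fits per panel) stays fast: risk-set sums are suffix cumulative sums, tied
event groups get the Efron correction only where ties actually occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ExpressionMatrix, SurvivalTable

__all__ = [
    "CoxFit",
    "StepwiseStep",
    "StepwiseTrace",
    "fit_cox",
    "predict_survival",
    "univariable_screen",
    "vif",
    "stepwise_forward",
]

_MAX_ITER = 100
_TOL = 1e-9
_ETA_CAP = 500.0  # |linear predictor| beyond this signals monotone likelihood


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``beta`` is on the log-hazard scale; ``hr = exp(beta)``.  ``loglik`` is
    the maximized partial log-likelihood, ``loglik_null`` its value at
    beta = 0.  ``converged`` is False when the likelihood is monotone
    (perfect separation) or Newton iteration failed.
    """

    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    loglik_null: float
    ties_method: str
    converged: bool
    n: int
    n_events: int
    # internals needed for prediction (Breslow baseline)
    _means: np.ndarray = field(repr=False, default=None)
    _bh_times: np.ndarray = field(repr=False, default=None)
    _bh_cumhaz: np.ndarray = field(repr=False, default=None)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_chi2(self) -> np.ndarray:
        return (self.beta / self.se) ** 2

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "p": self.wald_p,
            },
            index=self.covariate_names,
        )

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariate_names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "p": self.wald_p.tolist(),
            "hr": self.hr.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "ties_method": self.ties_method,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
        }


def _as_design(X, names: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(names)


def _surv_arrays(surv) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(surv, SurvivalTable):
        return surv.time, surv.event
    time, event = surv
    return np.asarray(time, float), np.asarray(event, int)


class _PartialLikelihood:
    """Precomputed event-time structure for one dataset."""

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str):
        order = np.argsort(time, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.t = time[order]
        self.d = event[order].astype(bool)
        self.ties = ties
        n = len(self.t)
        # unique-time group starts (risk set = suffix from group start)
        change = np.r_[True, self.t[1:] != self.t[:-1]]
        self.starts = np.nonzero(change)[0]
        gid = np.cumsum(change) - 1
        self.gid = gid
        n_groups = self.starts.size
        self.d_g = np.bincount(gid, weights=self.d.astype(float), minlength=n_groups)
        self.event_groups = np.nonzero(self.d_g > 0)[0]
        self.tied_groups = np.nonzero(self.d_g > 1)[0]
        self.p = X.shape[1]
        self.n = n

    def loglik(self, beta: np.ndarray) -> float:
        return self._eval(beta, order=0)[0]

    def loglik_grad_hess(self, beta: np.ndarray):
        return self._eval(beta, order=2)

    def _eval(self, beta: np.ndarray, order: int):
        X, d = self.X, self.d
        eta = X @ beta
        if np.max(np.abs(eta)) > _ETA_CAP:
            return (-np.inf, None, None) if order else (-np.inf,)
        w = np.exp(eta)
        c0 = np.cumsum(w[::-1])[::-1]
        eg = self.event_groups
        s0 = c0[self.starts[eg]]
        dg = self.d_g[eg]
        ll = float(eta[d].sum())
        if order >= 1:
            wX = w[:, None] * X
            c1 = np.cumsum(wX[::-1], axis=0)[::-1]
            s1 = c1[self.starts[eg]]
            wXX = wX[:, :, None] * X[:, None, :]
            c2 = np.cumsum(wXX[::-1], axis=0)[::-1]
            s2 = c2[self.starts[eg]]
            g = X[d].sum(axis=0)
            H = np.zeros((self.p, self.p))
        if self.ties == "breslow" or self.tied_groups.size == 0:
            ll -= float(dg @ np.log(s0))
            if order >= 1:
                r = s1 / s0[:, None]
                g -= dg @ r
                H -= np.einsum("g,gij->ij", dg / s0, s2)
                H += np.einsum("g,gi,gj->ij", dg, r, r)
        else:
            # Efron with ties: per event group, denominators shrink by l/d of
            # the tied-event mass; untied groups collapse to the Breslow term.
            for k, grp in enumerate(eg):
                start = self.starts[grp]
                stop = self.starts[grp + 1] if grp + 1 < self.starts.size else self.n
                members = np.arange(start, stop)
                ev = members[d[start:stop]]
                dk = int(round(dg[k]))
                D0 = w[ev].sum()
                frac = np.arange(dk) / dk
                denom = s0[k] - frac * D0
                ll -= float(np.log(denom).sum())
                if order >= 1:
                    D1 = wX[ev].sum(axis=0)
                    D2 = wXX[ev].sum(axis=0)
                    num1 = s1[k][None, :] - frac[:, None] * D1[None, :]
                    r = num1 / denom[:, None]
                    g -= r.sum(axis=0)
                    num2 = s2[k][None, :, :] - frac[:, None, None] * D2[None, :, :]
                    H -= np.einsum("l,lij->ij", 1.0 / denom, num2)
                    H += np.einsum("li,lj->ij", r, r)
        if order >= 1:
            return ll, g, H
        return (ll,)

    def breslow_cumhaz(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Breslow baseline cumulative hazard at the event times."""
        w = np.exp(self.X @ beta)
        c0 = np.cumsum(w[::-1])[::-1]
        eg = self.event_groups
        times = self.t[self.starts[eg]]
        h = self.d_g[eg] / c0[self.starts[eg]]
        return times, np.cumsum(h)


def fit_cox(X, surv, *, ties: str = "efron", names: Sequence[str] | None = None) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton iteration.

    ``X`` is a samples x covariates design (DataFrame or array), ``surv`` a
    :class:`SurvivalTable` or ``(time, event)`` pair.  Covariates are
    centered internally (invariant for beta, stabilizes exp()).  Standard
    errors come from the observed information; Wald p-values are two-sided
    normal.  Non-convergence and monotone likelihood are flagged, not raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    Xa, names = _as_design(X, names)
    time, event = _surv_arrays(surv)
    if Xa.shape[0] != len(time):
        raise ValueError("design and survival lengths differ")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("non-finite covariate values")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    sds = Xa.std(axis=0)
    if np.any(sds == 0):
        j = int(np.argmax(sds == 0))
        raise ValueError(f"constant covariate column {names[j]!r}")
    means = Xa.mean(axis=0)
    Xc = Xa - means
    pl = _PartialLikelihood(Xc, time, event, ties)

    p = Xc.shape[1]
    beta = np.zeros(p)
    ll0 = pl.loglik(beta)
    ll = ll0
    converged = False
    H = None
    for _ in range(_MAX_ITER):
        ll_cur, g, H = pl.loglik_grad_hess(beta)
        if not np.isfinite(ll_cur):
            break
        info = -H
        try:
            delta = np.linalg.solve(info, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(info + 1e-8 * np.eye(p), g)
        step = 1.0
        beta_new, ll_new = beta, -np.inf
        for _half in range(30):
            cand = beta + step * delta
            ll_cand = pl.loglik(cand)
            if ll_cand > ll_cur or np.isclose(ll_cand, ll_cur, rtol=0, atol=1e-13):
                beta_new, ll_new = cand, ll_cand
                break
            step /= 2.0
        else:
            beta_new, ll_new = beta, ll_cur
        if abs(ll_new - ll_cur) / (abs(ll_cur) + 1.0) < _TOL:
            beta, ll = beta_new, ll_new
            converged = True
            break
        beta, ll = beta_new, ll_new
    # monotone likelihood / separation: the per-SD log hazard drifts to
    # implausible magnitude and the information flattens out
    if np.max(np.abs(pl.X @ beta)) > _ETA_CAP * 0.9 or np.max(np.abs(beta) * sds) > 20.0:
        converged = False

    _, g, H = pl.loglik_grad_hess(beta)
    info = -H
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    bh_times, bh_cumhaz = pl.breslow_cumhaz(beta)
    return CoxFit(
        covariate_names=names,
        beta=beta,
        se=se,
        wald_p=wald_p,
        loglik=float(ll),
        loglik_null=float(ll0),
        ties_method=ties,
        converged=converged,
        n=pl.n,
        n_events=n_events,
        _means=means,
        _bh_times=bh_times,
        _bh_cumhaz=bh_cumhaz,
    )


def predict_survival(fit: CoxFit, X, times: np.ndarray) -> np.ndarray:
    """Predicted survival probabilities S(t | x) from the Breslow baseline.

    Returns a samples x times matrix.
    """
    Xa, _ = _as_design(X, fit.covariate_names)
    eta = (Xa - fit._means) @ fit.beta
    times = np.asarray(times, float)
    idx = np.searchsorted(fit._bh_times, times, side="right") - 1
    H0 = np.where(idx >= 0, fit._bh_cumhaz[np.clip(idx, 0, None)], 0.0)
    return np.exp(-np.outer(np.exp(eta), H0))


def _design_from(
    m: ExpressionMatrix | None,
    surv: SurvivalTable,
    genes: Sequence[str],
    clinical: Sequence[str],
) -> pd.DataFrame:
    cols = {}
    if genes:
        if m is None:
            raise ValueError("gene covariates requested but no expression matrix given")
        panel = m.panel(genes)
        if list(panel.index) != surv.sample_ids:
            panel = panel.loc[surv.sample_ids]
        for g in genes:
            cols[g] = panel[g].to_numpy()
    for c in clinical:
        cols[c] = surv.covariate(c)
    return pd.DataFrame(cols, index=surv.sample_ids)


def _drop_missing_adjusters(
    surv: SurvivalTable, adjust: Sequence[str]
) -> tuple[SurvivalTable, int]:
    if not adjust:
        return surv, 0
    ok = np.ones(len(surv), dtype=bool)
    for c in adjust:
        ok &= np.isfinite(surv.covariate(c))
    return surv.subset(ok), int((~ok).sum())


def univariable_screen(
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    genes: Sequence[str] | None = None,
    adjust: Sequence[str] = ("node",),
    ties: str = "efron",
) -> tuple[pd.DataFrame, int]:
    """Per-gene Cox fit (gene + adjusters); returns (table, n_dropped).

    The table is indexed by gene with columns beta, hr, p, converged.
    Samples with missing adjuster values are dropped once for the whole
    screen and counted.  Per-gene failures are flagged rows, never raised.
    """
    genes = list(genes) if genes is not None else list(m.gene_ids)
    surv_use, n_dropped = _drop_missing_adjusters(surv, adjust)
    m_use = m.subset_samples(surv_use.sample_ids)
    rows = []
    adj = np.column_stack([surv_use.covariate(c) for c in adjust]) if adjust else None
    gidx = m_use.gene_index(genes)
    for g, gi in zip(genes, gidx):
        x = m_use.values[gi]
        X = np.column_stack([x] + ([adj] if adj is not None else []))
        try:
            fit = fit_cox(X, surv_use, ties=ties, names=[g, *adjust])
            rows.append((g, fit.beta[0], float(np.exp(fit.beta[0])), fit.wald_p[0], fit.converged))
        except (ValueError, np.linalg.LinAlgError):
            rows.append((g, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(rows, columns=["gene", "beta", "hr", "p", "converged"]).set_index("gene")
    return out, n_dropped


def vif(X, *, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per covariate.

    R^2 is from an intercepted least-squares regression of each column on
    the remaining columns.  Exact collinearity yields +inf.
    """
    Xa, names = _as_design(X, names)
    n, p = Xa.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if n <= p:
        raise ValueError("VIF needs more samples than covariates")
    out = np.empty(p)
    for j in range(p):
        y = Xa[:, j]
        others = np.delete(Xa, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names)


@dataclass
class StepwiseStep:
    step: int
    action: str  # "enter" | "remove"
    covariate: str
    p_value: float
    vif_at_entry: float | None = None


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)
    final_covariates: list[str] = field(default_factory=list)
    n_dropped_samples: int = 0


def stepwise_forward(
    candidates: Sequence[str],
    m: ExpressionMatrix | None,
    surv: SurvivalTable,
    *,
    mandatory: Sequence[str] = ("node",),
    sle: float = 0.08,
    sls: float = 0.05,
    vif_max: float = 10.0,
    ties: str = "efron",
) -> tuple[CoxFit, StepwiseTrace]:
    """Stepwise forward Cox selection with SLE/SLS levels and a VIF guard.

    At each step the candidate with the smallest Wald p inside the augmented
    model enters, provided p <= sle and its VIF in the augmented design is
    <= vif_max (VIF-violating candidates are passed over).  After each entry
    any non-mandatory covariate with Wald p > sls is removed, worst first.
    Mandatory covariates sit in the model from step 0 and are never removed.
    Deterministic: ties in p are broken by covariate name.
    """
    candidates = list(dict.fromkeys(candidates))
    mandatory = list(mandatory)
    surv_use, n_dropped = _drop_missing_adjusters(surv, mandatory)
    if m is not None:
        m_use = m.subset_samples(surv_use.sample_ids)
    else:
        m_use = None
    trace = StepwiseTrace(n_dropped_samples=n_dropped)

    current: list[str] = []
    seen_states: set[frozenset] = set()
    step_no = 0

    def design(genes: Sequence[str]) -> pd.DataFrame:
        return _design_from(m_use, surv_use, list(genes), mandatory)

    def fit_model(genes: Sequence[str]) -> CoxFit:
        return fit_cox(design(genes), surv_use, ties=ties)

    while True:
        state = frozenset(current)
        if state in seen_states:
            break
        seen_states.add(state)
        # --- entry scan
        entries = []
        for cand in candidates:
            if cand in current:
                continue
            try:
                fit = fit_model([*current, cand])
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not fit.converged:
                continue
            p_cand = float(fit.wald_p[fit.covariate_names.index(cand)])
            entries.append((p_cand, cand, fit))
        entries.sort(key=lambda e: (e[0], e[1]))
        entered = None
        for p_cand, cand, fit in entries:
            if p_cand > sle:
                break
            D = design([*current, cand])
            v = float(vif(D)[cand]) if D.shape[1] >= 2 else 1.0
            if v <= vif_max:
                entered = (p_cand, cand, fit, v)
                break
        if entered is None:
            break
        step_no += 1
        p_cand, cand, fit, v = entered
        current.append(cand)
        trace.steps.append(StepwiseStep(step_no, "enter", cand, p_cand, v))
        # --- removal scan (worst first)
        while True:
            worst_p, worst = -1.0, None
            for name in current:
                p_name = float(fit.wald_p[fit.covariate_names.index(name)])
                if p_name > sls and p_name > worst_p:
                    worst_p, worst = p_name, name
            if worst is None:
                break
            current.remove(worst)
            trace.steps.append(StepwiseStep(step_no, "remove", worst, worst_p))
            if not current and not mandatory:
                break
            fit = fit_model(current)

    final_fit = fit_model(current) if (current or mandatory) else None
    if final_fit is None:
        raise ValueError("no covariates available: empty candidate and mandatory sets")
    trace.final_covariates = list(current)
    return final_fit, trace
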