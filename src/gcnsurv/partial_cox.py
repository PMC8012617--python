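"""Partial Cox regression: uncorrelated components, risk scores, risk groups.

Dimension reduction for censored outcomes in the style of partial least
squares: each component chi_k is a linear combination of the (residualized)
panel genes weighted by their univariable Cox coefficients, and the genes
are then residualized on chi_k so that successive components are mutually
uncorrelated in the training sample.  Components that are individually
prognostic (univariable Cox p < 0.05) are kept; a joint Cox fit on the kept
components gives the betas of the risk score

    riskscore_i = sum_k beta_k * chi_ik,

and patients are split into high/low risk at the natural cut-off of zero
(each component has training mean zero, so zero is the score's center).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cox_core import CoxFit, fit_cox
from .datamodel_io import SurvivalTable

__all__ = [
    "PartialCoxModel",
    "RiskScoreTable",
    "RiskGroupHR",
    "fit_partial_cox",
    "select_components",
    "risk_score",
    "risk_group_hr",
]

logger = logging.getLogger(__name__)


@dataclass
class PartialCoxModel:
    """Fitted partial Cox regression model.

    ``loadings`` maps centered panel expression (samples x genes) to
    component scores: ``chi = (X - training_means) @ loadings``.
    ``component_beta`` holds the joint-Cox coefficients of the selected
    components (zero for unselected).  ``cutoff`` (0) dichotomizes scores.
    """

    gene_names: list[str]
    training_means: np.ndarray
    loadings: np.ndarray  # genes x K
    component_beta: np.ndarray  # K, zeros where not selected
    component_p: np.ndarray  # K, univariable Cox p per component
    selected: np.ndarray  # K, bool
    cutoff: float = 0.0
    n_terminated_early: int = 0
    joint_fit: CoxFit | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def components(self, X) -> np.ndarray:
        """Component scores chi (samples x K) for a samples x genes panel."""
        Xa = _panel_array(X, self.gene_names)
        return (Xa - self.training_means) @ self.loadings

    def to_dict(self) -> dict:
        return {
            "gene_names": self.gene_names,
            "training_means": self.training_means.tolist(),
            "loadings": self.loadings.tolist(),
            "component_beta": self.component_beta.tolist(),
            "component_p": self.component_p.tolist(),
            "selected": self.selected.astype(bool).tolist(),
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartialCoxModel":
        return cls(
            gene_names=list(d["gene_names"]),
            training_means=np.asarray(d["training_means"], float),
            loadings=np.asarray(d["loadings"], float),
            component_beta=np.asarray(d["component_beta"], float),
            component_p=np.asarray(d["component_p"], float),
            selected=np.asarray(d["selected"], bool),
            cutoff=float(d["cutoff"]),
        )


@dataclass
class RiskScoreTable:
    """Per-sample risk score and zero-cutoff high/low group."""

    data: pd.DataFrame  # columns: sample_id, score, group

    @property
    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy()

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def __len__(self) -> int:
        return len(self.data)


def _panel_array(X, gene_names: Sequence[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [g for g in gene_names if g not in X.columns]
        if missing:
            raise KeyError(f"panel genes missing from input: {missing}")
        return X[list(gene_names)].to_numpy(dtype=float)
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    if Xa.shape[1] != len(gene_names):
        raise ValueError(
            f"panel has {len(gene_names)} genes but input has {Xa.shape[1]} columns"
        )
    return Xa


def fit_partial_cox(
    X,
    surv: SurvivalTable,
    *,
    n_components: int | None = None,
    gene_names: Sequence[str] | None = None,
    alpha: float = 0.05,
    ties: str = "efron",
) -> PartialCoxModel:
    """Extract mutually uncorrelated prognostic components from a gene panel.

    ``X`` is samples x genes (DataFrame with gene columns, or array plus
    ``gene_names``).  Component construction: center genes; at step k fit a
    univariable Cox model on each residual gene, weight genes by their
    coefficients (unit-normalized), form chi_k, then residualize every gene
    on chi_k by least squares.  Extraction stops early if the weights or the
    component variance degenerate.  Components with univariable Cox
    p < ``alpha`` are selected (falling back to the single smallest-p
    component if none qualifies) and refitted jointly.
    """
    if isinstance(X, pd.DataFrame):
        gene_names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        if gene_names is None:
            gene_names = [f"g{j}" for j in range(Xa.shape[1])]
        gene_names = list(gene_names)
    n, p = Xa.shape
    if int(surv.event.sum()) < 2:
        raise ValueError("need at least 2 events to fit a partial Cox model")
    if np.any(Xa.std(axis=0) == 0):
        bad = [gene_names[j] for j in np.nonzero(Xa.std(axis=0) == 0)[0]]
        raise ValueError(f"constant panel genes: {bad}")
    K = min(p, 5) if n_components is None else int(n_components)
    if not (1 <= K <= p):
        raise ValueError("n_components must be in [1, panel size]")

    means = Xa.mean(axis=0)
    cur = Xa - means
    P = np.eye(p)
    loadings = []
    n_terminated = 0
    for _k in range(K):
        gamma = np.zeros(p)
        for j in range(p):
            col = cur[:, j]
            if col.std() < 1e-10:
                continue
            try:
                f = fit_cox(col[:, None], surv, ties=ties, names=["x"])
            except (ValueError, np.linalg.LinAlgError):
                continue
            if f.converged:
                gamma[j] = f.beta[0]
        norm = np.linalg.norm(gamma)
        if norm < 1e-12:
            n_terminated = K - _k
            break
        w = gamma / norm
        chi = cur @ w
        var = float(chi @ chi)
        if var < 1e-12:
            n_terminated = K - _k
            break
        lk = P @ w
        loadings.append(lk)
        c = cur.T @ chi / var
        cur = cur - np.outer(chi, c)
        P = P - np.outer(lk, c)
    if not loadings:
        raise ValueError("no non-degenerate component could be extracted")
    if n_terminated:
        logger.info("component extraction terminated early; %d skipped", n_terminated)
    L = np.column_stack(loadings)
    model = PartialCoxModel(
        gene_names=gene_names,
        training_means=means,
        loadings=L,
        component_beta=np.zeros(L.shape[1]),
        component_p=np.full(L.shape[1], np.nan),
        selected=np.zeros(L.shape[1], dtype=bool),
        n_terminated_early=n_terminated,
    )
    chi_all = (Xa - means) @ L
    comp_p = np.empty(L.shape[1])
    for k in range(L.shape[1]):
        f = fit_cox(chi_all[:, [k]], surv, ties=ties, names=[f"chi{k + 1}"])
        comp_p[k] = f.wald_p[0]
    model.component_p = comp_p
    model._training_chi = chi_all
    model._surv = surv
    model._ties = ties
    return select_components(model, alpha=alpha, fallback_smallest=True)


def select_components(
    model: PartialCoxModel, alpha: float = 0.05, *, fallback_smallest: bool = False
) -> PartialCoxModel:
    """Keep components with univariable Cox p < alpha; refit betas jointly.

    With no component below alpha, raises unless ``fallback_smallest`` is
    set, in which case the single smallest-p component is retained (logged).
    """
    mask = model.component_p < alpha
    if not mask.any():
        if not fallback_smallest:
            raise ValueError(
                "no component passed selection; rerun with fallback_smallest=True "
                "to retain the single smallest-p component"
            )
        mask = np.zeros_like(mask)
        mask[int(np.nanargmin(model.component_p))] = True
        logger.info("component selection fell back to the smallest-p component")
    chi = getattr(model, "_training_chi", None)
    surv = getattr(model, "_surv", None)
    if chi is None or surv is None:
        raise ValueError("model lacks training data; refit with fit_partial_cox")
    ties = getattr(model, "_ties", "efron")
    joint = fit_cox(
        chi[:, mask],
        surv,
        ties=ties,
        names=[f"chi{k + 1}" for k in np.nonzero(mask)[0]],
    )
    beta = np.zeros(model.n_components)
    beta[mask] = joint.beta
    model.selected = mask
    model.component_beta = beta
    model.joint_fit = joint
    return model


def risk_score(model: PartialCoxModel, X, sample_ids: Sequence[str] | None = None) -> RiskScoreTable:
    """Formula-(2)-style risk scores and zero-cutoff high/low groups.

    ``score_i = sum_{k selected} beta_k chi_ik`` with components computed
    from expression centered at the training means; ``group`` is "high" iff
    score > cutoff (ties at the cutoff go to "low").
    """
    if isinstance(X, pd.DataFrame) and sample_ids is None:
        sample_ids = [str(i) for i in X.index]
    chi = model.components(X)
    scores = chi @ model.component_beta
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(scores))]
    groups = np.where(scores > model.cutoff, "high", "low")
    return RiskScoreTable(
        pd.DataFrame({"sample_id": list(sample_ids), "score": scores, "group": groups})
    )


@dataclass
class RiskGroupHR:
    hr_continuous: float
    p_continuous: float
    hr_high_vs_low: float
    p_high_vs_low: float
    categorical_flagged: bool = False


def risk_group_hr(
    scores: RiskScoreTable,
    surv: SurvivalTable,
    *,
    adjust: Sequence[str] = ("node",),
    ties: str = "efron",
) -> RiskGroupHR:
    """Cox hazard ratios of the risk score, continuous and dichotomized.

    Both fits are adjusted for the given clinical covariates (samples with
    missing adjusters dropped).  If one risk group is empty the categorical
    HR is flagged and returned as NaN; the continuous HR is still computed.
    """
    df = scores.data.set_index("sample_id").loc[surv.sample_ids]
    s = df["score"].to_numpy(dtype=float)
    hi = (df["group"] == "high").to_numpy(dtype=float)
    ok = np.ones(len(surv), dtype=bool)
    for c in adjust:
        ok &= np.isfinite(surv.covariate(c))
    surv_use = surv.subset(ok)
    adj = [surv_use.covariate(c) for c in adjust]
    X_cont = np.column_stack([s[ok], *adj])
    fit_c = fit_cox(X_cont, surv_use, ties=ties, names=["score", *adjust])
    hr_cont, p_cont = float(fit_c.hr[0]), float(fit_c.wald_p[0])
    hi_use = hi[ok]
    if hi_use.std() == 0:
        return RiskGroupHR(hr_cont, p_cont, np.nan, np.nan, categorical_flagged=True)
    X_cat = np.column_stack([hi_use, *adj])
    fit_g = fit_cox(X_cat, surv_use, ties=ties, names=["high_risk", *adjust])
    return RiskGroupHR(hr_cont, p_cont, float(fit_g.hr[0]), float(fit_g.wald_p[0]))
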