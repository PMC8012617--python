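"""Orchestration of the prognostic models.

Model 1 (reference) selects its panel from the seed genes alone; models
2-4 widen the candidate pool to the recurrence-stratum co-expression
network at decreasing correlation thresholds (0.82, 0.80, 0.79 in the
study design); model 5 — stepwise network modeling (SNM) — pools the final
genes of earlier models, filters them by adjusted univariable Cox
significance (p < 0.001) and hazard-ratio window (HR > 1.5 or < 0.7), and
refits.  Every model ends in a stepwise forward Cox panel plus a partial
Cox risk-score model; lymph-node status is a mandatory covariate
throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coexpression import build_gcn, network_gene_union, spearman_profile
from .cox_core import CoxFit, StepwiseTrace, stepwise_forward, univariable_screen
from .datamodel_io import ExpressionMatrix, SeedGeneSet, SurvivalTable
from .partial_cox import PartialCoxModel, RiskScoreTable, fit_partial_cox, risk_score

__all__ = [
    "GcnModelResult",
    "build_reference_model",
    "build_gcn_model",
    "snm",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.82, 0.80, 0.79)


@dataclass
class GcnModelResult:
    """One fitted prognostic model with its provenance."""

    model_id: int
    pool_provenance: str  # "seeds" | "gcn@r" | "snm-pool"
    input_gene_pool: list[str]
    final_genes: list[str]
    cox_fit: CoxFit
    trace: StepwiseTrace
    partial_cox: PartialCoxModel | None
    threshold_r: float | None = None

    def __post_init__(self) -> None:
        pool = set(self.input_gene_pool)
        extra = [g for g in self.final_genes if g not in pool]
        if extra:
            raise ValueError(f"final genes outside the input pool: {extra}")

    def scores(self, m: ExpressionMatrix) -> RiskScoreTable:
        if self.partial_cox is None:
            raise ValueError("model has no partial Cox component (empty panel)")
        return risk_score(self.partial_cox, m.panel(self.final_genes))

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "pool_provenance": self.pool_provenance,
            "input_gene_pool": self.input_gene_pool,
            "final_genes": self.final_genes,
            "threshold_r": self.threshold_r,
            "cox_fit": self.cox_fit.to_dict(),
            "partial_cox": None if self.partial_cox is None else self.partial_cox.to_dict(),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _finish_model(
    model_id: int,
    provenance: str,
    pool: list[str],
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    mandatory: Sequence[str],
    threshold_r: float | None = None,
    sle: float = 0.08,
    sls: float = 0.05,
    vif_max: float = 10.0,
) -> GcnModelResult:
    fit, trace = stepwise_forward(
        pool, m, surv, mandatory=mandatory, sle=sle, sls=sls, vif_max=vif_max
    )
    final = list(trace.final_covariates)
    pcox = None
    if final:
        ok = np.ones(len(surv), dtype=bool)
        for c in mandatory:
            ok &= np.isfinite(surv.covariate(c))
        surv_use = surv.subset(ok)
        panel = m.subset_samples(surv_use.sample_ids).panel(final)
        pcox = fit_partial_cox(panel, surv_use)
    return GcnModelResult(
        model_id=model_id,
        pool_provenance=provenance,
        input_gene_pool=pool,
        final_genes=final,
        cox_fit=fit,
        trace=trace,
        partial_cox=pcox,
        threshold_r=threshold_r,
    )


def build_reference_model(
    seeds: SeedGeneSet,
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    mandatory: Sequence[str] = ("node",),
    **stepwise_kw,
) -> GcnModelResult:
    """Model 1: stepwise Cox over the seed genes only."""
    present = seeds.present_in(m)
    if not present:
        raise ValueError("no seed gene is present in the expression matrix")
    return _finish_model(1, "seeds", sorted(present), m, surv, mandatory=mandatory, **stepwise_kw)


def build_gcn_model(
    threshold_r: float,
    seeds: SeedGeneSet,
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    model_id: int = 2,
    mandatory: Sequence[str] = ("node",),
    stratum_mask: np.ndarray | None = None,
    **stepwise_kw,
) -> GcnModelResult:
    """Models 2-4: stepwise Cox over the recurrence-stratum network pool.

    The candidate pool is the node union of the seed-anchored network built
    on the recurrence samples (event == 1) at ``threshold_r``, always
    including the seeds themselves.
    """
    present = seeds.present_in(m)
    if not present:
        raise ValueError("no seed gene is present in the expression matrix")
    seeds_here = SeedGeneSet(present)
    surv_al = surv.aligned_to(m)
    if stratum_mask is None:
        stratum_mask = surv_al.event == 1
    rho = spearman_profile(m, seeds_here, stratum_mask)
    net = build_gcn(rho, threshold_r, "recurrence")
    pool = sorted(set(network_gene_union([net])) | set(present))
    return _finish_model(
        model_id, f"gcn@{threshold_r}", pool, m, surv, mandatory=mandatory,
        threshold_r=threshold_r, **stepwise_kw,
    )


@dataclass
class SnmFilterRow:
    gene: str
    hr: float
    p: float
    passed: bool


def snm_filter(
    genes: Sequence[str],
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    p_max: float = 0.001,
    hr_lo: float = 0.7,
    hr_hi: float = 1.5,
    adjust: Sequence[str] = ("node",),
) -> list[SnmFilterRow]:
    """Adjusted univariable filter: keep p < p_max and HR outside [hr_lo, hr_hi].

    Boundary HRs exactly at 1.5 / 0.7 fail (strict inequalities).
    """
    screen, _ = univariable_screen(m, surv, genes=list(genes), adjust=adjust)
    rows = []
    for g in genes:
        hr = float(screen.loc[g, "hr"])
        p = float(screen.loc[g, "p"])
        passed = bool(np.isfinite(hr) and np.isfinite(p) and p < p_max and (hr > hr_hi or hr < hr_lo))
        rows.append(SnmFilterRow(g, hr, p, passed))
    return rows


def snm(
    models: Sequence[GcnModelResult],
    m: ExpressionMatrix,
    surv: SurvivalTable,
    *,
    p_max: float = 0.001,
    hr_lo: float = 0.7,
    hr_hi: float = 1.5,
    mandatory: Sequence[str] = ("node",),
    model_id: int = 5,
    **stepwise_kw,
) -> GcnModelResult:
    """Model 5 (stepwise network modeling): pool, filter, refit.

    Pools the final genes of the input models, keeps those passing the
    adjusted univariable significance and hazard-ratio window, and runs the
    stepwise + partial Cox pipeline on the survivors.
    """
    if not models:
        raise ValueError("SNM needs at least one input model")
    pool = sorted({g for res in models for g in res.final_genes})
    rows = snm_filter(pool, m, surv, p_max=p_max, hr_lo=hr_lo, hr_hi=hr_hi, adjust=mandatory)
    survivors = [r.gene for r in rows if r.passed]
    if not survivors:
        near = sorted(rows, key=lambda r: r.p if np.isfinite(r.p) else np.inf)[:10]
        detail = ", ".join(f"{r.gene}(hr={r.hr:.3g}, p={r.p:.3g})" for r in near)
        raise ValueError(f"SNM filter left no genes; nearest misses: {detail}")
    return _finish_model(
        model_id, "snm-pool", survivors, m, surv, mandatory=mandatory, **stepwise_kw
    )
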