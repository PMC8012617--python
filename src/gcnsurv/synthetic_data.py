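"""Synthetic expression + survival datasets with known ground truth.

Emulates the statistical structure the pipeline assumes in real cohorts:
blocks of genes Spearman-correlated with designated seed genes at
controlled strength (via the Gaussian-copula identity between Pearson and
Spearman correlation), relapse times from a proportional-hazards model
driven by a known subset of genes plus lymph-node status, independent
censoring calibrated to a target censoring fraction, and optional additive
batch shifts mimicking multi-dataset studies.

Default rates mirror the modeled cohort: ~900 samples, 34 seed genes, 12%
node-positive prevalence, 38% observed relapse (62% censoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel_io import ExpressionMatrix, SeedGeneSet, SurvivalTable

__all__ = [
    "CorrelationBlock",
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "make_canonical_scenario",
    "spearman_to_pearson",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: the Pearson correlation of a bivariate
    normal whose Spearman correlation is ``rho_s`` (rho_s = (6/pi) asin(r/2))."""
    if abs(rho_s) >= 1:
        raise ValueError("Spearman target must satisfy |rho| < 1")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class CorrelationBlock:
    seed_id: str
    n_partners: int
    spearman_rho: float

    def __post_init__(self) -> None:
        if not (0 < abs(self.spearman_rho) < 1):
            raise ValueError("block Spearman target must be in (0, 1) in magnitude")
        if self.n_partners < 1:
            raise ValueError("block needs at least one partner")


@dataclass
class SimulationConfig:
    """All knobs of one simulated cohort; identical config + seed gives an
    identical dataset."""

    n_samples: int = 900
    n_genes: int = 500  # total, including seeds and block partners
    n_seed_genes: int = 34
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    prognostic_genes: list[tuple[str, float]] = field(default_factory=list)  # (gene, log-HR)
    node_prevalence: float = 0.12
    node_log_hr: float = 0.6
    baseline: str = "exponential"  # or "weibull"
    baseline_rate: float = 0.08  # events per year at the reference profile
    weibull_shape: float = 1.0
    censoring_rate: float = 0.62  # target fraction censored
    n_datasets: int = 1
    batch_shift: float = 0.0
    expression_mean: float = 8.0  # log2-intensity location
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.node_prevalence <= 1):
            raise ValueError("node_prevalence must lie in [0, 1]")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.n_seed_genes > self.n_genes:
            raise ValueError("more seed genes than genes")
        n_partners = sum(b.n_partners for b in self.correlation_blocks)
        if self.n_seed_genes + n_partners > self.n_genes:
            raise ValueError("seeds + block partners exceed n_genes")

    @property
    def seed_ids(self) -> list[str]:
        return [f"SEED{i + 1:03d}" for i in range(self.n_seed_genes)]


@dataclass
class GroundTruth:
    prognostic_genes: dict[str, float]  # gene -> true log-HR
    block_members: dict[str, list[str]]  # seed -> partner genes
    linear_predictor: np.ndarray  # per sample, includes the node term
    censoring_rate_param: float
    node_log_hr: float


def _solve_censoring_rate(T: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with expected censored fraction
    E[1 - exp(-c T)] equal to the target, solved by bisection on the
    realized event times."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(1.0 - np.exp(-c * T)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Draw one cohort: expression, survival outcome, and its ground truth.

    Partner genes in a correlation block are generated as
    ``r * z_seed + sqrt(1 - r^2) * noise`` with r chosen so the implied
    Spearman correlation hits the block target.  Relapse times follow the
    proportional-hazards model on the standardized latent expression;
    censoring is independent exponential with its rate solved to match the
    configured censored fraction.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, G = config.n_samples, config.n_genes
    seed_ids = config.seed_ids
    seed_pos = {g: i for i, g in enumerate(seed_ids)}
    for b in config.correlation_blocks:
        if b.seed_id not in seed_pos:
            raise ValueError(f"block seed {b.seed_id!r} is not a seed gene")

    gene_ids = list(seed_ids)
    Z = np.empty((G, n))
    Z[: len(seed_ids)] = rng.standard_normal((len(seed_ids), n))
    block_members: dict[str, list[str]] = {}
    row = len(seed_ids)
    for b in config.correlation_blocks:
        r = spearman_to_pearson(b.spearman_rho)
        z_seed = Z[seed_pos[b.seed_id]]
        members = []
        for k in range(b.n_partners):
            gid = f"{b.seed_id}_P{k + 1:02d}"
            eps = rng.standard_normal(n)
            Z[row] = r * z_seed + np.sqrt(1.0 - r * r) * eps
            gene_ids.append(gid)
            members.append(gid)
            row += 1
        block_members[b.seed_id] = members
    n_filler = G - row
    for k in range(n_filler):
        gene_ids.append(f"GENE{k + 1:04d}")
    if n_filler:
        Z[row:] = rng.standard_normal((n_filler, n))

    gene_lookup = {g: i for i, g in enumerate(gene_ids)}
    truth_beta = dict(config.prognostic_genes)
    for g in truth_beta:
        if g not in gene_lookup:
            raise ValueError(f"prognostic gene {g!r} not in the simulated panel")

    node = (rng.random(n) < config.node_prevalence).astype(float)
    lp = config.node_log_hr * node
    for g, beta in truth_beta.items():
        lp = lp + beta * Z[gene_lookup[g]]

    u = rng.random(n)
    hazard = config.baseline_rate * np.exp(lp)
    if config.baseline == "exponential":
        T = -np.log(u) / hazard
    else:
        T = (-np.log(u) / hazard) ** (1.0 / config.weibull_shape)

    c_rate = _solve_censoring_rate(T, config.censoring_rate)
    if c_rate > 0:
        C = rng.exponential(1.0 / c_rate, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)

    values = config.expression_mean + Z
    if config.n_datasets > 1 and config.batch_shift != 0.0:
        batch = np.arange(n) % config.n_datasets
        values = values + config.batch_shift * batch[None, :]

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    m = ExpressionMatrix(gene_ids, sample_ids, values)
    clin = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "node": node,
            "er": (rng.random(n) < 0.79).astype(float),
            "grade": rng.choice([1.0, 2.0, 3.0], size=n, p=[0.23, 0.45, 0.32]),
            "size": np.round(np.exp(rng.normal(np.log(2.2), 0.4, size=n)), 2),
            "age": np.round(rng.normal(59, 13, size=n), 1),
        }
    )
    surv = SurvivalTable(clin)
    truth = GroundTruth(
        prognostic_genes=truth_beta,
        block_members=block_members,
        linear_predictor=lp,
        censoring_rate_param=c_rate,
        node_log_hr=config.node_log_hr,
    )
    return m, surv, truth


def make_canonical_scenario(
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth, SeedGeneSet]:
    """Canonical fixture encoding the central mechanism the pipeline probes.

    900 samples, 34 seed genes, eight co-expression blocks.  Three strongly
    prognostic genes are non-seed partners, so a seed-only model cannot see
    them while a network-widened candidate pool can; one mildly prognostic
    seed keeps the reference model non-trivial.  The prognostic blocks sit
    at Spearman 0.88 so that, after outcome-selection attenuation in the
    recurrence stratum (~ -0.01) and sampling noise (sd ~ 0.015 at ~340
    recurrence samples), their empirical correlation stays above the 0.82
    network threshold essentially always.
    """
    blocks = [
        CorrelationBlock("SEED001", 6, 0.88),
        CorrelationBlock("SEED002", 6, 0.88),
        CorrelationBlock("SEED003", 6, 0.88),
        CorrelationBlock("SEED004", 5, 0.84),
        CorrelationBlock("SEED005", 5, 0.83),
        CorrelationBlock("SEED006", 5, 0.82),
        CorrelationBlock("SEED007", 4, 0.81),
        CorrelationBlock("SEED008", 4, 0.80),
    ]
    config = SimulationConfig(
        n_samples=900,
        n_genes=400,
        correlation_blocks=blocks,
        prognostic_genes=[
            ("SEED001_P01", 0.6),
            ("SEED002_P01", 0.6),
            ("SEED003_P01", 0.5),
            ("SEED004", 0.4),
        ],
        rng_seed=rng_seed,
    )
    m, surv, truth = simulate(config)
    return m, surv, truth, SeedGeneSet(config.seed_ids)
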