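"""Core containers and preprocessing for expression/survival studies.

The pipeline operates on a log2-scale expression matrix (genes x samples),
a per-sample survival table (relapse-free survival time in years, event
indicator, clinical covariates), and a list of seed genes that anchor the
co-expression networks.  Three preprocessing steps are provided: collapsing
probe-level rows to genes by the per-sample median, quantile normalization,
and quantile-mapping a dataset's pooled value distribution onto that of a
reference dataset.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "SeedGeneSet",
    "CollapseReport",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_probe_map",
    "read_seed_genes",
    "collapse_probes",
    "quantile_normalize",
    "align_to_reference",
]

SURVIVAL_COLUMNS = ("sample_id", "time", "event", "node", "er", "grade", "size", "age")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for g in ids:
        if g in seen:
            dups.append(g)
        seen[g] = 1
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression intensities.

    Identifiers are case-sensitive exact strings; duplicates are rejected at
    construction.  ``values[i, j]`` is gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, idx])

    def panel(self, genes: Sequence[str]) -> pd.DataFrame:
        """Samples x genes design frame for a gene panel."""
        idx = self.gene_index(genes)
        return pd.DataFrame(self.values[idx].T, index=self.sample_ids, columns=list(genes))

    def assert_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            g, s = bad[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} ({len(bad)} total)"
            )


@dataclass
class SurvivalTable:
    """Per-sample relapse-free survival outcome and clinical covariates.

    ``time`` is follow-up in years, ``event`` is 1 for observed relapse and
    0 for censoring.  Clinical covariates (node, er, grade, size, age) may
    contain missing values (NaN); modeling code decides how to handle them.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing required column {col!r}")
        for col in SURVIVAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["sample_id"] = df["sample_id"].astype(str)
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        _check_unique(list(df["sample_id"]), "sample")
        if (df["time"] < 0).any():
            raise ValueError("survival times must be non-negative")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"unknown covariate {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def aligned_to(self, m: ExpressionMatrix) -> "SurvivalTable":
        """Reorder rows to the sample order of an expression matrix.

        Requires a one-to-one match between sample id sets.
        """
        here = set(self.sample_ids)
        there = set(m.sample_ids)
        if here != there:
            raise ValueError(
                f"sample mismatch: {sorted(there - here)[:5]} missing from survival, "
                f"{sorted(here - there)[:5]} missing from expression"
            )
        df = self.data.set_index("sample_id").loc[m.sample_ids].reset_index()
        return SurvivalTable(df)

    def subset(self, mask: np.ndarray) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[np.asarray(mask, bool)].reset_index(drop=True))


@dataclass
class SeedGeneSet:
    """The seed genes anchoring co-expression networks (34 in the study design)."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "seed gene")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def missing_from(self, m: ExpressionMatrix) -> list[str]:
        present = set(m.gene_ids)
        return [g for g in self.gene_ids if g not in present]

    def present_in(self, m: ExpressionMatrix) -> list[str]:
        present = set(m.gene_ids)
        return [g for g in self.gene_ids if g in present]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path, *, genes_in_rows: bool = True, sep: str | None = None
) -> ExpressionMatrix:
    """Read a delimited expression table into genes x samples orientation.

    The first column holds row identifiers, the header row column
    identifiers.  With ``genes_in_rows=False`` the on-disk table is
    samples x genes and is transposed on read.  Non-numeric cells and
    duplicate identifiers raise informative errors.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        body = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            raw_na = df[col].isna()
            bad = coerced.isna() & ~raw_na
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if not genes_in_rows:
        body = body.T
    return ExpressionMatrix.from_frame(body)


def write_expression(
    m: ExpressionMatrix, path: str | Path, *, genes_in_rows: bool = True, sep: str | None = None
) -> None:
    df = m.to_frame()
    if not genes_in_rows:
        df = df.T
    df.to_csv(path, sep=_sep_for(path, sep))


def read_survival(path: str | Path, *, sep: str | None = None) -> SurvivalTable:
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    return SurvivalTable(df)


def write_survival(t: SurvivalTable, path: str | Path, *, sep: str | None = None) -> None:
    t.data.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_probe_map(path: str | Path, *, sep: str | None = None) -> dict[str, str]:
    """Two-column (probe, gene) map; a probe may appear at most once."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe, gene")
    probes = df.iloc[:, 0].tolist()
    _check_unique(probes, "probe")
    return dict(zip(probes, df.iloc[:, 1].tolist()))


def read_seed_genes(path: str | Path) -> SeedGeneSet:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return SeedGeneSet([g for g in genes if g and not g.startswith("#")])


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass
class CollapseReport:
    n_probes_in: int
    n_genes_out: int
    n_unmapped: int
    unmapped_probes: list[str] = field(default_factory=list)


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, CollapseReport]:
    """Collapse probe-level rows to one row per gene by the per-sample median.

    Probes absent from the map are dropped and counted in the report.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    genes = np.array([probe_to_gene.get(p) for p in probe_matrix.gene_ids], dtype=object)
    mapped = np.array([g is not None for g in genes])
    unmapped = [p for p, ok in zip(probe_matrix.gene_ids, mapped) if not ok]
    df = pd.DataFrame(
        probe_matrix.values[mapped],
        index=pd.Index(genes[mapped].astype(str), name="gene"),
        columns=probe_matrix.sample_ids,
    )
    collapsed = df.groupby(level="gene", sort=True).median()
    out = ExpressionMatrix.from_frame(collapsed)
    report = CollapseReport(
        n_probes_in=probe_matrix.n_genes,
        n_genes_out=out.n_genes,
        n_unmapped=len(unmapped),
        unmapped_probes=unmapped,
    )
    return out, report


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the across-sample mean order statistics.

    Ties within a column receive the mean of the quantile values they span
    (the order-independent "ties = average" dialect), which makes the
    transform deterministic and idempotent.
    """
    vals = m.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("quantile normalization requires a complete matrix; "
                         "impute or filter missing values upstream")
    if m.n_samples < 1:
        raise ValueError("need at least one sample")
    mean_q = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = m.n_genes
    for j in range(m.n_samples):
        col = vals[:, j]
        idx = np.argsort(col, kind="stable")
        sc = col[idx]
        grp = np.empty(n, dtype=int)
        grp[0] = 0
        np.cumsum(sc[1:] != sc[:-1], out=grp[1:])
        gmeans = np.bincount(grp, weights=mean_q) / np.bincount(grp)
        out[idx, j] = gmeans[grp]
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), out)


def align_to_reference(target: ExpressionMatrix, reference: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-map the target's pooled value distribution onto the reference's.

    Every target value is replaced by the reference-pool quantile at its own
    pooled (mid-)rank — a monotone transform, so within-sample and
    within-gene orderings are preserved.  Used to put datasets measured on
    shifted scales onto the scale of a chosen reference dataset.
    """
    ref_pool = np.sort(reference.values, axis=None)
    if ref_pool.size == 0:
        raise ValueError("empty reference matrix")
    flat = target.values.ravel()
    if flat.size == 0:
        raise ValueError("empty target matrix")
    ranks = stats.rankdata(flat, method="average")
    if flat.size == 1:
        mapped = np.array([np.median(ref_pool)])
    else:
        q = (ranks - 1.0) / (flat.size - 1.0)
        mapped = np.quantile(ref_pool, q)
    return ExpressionMatrix(
        list(target.gene_ids), list(target.sample_ids), mapped.reshape(target.values.shape)
    )
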