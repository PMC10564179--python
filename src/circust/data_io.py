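"""Reading, preprocessing and writing of expression matrices and atlas tables.

The pipeline consumes a genes x samples matrix of expression values in
arbitrary units (counts, TPM, log-intensities -- whatever quantification the
study produced).  Preprocessing discards genes with too many zero counts and
rescales every gene row into [-1, 1] with a min-max map, which is the scale
on which the circular ordering and all rhythmicity fits operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cpca import SampleOrdering

log = logging.getLogger("circust")

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "filter_low_expression",
    "minmax_normalize",
    "write_atlas",
    "write_sample_times",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with identifiers and a processing state.

    ``state`` tracks where the matrix sits in the preprocessing chain:
    ``raw`` (as read), ``normalized`` (per-gene min-max into [-1, 1]) or
    ``ordered`` (columns arranged along the reconstructed circular order,
    with the ordering stored in ``order``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    state: str = "raw"
    order: Optional["SampleOrdering"] = None
    constant_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("column count does not match number of sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers not unique after upper-casing")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene.upper())
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.gene_ids

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset (case-insensitive); missing genes raise KeyError."""
        idx = [self.gene_index(g) for g in genes]
        return replace(
            self,
            values=self.values[idx].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            constant_genes={g for g in self.constant_genes
                            if g in {self.gene_ids[i] for i in idx}},
        )

    def drop_samples(self, indices: set[int]) -> "ExpressionMatrix":
        keep = [j for j in range(self.n_samples) if j not in indices]
        return replace(
            self,
            values=self.values[:, keep].copy(),
            sample_ids=[self.sample_ids[j] for j in keep],
            order=None,
        )

    def reorder_samples(self, permutation: np.ndarray,
                        order: Optional["SampleOrdering"] = None) -> "ExpressionMatrix":
        perm = np.asarray(permutation, dtype=int)
        return replace(
            self,
            values=self.values[:, perm].copy(),
            sample_ids=[self.sample_ids[j] for j in perm],
            state="ordered",
            order=order,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


# -- input ---------------------------------------------------------------------


def _infer_dialect(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".gct"):
        return "gct"
    if lower.endswith(".csv"):
        return "csv"
    return "tsv"


def read_expression(path: str, dialect: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples table (TSV, CSV or GCT 1.2) into an ExpressionMatrix.

    The first column holds gene identifiers and the header row sample
    identifiers.  The GCT dialect skips the two-line preamble and the
    Description column.  Duplicate gene symbols (case-insensitive) are
    resolved by keeping the row with the highest total expression.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect == "gct":
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=str)
        first = df.columns[0]
        if first.lower() in {"description", "desc"}:
            df = df.drop(columns=[first])
    elif dialect in {"tsv", "csv"}:
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unparseable numeric cell at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, found {numeric.shape[1]}")

    numeric.index = [str(g).upper() for g in numeric.index]
    if numeric.index.has_duplicates:
        totals = numeric.sum(axis=1)
        keep_rows = []
        seen: dict[str, int] = {}
        for pos, gene in enumerate(numeric.index):
            if gene not in seen:
                seen[gene] = pos
                keep_rows.append(pos)
            else:
                prev = seen[gene]
                if totals.iloc[pos] > totals.iloc[prev]:
                    keep_rows[keep_rows.index(prev)] = pos
                    seen[gene] = pos
                log.info("duplicate gene symbol %s: kept row with total %.6g",
                         gene, max(totals.iloc[pos], totals.iloc[prev]))
        numeric = numeric.iloc[keep_rows]

    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        gene_ids=list(numeric.index),
        sample_ids=list(numeric.columns),
        state="raw",
    )


# -- preprocessing -------------------------------------------------------------


def filter_low_expression(x: ExpressionMatrix, max_zero_frac: float = 0.30,
                          epsilon: float = 0.0) -> ExpressionMatrix:
    """Discard genes whose fraction of zero counts exceeds ``max_zero_frac``.

    A value counts as zero when its magnitude is <= ``epsilon`` (default 0,
    i.e. exact zeros on the input scale).  The boundary is inclusive on the
    keep side: a gene with exactly ``max_zero_frac`` zeros is retained.
    """
    if x.state != "raw":
        raise ValueError("low-expression filtering operates on the raw matrix")
    zero_frac = (np.abs(x.values) <= epsilon).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all genes removed by the zero-count filter")
    if n_removed:
        log.info("zero-count filter removed %d of %d genes", n_removed, x.n_genes)
    return replace(
        x,
        values=x.values[keep].copy(),
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
    )


def minmax_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Map each gene row into [-1, 1]: v -> 2 (v - min) / (max - min) - 1.

    Constant rows cannot be rescaled; they are mapped to all-zeros and
    recorded in ``constant_genes`` so that downstream rhythmicity fitting
    can exclude them.
    """
    vmin = x.values.min(axis=1, keepdims=True)
    vmax = x.values.max(axis=1, keepdims=True)
    span = vmax - vmin
    constant = span[:, 0] == 0
    safe_span = np.where(span == 0, 1.0, span)
    values = 2.0 * (x.values - vmin) / safe_span - 1.0
    values[constant] = 0.0
    flagged = {g for g, c in zip(x.gene_ids, constant) if c}
    if flagged:
        log.info("min-max normalization flagged %d constant gene(s)", len(flagged))
    return replace(x, values=values, state="normalized",
                   constant_genes=x.constant_genes | flagged)


# -- output --------------------------------------------------------------------


def write_atlas(atlas, path: str) -> None:
    """Write an atlas table as TSV, ranked from highest to lowest rhythmicity.

    Columns: gene, R2_med, tU_rad, tU_hours, omega_med, A_med, M_med,
    phase_class.  ``tU_hours = 24 * tU_rad / (2 pi)``; ``phase_class`` is
    ``active`` for peaks in [0, pi) and ``inactive`` for [pi, 2 pi).
    Values are written with 6 significant digits.
    """
    df = atlas.table.copy()
    out = pd.DataFrame({
        "gene": df["gene"],
        "R2_med": df["r2_med"],
        "tU_rad": df["tU_med"],
        "tU_hours": 24.0 * df["tU_med"] / (2.0 * np.pi),
        "omega_med": df["omega_med"],
        "A_med": df["A_med"],
        "M_med": df["M_med"],
        "phase_class": df["phase_class"],
    })
    out = out.sort_values("R2_med", ascending=False, kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sample_times(ordering, sample_ids: Sequence[str], path: str) -> None:
    """Write per-sample estimated angular times (radians and hours) as TSV."""
    theta = np.asarray(ordering.theta, dtype=float)
    outliers = ordering.outliers or set()
    df = pd.DataFrame({
        "sample_id": list(sample_ids),
        "theta_rad": theta,
        "theta_hours": 24.0 * theta / (2.0 * np.pi),
        "outlier_flag": [int(i in outliers) for i in range(len(sample_ids))],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
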