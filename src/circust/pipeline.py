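"""Orchestration of the four-step ordering-and-atlas pipeline.

Step 1 (preprocessing) removes zero-heavy genes and min-max normalizes.
Step 2 (preliminary order) runs circular PCA on the 12-seed-gene submatrix,
removes outlier samples, re-normalizes, orders and orients the cohort, and
gates on the median seed-gene FMM fit.  Step 3 screens genes with the fast
circular unimodal R2, fits the FMM wave to survivors, selects the TOP set
(sharp-spike-free omega > 0.1, R2 > 0.5, peaks covering all four quarters,
seed genes always included), and re-derives K orderings from random
two-thirds subsets of the TOP genes subject to angular-coverage validity
conditions.  Step 4 fits every TOP gene under each accepted ordering and
aggregates the K parameter estimates by medians (circular for the peak
phase) into the atlas table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cpca import (SampleOrdering, circular_order, compute_eigengenes,
                   detect_outlier_samples, orient, project_to_circle)
from .data_io import ExpressionMatrix, filter_low_expression, minmax_normalize
from .fmm import DEFAULT_GRID, FMMFit, GridSpec, fmm_fit_batch
from .metrics import angular_mad, circ_circ_rho, circular_correlation, \
    circular_median
from .ori import ori_fit

log = logging.getLogger("circust")

TWO_PI = 2.0 * np.pi

DEFAULT_SEED_GENES = ("PER1", "PER2", "PER3", "CRY1", "CRY2", "ARNTL",
                      "CLOCK", "NR1D1", "RORA", "DBP", "TEF", "STAT3")

__all__ = [
    "PipelineConfig",
    "AtlasTable",
    "RunResult",
    "parse_prior_text",
    "preliminary_order",
    "select_top_genes",
    "top_orderings",
    "robust_estimates",
    "run_circust",
]


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline."""

    seed_genes: tuple[str, ...] = DEFAULT_SEED_GENES
    K: int = 5
    subset_frac: float = 2.0 / 3.0
    max_zero_frac: float = 0.30
    zero_epsilon: float = 0.0
    min_r2_ori: float = 0.5
    min_r2_fmm: float = 0.5
    min_omega: float = 0.1
    quality_gate: float = 0.3
    rng_seed: int = 20230928
    max_subset_attempts: int = 200
    prior: Optional[Sequence[Sequence[Sequence[str]]]] = None
    seed_pair: tuple[str, str] = ("DBP", "ARNTL")
    fallback_pair: tuple[str, str] = ("DBP", "CRY2")
    force_past_gate: bool = False
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.subset_frac < 1.0):
            raise ValueError("subset_frac must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("max_zero_frac", "min_r2_ori", "min_r2_fmm",
                     "min_omega", "quality_gate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        self.seed_genes = tuple(g.upper() for g in self.seed_genes)


@dataclass
class AtlasTable:
    """Per-TOP-gene robust medians of the FMM features.

    Columns: gene, r2_med, tU_med (circular median, radians), omega_med,
    A_med, M_med, phase_class (active for peaks in [0, pi)), and
    n_valid_orderings.
    """

    table: pd.DataFrame


@dataclass
class RunResult:
    atlas: Optional[AtlasTable]
    ordering: Optional[SampleOrdering]
    matrix: Optional[ExpressionMatrix]
    report: dict


def parse_prior_text(text: str) -> list[list[list[str]]]:
    """Parse peak-precedence chains like ``{DBP} <= {CRY1,CRY2} <= {ARNTL}``
    (one chain per line) into nested gene-group lists."""
    chains = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        groups = []
        for part in line.replace("⪯", "<=").split("<="):
            part = part.strip().strip("{}")
            genes = [g.strip().upper() for g in part.split(",") if g.strip()]
            if genes:
                groups.append(genes)
        if len(groups) >= 2:
            chains.append(groups)
    return chains


def _max_circular_gap(theta: np.ndarray) -> float:
    """Largest gap between circularly consecutive angles."""
    s = np.sort(np.mod(theta, TWO_PI))
    if len(s) < 2:
        return TWO_PI
    gaps = np.diff(s)
    wrap = TWO_PI - (s[-1] - s[0])
    return float(max(gaps.max(), wrap))


# -- Step 2 --------------------------------------------------------------------


def preliminary_order(n: ExpressionMatrix, cfg: PipelineConfig
                      ) -> tuple[ExpressionMatrix, SampleOrdering, bool, dict]:
    """Seed-gene circular PCA: outlier removal, ordering, orientation, gate.

    Returns the column-reordered matrix, the ordering (theta sorted,
    aligned with the returned columns), the gate flag (True = passed) and a
    small diagnostics dict (outlier sample ids, median seed R2).
    """
    if n.state != "normalized":
        raise ValueError("preliminary_order expects a normalized matrix")
    seeds = [g for g in cfg.seed_genes if g in n and g not in n.constant_genes]
    if len(seeds) < 4:
        raise ValueError(
            f"only {len(seeds)} of the configured seed genes are present; "
            "at least 4 are required"
        )
    if len(seeds) < len(cfg.seed_genes):
        log.warning("only %d of %d seed genes present", len(seeds),
                    len(cfg.seed_genes))

    eig = compute_eigengenes(n.subset_genes(seeds))
    outliers: set[int] = set()
    if n.n_samples >= 10:
        outliers = detect_outlier_samples(eig)
    outlier_ids = [n.sample_ids[j] for j in sorted(outliers)]
    if outliers:
        log.info("removing %d outlier sample(s): %s", len(outliers),
                 ", ".join(outlier_ids))
        n = minmax_normalize(n.drop_samples(outliers))

    seed_sub = n.subset_genes(seeds)
    eig = compute_eigengenes(seed_sub)
    theta = project_to_circle(eig)
    ordering = orient(theta, seed_sub, seed_pair=cfg.seed_pair,
                      fallback_pair=cfg.fallback_pair, prior=cfg.prior,
                      grid=cfg.grid)

    fits = fmm_fit_batch(seed_sub.values, ordering.theta, cfg.grid)
    med_r2 = float(np.median([f.r2 for f in fits]))
    gate_passed = med_r2 >= cfg.quality_gate
    if not gate_passed:
        log.warning("quality gate failed: median seed R2 = %.3f < %.2f",
                    med_r2, cfg.quality_gate)

    perm = ordering.order
    sorted_ordering = SampleOrdering(
        theta=ordering.theta[perm],
        order=np.arange(n.n_samples),
        direction=ordering.direction,
        rotation=ordering.rotation,
    )
    x = n.reorder_samples(perm, order=sorted_ordering)
    diag = {"outlier_samples": outlier_ids, "gate_median_seed_r2": med_r2}
    return x, sorted_ordering, gate_passed, diag


# -- Step 3 --------------------------------------------------------------------

_QUARTERS = [(0.0, np.pi / 2), (np.pi / 2, np.pi),
             (np.pi, 3 * np.pi / 2), (3 * np.pi / 2, TWO_PI)]


def select_top_genes(x: ExpressionMatrix, ordering: SampleOrdering,
                     cfg: PipelineConfig
                     ) -> tuple[list[str], dict[str, FMMFit], list[str]]:
    """ORI screen, FMM fit, and TOP selection with quarter coverage.

    Returns (TOP gene list, per-gene FMM fits of all screened genes,
    coverage-added gene list).
    """
    theta = ordering.theta
    seeds = {g for g in cfg.seed_genes if g in x}
    candidates: list[int] = []
    for i, gene in enumerate(x.gene_ids):
        row = x.values[i]
        if np.ptp(row) == 0 or gene in x.constant_genes:
            continue
        if gene in seeds or ori_fit(row).r2 >= cfg.min_r2_ori:
            candidates.append(i)
    if not candidates:
        raise ValueError("no gene passed the ORI screen")
    log.info("ORI screen retained %d of %d genes", len(candidates), x.n_genes)

    fit_list = fmm_fit_batch(x.values[candidates], theta, cfg.grid)
    fits = {x.gene_ids[i]: f for i, f in zip(candidates, fit_list)}

    top = [g for g, f in fits.items()
           if f.params.omega > cfg.min_omega and f.r2 > cfg.min_r2_fmm]
    forced = [g for g in seeds if g not in top]
    if forced:
        log.info("forcing %d seed gene(s) into the TOP set: %s",
                 len(forced), ", ".join(sorted(forced)))
        top.extend(sorted(forced))

    coverage_added: list[str] = []
    top_peaks = [fits[g].t_u for g in top if fits[g].params.a > 0]
    for lo, hi in _QUARTERS:
        if any(lo <= t < hi for t in top_peaks):
            continue
        pool = [(fits[g].r2, g) for g in fits
                if g not in top and fits[g].params.omega > cfg.min_omega
                and fits[g].params.a > 0 and lo <= fits[g].t_u < hi]
        if pool:
            _, best_gene = max(pool)
            top.append(best_gene)
            coverage_added.append(best_gene)
            log.info("coverage-added gene %s for quarter [%.2f, %.2f)",
                     best_gene, lo, hi)
        else:
            log.warning("no candidate peaks in quarter [%.2f, %.2f)", lo, hi)
    if not top:
        raise ValueError("TOP selection produced no genes")
    # preserve input gene order for determinism
    order_index = {g: i for i, g in enumerate(x.gene_ids)}
    top = sorted(set(top), key=lambda g: order_index[g])
    return top, fits, coverage_added


def top_orderings(xtop: ExpressionMatrix, prelim: SampleOrdering,
                  cfg: PipelineConfig) -> list[SampleOrdering]:
    """K re-orderings from random 2/3 subsets of the TOP genes.

    A subset's ordering is accepted when (a) its angles span more than half
    the circle (circular span = 2 pi - largest gap > pi) and (b) its largest
    circular gap does not exceed the preliminary ordering's largest gap.
    When no draw satisfies (b) within the attempt budget -- which can happen
    on healthy cohorts whose preliminary gap is unusually small -- the
    span-passing orderings with the smallest gaps are used instead (with a
    loud warning), since (b)'s purpose is to reject subsets opening spurious
    holes, not to abort the run.  Only a cohort with no span-passing subset
    at all is a hard error.
    """
    if xtop.n_genes < 6:
        raise ValueError("need at least 6 TOP genes for subset re-orderings")
    rng = np.random.default_rng(cfg.rng_seed)
    size = math.ceil(cfg.subset_frac * xtop.n_genes)
    gap_pre = _max_circular_gap(prelim.theta)
    seeds_in_top = [g for g in cfg.seed_genes if g in xtop]

    accepted: list[SampleOrdering] = []
    near_misses: list[tuple[float, int, SampleOrdering]] = []
    stats = []
    for attempt in range(cfg.max_subset_attempts):
        if len(accepted) >= cfg.K:
            break
        idx = np.sort(rng.choice(xtop.n_genes, size=size, replace=False))
        sub = xtop.subset_genes([xtop.gene_ids[i] for i in idx])
        try:
            eig = compute_eigengenes(sub)
            theta = project_to_circle(eig)
            seed_sub = xtop.subset_genes(seeds_in_top) if seeds_in_top else sub
            ordering = orient(theta, seed_sub, seed_pair=cfg.seed_pair,
                              fallback_pair=cfg.fallback_pair, prior=cfg.prior,
                              grid=cfg.grid)
        except ValueError as exc:
            stats.append((attempt, "error", str(exc)))
            continue
        gap = _max_circular_gap(ordering.theta)
        span = TWO_PI - gap
        if span <= np.pi:
            stats.append((attempt, "span", span))
            continue
        if gap > gap_pre + 1e-12:
            stats.append((attempt, "gap", gap))
            near_misses.append((gap, attempt, ordering))
            continue
        accepted.append(ordering)
    if not accepted and not near_misses:
        raise ValueError(
            f"no subset ordering spans more than half the circle in "
            f"{cfg.max_subset_attempts} attempts; preliminary max gap "
            f"{gap_pre:.3f}; rejections: {stats[-5:]}"
        )
    if len(accepted) < cfg.K and near_misses:
        n_fill = min(cfg.K - len(accepted), len(near_misses))
        log.warning(
            "only %d subset ordering(s) met the gap condition "
            "(preliminary max gap %.3f); filling with the %d smallest-gap "
            "span-passing orderings", len(accepted), gap_pre, n_fill)
        near_misses.sort(key=lambda item: (item[0], item[1]))
        accepted.extend(o for _, _, o in near_misses[:n_fill])
    if len(accepted) < cfg.K:
        log.warning("accepted only %d of K=%d subset orderings",
                    len(accepted), cfg.K)
    return accepted


# -- Step 4 --------------------------------------------------------------------


def robust_estimates(xtop: ExpressionMatrix,
                     orderings: Sequence[SampleOrdering]) -> AtlasTable:
    """Median-aggregate the per-ordering FMM fits of every TOP gene.

    Ordinary medians for M, A, omega and R2; circular median for the peak
    phase t_U.  A gene failing to fit under some ordering loses that
    ordering (n_valid_orderings decremented) and is dropped if it fails
    under all.
    """
    if not orderings:
        raise ValueError("need at least one ordering")
    per_gene: dict[str, list[FMMFit]] = {g: [] for g in xtop.gene_ids}
    for ordering in orderings:
        fits = fmm_fit_batch(xtop.values, ordering.theta, skip_errors=True)
        for gene, fit in zip(xtop.gene_ids, fits):
            if fit is not None:
                per_gene[gene].append(fit)

    rows = []
    for gene in xtop.gene_ids:
        fits = per_gene[gene]
        if not fits:
            log.warning("gene %s failed to fit under every ordering; dropped",
                        gene)
            continue
        tu_med = circular_median([f.t_u for f in fits])
        rows.append({
            "gene": gene,
            "r2_med": float(np.median([f.r2 for f in fits])),
            "tU_med": tu_med,
            "omega_med": float(np.median([f.params.omega for f in fits])),
            "A_med": float(np.median([f.params.a for f in fits])),
            "M_med": float(np.median([f.params.m for f in fits])),
            "phase_class": "active" if tu_med < np.pi else "inactive",
            "n_valid_orderings": len(fits),
        })
    if not rows:
        raise ValueError("every TOP gene failed robust estimation")
    table = pd.DataFrame(rows).sort_values(
        "r2_med", ascending=False, kind="stable").reset_index(drop=True)
    return AtlasTable(table=table)


# -- full chain ----------------------------------------------------------------


def run_circust(raw: ExpressionMatrix, cfg: PipelineConfig | None = None,
                known_times: Optional[dict[str, float]] = None) -> RunResult:
    """Run the full chain raw -> preprocessing -> preliminary order ->
    TOP orderings -> robust atlas.

    ``known_times`` (sample id -> true angle in radians) is used only for
    validation metrics in the report, never by the estimation itself.
    When the seed quality gate fails the run stops after the preliminary
    order (unless ``cfg.force_past_gate``) and the atlas is None.
    """
    cfg = cfg or PipelineConfig()
    report: dict = {
        "n_genes_input": raw.n_genes,
        "n_samples_input": raw.n_samples,
        "K": cfg.K,
        "subset_frac": cfg.subset_frac,
        "rng_seed": cfg.rng_seed,
    }

    filtered = filter_low_expression(raw, cfg.max_zero_frac, cfg.zero_epsilon)
    report["n_genes_after_filter"] = filtered.n_genes
    normalized = minmax_normalize(filtered)

    x, ordering, gate_passed, diag = preliminary_order(normalized, cfg)
    report.update(diag)
    report["gate_status"] = "passed" if gate_passed else "failed"

    if known_times is not None:
        truth = np.array([known_times[s] for s in x.sample_ids])
        report["validation"] = _validation_metrics(ordering.theta, truth)

    if not gate_passed and not cfg.force_past_gate:
        log.warning("stopping after preliminary order (gate failed)")
        return RunResult(atlas=None, ordering=ordering, matrix=x,
                         report=report)

    top, _, coverage_added = select_top_genes(x, ordering, cfg)
    report["n_top"] = len(top)
    report["top_genes"] = top
    report["coverage_added"] = coverage_added

    xtop = x.subset_genes(top)
    orderings = top_orderings(xtop, ordering, cfg)
    report["n_orderings_accepted"] = len(orderings)

    atlas = robust_estimates(xtop, orderings)
    return RunResult(atlas=atlas, ordering=ordering, matrix=x, report=report)


def _validation_metrics(theta: np.ndarray, truth: np.ndarray) -> dict:
    out = {}
    try:
        out["circular_correlation"] = circular_correlation(theta, truth)
    except ValueError as exc:
        out["circular_correlation_error"] = str(exc)
    out["angular_mad_rad"] = angular_mad(theta, truth)
    out["circ_circ_rho"] = circ_circ_rho(truth, theta)
    return out
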