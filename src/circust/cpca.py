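"""Circular PCA: eigengenes, projection to the unit circle, outlier
detection, circular ordering and orientation by seed-gene peak constraints.

Two eigengenes (the leading right-singular vectors of a row-centered genes x
samples submatrix of rhythmic genes) span the plane in which rhythmic
samples trace an ellipse.  Whitening the two scores and taking the
two-argument arctangent places each sample on the unit circle, and sorting
the angles yields the circular order.  The circle leaves a starting point
and a direction undetermined (2m readings of the same order); those are
resolved by fitting the FMM wave to seed clock genes against the candidate
angles and requiring the canonical peak precedences (base rule: DBP peaks
before ARNTL along the counterclockwise arc), optionally refined by a
user-supplied chain of peak-order inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_io import ExpressionMatrix
from .fmm import DEFAULT_GRID, GridSpec, fmm_fit_batch

log = logging.getLogger("circust")

TWO_PI = 2.0 * np.pi

__all__ = [
    "SampleOrdering",
    "EigengenePair",
    "compute_eigengenes",
    "project_to_circle",
    "circular_order",
    "detect_outlier_samples",
    "orient",
]


@dataclass
class SampleOrdering:
    """Angular sample positions plus the derived circular order.

    ``theta`` holds one angle in [0, 2 pi) per sample (in column order of
    the matrix it was derived from), ``order`` the permutation sorting the
    angles from 0, ``direction`` and ``rotation`` the resolution of the
    reflection/starting-point ambiguity, and ``outliers`` sample indices
    removed before ordering.
    """

    theta: np.ndarray
    order: np.ndarray
    direction: str = "counterclockwise"
    rotation: float = 0.0
    outliers: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.theta = np.mod(np.asarray(self.theta, dtype=float), TWO_PI)
        self.order = np.asarray(self.order, dtype=int)
        self.rotation = float(np.mod(self.rotation, TWO_PI))

    @property
    def m(self) -> int:
        return len(self.theta)


@dataclass(frozen=True)
class EigengenePair:
    """First two eigengenes (scaled right-singular vectors) and the fraction
    of variance each explains."""

    e1: np.ndarray
    e2: np.ndarray
    explained: tuple[float, float]


def compute_eigengenes(x: ExpressionMatrix) -> EigengenePair:
    """Row-centered SVD of the genes x samples matrix; the first two right-
    singular vectors scaled by their singular values are the eigengenes.

    Sign convention: each eigengene's largest-magnitude entry is positive.
    Raises when the second singular value vanishes (no planar structure).
    """
    if x.state == "raw":
        raise ValueError("eigengenes require a normalized (or ordered) matrix")
    if x.n_genes < 2 or x.n_samples < 4:
        raise ValueError("need at least 2 genes and 4 samples")
    centered = x.values - x.values.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate circular structure: rank < 2")
    total = float((s**2).sum())
    comps = []
    for i in range(2):
        e = s[i] * vt[i]
        if e[np.argmax(np.abs(e))] < 0:
            e = -e
        comps.append(e)
    return EigengenePair(
        e1=comps[0],
        e2=comps[1],
        explained=(float(s[0] ** 2 / total), float(s[1] ** 2 / total)),
    )


def _whiten(e: np.ndarray) -> np.ndarray:
    centered = e - e.mean()
    sd = centered.std()
    if sd == 0:
        raise ValueError("degenerate eigengene: zero variance")
    return centered / sd


def project_to_circle(e: EigengenePair) -> np.ndarray:
    """Angles theta_j = atan2(e2_j, e1_j) of the whitened eigengene scores.

    Whitening (per-eigengene centering and unit-variance scaling) removes
    the ellipse eccentricity so angular coverage is not compressed along
    the minor axis.  Samples at the exact origin are flagged and assigned
    theta = 0.
    """
    w1 = _whiten(e.e1)
    w2 = _whiten(e.e2)
    radius = np.hypot(w1, w2)
    at_origin = radius < 1e-12
    theta = np.mod(np.arctan2(w2, w1), TWO_PI)
    if at_origin.any():
        log.warning("%d sample(s) at the projection origin; candidate outliers",
                    int(at_origin.sum()))
        theta[at_origin] = 0.0
    return theta


def circular_order(theta: Sequence[float]) -> np.ndarray:
    """Stable argsort of angles increasing from 0; ties keep input order."""
    theta = np.mod(np.asarray(theta, dtype=float), TWO_PI)
    return np.argsort(theta, kind="stable")


def detect_outlier_samples(e: EigengenePair) -> set[int]:
    """Samples whose whitened score radius deviates from the median by more
    than 3 robust standard deviations (1.4826 * MAD).

    At most max(1, floor(0.05 m)) samples are flagged, farthest first; with
    zero MAD only radii strictly different from the median can be flagged.
    Requires at least 10 samples.
    """
    if len(e.e1) < 10:
        raise ValueError("outlier detection needs at least 10 samples")
    r = np.hypot(_whiten(e.e1), _whiten(e.e2))
    med = float(np.median(r))
    dev = np.abs(r - med)
    mad = float(np.median(dev))
    if mad <= 1e-8 * max(med, 1e-300):
        # all radii (robustly) equal: only flag genuine departures, not
        # floating-point noise
        flagged = np.flatnonzero(dev > 1e-8 * max(med, 1e-300))
    else:
        flagged = np.flatnonzero(dev > 3.0 * 1.4826 * mad)
    cap = max(1, int(np.floor(0.05 * len(r))))
    if len(flagged) > cap:
        flagged = flagged[np.argsort(-dev[flagged], kind="stable")][:cap]
    return set(int(i) for i in flagged)


# -- orientation ---------------------------------------------------------------


def _peak_table(theta: np.ndarray, x: ExpressionMatrix,
                grid: GridSpec) -> dict[str, float]:
    fits = fmm_fit_batch(x.values, theta, grid)
    out = {}
    for gene, fit in zip(x.gene_ids, fits):
        if fit.params.a > 0:
            out[gene] = fit.t_u
    return out


def _active_count(peaks: dict[str, float], delta: float) -> int:
    return sum(1 for t in peaks.values() if np.mod(t + delta, TWO_PI) < np.pi)


def _best_rotation(peaks: dict[str, float],
                   anchor: str = "ARNTL") -> tuple[float, int]:
    """Rotation maximizing the number of peaks in the active half [0, pi).

    The count is piecewise constant in the rotation with breakpoints where a
    peak crosses 0, so rotations placing each peak at 0 are sufficient
    candidates.  Ties prefer the rotation setting the anchor gene's (ARNTL)
    peak to pi; otherwise the smallest rotation wins.
    """
    if not peaks:
        return 0.0, 0
    candidates = sorted(np.mod(-t, TWO_PI) for t in peaks.values())
    counts = [_active_count(peaks, d) for d in candidates]
    best = max(counts)
    if anchor in peaks:
        d_anchor = float(np.mod(np.pi - peaks[anchor], TWO_PI))
        if _active_count(peaks, d_anchor) == best:
            return d_anchor, best
    for d, c in zip(candidates, counts):
        if c == best:
            return float(d), best
    return 0.0, 0  # pragma: no cover


def _prior_count(peaks: dict[str, float],
                 prior: Sequence[Sequence[Sequence[str]]]) -> int:
    """Number of satisfied pairwise precedences in the prior chains.

    g1 <= g2 is satisfied when the counterclockwise arc from g1's peak to
    g2's peak is in (0, pi] (g1 peaks before g2 by less than half a cycle);
    this is rotation-invariant but direction-sensitive.
    """
    n = 0
    for chain in prior:
        for g_earlier, g_later in zip(chain[:-1], chain[1:]):
            for g1 in g_earlier:
                for g2 in g_later:
                    t1 = peaks.get(g1.upper())
                    t2 = peaks.get(g2.upper())
                    if t1 is None or t2 is None:
                        continue
                    arc = np.mod(t2 - t1, TWO_PI)
                    if 0 < arc <= np.pi:
                        n += 1
    return n


def orient(theta: Sequence[float], x: ExpressionMatrix,
           seed_pair: tuple[str, str] = ("DBP", "ARNTL"),
           fallback_pair: tuple[str, str] = ("DBP", "CRY2"),
           prior: Optional[Sequence[Sequence[Sequence[str]]]] = None,
           grid: GridSpec = DEFAULT_GRID) -> SampleOrdering:
    """Resolve direction and starting point of the candidate angles.

    ``x`` is the seed-gene submatrix (normalized); the FMM wave is fitted to
    every seed gene against the candidate angles, in both directions (theta
    and its reflection 2 pi - theta).  ``seed_pair = (early, late)`` names
    the one required precedence: the direction in which the early gene's
    peak precedes the late gene's along a counterclockwise arc shorter than
    pi is selected.  The rotation then maximizes the number of seed peaks in
    the active half-circle [0, pi), with ties anchored at ARNTL's peak = pi.
    With ``prior`` chains given, the direction satisfying more prior
    precedences is preferred provided it does not reduce the number of
    peaks in the active half.
    """
    theta = np.mod(np.asarray(theta, dtype=float), TWO_PI)
    pair = seed_pair
    if pair[0].upper() not in x or pair[1].upper() not in x:
        if fallback_pair[0].upper() in x and fallback_pair[1].upper() in x:
            log.warning("seed pair %s unavailable; falling back to %s",
                        seed_pair, fallback_pair)
            pair = fallback_pair
        else:
            raise ValueError(
                f"orientation seed pair {seed_pair} not found; configure a "
                f"fallback pair (default {fallback_pair}) present in the data"
            )
    early, late = pair[0].upper(), pair[1].upper()

    directions = {
        "counterclockwise": theta,
        "clockwise": np.mod(-theta, TWO_PI),
    }
    info = {}
    for name, th in directions.items():
        peaks = _peak_table(th, x, grid)
        if early not in peaks or late not in peaks:
            raise ValueError(
                f"seed gene {early if early not in peaks else late} fitted "
                "flat; cannot orient"
            )
        arc = float(np.mod(peaks[late] - peaks[early], TWO_PI))
        delta, active = _best_rotation(peaks)
        info[name] = {
            "theta": th, "peaks": peaks, "arc": arc,
            "rotation": delta, "active": active,
        }

    # base rule: the early gene precedes the late gene by an arc < pi
    if info["counterclockwise"]["arc"] <= info["clockwise"]["arc"]:
        base_dir = "counterclockwise"
    else:
        base_dir = "clockwise"

    chosen = base_dir
    if prior:
        pc = {name: _prior_count(d["peaks"], prior) for name, d in info.items()}
        prior_dir = max(info, key=lambda name: (pc[name], name == base_dir))
        if prior_dir != base_dir and \
                info[prior_dir]["active"] >= info[base_dir]["active"]:
            chosen = prior_dir
            log.info("prior precedences (%d vs %d) selected the %s direction",
                     pc[prior_dir], pc[base_dir], prior_dir)

    sel = info[chosen]
    theta_final = np.mod(sel["theta"] + sel["rotation"], TWO_PI)
    return SampleOrdering(
        theta=theta_final,
        order=circular_order(theta_final),
        direction=chosen,
        rotation=sel["rotation"],
    )
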