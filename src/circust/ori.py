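"""Order-restricted rhythmicity screening (circular "up-down-up" fit).

A rhythmic expression profile read along the circular sample order rises to
a single peak and falls to a single trough.  The ORI fit projects a profile
onto the cone of circularly unimodal sequences by searching every rotation
(trough cut point) and peak position, fitting each monotone arm by isotonic
least squares (pool-adjacent-violators).  Its R2 is a fast pre-filter:
genes with R2_ORI < 0.5 are discarded before the more expensive FMM fits.

For one rotation, the SSEs of isotonic fits on all prefixes (and antitonic
fits on all suffixes) are obtained in a single incremental PAVA sweep, so a
full fit costs O(m^2) amortized block merges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression

from .data_io import ExpressionMatrix

import logging

log = logging.getLogger("circust")

__all__ = ["ORIFit", "ori_fit", "ori_screen"]


@dataclass(frozen=True)
class ORIFit:
    r2: float
    peak_index: int
    trough_index: int
    fitted: np.ndarray


def _prefix_isotonic_sse(z: np.ndarray) -> np.ndarray:
    """sse[p] = SSE of the non-decreasing isotonic fit on z[0..p].

    Incremental PAVA: blocks are (mean, weight); merging blocks with means
    m1, m2 and weights w1, w2 adds w1*w2*(m1-m2)^2/(w1+w2) to the SSE.
    """
    m = len(z)
    out = np.empty(m)
    means: list[float] = []
    weights: list[float] = []
    total = 0.0
    for i in range(m):
        mu = float(z[i])
        w = 1.0
        while means and means[-1] > mu:
            m1, w1 = means.pop(), weights.pop()
            total += w1 * w * (m1 - mu) ** 2 / (w1 + w)
            mu = (w1 * m1 + w * mu) / (w1 + w)
            w += w1
        means.append(mu)
        weights.append(w)
        out[i] = total
    return out


def _suffix_antitonic_sse(z: np.ndarray) -> np.ndarray:
    """sse[p] = SSE of the non-increasing fit on z[p..m-1]; sse[m] = 0."""
    pref = _prefix_isotonic_sse(z[::-1])
    out = np.zeros(len(z) + 1)
    out[:-1] = pref[::-1]
    return out


def ori_fit(y: Sequence[float]) -> ORIFit:
    """Best circular unimodal (up-then-down) least-squares fit of y.

    Searches all m rotations and, within each, all peak positions; ties are
    broken lexicographically on (rotation, peak).  R2 = 1 - SSE/SST, with
    the convention R2 = 0 for constant input.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("ori_fit needs a 1-D sequence of length >= 4")
    m = len(y)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return ORIFit(r2=0.0, peak_index=0, trough_index=0, fitted=y.copy())

    best_sse = np.inf
    best_r = 0
    best_p = 0
    for r in range(m):
        z = np.roll(y, -r)
        up = _prefix_isotonic_sse(z)
        down = _suffix_antitonic_sse(z)
        sse_p = up + down[1:]
        p = int(np.argmin(sse_p))
        if sse_p[p] < best_sse - 1e-15:
            best_sse = float(sse_p[p])
            best_r, best_p = r, p

    z = np.roll(y, -best_r)
    arm_up = isotonic_regression(z[: best_p + 1], increasing=True).x
    fitted_rot = np.empty(m)
    fitted_rot[: best_p + 1] = arm_up
    if best_p + 1 < m:
        arm_down = isotonic_regression(z[best_p + 1:], increasing=False).x
        fitted_rot[best_p + 1:] = arm_down
    fitted = np.roll(fitted_rot, best_r)
    sse = float(((y - fitted) ** 2).sum())
    r2 = float(min(1.0, max(0.0, 1.0 - sse / sst)))
    return ORIFit(
        r2=r2,
        peak_index=int(np.argmax(fitted)),
        trough_index=int(np.argmin(fitted)),
        fitted=fitted,
    )


def ori_screen(x: ExpressionMatrix, min_r2: float = 0.5) -> ExpressionMatrix:
    """Retain genes whose circular unimodal fit reaches R2_ORI >= min_r2.

    Operates on a sample-ordered matrix (columns follow the circular order).
    Constant genes are always dropped (they carry no rhythmic signal).
    """
    if x.state != "ordered":
        raise ValueError("ori_screen expects an ordered matrix")
    keep = []
    for i, gene in enumerate(x.gene_ids):
        row = x.values[i]
        if np.ptp(row) == 0 or gene in x.constant_genes:
            continue
        if ori_fit(row).r2 >= min_r2:
            keep.append(i)
    if not keep:
        raise ValueError(
            "no gene passed the ORI screen; the preliminary ordering is "
            "likely uninformative (check the seed-gene quality gate)"
        )
    log.info("ORI screen retained %d of %d genes (%.1f%%)",
             len(keep), x.n_genes, 100.0 * len(keep) / x.n_genes)
    return _dc_replace(
        x,
        values=x.values[keep].copy(),
        gene_ids=[x.gene_ids[i] for i in keep],
    )
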